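# Methods

This note documents the statistical model, the default parameters and their
rationale, the synthetic-data generator, and the numerical choices made in
crispri-kit. It is the reference for anyone auditing the pipeline's
behaviour or re-deriving its results.

## 1. Library design

### Candidate enumeration

CRISPRi represses transcription most effectively when the sgRNA base-pairs
with the non-template (coding-sense) strand near the 5′ end of the ORF. A
candidate therefore exists at every coding-strand `CC` dinucleotide at
1-based positions (p−1, p) with 2 ≤ p ≤ L−21, so that the 23-nt protospacer +
PAM site lies fully inside the ORF; the 20-nt spacer is the reverse
complement of coding positions p+2..p+21 and the candidate is named
`gene_p`.

### Off-target penalty metric

A genomic site resembling a spacer is scored by summing per-mismatch
penalties that depend on where in the spacer the mismatch falls (1 = PAM-
distal, 20 = PAM-proximal):

| Region | Spacer positions | NGG penalty | NAG penalty |
|--------|------------------|-------------|-------------|
| III    | 1–8              | 2.5         | 3           |
| II     | 9–13             | 4.5         | 7           |
| I (seed)| 14–20           | 8           | 10          |

Sites with any other PAM get 100 per mismatch (effectively never
significant). A site is *significant* — and the candidate rejected — when
its total penalty is **strictly below** the design threshold: 21 in
genome-scale mode, 11 in tiling mode. Low penalty means a plausible
off-target (few, PAM-distal mismatches); the seed region and the NGG PAM
dominate binding, so seed mismatches are weighted heaviest. Two worked
examples pin the arithmetic: NGG with two Region-I and one Region-II
mismatch scores 2×8 + 4.5 = 20.5 (< 21, rejected in genome mode); NGG with
one Region-I and one Region-III mismatch scores 8 + 2.5 = 10.5 (< 11,
rejected in tiling mode).

The search considers both strands, allows at most 5 mismatches, and treats
ambiguous genome bases as mismatching every spacer base. Perfect sites
inside the candidate's own gene cluster are exempt (they are the on-target).
The implementation uses an integer-encoded genome index; the test suite
checks exact set equality against a naive 23-mer scan.

### Filtering, selection, clustering, negative controls

- GC content must lie in [0.30, 0.85] (inclusive); extreme-GC spacers are
  poor binders and bias synthesis and PCR.
- Genome mode keeps up to 15 sgRNAs per gene: all candidates in the *active
  region* (first 5% of the ORF, where repression is strongest) come first,
  5′-most first; the remainder is filled by evenly spaced rank quantiles of
  the remaining 5′→3′-ordered candidates. Tiling mode keeps the first 50.
- Genes with >95% sequence identity over >95% mutual coverage (global
  alignment via edlib) are collapsed into clusters targeted jointly, since
  their sgRNAs cannot distinguish the copies; the representative is the
  longest member (ties lexicographic).
- 400 negative-control spacers are drawn by rejection sampling: random
  20-mers within GC bounds and with **no** site anywhere in the genome at ≤5
  mismatches under the design threshold. They carry no target and define
  the experimental null.

## 2. Read counting

Reads longer than 194 nt are discarded (longer molecules indicate cassette
concatemers). Ends are trimmed while the terminal base quality is < Q25; a
read is kept only if, after trimming, it has zero bases below Q10, more than
85% of bases ≥ Q20, and more than 60% ≥ Q30 (strict inequalities). The
spacer is the 20 nt between an exact `GCAC` and `GTTT` flank, searched first
on the forward read then on its reverse complement, taking the first valid
cassette. Counting is exact-match against the designed spacers — with a
designed library there is no read-mapping ambiguity to resolve, and
near-miss tolerance would double-count sequencing errors.

Counts are normalized per library by `factor = total / mean(totals)` so all
libraries have equal effective size; sgRNAs with fewer than 20 reads in the
reference (initial/control) library are removed (exactly 20 is kept), since
their fold changes are dominated by shot noise. Biological replicates are
combined by the geometric mean (zero in either replicate → zero), which
averages log-fold-changes rather than counts.

## 3. Screen statistics

### sgRNA fitness

`fitness' = log2((n_sel + 1) / (n_ctrl + 1))`, then centred by subtracting
the median fitness' of the negative controls — this removes the
compositional shift that depletion of essential genes imposes on everything
else. Z-scores divide by σ, the maximum-likelihood (ddof = 0) standard
deviation of a normal fit to the NC fitness values. sgRNAs with |Z| ≥ 2 are
called *active*.

### Gene scores and the quasi-gene null

sgRNAs of a gene are ordered 5′→3′ and every prefix subset M = 1..N is
scored: `S_M = |median(fitness_1..M)| × (−log10 P_M)` with P_M a two-tailed
Mann–Whitney U test of the subset against the negative controls. Working on
prefixes reflects the positional activity bias: the 5′-proximal sgRNAs are
the most repressive, so the most informative subset is a prefix.

The null distribution of S_M comes from *quasi genes*: random size-M subsets
of the 400 NCs, scored identically. Size 1 uses all 400 singletons; sizes
2..15 draw `n_quasi` subsets each (default 10,000). A gene's S_M maps to an
empirical FPR by linear interpolation in its size-M quasi score
distribution, clamped to [1/(2·n_set), 1]; the gene takes the subset with
minimal FPR, ties broken toward smaller M.

### Two calibration layers (implementation choices)

Two adjustments are needed to make the reported FPR actually uniform on null
genes — the property that both the FDR machinery and any sensible reading of
"false positive rate" require:

1. **Leave-subset-out quasi scoring.** A quasi gene is a subset of the very
   NC set it is tested against; self-ties compress its score range relative
   to an independent null gene. Each quasi subset is therefore scored
   against the 400 − M NCs *excluding its own members* (vectorized rank
   computation), which makes the quasi score distribution match that of a
   fresh null gene.
2. **Selection-adjusted FPR.** Taking the minimum FPR over M = 1..N is a
   selection step: the minimum of N dependent, individually-uniform
   variables is stochastically smaller than uniform. The null model
   additionally records, per gene size N, the null distribution of the
   min-over-prefixes FPR computed from the same quasi genes; the reported
   per-gene `fpr` is the empirical probability that a null gene of the same
   size attains an equal or smaller minimum. The unadjusted value is kept
   as `fpr_raw`. The chosen subset (argmin) is unchanged.

Without these, a fully null screen reports ~24% of genes below FPR 0.05 and
the q-value machinery collapses; with them, the fraction of null genes below
α matches α within binomial error at α ∈ {0.01, 0.05, 0.1}.

On the scoring path, all Mann–Whitney P-values (genes and quasi genes alike)
use the tie-corrected normal approximation with continuity correction so the
calibration compares like with like; with 400 reference NCs the exact test
would never be selected anyway. The standalone `mwu_test` helper defaults
to the conventional rule (exact when the smaller sample has ≤ 8 values and
there are no ties) and is verified against exhaustive permutation.

### q-values and calls

Storey q-values with π₀ = min(1, #{FPR > 0.5} / (0.5·m)): FPRs above 0.5
should be uniform for true nulls, so their density estimates the null
fraction. q = reverse cumulative minimum of π₀·m·FPR/rank, capped at 1.
Hits are genes with q below the chosen FDR (default 0.05). Genes with
fitness ≤ −6 are flagged `no_doubling` (complete growth arrest at the
experiment's ~6 doublings); an essential-gene exclusion list collects genes
with fitness ≤ −4 and q ≤ 0.01.

`resolution_limit(depth, doublings) = min(log2 depth, doublings)` bounds the
measurable depletion: at 100× depth an sgRNA that vanishes entirely still
shows only ≈ −log2(100) ≈ −6.6 before pseudocounts, and the organism itself
only doubles `doublings` times. This is why planted −6 effects at 100×
depth are recovered around −4.5 to −5.5.

## 4. Benchmark classifiers

Three essentiality scores on [0, 1], compared by ROC-AUC (scikit-learn; the
test suite pins the AUC to an O(n²) concordance oracle with tie weight 0.5):

- **CRISPRi**: `1 − FPR` if gene fitness < 0, else 0.
- **Insertion index**: a gene is *required* if unique insertions / length
  < 0.00125; its score is `1 − exp(−local_index × length)` with the local
  index the insertion count in a 10-kb window centred on the gene midpoint
  divided by 10,000 (the divisor stays 10,000 when the window is truncated
  at a chromosome end). Dense genes score 0.
- **Footprinting-style**: `1 − P` if called essential, else 0.

## 5. Synthetic fixtures

The generator produces everything the analysis consumes, with ground truth:

- **Genomes**: random chromosomes with non-overlapping ATG…stop ORFs on
  random strands, optional near-identical duplicate gene pairs (~0.4%
  substitutions) to exercise clustering, written as FASTA + GFF3.
- **Screens**: initial abundances uniform (or spread 10-fold), selective
  abundance `initial × 2^(activity × effect)`, and
  `round(depth × n_sgRNAs)` multinomial reads per library, two replicates.
  sgRNA activities are Beta(2, 2) draws, shifted upward by
  `active_region_boost` inside the first 5% of the ORF and clipped to
  [0, 1].
- **Reads**: random background with the `GCAC + spacer + GTTT` cassette at a
  random offset in random orientation; optional uniform substitution
  errors. Backgrounds that coincidentally spell a second cassette are
  redrawn, so error-free reads round-trip exactly through extraction.
- **Insertions**: Bernoulli-per-bp positions with insertions removed from
  essential gene bodies.

**`active_region_boost` default (0.4).** The mean of Beta(2, 2) is 0.5, so
without an uplift even a lethal gene's sgRNAs would average only half the
planted effect and a screen could not recover planted fitness values. The
default shifts in-region activities to a mean of ≈ 0.85 with substantial
mass at 1.0, matching the empirical picture that 5′-proximal sgRNAs of
strongly depleted genes are nearly all highly active, and making planted
effects recoverable through the 5′-prefix scoring path. The parameter is
exposed so other regimes can be simulated.

What the generator does **not** emulate: operon polarity (silencing a gene
also silences downstream genes in its transcription unit), PCR jackpot
amplification, cross-contamination between libraries, position-dependent
sequencing error profiles, or growth-rate-dependent copy-number gradients
along the replichore. Benchmarks on these fixtures therefore bound the
statistical machinery, not protocol artifacts.

## 6. Problem sizes in the test suite

The acceptance tests run at desk scale, chosen as the smallest sizes at
which the statistical claims are testable at their stated tolerances:

- Null calibration: 1,000 genes × 10 sgRNAs + 400 NCs at 100× depth,
  n_quasi = 10,000, pooled over 16 seeded screens (within one screen all
  genes share one estimated null model, so per-screen fractions are
  over-dispersed relative to binomial; pooling restores the nominal
  binomial error bound).
- FDR control / recovery: 20 seeded screens of 200 genes × 15 sgRNAs + 400
  NCs, 10% of genes planted at effect −6, 100× depth, n_quasi = 2,000.
- Oracle equivalences: ≤10-kb genomes for the off-target scan, samples of
  ≤ 8 for exhaustive permutation, ≤ 200 genes for the concordance oracle.
- Round trip: 500 spacers × 200 reads = 10⁵ reads.

These sizes are this package's own compute-budget choice; all statistical
thresholds and tolerances are independent of them.

## 7. Limitations

- Gene-level attribution inherits CRISPRi's polar effects; calls are per
  *cluster* of indistinguishable genes, and operon structure must be
  interpreted by the user.
- Fitness estimates saturate at −log2(depth); strongly lethal genes are
  censored, not measured (reported via `resolution_limit`).
- Exact-match counting discards reads with spacer-internal sequencing
  errors (~2% per percent error rate at 20 nt); this loses depth but does
  not bias fitness, since loss is uniform across libraries.
- The quasi-gene null assumes negative controls are exchangeable with
  inactive targeting sgRNAs; strong fitness effects of dCas9 expression
  itself would violate this.
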