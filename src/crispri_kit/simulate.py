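"""Synthetic fixtures with known ground truth.

Everything the analysis modules consume can be generated here: random
bacterial genomes with annotated non-overlapping ORFs (optionally with
near-identical duplicated gene pairs), screen count tables produced by a
competitive-growth model (selective abundance proportional to
``initial x 2^(activity x effect)``, multinomial sequencing noise),
FASTQ reads embedding the GCAC+N20+GTTT cassette, and transposon-insertion
tables with insertions suppressed in essential gene bodies.

The growth model realises an expected log2 abundance change of
``activity x gene_effect`` per sgRNA (before the compositional shift that
negative-control centering removes); negative controls always have effect
zero.  sgRNA activities default to 1 but can be drawn heterogeneously
(Beta(2, 2), with a mean uplift within the first 5% of the ORF to mimic the
observed positional activity bias; the default uplift of 0.4 places most
5'-proximal sgRNAs near full activity, consistent with the high fraction of
active sgRNAs observed for strongly depleted genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from crispri_kit.counting import CASSETTE_DOWN, CASSETTE_UP, ReadRecord
from crispri_kit.genome import GeneModel, revcomp

_STOP = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationTruth:
    """Ground truth of a simulated screen."""

    gene_effects: dict[str, float]
    sgrna_activity: pd.Series
    doublings: float
    depth: float
    seed: int

    def expected_log2_change(self, library: pd.DataFrame) -> pd.Series:
        effects = library["cluster_id"].map(self.gene_effects).fillna(0.0)
        return self.sgrna_activity.reindex(library.index).fillna(1.0) * effects


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

def make_genome_annotation(
    n_genes: int,
    gene_length_range: tuple[int, int] = (300, 900),
    gc: float = 0.5,
    n_duplicate_pairs: int = 0,
    seed: int = 0,
    intergenic_range: tuple[int, int] = (60, 200),
    chromosome: str = "chr1",
    duplicate_substitution_rate: float = 0.004,
):
    """Random chromosome with ``n_genes`` non-overlapping ORFs.

    Each ORF starts with ATG and ends with a stop codon; lengths are uniform
    multiples of 3 within ``gene_length_range``.  The first
    ``n_duplicate_pairs`` pairs of genes are near-identical copies
    (substitution rate ~0.4%, i.e. >=99% identity) to exercise gene
    clustering.  Genes are placed sequentially on random strands with random
    intergenic spacers.  Deterministic under ``seed``.

    Returns ``(genome: {chromosome: sequence}, genes: list[GeneModel])``.
    """
    if n_genes <= 0 or gene_length_range[0] < 30 or not (0 < gc < 1):
        raise ValueError("need n_genes > 0, gene lengths >= 30 and gc in (0, 1)")
    if 2 * n_duplicate_pairs > n_genes:
        raise ValueError("more duplicate pairs than genes")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    def random_orf(length: int) -> str:
        body = "".join(rng.choice(_BASES, size=length - 6, p=probs))
        return "ATG" + body + _STOP[rng.integers(len(_STOP))]

    def mutate(seq: str) -> str:
        out = list(seq)
        hits = np.nonzero(rng.random(len(seq)) < duplicate_substitution_rate)[0]
        for i in hits:
            choices = [b for b in "ACGT" if b != out[i]]
            out[i] = choices[rng.integers(3)]
        return "".join(out)

    cds_list: list[str] = []
    for g in range(n_genes):
        if g % 2 == 1 and g // 2 < n_duplicate_pairs:
            cds_list.append(mutate(cds_list[g - 1]))
        else:
            lo, hi = gene_length_range
            length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
            cds_list.append(random_orf(length))

    parts: list[str] = []
    genes: list[GeneModel] = []
    cursor = 0
    for g, cds in enumerate(cds_list):
        gap = "".join(rng.choice(_BASES, size=rng.integers(*intergenic_range), p=probs))
        parts.append(gap)
        cursor += len(gap)
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor + 1
        end = cursor + len(cds)
        parts.append(cds if strand == "+" else revcomp(cds))
        cursor = end
        genes.append(
            GeneModel(
                gene_id=f"gene{g:03d}",
                chromosome=chromosome,
                start=start,
                end=end,
                strand=strand,
                cds_sequence=cds,
            )
        )
    tail = "".join(rng.choice(_BASES, size=intergenic_range[1], p=probs))
    parts.append(tail)
    return {chromosome: "".join(parts)}, genes


def write_gff3(path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = "CDS" if g.biotype == "protein_coding" else "ncRNA"
            fh.write(
                f"{g.chromosome}\tcrispri_kit\t{ftype}\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id};gene_id={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Screen counts
# ---------------------------------------------------------------------------

def sample_activities(
    library: pd.DataFrame,
    rng: np.random.Generator,
    heterogeneous: bool = True,
    active_region_boost: float = 0.4,
    active_fraction: float = 0.05,
) -> pd.Series:
    """sgRNA activities in [0, 1]: Beta(2, 2) draws, shifted upward inside
    the first 5% of the ORF; homogeneous mode returns all ones."""
    if not heterogeneous:
        return pd.Series(1.0, index=library.index)
    act = rng.beta(2.0, 2.0, size=len(library))
    if "relative_position" in library.columns:
        in_active = (library["relative_position"].fillna(1.0) <= active_fraction).to_numpy()
        act = np.where(in_active, act + active_region_boost, act)
    return pd.Series(np.clip(act, 0.0, 1.0), index=library.index)


def simulate_screen_counts(
    library: pd.DataFrame,
    truth: SimulationTruth,
    depth: float,
    n_replicates: int = 2,
    abundance_skew: str | None = None,
) -> pd.DataFrame:
    """Counts for control and selective libraries under competitive growth.

    ``library`` is indexed by sgRNA name with a ``cluster_id`` column
    (negative controls map to no gene and have effect 0).  Initial relative
    abundances are uniform, or spread over a 10-fold range when
    ``abundance_skew='tenfold'``.  The selective abundance of each sgRNA is
    ``initial x 2^(activity x effect)``; each library draws
    ``round(depth x n_sgRNAs)`` multinomial reads.  Replicates are
    independent draws from independent initial pools.
    """
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    rng = np.random.default_rng(truth.seed)
    n = len(library)
    total = int(round(depth * n))
    log2_change = truth.expected_log2_change(library).to_numpy()
    columns = {}
    for rep in range(1, n_replicates + 1):
        if abundance_skew == "tenfold":
            initial = 10 ** rng.uniform(-0.5, 0.5, size=n)
        elif abundance_skew is None:
            initial = np.ones(n)
        else:
            raise ValueError(f"unknown abundance_skew {abundance_skew!r}")
        selective = initial * 2.0 ** log2_change
        columns[f"control_{rep}"] = rng.multinomial(total, initial / initial.sum())
        columns[f"selective_{rep}"] = rng.multinomial(total, selective / selective.sum())
    return pd.DataFrame(columns, index=library.index)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(
    counts: pd.Series,
    library_spacers: pd.Series,
    error_rate: float = 0.0,
    read_length: int = 150,
    quality: int = 37,
    seed: int = 0,
):
    """Error-configurable reads embedding each spacer's cassette.

    Each sgRNA emits ``counts[name]`` reads consisting of random background
    with ``GCAC + spacer + GTTT`` at a random offset, in random orientation;
    substitution errors are applied uniformly at ``error_rate``.  Random
    backgrounds that happen to spell out a second, spurious cassette are
    redrawn so that error-free reads round-trip exactly through extraction.
    Yields :class:`~crispri_kit.counting.ReadRecord`.
    """
    from crispri_kit.counting import extract_spacer

    cassette_len = len(CASSETTE_UP) + 20 + len(CASSETTE_DOWN)
    if read_length < cassette_len:
        raise ValueError(f"read_length must be >= {cassette_len}")
    rng = np.random.default_rng(seed)
    quals = [quality] * read_length
    k = 0
    for name, count in counts.items():
        spacer = library_spacers[name]
        cassette = CASSETTE_UP + spacer + CASSETTE_DOWN
        for _ in range(int(count)):
            while True:
                offset = int(rng.integers(0, read_length - cassette_len + 1))
                bases = list("".join(rng.choice(_BASES, size=read_length)))
                bases[offset : offset + cassette_len] = cassette
                seq = "".join(bases)
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                if extract_spacer(seq) == spacer:
                    break
            if error_rate > 0:
                out = list(seq)
                errs = np.nonzero(rng.random(read_length) < error_rate)[0]
                for i in errs:
                    alternatives = [b for b in "ACGT" if b != out[i]]
                    out[i] = alternatives[rng.integers(3)]
                seq = "".join(out)
            k += 1
            yield ReadRecord(f"read{k}_{name}", seq, quals)


def write_fastq(path, reads) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.identifier}\n{read.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Transposon insertions
# ---------------------------------------------------------------------------

def simulate_tn_insertions(
    genes: list[GeneModel],
    genome_length: int,
    density: float,
    essential_ids,
    seed: int = 0,
) -> np.ndarray:
    """Unique 1-based insertion positions, absent from essential gene bodies.

    Each position carries an insertion with probability ``density``
    (Bernoulli per bp, i.e. ~Poisson genome-wide); insertions falling inside
    the body of an essential gene are removed.
    """
    if density <= 0:
        raise ValueError("insertion density must be positive")
    rng = np.random.default_rng(seed)
    positions = np.nonzero(rng.random(genome_length) < density)[0] + 1
    essential = set(essential_ids)
    mask = np.ones(positions.size, dtype=bool)
    for g in genes:
        if g.gene_id in essential:
            mask &= ~((positions >= g.start) & (positions <= g.end))
    return positions[mask]
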