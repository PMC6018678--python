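"""Fitness statistics and hit calling for pooled CRISPRi screens.

sgRNA fitness is the log2 change in relative abundance between the selective
and control libraries, centered on the median of the negative-control (NC)
sgRNAs; Z scores divide by the standard deviation of a normal fit to the NC
fitness.  Gene-level calls use an empirical false-positive-rate (FPR) null:
"quasi genes" are assembled from random NC subsets of each size i = 1..15,
scored by |median fitness| x (-log10 P) with P from a two-tailed
Mann-Whitney U test against all NCs, and the sorted quasi scores define
FPR(score) curves by linear interpolation.  For a real gene the sgRNAs are
ordered 5'->3' and every prefix subset is scored; the prefix with the
smallest FPR determines the gene's fitness, P, score and FPR.  FPR values
are converted to q-values with the Storey-Tibshirani procedure and genes
with q below the FDR threshold are hits.

Method note: a quasi gene's members are drawn from the NC set itself, so the
subset values tie exactly with the reference sample; the tie-corrected
normal approximation (with continuity correction) is therefore the default
throughout the scoring path so real genes and the null are treated
identically.  The standalone :func:`mwu_test` uses the exact distribution
for small tie-free samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 1.0


# ---------------------------------------------------------------------------
# sgRNA-level statistics
# ---------------------------------------------------------------------------

def sgrna_fitness(
    selective_counts: pd.Series, control_counts: pd.Series, nc_names
) -> pd.DataFrame:
    """Per-sgRNA fitness from selective vs control (normalized) counts.

    ``fitness_raw = log2((selective + 1) / (control + 1))`` and ``fitness``
    subtracts the median raw fitness of the negative controls, so the NC
    median is exactly zero after centering.
    """
    nc_names = [n for n in nc_names if n in selective_counts.index]
    if not nc_names:
        raise ValueError("no negative-control sgRNAs present in the count table")
    sel, ctrl = selective_counts.align(control_counts, join="inner")
    raw = np.log2((sel + PSEUDOCOUNT) / (ctrl + PSEUDOCOUNT))
    centered = raw - raw.loc[nc_names].median()
    table = pd.DataFrame({"fitness_raw": raw, "fitness": centered})
    table["is_nc"] = table.index.isin(nc_names)
    return table


def z_scores(fitness_table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Z score of each sgRNA: fitness divided by the NC standard deviation.

    The sigma is the normal-fit (maximum-likelihood) standard deviation of
    the negative-control fitness values.
    """
    nc = fitness_table.loc[fitness_table["is_nc"], "fitness"].to_numpy()
    if nc.size < 2:
        raise ValueError("need at least two negative controls to estimate sigma")
    sigma = float(nc.std(ddof=0))
    if sigma == 0:
        raise ValueError("negative-control fitness has zero spread")
    out = fitness_table.copy()
    out["Z"] = out["fitness"] / sigma
    return out, sigma


def mwu_test(x, y, method: str = "auto") -> float:
    """Two-sided Mann-Whitney U test P-value.

    ``method='auto'`` uses the exact null distribution when the smaller
    sample has at most 8 observations and the pooled data are tie-free, and
    the tie-corrected normal approximation with continuity correction
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        pooled = np.concatenate([x, y])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (min(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def _batch_mwu_p(subsets: np.ndarray, reference: np.ndarray, method: str) -> np.ndarray:
    """Vectorized two-sided MWU P for many equal-size subsets vs one
    reference sample."""
    res = sps.mannwhitneyu(
        subsets, reference[None, :], alternative="two-sided", method=method, axis=-1
    )
    return np.atleast_1d(res.pvalue)


def gene_score(subset_fitness, nc_fitness, method: str = "asymptotic"):
    """Score of one sgRNA subset: ``|median| x (-log10 P)`` with P from the
    two-tailed MWU test of the subset against all NC fitness values.

    Returns ``(median, P, score)``.  P = 1 gives score 0; the score is
    symmetric in the sign of the median.
    """
    subset = np.asarray(subset_fitness, dtype=float)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    median = float(np.median(subset))
    p = mwu_test(subset, nc_fitness, method=method)
    score = abs(median) * (-math.log10(p)) if p < 1 else 0.0
    return median, p, max(score, 0.0)


# ---------------------------------------------------------------------------
# Quasi-gene FPR null
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """Empirical FPR curves from negative-control quasi genes.

    ``quasi_scores[i]`` holds the scores (ascending) of the size-i quasi
    gene set; ``fpr`` evaluates the interpolated FPR(score) curve for a
    given subset size, clamped to ``[1/(2 N_i), 1]``.

    ``min_fpr[n]`` holds the null distribution (ascending) of the smallest
    prefix-subset FPR for quasi genes with n sgRNAs.  Because a real gene is
    called on the prefix subset minimising the FPR, the raw minimum is
    stochastically smaller than uniform under the null;
    :meth:`selection_adjusted_fpr` converts it back to a calibrated
    false-positive rate (the null ECDF of the minimum), which is what the
    Storey q-value step consumes — FPR values enter that step as P values
    and must be uniform under the null for it to be valid.
    """

    quasi_scores: dict[int, np.ndarray]
    min_fpr: dict[int, np.ndarray]
    seed: int
    n_quasi: int
    p_method: str = "asymptotic"

    @property
    def max_size(self) -> int:
        return max(self.quasi_scores)

    def fpr(self, scores, size: int) -> np.ndarray:
        if size not in self.quasi_scores:
            raise KeyError(f"no null curve for subset size {size}")
        xs = self.quasi_scores[size]
        n = xs.size
        # fraction of quasi scores strictly greater than each sample point
        ys = (n - 1 - np.arange(n)) / n
        lam = np.atleast_1d(np.asarray(scores, dtype=float))
        out = np.interp(lam, xs, ys)
        out = np.where(lam < xs[0], 1.0, out)
        floor = 1.0 / (2 * n)
        out = np.clip(out, floor, 1.0)
        return out if np.ndim(scores) else float(out[0])

    def selection_adjusted_fpr(self, min_fpr_value, n_sgrnas: int):
        """Calibrated FPR of an observed minimum-over-prefixes FPR.

        Returns the fraction of size-``n_sgrnas`` null quasi genes whose own
        minimum prefix FPR is at most the observed value, clamped to
        ``[1/(2 N), 1]``.
        """
        if n_sgrnas not in self.min_fpr:
            raise KeyError(f"no selection null for genes with {n_sgrnas} sgRNAs")
        dist = self.min_fpr[n_sgrnas]
        x = np.atleast_1d(np.asarray(min_fpr_value, dtype=float))
        frac = np.searchsorted(dist, x, side="right") / dist.size
        out = np.clip(frac, 1.0 / (2 * dist.size), 1.0)
        return out if np.ndim(min_fpr_value) else float(out[0])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"size": i, "rank": j + 1, "score": s}
            for i, xs in sorted(self.quasi_scores.items())
            for j, s in enumerate(xs)
        ]
        return pd.DataFrame(rows)


def _loo_quasi_pvalues(subset_idx: np.ndarray, nc_sorted: np.ndarray) -> np.ndarray:
    """Two-sided MWU P of NC subsets against the remaining NCs, vectorized.

    ``subset_idx`` indexes rows of subsets into the ascending-sorted NC
    array.  Testing each subset against the other ``n - m`` controls keeps
    the null exchangeable with a real (non-NC) gene of the same size; the
    P uses the normal approximation with continuity correction.
    """
    m = subset_idx.shape[1]
    n_ref = nc_sorted.size - m
    # values are the sorted-array indices themselves: #(nc < x) = index
    less_full = subset_idx
    # rank of each element within its own subset
    order_in_row = np.argsort(np.argsort(subset_idx, axis=1), axis=1)
    u = (less_full - order_in_row).sum(axis=1).astype(float)
    mean = m * n_ref / 2.0
    sd = np.sqrt(m * n_ref * (m + n_ref + 1) / 12.0)
    z = (np.abs(u - mean) - 0.5) / sd
    return np.clip(2.0 * sps.norm.sf(z), 0.0, 1.0)


def build_fpr_curves(
    nc_fitness,
    n_quasi: int = 10_000,
    max_size: int = 15,
    seed: int = 0,
    p_method: str = "asymptotic",
    exclude_subset: bool = True,
) -> NullModel:
    """Build the per-size quasi-gene null from NC fitness values.

    Size 1 enumerates every NC singleton; each larger size draws ``n_quasi``
    quasi genes of i distinct NCs (without replacement within a quasi gene,
    with replacement across quasi genes) and stores their sorted scores.

    By default each quasi gene is rank-tested against the negative controls
    *excluding its own members* (``exclude_subset=True``).  A real gene's
    sgRNAs are disjoint from the NC set, so a quasi gene tested against all
    controls ties with itself and its scores are slightly compressed
    relative to a true null gene; excluding the subset restores
    exchangeability.  ``exclude_subset=False`` reproduces the plain
    all-controls reference.
    """
    nc = np.asarray(nc_fitness, dtype=float)
    if max_size > nc.size:
        raise ValueError(f"max_size {max_size} exceeds the {nc.size} negative controls")
    rng = np.random.default_rng(seed)
    nc_sorted = np.sort(nc)

    def batch_scores(subset_idx: np.ndarray) -> np.ndarray:
        subsets = nc_sorted[subset_idx]
        medians = np.abs(np.median(subsets, axis=1))
        if exclude_subset:
            pvals = _loo_quasi_pvalues(subset_idx, nc_sorted)
        else:
            pvals = _batch_mwu_p(subsets, nc, p_method)
        with np.errstate(divide="ignore"):
            return medians * np.where(pvals < 1, -np.log10(pvals), 0.0)

    # one pool of ordered quasi genes of the maximum size; its size-i
    # prefixes are themselves uniform random size-i subsets, reused both for
    # the per-size score curves (i >= 2) and for the min-FPR selection null
    order = rng.random((n_quasi, nc.size)).argsort(axis=1)[:, :max_size] if max_size > 1 else None
    prefix_scores: dict[int, np.ndarray] = {}
    quasi_scores: dict[int, np.ndarray] = {
        1: np.sort(batch_scores(np.arange(nc.size)[:, None]))
    }
    for i in range(2, max_size + 1):
        prefix_scores[i] = batch_scores(order[:, :i])
        quasi_scores[i] = np.sort(prefix_scores[i])
    prefix_scores[1] = batch_scores(order[:, :1]) if order is not None else None

    model = NullModel(
        quasi_scores=quasi_scores, min_fpr={}, seed=seed, n_quasi=n_quasi, p_method=p_method
    )
    # null distribution of the minimum prefix FPR for genes with n sgRNAs
    if order is not None:
        fpr_cols = np.column_stack(
            [model.fpr(prefix_scores[i], i) for i in range(1, max_size + 1)]
        )
        running = np.minimum.accumulate(fpr_cols, axis=1)
        for n in range(1, max_size + 1):
            model.min_fpr[n] = np.sort(running[:, n - 1])
    else:
        model.min_fpr[1] = np.sort(model.fpr(quasi_scores[1], 1))
    return model


# ---------------------------------------------------------------------------
# Gene-level calls
# ---------------------------------------------------------------------------

@dataclass
class GeneResult:
    """Gene-level call: the 5'-prefix subset with the smallest FPR.

    ``fpr_raw`` is the smallest per-size curve value over the prefix
    subsets; ``fpr`` is its selection-adjusted (calibrated) counterpart used
    for q-values and hit calling.
    """

    cluster_id: str
    n_sgrnas: int
    subset_size: int
    fitness: float
    p_value: float
    score: float
    fpr: float
    fpr_raw: float
    q_value: float = float("nan")
    hit: bool = False
    direction: str = ""


def call_gene(
    gene_fitness,
    nc_fitness,
    null_model: NullModel,
    cluster_id: str = "",
) -> GeneResult:
    """Call one gene from its position-ordered sgRNA fitness values.

    For each prefix subset (first M sgRNAs, M = 1..N) the median, MWU P,
    score and size-M FPR are computed; the subset with the smallest FPR
    (ties toward smaller M) provides the gene's metrics.
    """
    values = np.asarray(gene_fitness, dtype=float)
    if values.size == 0:
        raise ValueError("gene has no usable sgRNA fitness values")
    n = values.size
    if n > null_model.max_size:
        logger.warning(
            "%s: %d sgRNAs exceed the null model's max size %d; capping",
            cluster_id, n, null_model.max_size,
        )
        n = null_model.max_size
    nc = np.asarray(nc_fitness, dtype=float)
    best = None
    for m in range(1, n + 1):
        median, p, score = gene_score(values[:m], nc, method=null_model.p_method)
        fpr = float(null_model.fpr(score, m))
        if best is None or fpr < best[0]:
            best = (fpr, m, median, p, score)
    fpr_raw, m, median, p, score = best
    fpr = float(null_model.selection_adjusted_fpr(fpr_raw, n))
    return GeneResult(
        cluster_id=cluster_id,
        n_sgrnas=values.size,
        subset_size=m,
        fitness=median,
        p_value=p,
        score=score,
        fpr=fpr,
        fpr_raw=fpr_raw,
    )


def call_genes(
    fitness_by_gene: dict[str, np.ndarray],
    nc_fitness,
    null_model: NullModel,
) -> pd.DataFrame:
    """Vectorized gene calling for many genes at once.

    Equivalent to :func:`call_gene` per gene; prefix subsets are grouped by
    size so the rank tests run in batched form.  Returns a DataFrame indexed
    by gene with columns n_sgrnas, subset_size, fitness, p_value, score,
    fpr.
    """
    nc = np.asarray(nc_fitness, dtype=float)
    names = list(fitness_by_gene)
    arrays = {g: np.asarray(v, dtype=float) for g, v in fitness_by_gene.items()}
    capped = {g: min(v.size, null_model.max_size) for g, v in arrays.items()}
    per_gene: dict[str, list[tuple]] = {g: [] for g in names}
    for m in range(1, max(capped.values(), default=0) + 1):
        group = [g for g in names if capped[g] >= m]
        if not group:
            continue
        subsets = np.stack([arrays[g][:m] for g in group])
        medians = np.median(subsets, axis=1)
        pvals = _batch_mwu_p(subsets, nc, null_model.p_method)
        with np.errstate(divide="ignore"):
            scores = np.abs(medians) * np.where(pvals < 1, -np.log10(pvals), 0.0)
        fprs = null_model.fpr(scores, m)
        for g, median, p, score, fpr in zip(group, medians, pvals, scores, np.atleast_1d(fprs)):
            per_gene[g].append((float(fpr), m, float(median), float(p), float(score)))
    rows = []
    for g in names:
        fpr_raw, m, median, p, score = min(per_gene[g], key=lambda t: (t[0], t[1]))
        rows.append(
            {
                "gene": g,
                "n_sgrnas": arrays[g].size,
                "subset_size": m,
                "fitness": median,
                "p_value": p,
                "score": score,
                "fpr": float(null_model.selection_adjusted_fpr(fpr_raw, capped[g])),
                "fpr_raw": fpr_raw,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# FDR and hit calling
# ---------------------------------------------------------------------------

def estimate_qvalues(fpr_values) -> np.ndarray:
    """Storey-Tibshirani q-values from FPR values (treated as P values).

    ``pi0 = min(1, #{FPR > 0.5} / (0.5 m))`` (the lambda = 0.5 estimator);
    ``q_i = min_{j: FPR_j >= FPR_i} pi0 * m * FPR_j / rank_j``, which is
    monotone in FPR.
    """
    fpr = np.asarray(fpr_values, dtype=float)
    m = fpr.size
    if m == 0:
        return fpr.copy()
    pi0 = min(1.0, (fpr > 0.5).sum() / (0.5 * m))
    order = np.argsort(fpr, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * fpr[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


NO_DOUBLING_FITNESS = -6.0
ESSENTIAL_EXCLUSION_FITNESS = -4.0
ESSENTIAL_EXCLUSION_FDR = 0.01


def call_hits(
    results: pd.DataFrame, fdr: float = 0.05, exclude=None
) -> pd.DataFrame:
    """Annotate gene results with hit flags at the given FDR.

    Adds ``q_value`` (if absent), ``hit`` (q < fdr), ``direction``
    (depleted/enriched) and ``no_doubling`` (fitness <= -6, the level at
    which cells show no net division over the screen).  ``exclude`` drops
    listed genes (e.g. essential genes from a reference essentiality run)
    before calling.
    """
    out = results.copy()
    if exclude is not None:
        out = out.loc[~out.index.isin(set(exclude))]
    if "q_value" not in out.columns or out["q_value"].isna().all():
        out["q_value"] = estimate_qvalues(out["fpr"].to_numpy())
    out["hit"] = out["q_value"] < fdr
    out["direction"] = np.where(out["fitness"] < 0, "depleted", "enriched")
    out["no_doubling"] = out["fitness"] <= NO_DOUBLING_FITNESS
    return out


def essential_exclusion_list(
    reference_results: pd.DataFrame,
    fitness_max: float = ESSENTIAL_EXCLUSION_FITNESS,
    fdr_max: float = ESSENTIAL_EXCLUSION_FDR,
) -> list[str]:
    """Genes called essential in a reference run (fitness <= -4, q <= 0.01),
    to be excluded from downstream condition screens."""
    ref = reference_results
    q = ref["q_value"] if "q_value" in ref.columns else pd.Series(
        estimate_qvalues(ref["fpr"].to_numpy()), index=ref.index
    )
    mask = (ref["fitness"] <= fitness_max) & (q <= fdr_max)
    return list(ref.index[mask])


# ---------------------------------------------------------------------------
# Positional analyses
# ---------------------------------------------------------------------------

def position_activity_profile(sgrnas: pd.DataFrame, bin_width: float = 0.05) -> pd.DataFrame:
    """sgRNA activity (|Z|) by relative position along the ORF.

    Bins are [0, 0.05], (0.05, 0.10], ..., (0.95, 1]; each bin's |Z|
    distribution is compared with the pooled set by a two-tailed MWU test.
    Empty bins yield NaN.
    """
    rel = sgrnas["relative_position"].to_numpy()
    absz = sgrnas["Z"].abs().to_numpy()
    n_bins = int(round(1.0 / bin_width))
    idx = np.ceil(rel / bin_width).astype(int)
    idx = np.clip(idx, 1, n_bins)
    rows = []
    for b in range(1, n_bins + 1):
        values = absz[idx == b]
        if values.size == 0:
            rows.append({"bin_start": (b - 1) * bin_width, "bin_end": b * bin_width,
                         "n": 0, "median_abs_z": np.nan, "p_value": np.nan})
            continue
        p = mwu_test(values, absz, method="asymptotic")
        rows.append(
            {
                "bin_start": (b - 1) * bin_width,
                "bin_end": b * bin_width,
                "n": int(values.size),
                "median_abs_z": float(np.median(values)),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def subsample_gene_pvalues(
    genes: dict[str, pd.DataFrame],
    nc_fitness,
    sizes=(3, 5, 10, 15, 20, 30),
    method: str = "position",
    seed: int = 0,
) -> pd.DataFrame:
    """-log10 MWU P of each gene recomputed on sgRNA subsets of given sizes.

    ``genes`` maps gene -> DataFrame with columns ``p`` (position within the
    ORF) and ``fitness``.  ``method='position'`` takes the X sgRNAs most
    proximal to the start codon; ``method='random'`` draws a seeded uniform
    subset.  A size larger than the available sgRNAs uses them all and flags
    the row.
    """
    if method not in ("position", "random"):
        raise ValueError("method must be 'position' or 'random'")
    nc = np.asarray(nc_fitness, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for gene, df in genes.items():
        ordered = df.sort_values("p")
        for size in sizes:
            capped = min(size, len(ordered))
            if method == "position":
                subset = ordered["fitness"].to_numpy()[:capped]
            else:
                pick = rng.choice(len(ordered), size=capped, replace=False)
                subset = ordered["fitness"].to_numpy()[np.sort(pick)]
            p = mwu_test(subset, nc, method="asymptotic")
            rows.append(
                {
                    "gene": gene,
                    "size": size,
                    "method": method,
                    "n_used": capped,
                    "undersized": capped < size,
                    "minus_log10_p": -math.log10(p) if p > 0 else math.inf,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Screen resolution
# ---------------------------------------------------------------------------

def resolution_limit(median_depth: float, n_doublings: float) -> float:
    """Smallest detectable fitness magnitude of a dropout screen:
    ``min(log2(sequencing depth), cell doublings during screening)``."""
    if median_depth <= 0 or n_doublings <= 0:
        raise ValueError("depth and doublings must be positive")
    return min(math.log2(median_depth), n_doublings)


def doublings(n_initial: float, n_final: float) -> float:
    """Number of population doublings: ``log2(n_final / n_initial)``."""
    if n_initial <= 0 or n_final <= 0:
        raise ValueError("cell numbers must be positive")
    return math.log2(n_final / n_initial)
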