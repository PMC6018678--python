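"""sgRNA library design for pooled CRISPRi screens in bacteria.

The designer enumerates every protospacer on the non-template strand of each
coding region (coding-strand ``CC`` dinucleotides, i.e. an NGG PAM on the
template strand), filters candidates by GC content and by a region-weighted
off-target penalty, and selects either a 5'->3' tiling set or a genome-scale
set that prioritises the "active" region near the start codon.  Duplicated
genes are grouped into >=95%-identity clusters that are targeted jointly, and
negative-control spacers with no genomic site at up to five mismatches are
appended.

Off-target metric
-----------------
The 20-nt protospacer is split by distance to the PAM into Region III
(spacer positions 1-8, PAM-distal), Region II (9-13) and Region I (14-20,
PAM-proximal).  Each mismatch at a candidate off-target site contributes a
region penalty: 2.5/4.5/8 for an NGG PAM and 3/7/10 for NAG (Regions
III/II/I); any other PAM contributes 100 per mismatch.  A site whose summed
penalty falls below the design threshold (11 in tiling mode, 21 in
genome-scale mode) flags the sgRNA as off-target-prone and removes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from crispri_kit.genome import GeneModel, gc_fraction, revcomp

logger = logging.getLogger(__name__)

SPACER_LEN = 20
SITE_LEN = 23  # protospacer + PAM

# Region boundaries on spacer coordinates (1 = 5' end, 20 = PAM-proximal).
REGION_III = range(1, 9)  # positions 1-8
REGION_II = range(9, 14)  # positions 9-13
REGION_I = range(14, 21)  # positions 14-20

# Per-mismatch penalties by (pam_class, region).
_PENALTIES = {
    "NGG": {"III": 2.5, "II": 4.5, "I": 8.0},
    "NAG": {"III": 3.0, "II": 7.0, "I": 10.0},
}
OTHER_PAM_PENALTY = 100.0


def _region(position: int) -> str:
    if position in REGION_III:
        return "III"
    if position in REGION_II:
        return "II"
    if position in REGION_I:
        return "I"
    raise ValueError(f"spacer position must be in 1..20, got {position}")


@dataclass
class DesignParams:
    """Tunable parameters of the library designer.

    Defaults follow the genome-scale design rules: at most 15 sgRNAs per gene
    cluster, off-target rejection threshold 21, GC content within [0.30,
    0.85], the active region spanning the first 5% of the ORF, gene
    clustering at 95% identity/coverage and 400 negative controls.  Tiling
    mode uses up to 50 sgRNAs per gene and threshold 11.
    """

    mode: str = "genome"
    max_per_gene: int | None = None
    offtarget_threshold: float | None = None
    gc_min: float = 0.30
    gc_max: float = 0.85
    active_fraction: float = 0.05
    cluster_identity: float = 0.95
    cluster_coverage: float = 0.95
    n_negative_controls: int = 400
    nc_attempt_budget: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("tiling", "genome"):
            raise ValueError(f"mode must be 'tiling' or 'genome', got {self.mode!r}")
        if self.max_per_gene is None:
            self.max_per_gene = 50 if self.mode == "tiling" else 15
        if self.offtarget_threshold is None:
            self.offtarget_threshold = 11.0 if self.mode == "tiling" else 21.0
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ValueError("require 0 <= gc_min < gc_max <= 1")
        if self.offtarget_threshold <= 0:
            raise ValueError("offtarget_threshold must be positive")


@dataclass
class GeneCluster:
    """A set of near-identical genes targeted by the same sgRNAs."""

    cluster_id: str
    member_ids: list[str]
    representative_id: str

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("cluster must have at least one member")
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")


@dataclass
class SgRNACandidate:
    """A candidate spacer within a coding region.

    ``p`` is the 1-based coding coordinate of the 5'-most guanine of the
    template-strand PAM (the coding strand reads ``CC`` at positions p-1, p);
    names follow the ``gene_p`` convention.
    """

    name: str
    cluster_id: str
    spacer: str
    p: int
    relative_position: float
    gc_fraction: float
    status: str = "kept"

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LEN:
            raise ValueError("spacer must be 20 nt")


@dataclass
class OffTargetSite:
    """A genomic 23-mer (protospacer + PAM) resembling a spacer."""

    chromosome: str
    position: int  # 1-based, leftmost base of the 23-mer on the forward strand
    strand: str
    pam_class: str
    mismatch_positions: tuple[int, ...]
    penalty: float


@dataclass
class LibraryDesign:
    """A designed sgRNA library plus negative controls and reports."""

    table: pd.DataFrame  # one row per selected sgRNA
    negative_controls: list[str]
    clusters: list[GeneCluster]
    per_gene_counts: dict[str, int]
    rejection_tallies: dict[str, int] = field(default_factory=dict)
    sublibrary_map: dict[str, str] = field(default_factory=dict)

    @property
    def sgrna_names(self) -> list[str]:
        return list(self.table["name"])

    def coverage_report(self) -> pd.DataFrame:
        """Per-cluster sgRNA counts with >=1 / >=3 coverage flags."""
        rows = [
            {
                "cluster_id": c.cluster_id,
                "n_sgrnas": self.per_gene_counts.get(c.cluster_id, 0),
            }
            for c in self.clusters
        ]
        df = pd.DataFrame(rows)
        df["ge1"] = df["n_sgrnas"] >= 1
        df["ge3"] = df["n_sgrnas"] >= 3
        return df

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def oligos_fasta(self, path, upstream: str = "GCAC", downstream: str = "GTTT") -> None:
        """Write synthesis oligos with the fixed cassette flanks."""
        with open(path, "w") as fh:
            for _, row in self.table.iterrows():
                fh.write(f">{row['name']}\n{upstream}{row['spacer']}{downstream}\n")
            for k, spacer in enumerate(self.negative_controls, 1):
                fh.write(f">NC_{k}\n{upstream}{spacer}{downstream}\n")


# ---------------------------------------------------------------------------
# Off-target scoring and search
# ---------------------------------------------------------------------------

def score_offtarget_site(pam_class: str, mismatch_positions) -> float:
    """Region-weighted penalty of an off-target site.

    Sums the per-mismatch region penalty for the given PAM class; PAMs other
    than NGG/NAG cost 100 per mismatch.
    """
    positions = list(mismatch_positions)
    table = _PENALTIES.get(pam_class)
    total = 0.0
    for pos in positions:
        region = _region(int(pos))  # validates the position range
        total += table[region] if table is not None else OTHER_PAM_PENALTY
    return total


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    """Encode bases as 0..3; ambiguity codes get 4 (mismatch everything)."""
    arr = np.full(len(seq), 4, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


class GenomeIndex:
    """Pre-computed 23-mer windows of a genome, both strands, for fast
    mismatch scans against many spacers."""

    def __init__(self, genome: dict[str, str]):
        self._entries = []  # (chromosome, strand, windows, positions, pam_class)
        for chrom, seq in genome.items():
            for strand, s in (("+", seq.upper()), ("-", revcomp(seq.upper()))):
                if len(s) < SITE_LEN:
                    continue
                codes = _encode(s)
                windows = np.lib.stride_tricks.sliding_window_view(codes, SITE_LEN)
                second, third = windows[:, 21], windows[:, 22]
                pam_class = np.full(len(windows), "", dtype=object)
                pam_class[(second == 2) & (third == 2)] = "NGG"
                pam_class[(second == 0) & (third == 2)] = "NAG"
                keep = pam_class != ""
                idx = np.nonzero(keep)[0]
                if strand == "+":
                    positions = idx + 1  # leftmost base, 1-based
                else:
                    positions = len(s) - (idx + SITE_LEN) + 1
                self._entries.append(
                    (chrom, strand, windows[keep, :SPACER_LEN], positions, pam_class[keep])
                )

    def scan(self, spacer: str, max_mismatch: int = 5) -> list[OffTargetSite]:
        spacer_codes = _encode(spacer.upper())
        sites = []
        for chrom, strand, prefixes, positions, pam_class in self._entries:
            mism = prefixes != spacer_codes
            n_mism = mism.sum(axis=1)
            hits = np.nonzero(n_mism <= max_mismatch)[0]
            for h in hits:
                mpos = tuple(int(j) + 1 for j in np.nonzero(mism[h])[0])
                pam = str(pam_class[h])
                sites.append(
                    OffTargetSite(
                        chromosome=chrom,
                        position=int(positions[h]),
                        strand=strand,
                        pam_class=pam,
                        mismatch_positions=mpos,
                        penalty=score_offtarget_site(pam, mpos),
                    )
                )
        return sites


def find_offtarget_sites(
    spacer: str, genome: dict[str, str] | GenomeIndex, max_mismatch: int = 5
) -> list[OffTargetSite]:
    """All genomic N20-NGG/NAG 23-mers within ``max_mismatch`` of ``spacer``.

    Both strands are searched; ambiguous genome bases mismatch every spacer
    base.  ``genome`` may be a plain ``{chrom: sequence}`` dict or a
    pre-built :class:`GenomeIndex` (reused across many spacers).
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    return index.scan(spacer, max_mismatch=max_mismatch)


# ---------------------------------------------------------------------------
# Candidate enumeration, filtering, selection
# ---------------------------------------------------------------------------

def enumerate_candidates(gene: GeneModel, cluster_id: str | None = None) -> list[SgRNACandidate]:
    """Every spacer on the non-template strand of a coding region.

    A candidate exists at each coding-strand ``CC`` at positions (p-1, p)
    with 2 <= p <= L-21 (PAM and protospacer fully inside the ORF); the
    spacer is the reverse complement of coding positions p+2..p+21.
    Candidates are ordered 5'->3' by p.
    """
    cds = gene.cds_sequence
    L = len(cds)
    if L < SITE_LEN:
        logger.warning("%s: coding sequence too short for any sgRNA", gene.gene_id)
        return []
    cid = cluster_id if cluster_id is not None else gene.gene_id
    out = []
    for p in range(2, L - SPACER_LEN):  # p <= L - 21
        if cds[p - 2] == "C" and cds[p - 1] == "C":
            protospacer = cds[p + 1 : p + 1 + SPACER_LEN]  # coding p+2..p+21
            spacer = revcomp(protospacer)
            out.append(
                SgRNACandidate(
                    name=f"{gene.gene_id}_{p}",
                    cluster_id=cid,
                    spacer=spacer,
                    p=p,
                    relative_position=p / L,
                    gc_fraction=gc_fraction(spacer),
                )
            )
    return out


def filter_candidate(
    candidate: SgRNACandidate,
    sites: list[OffTargetSite],
    params: DesignParams,
    on_target_positions: set[tuple[str, int, str]] = frozenset(),
) -> str:
    """Assign kept / rejected_gc / rejected_offtarget.

    GC bounds are inclusive.  A site is ignored if its (chromosome,
    position, strand) is in ``on_target_positions`` (perfect matches inside
    the candidate's own cluster); any other site with penalty strictly below
    the design threshold rejects the candidate.
    """
    if not (params.gc_min <= candidate.gc_fraction <= params.gc_max):
        return "rejected_gc"
    for site in sites:
        if (site.chromosome, site.position, site.strand) in on_target_positions:
            continue
        if site.penalty < params.offtarget_threshold:
            return "rejected_offtarget"
    return "kept"


def select_sgrnas(kept_candidates: list[SgRNACandidate], params: DesignParams) -> list[SgRNACandidate]:
    """Pick the final sgRNA set for one gene cluster.

    Tiling mode takes the first ``max_per_gene`` kept candidates 5'->3'.
    Genome mode first takes candidates within the active region (relative
    position <= ``active_fraction``, most 5'-proximal first) and, if fewer
    than ``max_per_gene``, fills up with candidates taken at evenly spaced
    rank quantiles of the remaining position-ordered list.
    """
    cands = sorted(kept_candidates, key=lambda c: c.p)
    if not cands:
        logger.warning("no kept candidates to select from")
        return []
    m = params.max_per_gene
    if params.mode == "tiling":
        return cands[:m]
    active = [c for c in cands if c.relative_position <= params.active_fraction]
    selected = active[:m]
    n_fill = m - len(selected)
    if n_fill > 0:
        remaining = [c for c in cands if c.relative_position > params.active_fraction]
        if remaining:
            k = min(n_fill, len(remaining))
            ranks = np.unique(np.round(np.linspace(0, len(remaining) - 1, k)).astype(int))
            selected += [remaining[r] for r in ranks]
    return selected


def design_negative_controls(
    genome: dict[str, str] | GenomeIndex,
    params: DesignParams,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Random 20-mers with in-range GC and no genomic site at <=5 mismatches.

    Rejection-samples seeded uniform spacers until ``n_negative_controls``
    pass; raises if the attempt budget is exhausted (degenerate genomes).
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    bases = np.array(list("ACGT"))
    controls: list[str] = []
    attempts = 0
    while len(controls) < params.n_negative_controls:
        if attempts >= params.nc_attempt_budget:
            raise RuntimeError(
                f"negative-control sampling exhausted the attempt budget of "
                f"{params.nc_attempt_budget} before reaching "
                f"{params.n_negative_controls} controls"
            )
        attempts += 1
        spacer = "".join(rng.choice(bases, SPACER_LEN))
        if not (params.gc_min <= gc_fraction(spacer) <= params.gc_max):
            continue
        if index.scan(spacer, max_mismatch=5):
            continue
        controls.append(spacer)
    return controls


# ---------------------------------------------------------------------------
# Gene clustering
# ---------------------------------------------------------------------------

def _pair_linked(a: str, b: str, identity: float, coverage: float) -> bool:
    """Global-alignment identity/coverage test for one gene pair."""
    la, lb = len(a), len(b)
    if min(la, lb) / max(la, lb) < coverage:
        return False
    result = edlib.align(a, b, task="distance", mode="NW")
    dist = result["editDistance"]
    aln_len = max(la, lb)  # lower bound on NW alignment columns
    return 1 - dist / aln_len >= identity


def cluster_genes(
    genes: list[GeneModel], identity: float = 0.95, coverage: float = 0.95
) -> list[GeneCluster]:
    """Single-linkage clusters of near-identical genes.

    Two genes are linked when their global alignment reaches the identity
    threshold and their lengths are mutually compatible with the coverage
    threshold.  The representative is the longest member (ties broken by
    lexicographic gene id); cluster ids equal the representative id.
    """
    if not (0 < identity <= 1 and 0 < coverage <= 1):
        raise ValueError("identity and coverage must be in (0, 1]")
    for g in genes:
        if not g.cds_sequence:
            raise ValueError(f"{g.gene_id}: empty sequence cannot be clustered")
    n = len(genes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: genes[i].gene_id)
    for ii in range(n):
        for jj in range(ii + 1, n):
            i, j = order[ii], order[jj]
            if find(i) == find(j):
                continue
            if _pair_linked(genes[i].cds_sequence, genes[j].cds_sequence, identity, coverage):
                parent[find(i)] = find(j)

    groups: dict[int, list[GeneModel]] = {}
    for i, g in enumerate(genes):
        groups.setdefault(find(i), []).append(g)
    clusters = []
    for members in groups.values():
        rep = min(members, key=lambda g: (-g.length, g.gene_id))
        clusters.append(
            GeneCluster(
                cluster_id=rep.gene_id,
                member_ids=sorted(g.gene_id for g in members),
                representative_id=rep.gene_id,
            )
        )
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


# ---------------------------------------------------------------------------
# Full design
# ---------------------------------------------------------------------------

def design_library(
    genome: dict[str, str],
    genes: list[GeneModel],
    params: DesignParams,
    clusters: list[GeneCluster] | None = None,
    sublibrary_map: dict[str, str] | None = None,
) -> LibraryDesign:
    """Design a complete sgRNA library (tiling or genome-scale).

    Candidates are enumerated on each cluster's representative gene and must
    match every member exactly (the protospacer+PAM context substring must be
    present in each member's coding sequence); perfect-match sites lying
    inside any member's annotated span are exempt from off-target rejection.
    Negative controls are appended last.
    """
    if clusters is None:
        clusters = cluster_genes(
            genes, identity=params.cluster_identity, coverage=params.cluster_coverage
        )
    by_id = {g.gene_id: g for g in genes}
    index = GenomeIndex(genome)
    rows = []
    per_gene_counts: dict[str, int] = {}
    tallies = {"rejected_gc": 0, "rejected_offtarget": 0, "dropped_member_mismatch": 0}

    for cluster in clusters:
        rep = by_id[cluster.representative_id]
        members = [by_id[m] for m in cluster.member_ids]
        member_spans = {
            (m.chromosome, m.start, m.end) for m in members
        }
        candidates = enumerate_candidates(rep, cluster_id=cluster.cluster_id)
        kept = []
        for cand in candidates:
            # exact-match requirement in every cluster member: the full
            # CC + protospacer coding context must be present verbatim
            context = rep.cds_sequence[cand.p - 2 : cand.p + 1 + SPACER_LEN]
            if any(context not in m.cds_sequence for m in members):
                cand.status = "not_selected"
                tallies["dropped_member_mismatch"] += 1
                continue
            sites = index.scan(cand.spacer, max_mismatch=5)
            on_target = {
                (s.chromosome, s.position, s.strand)
                for s in sites
                if not s.mismatch_positions
                and any(
                    chrom == s.chromosome and start <= s.position and s.position + SITE_LEN - 1 <= end
                    for chrom, start, end in member_spans
                )
            }
            cand.status = filter_candidate(cand, sites, params, on_target)
            if cand.status == "kept":
                kept.append(cand)
            else:
                tallies[cand.status] += 1
        selected = select_sgrnas(kept, params)
        selected_names = {c.name for c in selected}
        per_gene_counts[cluster.cluster_id] = len(selected)
        for cand in kept:
            if cand.name not in selected_names:
                cand.status = "not_selected"
        for cand in selected:
            rows.append(
                {
                    "name": cand.name,
                    "cluster_id": cluster.cluster_id,
                    "member_ids": ",".join(cluster.member_ids),
                    "spacer": cand.spacer,
                    "p": cand.p,
                    "relative_position": cand.relative_position,
                    "gc": cand.gc_fraction,
                    "status": cand.status,
                }
            )

    table = pd.DataFrame(
        rows,
        columns=[
            "name", "cluster_id", "member_ids", "spacer", "p",
            "relative_position", "gc", "status",
        ],
    )
    if table["name"].duplicated().any():
        raise ValueError("duplicate sgRNA names in design")
    controls = design_negative_controls(index, params)
    sublib = dict(sublibrary_map) if sublibrary_map else {}
    return LibraryDesign(
        table=table,
        negative_controls=controls,
        clusters=clusters,
        per_gene_counts=per_gene_counts,
        rejection_tallies=tallies,
        sublibrary_map=sublib,
    )
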