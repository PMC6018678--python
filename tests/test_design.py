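"""Library design: off-target scoring, candidate rules, selection, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crispri_kit import design as dz
from crispri_kit import simulate as sim
from crispri_kit.genome import GeneModel

# ---------------------------------------------------------------------------
# Independent helpers (oracles; deliberately naive, string-based)
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_NGG_PEN = {**{k: 2.5 for k in range(1, 9)}, **{k: 4.5 for k in range(9, 14)},
            **{k: 8.0 for k in range(14, 21)}}
_NAG_PEN = {**{k: 3.0 for k in range(1, 9)}, **{k: 7.0 for k in range(9, 14)},
            **{k: 10.0 for k in range(14, 21)}}


def ref_penalty(pam_class: str, mismatches) -> float:
    if pam_class == "NGG":
        return sum(_NGG_PEN[m] for m in mismatches)
    if pam_class == "NAG":
        return sum(_NAG_PEN[m] for m in mismatches)
    return 100.0 * len(mismatches)


def brute_force_sites(spacer: str, genome: dict, max_mismatch: int = 5) -> set:
    """Naive scan of every genomic 23-mer on both strands."""
    found = set()
    for chrom, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else rc(seq)
            for i in range(n - 22):
                pam = s[i + 20 : i + 23]
                if pam[1] == "G" and pam[2] == "G":
                    pam_class = "NGG"
                elif pam[1] == "A" and pam[2] == "G":
                    pam_class = "NAG"
                else:
                    continue
                mism = []
                for j in range(20):
                    b = s[i + j]
                    if b != spacer[j] or b not in "ACGT":
                        mism.append(j + 1)
                        if len(mism) > max_mismatch:
                            break
                if len(mism) <= max_mismatch:
                    pos = i + 1 if strand == "+" else n - (i + 23) + 1
                    found.add((chrom, pos, strand, pam_class, tuple(mism)))
    return found


def as_tuples(sites) -> set:
    return {
        (s.chromosome, s.position, s.strand, s.pam_class, s.mismatch_positions)
        for s in sites
    }


# ---------------------------------------------------------------------------
# Off-target penalty metric
# ---------------------------------------------------------------------------

def test_region_partition_covers_spacer():
    regions = [set(dz.REGION_III), set(dz.REGION_II), set(dz.REGION_I)]
    assert [len(r) for r in regions] == [8, 5, 7]
    union = set().union(*regions)
    assert union == set(range(1, 21))
    assert sum(len(r) for r in regions) == 20  # disjoint


def test_score_worked_examples():
    # NGG: two Region-I + one Region-II mismatches
    assert dz.score_offtarget_site("NGG", [14, 20, 9]) == pytest.approx(20.5)
    # NGG: one Region-I + one Region-III
    assert dz.score_offtarget_site("NGG", [1, 14]) == pytest.approx(10.5)
    assert dz.score_offtarget_site("NGG", []) == 0.0
    # NAG: one mismatch per region
    assert dz.score_offtarget_site("NAG", [1, 9, 14]) == pytest.approx(20.0)
    # any other PAM: 100 per mismatch
    assert dz.score_offtarget_site("NTT", [5, 12]) == pytest.approx(200.0)


def test_score_rejects_bad_positions():
    with pytest.raises(ValueError):
        dz.score_offtarget_site("NGG", [0])
    with pytest.raises(ValueError):
        dz.score_offtarget_site("NGG", [21])


@given(
    pam=st.sampled_from(["NGG", "NAG", "NCC"]),
    positions=st.sets(st.integers(1, 20), max_size=5),
    extra=st.integers(1, 20),
)
@settings(max_examples=200, deadline=None)
def test_penalty_monotone_in_mismatches(pam, positions, extra):
    base = dz.score_offtarget_site(pam, sorted(positions))
    more = dz.score_offtarget_site(pam, sorted(positions | {extra}))
    assert more >= base
    assert base == pytest.approx(ref_penalty(pam, positions))


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def _gene(cds: str, gene_id: str = "toy") -> GeneModel:
    return GeneModel(gene_id, "chr1", 1, len(cds), "+", cds)


def test_enumerate_no_cc_dinucleotide():
    cds = "ATG" + "A" * 57  # no CC anywhere
    assert dz.enumerate_candidates(_gene(cds)) == []


def test_enumerate_toy_convention():
    # 60-nt cds with its only CC at coding positions (8, 9)
    rng = np.random.default_rng(3)
    while True:
        body = "".join(rng.choice(list("AGT"), 60))  # no C outside the planted CC
        cds = body[:7] + "CC" + body[9:]
        if cds[6:10].count("CC") == 1:
            break
    cands = dz.enumerate_candidates(_gene(cds))
    assert len(cands) == 1
    c = cands[0]
    assert c.name == "toy_9"
    assert c.p == 9
    # spacer = revcomp of coding positions 11..30 (1-based)
    assert c.spacer == rc(cds[10:30])
    assert c.relative_position == pytest.approx(9 / 60)


def test_enumerate_window_bounds():
    # CC at the last eligible position p = L - 21 is kept; one later is not
    L = 60
    cds_ok = "A" * (L - 23) + "CC" + "A" * 21  # p = L - 21 = 39
    cands = dz.enumerate_candidates(_gene(cds_ok))
    assert [c.p for c in cands] == [39]
    cds_late = "A" * (L - 22) + "CC" + "A" * 20  # p = 40 > L - 21
    assert dz.enumerate_candidates(_gene(cds_late)) == []


def test_enumerate_short_gene_empty():
    assert dz.enumerate_candidates(_gene("ATGCCATGA")) == []


def test_enumerate_ordered_by_position():
    rng = np.random.default_rng(5)
    cds = "".join(rng.choice(list("ACGT"), 300))
    cands = dz.enumerate_candidates(_gene(cds))
    ps = [c.p for c in cands]
    assert ps == sorted(ps)
    for c in cands:
        assert len(c.spacer) == 20
        assert 2 <= c.p <= 300 - 21


# ---------------------------------------------------------------------------
# Off-target search
# ---------------------------------------------------------------------------

def _random_genome(n: int, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(rng.choice(list("ACGT"), n))}


def test_find_planted_site():
    rng = np.random.default_rng(11)
    spacer = "".join(rng.choice(list("ACGT"), 20))
    background = "".join(rng.choice(list("ACGT"), 400))
    genome = {"chr1": background[:200] + spacer + "AGG" + background[200:]}
    sites = dz.find_offtarget_sites(spacer, genome)
    exact = [s for s in sites if not s.mismatch_positions]
    assert len(exact) == 1
    s = exact[0]
    assert (s.position, s.strand, s.pam_class, s.penalty) == (201, "+", "NGG", 0.0)


def test_find_site_on_reverse_strand():
    rng = np.random.default_rng(13)
    spacer = "".join(rng.choice(list("ACGT"), 20))
    background = "".join(rng.choice(list("ACGT"), 300))
    genome = {"chr1": background[:150] + rc(spacer + "TGG") + background[150:]}
    sites = dz.find_offtarget_sites(spacer, genome)
    exact = [s for s in sites if not s.mismatch_positions]
    assert len(exact) == 1
    assert exact[0].strand == "-"
    assert exact[0].position == 151


def test_six_mismatches_absent():
    spacer = "ACGTACGTACGTACGTACGT"
    mutated = list(spacer)
    for j in [0, 3, 6, 9, 12, 15]:  # 6 substitutions
        mutated[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[j]]
    genome = {"chr1": "T" * 100 + "".join(mutated) + "AGG" + "T" * 100}
    sites = dz.find_offtarget_sites(spacer, genome)
    assert all(s.position != 101 for s in sites)


def test_ambiguous_base_counts_as_mismatch():
    rng = np.random.default_rng(17)
    spacer = "".join(rng.choice(list("ACGT"), 20))
    planted = spacer[:4] + "N" + spacer[5:]
    genome = {"chr1": "T" * 80 + planted + "CGG" + "T" * 80}
    sites = [s for s in dz.find_offtarget_sites(spacer, genome) if s.position == 81]
    assert len(sites) == 1
    assert 5 in sites[0].mismatch_positions
    assert sites[0].penalty == pytest.approx(ref_penalty("NGG", sites[0].mismatch_positions))


def test_brute_force_oracle_small():
    genome = _random_genome(1000, seed=23)
    rng = np.random.default_rng(29)
    spacers = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(2)]
    # plant one near-match for a non-trivial hit
    near = list(spacers[0])
    near[2], near[15] = "A" if near[2] != "A" else "C", "A" if near[15] != "A" else "C"
    genome["chr1"] = genome["chr1"][:500] + "".join(near) + "TGG" + genome["chr1"][500:]
    index = dz.GenomeIndex(genome)
    for spacer in spacers:
        for mm in (0, 2, 5):
            got = as_tuples(index.scan(spacer, max_mismatch=mm))
            assert got == brute_force_sites(spacer, genome, mm)


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------

def _candidate(spacer: str) -> dz.SgRNACandidate:
    from crispri_kit.genome import gc_fraction

    return dz.SgRNACandidate(
        name="g_10", cluster_id="g", spacer=spacer, p=10,
        relative_position=0.02, gc_fraction=gc_fraction(spacer),
    )


def _site(pam: str, mism, chrom="chr1", pos=100, strand="+") -> dz.OffTargetSite:
    return dz.OffTargetSite(chrom, pos, strand, pam, tuple(mism),
                            dz.score_offtarget_site(pam, mism))


def test_filter_gc_bounds():
    params = dz.DesignParams(mode="genome")
    assert dz.filter_candidate(_candidate("A" * 20), [], params) == "rejected_gc"
    # inclusive boundaries: GC exactly 0.30 and 0.85 are kept
    assert dz.filter_candidate(_candidate("G" * 6 + "A" * 14), [], params) == "kept"
    assert dz.filter_candidate(_candidate("G" * 17 + "A" * 3), [], params) == "kept"
    assert dz.filter_candidate(_candidate("G" * 18 + "A" * 2), [], params) == "rejected_gc"


def test_filter_offtarget_worked_examples():
    spacer = "G" * 10 + "A" * 10  # GC 0.5
    genome_params = dz.DesignParams(mode="genome")  # threshold 21
    tiling_params = dz.DesignParams(mode="tiling")  # threshold 11
    site_205 = _site("NGG", [14, 20, 9])  # 8 + 8 + 4.5 = 20.5
    site_105 = _site("NGG", [1, 14])  # 2.5 + 8 = 10.5
    assert dz.filter_candidate(_candidate(spacer), [site_205], genome_params) == "rejected_offtarget"
    assert dz.filter_candidate(_candidate(spacer), [site_105], tiling_params) == "rejected_offtarget"
    # 20.5 is not significant under the tiling threshold 11
    assert dz.filter_candidate(_candidate(spacer), [site_205], tiling_params) == "kept"


def test_filter_on_target_exemption():
    spacer = "G" * 10 + "A" * 10
    params = dz.DesignParams(mode="genome")
    perfect = _site("NGG", [], pos=250)
    on_target = {("chr1", 250, "+")}
    assert dz.filter_candidate(_candidate(spacer), [perfect], params, on_target) == "kept"
    assert dz.filter_candidate(_candidate(spacer), [perfect], params) == "rejected_offtarget"


def test_filter_gc_checked_before_offtarget():
    params = dz.DesignParams(mode="genome")
    assert dz.filter_candidate(_candidate("A" * 20), [_site("NGG", [])], params) == "rejected_gc"


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _cands_at(ps, L):
    return [
        dz.SgRNACandidate(f"g_{p}", "g", "A" * 20, p, p / L, 0.5) for p in ps
    ]


def test_select_genome_fill():
    L = 1000
    active = _cands_at([10, 20, 40], L)  # relative_position <= 0.05
    downstream = _cands_at(range(100, 100 + 24 * 30, 30), L)
    params = dz.DesignParams(mode="genome")
    picked = dz.select_sgrnas(active + downstream, params)
    assert len(picked) == 15
    assert picked[:3] == sorted(active, key=lambda c: c.p)
    fill = picked[3:]
    ranks = np.unique(np.round(np.linspace(0, 23, 12)).astype(int))
    assert [c.p for c in fill] == [downstream[r].p for r in ranks]
    # first and last downstream candidates are always included
    assert downstream[0] in fill and downstream[-1] in fill


def test_select_genome_active_overflow():
    L = 2000
    active = _cands_at(range(5, 5 + 20 * 4, 4), L)  # 20 candidates, all <= 0.05
    picked = dz.select_sgrnas(active, dz.DesignParams(mode="genome"))
    assert len(picked) == 15
    assert [c.p for c in picked] == [c.p for c in active[:15]]
    assert all(c.relative_position <= 0.05 for c in picked)


def test_select_empty():
    assert dz.select_sgrnas([], dz.DesignParams(mode="genome")) == []


def test_select_tiling_first_m():
    L = 5000
    cands = _cands_at(range(10, 10 + 60 * 7, 7), L)
    picked = dz.select_sgrnas(cands, dz.DesignParams(mode="tiling"))
    assert len(picked) == 50
    assert [c.p for c in picked] == [c.p for c in cands[:50]]


def test_select_fewer_than_max():
    cands = _cands_at([100, 200], 1000)
    assert len(dz.select_sgrnas(cands, dz.DesignParams(mode="genome"))) == 2


# ---------------------------------------------------------------------------
# Negative controls
# ---------------------------------------------------------------------------

def test_negative_controls_verified_site_free():
    genome = _random_genome(3000, seed=31)
    params = dz.DesignParams(mode="genome", n_negative_controls=15, seed=4)
    controls = dz.design_negative_controls(genome, params)
    assert len(controls) == 15
    for spacer in controls:
        gc = (spacer.count("G") + spacer.count("C")) / 20
        assert 0.30 <= gc <= 0.85
        assert brute_force_sites(spacer, genome, 5) == set()


def test_negative_controls_deterministic():
    genome = _random_genome(2000, seed=37)
    params = dz.DesignParams(mode="genome", n_negative_controls=10, seed=9)
    assert dz.design_negative_controls(genome, params) == dz.design_negative_controls(
        genome, params
    )


def test_negative_controls_budget_error():
    genome = _random_genome(2000, seed=37)
    params = dz.DesignParams(mode="genome", n_negative_controls=10, nc_attempt_budget=0)
    with pytest.raises(RuntimeError, match="budget"):
        dz.design_negative_controls(genome, params)


# ---------------------------------------------------------------------------
# Gene clustering
# ---------------------------------------------------------------------------

def _rand_gene(gene_id, length, seed, start=1):
    rng = np.random.default_rng(seed)
    cds = "".join(rng.choice(list("ACGT"), length))
    return GeneModel(gene_id, "chr1", start, start + length - 1, "+", cds)


def test_cluster_identical_pair():
    a = _rand_gene("a", 300, 1)
    b = GeneModel("b", "chr1", 400, 699, "+", a.cds_sequence)
    (cluster,) = dz.cluster_genes([a, b])
    assert sorted(cluster.member_ids) == ["a", "b"]


def test_cluster_99_percent_identity_pair():
    a = _rand_gene("tufA", 300, 2)
    seq = list(a.cds_sequence)
    for i in (10, 150, 290):  # 3 substitutions = 99% identity
        seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
    b = GeneModel("tufB", "chr1", 400, 699, "+", "".join(seq))
    (cluster,) = dz.cluster_genes([a, b])
    assert sorted(cluster.member_ids) == ["tufA", "tufB"]


def test_cluster_random_pair_singletons():
    genes = [_rand_gene("a", 300, 3), _rand_gene("b", 300, 4, start=400)]
    clusters = dz.cluster_genes(genes)
    assert sorted(len(c.member_ids) for c in clusters) == [1, 1]


def test_cluster_coverage_gate():
    a = _rand_gene("long", 300, 5)
    b = GeneModel("short", "chr1", 400, 639, "+", a.cds_sequence[:240])
    clusters = dz.cluster_genes([a, b])  # 240/300 = 0.8 < 0.95 coverage
    assert len(clusters) == 2


def test_cluster_partition_and_order_invariance():
    genes = [_rand_gene(f"g{i}", 300, 10 + i) for i in range(4)]
    dup = GeneModel("g0dup", "chr1", 2000, 2299, "+", genes[0].cds_sequence)
    pool = genes + [dup]
    forward = dz.cluster_genes(pool)
    backward = dz.cluster_genes(pool[::-1])
    assert {frozenset(c.member_ids) for c in forward} == {
        frozenset(c.member_ids) for c in backward
    }
    members = sorted(m for c in forward for m in c.member_ids)
    assert members == sorted(g.gene_id for g in pool)  # exact partition


def test_cluster_representative_longest_then_lexicographic():
    a = _rand_gene("zzz", 300, 6)
    b = GeneModel("aaa", "chr1", 400, 699, "+", a.cds_sequence)
    (cluster,) = dz.cluster_genes([a, b])
    assert cluster.representative_id == "aaa"  # equal length, lexicographic


def test_cluster_edge_cases():
    assert dz.cluster_genes([]) == []
    bad = GeneModel("empty", "chr1", 1, 1, "+", "A")
    bad.cds_sequence = ""
    with pytest.raises(ValueError):
        dz.cluster_genes([bad])


# ---------------------------------------------------------------------------
# Full library design
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def designed(tiny_genome):
    genome, genes = tiny_genome
    params = dz.DesignParams(mode="genome", n_negative_controls=25, seed=0)
    return genome, genes, params, dz.design_library(genome, genes, params)


def test_design_library_against_reference():
    """Per-gene selections equal an independent naive implementation."""
    genome, genes = sim.make_genome_annotation(6, gene_length_range=(240, 360), seed=41)
    params = dz.DesignParams(mode="genome", n_negative_controls=5, seed=1)
    lib = dz.design_library(genome, genes, params)

    for gene in genes:
        cds, L = gene.cds_sequence, len(gene.cds_sequence)
        kept = []
        for p in range(2, L - 20):  # 1-based p in [2, L-21]
            if cds[p - 2 : p] != "CC":
                continue
            spacer = rc(cds[p + 1 : p + 21])
            gc = (spacer.count("G") + spacer.count("C")) / 20
            if not (0.30 <= gc <= 0.85):
                continue
            rejected = False
            for chrom, pos, strand, pam, mism in brute_force_sites(spacer, genome, 5):
                on_target = (
                    not mism
                    and chrom == gene.chromosome
                    and gene.start <= pos
                    and pos + 22 <= gene.end
                )
                if not on_target and ref_penalty(pam, mism) < 21:
                    rejected = True
                    break
            if not rejected:
                kept.append(p)
        active = [p for p in kept if p / L <= 0.05]
        expected = active[:15]
        fill = 15 - len(expected)
        remaining = [p for p in kept if p / L > 0.05]
        if fill > 0 and remaining:
            k = min(fill, len(remaining))
            ranks = np.unique(np.round(np.linspace(0, len(remaining) - 1, k)).astype(int))
            expected += [remaining[r] for r in ranks]
        got = sorted(
            lib.table.loc[lib.table["cluster_id"] == gene.gene_id, "p"].astype(int)
        )
        assert got == sorted(expected), gene.gene_id


def test_design_library_duplicate_clusters(designed):
    genome, genes, params, lib = designed
    sizes = sorted(len(c.member_ids) for c in lib.clusters)
    assert sizes == [1] * 6 + [2, 2]
    for cluster in lib.clusters:
        if len(cluster.member_ids) < 2:
            continue
        rows = lib.table[lib.table["cluster_id"] == cluster.cluster_id]
        assert (rows["member_ids"] == ",".join(cluster.member_ids)).all()
        # every selected spacer's coding context is present in each member
        by_id = {g.gene_id: g for g in genes}
        rep = by_id[cluster.representative_id]
        for _, row in rows.iterrows():
            p = int(row["p"])
            context = rep.cds_sequence[p - 2 : p + 21]
            for member in cluster.member_ids:
                assert context in by_id[member].cds_sequence


def test_design_library_posthoc_invariants(designed):
    genome, genes, params, lib = designed
    index = dz.GenomeIndex(genome)
    by_id = {g.gene_id: g for g in genes}
    cluster_by_id = {c.cluster_id: c for c in lib.clusters}
    for _, row in lib.table.iterrows():
        assert params.gc_min <= row["gc"] <= params.gc_max
        members = [by_id[m] for m in cluster_by_id[row["cluster_id"]].member_ids]
        for site in index.scan(row["spacer"], max_mismatch=5):
            on_target = not site.mismatch_positions and any(
                m.chromosome == site.chromosome
                and m.start <= site.position
                and site.position + 22 <= m.end
                for m in members
            )
            if not on_target:
                assert site.penalty >= params.offtarget_threshold
    # per-cluster cap and name uniqueness
    assert all(v <= params.max_per_gene for v in lib.per_gene_counts.values())
    assert not lib.table["name"].duplicated().any()
    assert len(lib.negative_controls) == params.n_negative_controls


def test_design_library_deterministic(designed):
    genome, genes, params, lib = designed
    again = dz.design_library(genome, genes, params)
    assert lib.table.equals(again.table)
    assert lib.negative_controls == again.negative_controls


def test_design_library_short_gene_no_crash(tiny_genome):
    genome, genes = tiny_genome
    short = GeneModel("stub", "chr1", 1, 21, "+", genome["chr1"][:21])
    params = dz.DesignParams(mode="genome", n_negative_controls=3, seed=2)
    lib = dz.design_library(genome, list(genes) + [short], params)
    assert lib.per_gene_counts.get("stub", 0) == 0


def test_coverage_report(designed):
    _, _, _, lib = designed
    report = lib.coverage_report()
    assert set(report["cluster_id"]) == {c.cluster_id for c in lib.clusters}
    assert report["ge1"].all()  # every 240+ nt random gene yields sgRNAs
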