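"""Shared fixtures: synthetic screen builders used across the test suite."""

import numpy as np
import pandas as pd
import pytest

from crispri_kit import simulate as sim


def make_library(n_genes: int, n_sg: int, n_nc: int = 400, n_active: int = 3) -> pd.DataFrame:
    """Library table mimicking genome-mode design geometry.

    The first ``n_active`` sgRNAs of each gene lie inside the 5% active
    region; the rest are spread evenly over the remaining ORF.
    """
    n_active = min(n_active, n_sg)
    rows = []
    for g in range(n_genes):
        for j in range(n_sg):
            if j < n_active:
                rel = (j + 1) * 0.05 / (n_active + 1)
            else:
                rel = 0.05 + (j - n_active + 1) * 0.95 / (n_sg - n_active)
            rows.append(
                {
                    "name": f"g{g:04d}_{j + 1}",
                    "cluster_id": f"g{g:04d}",
                    "p": j + 1,
                    "relative_position": rel,
                }
            )
    for k in range(n_nc):
        rows.append(
            {"name": f"NC_{k + 1}", "cluster_id": None, "p": np.nan, "relative_position": np.nan}
        )
    return pd.DataFrame(rows).set_index("name")


def make_screen(
    n_genes: int,
    n_sg: int,
    seed: int,
    frac_hit: float = 0.0,
    effect: float = -6.0,
    depth: float = 100.0,
    heterogeneous: bool = True,
    n_nc: int = 400,
):
    """Simulated screen with planted effects.

    Returns ``(library, counts, truth, hit_gene_set)``.
    """
    rng = np.random.default_rng(seed)
    library = make_library(n_genes, n_sg, n_nc=n_nc)
    n_hit = int(round(frac_hit * n_genes))
    hits = [f"g{g:04d}" for g in rng.choice(n_genes, n_hit, replace=False)]
    activities = sim.sample_activities(library, rng, heterogeneous=heterogeneous)
    truth = sim.SimulationTruth(
        gene_effects={g: effect for g in hits},
        sgrna_activity=activities,
        doublings=abs(effect) if effect else 6.0,
        depth=depth,
        seed=seed,
    )
    counts = sim.simulate_screen_counts(library, truth, depth=depth)
    return library, counts, truth, set(hits)


@pytest.fixture(scope="session")
def library_factory():
    return make_library


@pytest.fixture(scope="session")
def screen_factory():
    return make_screen


@pytest.fixture(scope="session")
def tiny_genome():
    """Small random genome + annotation with two duplicated gene pairs."""
    genome, genes = sim.make_genome_annotation(
        10, gene_length_range=(240, 420), n_duplicate_pairs=2, seed=7
    )
    return genome, genes
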