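"""Screen-analysis model: counts in, gene-level calls out.

:class:`CrisprScreen` bundles a count table, the designed library and the
phenotype design (selective vs control libraries) into a fitted model;
:meth:`CrisprScreen.fit` runs normalization, low-count filtering, replicate
combination, sgRNA fitness/Z computation, quasi-gene null construction and
gene calling, returning a :class:`CrisprScreenResults` with the tables, the
null model and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from crispri_kit import counting, stats


class CrisprScreen:
    """A pooled CRISPRi screen ready to be fitted.

    Parameters
    ----------
    counts : DataFrame
        sgRNA x library raw counts (rows indexed by sgRNA name).
    library : DataFrame
        Designed-library table with at least columns ``cluster_id`` and ``p``
        for gene-targeting sgRNAs, indexed by sgRNA name.  Negative controls
        are the rows listed in ``nc_names`` (default: names starting with
        ``NC_``).
    selective, control : str or sequence of str
        Library labels for the selective and control conditions; two labels
        mean biological replicates combined by geometric mean.
    reference : str, optional
        Library used for the <20-read filter (defaults to the control; the
        initial library of the experiment when available).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        library: pd.DataFrame,
        selective,
        control,
        nc_names=None,
        reference: str | None = None,
        min_reads: float = 20,
    ):
        self.counts = counts
        self.library = library
        self.selective = [selective] if isinstance(selective, str) else list(selective)
        self.control = [control] if isinstance(control, str) else list(control)
        if set(self.selective) & set(self.control):
            raise ValueError("selective and control libraries must differ")
        if nc_names is None:
            nc_names = [n for n in counts.index if str(n).startswith("NC_")]
        self.nc_names = list(nc_names)
        self.reference = reference
        self.min_reads = min_reads

    @classmethod
    def from_tables(
        cls, counts_tsv, library_tsv, selective, control, **kwargs
    ) -> "CrisprScreen":
        """Build a model from count and library TSV files."""
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        library = pd.read_csv(library_tsv, sep="\t", index_col=0)
        return cls(counts, library, selective, control, **kwargs)

    def _combined_condition(self, normalized: pd.DataFrame, labels: list[str]) -> pd.Series:
        if len(labels) == 1:
            return normalized[labels[0]]
        if len(labels) == 2:
            a = normalized[[labels[0]]].rename(columns={labels[0]: "x"})
            b = normalized[[labels[1]]].rename(columns={labels[1]: "x"})
            return counting.combine_replicates(a, b)["x"]
        raise ValueError("a condition takes one library or two replicates")

    def fit(
        self,
        n_quasi: int = 10_000,
        max_size: int = 15,
        fdr: float = 0.05,
        seed: int = 0,
        p_method: str = "asymptotic",
        exclude=None,
    ) -> "CrisprScreenResults":
        normalized = counting.normalize_counts(self.counts)
        reference = self.reference or self.control[0]
        filtered = counting.filter_low_count(normalized, reference, self.min_reads)
        sel = self._combined_condition(filtered, self.selective)
        ctrl = self._combined_condition(filtered, self.control)
        nc_present = [n for n in self.nc_names if n in filtered.index]
        fitness = stats.sgrna_fitness(sel, ctrl, nc_present)
        fitness, sigma = stats.z_scores(fitness)
        if "relative_position" in self.library.columns:
            fitness = fitness.join(self.library["relative_position"], how="left")

        nc_fitness = fitness.loc[fitness["is_nc"], "fitness"].to_numpy()
        null_model = stats.build_fpr_curves(
            nc_fitness, n_quasi=n_quasi, max_size=max_size, seed=seed, p_method=p_method
        )

        targeting = fitness.loc[~fitness["is_nc"]].join(
            self.library[["cluster_id", "p"]], how="inner"
        )
        fitness_by_gene = {
            str(gene): grp.sort_values("p")["fitness"].to_numpy()
            for gene, grp in targeting.groupby("cluster_id")
        }
        gene_table = stats.call_genes(fitness_by_gene, nc_fitness, null_model)
        gene_table["q_value"] = stats.estimate_qvalues(gene_table["fpr"].to_numpy())
        gene_table = stats.call_hits(gene_table, fdr=fdr, exclude=exclude)
        return CrisprScreenResults(
            model=self,
            sgrna_table=fitness,
            gene_table=gene_table,
            null_model=null_model,
            sigma=sigma,
            fdr=fdr,
        )


@dataclass
class CrisprScreenResults:
    """Fitted screen: sgRNA fitness/Z, gene calls, and the FPR null."""

    model: CrisprScreen
    sgrna_table: pd.DataFrame
    gene_table: pd.DataFrame
    null_model: "stats.NullModel"
    sigma: float
    fdr: float

    @property
    def hits(self) -> pd.DataFrame:
        return self.gene_table.loc[self.gene_table["hit"]]

    def active_sgrnas(self, z_threshold: float = 2.0) -> pd.Series:
        """Boolean activity call per sgRNA at the |Z| >= threshold rule."""
        return self.sgrna_table["Z"].abs() >= z_threshold

    def position_profile(self, bin_width: float = 0.05) -> pd.DataFrame:
        table = self.sgrna_table.dropna(subset=["relative_position"])
        return stats.position_activity_profile(table, bin_width=bin_width)

    def summary(self) -> str:
        g = self.gene_table
        lines = [
            "Pooled CRISPRi screen fit",
            "=" * 41,
            f"sgRNAs analysed:          {len(self.sgrna_table):>8d}",
            f"  negative controls:      {int(self.sgrna_table['is_nc'].sum()):>8d}",
            f"NC fitness sigma:         {self.sigma:>8.3f}",
            f"genes (clusters) called:  {len(g):>8d}",
            f"hits at FDR {self.fdr:.2g}:          {int(g['hit'].sum()):>8d}",
            f"  depleted / enriched:    {int((g['hit'] & (g['direction'] == 'depleted')).sum()):>4d} / "
            f"{int((g['hit'] & (g['direction'] == 'enriched')).sum()):<4d}",
            f"  no-doubling (<= -6):    {int(g['no_doubling'].sum()):>8d}",
            f"null model: sizes 1..{self.null_model.max_size}, "
            f"{self.null_model.n_quasi} quasi genes/size, seed {self.null_model.seed}",
        ]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sgrna_table.to_csv(out / "sgrna_fitness.tsv", sep="\t")
        self.gene_table.to_csv(out / "gene_results.tsv", sep="\t")
        self.null_model.to_frame().to_csv(out / "null_model.tsv", sep="\t", index=False)
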