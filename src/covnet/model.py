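"""Model/Results front-end over the covariance-network pipeline.

:class:`StructuralCovarianceNetwork` plays the role of a statsmodels-style
model object: it is built from one group's data (volumes + covariates) and
``fit`` runs the pipeline — confound regression, Pearson correlation,
sparsity thresholding, small-world indices against degree-matched surrogates,
betweenness/hub detection — returning a
:class:`StructuralCovarianceResults` that carries the estimates and exposes
group comparison, bootstrap uncertainty, and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, aal_region_table
from .cohort import Cohort
from . import graph, io, network, stats


class StructuralCovarianceNetwork:
    """Structural covariance network model for one diagnostic group.

    Parameters
    ----------
    volumes, covariates
        Per-subject regional volumes (atlas order) and ``age`` / ``sex`` /
        ``total_gm_volume`` covariates; see :class:`covnet.cohort.Cohort`.
    group_label
        Name of the group ("NC", "MCI", "AD", ...).
    atlas
        Region atlas; defaults to AAL-90.
    """

    def __init__(self, volumes: pd.DataFrame, covariates: pd.DataFrame,
                 group_label: str = "group", atlas: RegionAtlas | None = None):
        self.cohort = Cohort(group_label=group_label, volumes=volumes,
                             covariates=covariates, atlas=atlas or aal_region_table())

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "StructuralCovarianceNetwork":
        obj = cls.__new__(cls)
        obj.cohort = cohort
        return obj

    @classmethod
    def from_csv(cls, path, group_label: str,
                 atlas: RegionAtlas | None = None) -> "StructuralCovarianceNetwork":
        return cls.from_cohort(io.read_cohort(path, group_label, atlas=atlas))

    def fit(self, sparsity: float = 0.15, n_random: int = 100, seed=None,
            rank: str = "absolute") -> "StructuralCovarianceResults":
        """Run the full pipeline at one sparsity and return the results."""
        residuals = network.residualize(self.cohort)
        corr = network.correlation_matrix(residuals)
        net = graph.threshold_by_sparsity(corr, sparsity, rank=rank)
        global_metrics = graph.small_world_indices(net, n_random=n_random, seed=seed)
        nodal = graph.nodal_metrics(net)
        return StructuralCovarianceResults(
            model=self, residuals=residuals, corr=corr, net=net,
            global_metrics=global_metrics, nodal=nodal,
            sparsity=sparsity, n_random=n_random, seed=seed, rank=rank,
        )


@dataclass
class StructuralCovarianceResults:
    """Fitted group network with its metrics."""

    model: StructuralCovarianceNetwork
    residuals: network.ResidualMatrix
    corr: network.CorrelationMatrix
    net: graph.BinaryNetwork
    global_metrics: graph.GlobalMetrics
    nodal: pd.DataFrame
    sparsity: float
    n_random: int
    seed: object
    rank: str

    @property
    def cohort(self) -> Cohort:
        return self.model.cohort

    @property
    def hubs(self) -> pd.DataFrame:
        """Hub regions (normalized betweenness > 2), strongest first."""
        h = self.nodal[self.nodal["hub"]]
        return h.sort_values("normalized_betweenness", ascending=False).reset_index(drop=True)

    # -- comparisons --------------------------------------------------------
    def compare_edges(self, other: "StructuralCovarianceResults",
                      q: float = 0.01, method: str = "bh") -> stats.EdgeDifferenceResult:
        """Edge-wise Fisher-z comparison (other vs self) with FDR at q."""
        return stats.edge_difference_map(self.corr, other.corr, q=q, method=method)

    def permutation_test(self, other: "StructuralCovarianceResults",
                         n_perm: int = 1000, seed=None) -> stats.PermutationResult:
        """Label-permutation test of Cp/Lp differences (self minus other)."""
        return stats.permutation_test_metrics(self.cohort, other.cohort,
                                              sparsity=self.sparsity,
                                              n_perm=n_perm, seed=seed, rank=self.rank)

    def bootstrap_ci(self, n_boot: int = 1000, seed=None, n_random: int = 10) -> pd.DataFrame:
        """Bootstrap SEs and percentile intervals for Cp, Lp, gamma, lambda."""
        return stats.bootstrap_metric_ci(self.cohort, self.sparsity, n_boot=n_boot,
                                         seed=seed, n_random=n_random, rank=self.rank)

    # -- output -------------------------------------------------------------
    def summary(self) -> str:
        gm = self.global_metrics
        c = self.cohort
        lines = [
            "Structural Covariance Network Results",
            "=" * 53,
            f"Group:                {c.group_label}",
            f"Subjects:             {c.n_subjects}",
            f"Regions:              {c.n_regions}",
            f"Confound design rank: {self.residuals.design_rank}",
            f"Sparsity:             {self.sparsity:.3f}  (K = {self.net.n_edges} edges)",
            f"Surrogates:           {self.n_random} (degree-matched rewired)",
            "-" * 53,
            f"Cp     (clustering):        {gm.Cp:.4f}",
            f"Lp     (path length):       {gm.Lp:.4f}",
            f"gamma  (Cp / Cp_rand):      {gm.gamma:.4f}",
            f"lambda (Lp / Lp_rand):      {gm.lam:.4f}",
            "-" * 53,
        ]
        hubs = self.hubs
        if len(hubs):
            lines.append("Hub regions (normalized betweenness > 2):")
            for _, row in hubs.iterrows():
                lines.append(f"  {row['name']:<24s} b = {row['normalized_betweenness']:.3f}")
        else:
            lines.append("Hub regions: none")
        return "\n".join(lines)

    def save_outputs(self, directory, prefix: str | None = None) -> None:
        """Write the correlation matrix, edge list and nodal table to CSV."""
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.cohort.group_label.lower()
        io.write_matrix(self.corr.r, directory / f"{prefix}_corr.csv",
                        atlas=self.corr.atlas, group_label=self.corr.group_label,
                        n_subjects=self.corr.n_subjects)
        edges = [(i, j, self.corr.r[i, j]) for i, j in self.net.edges()]
        io.write_edge_list(edges, directory / f"{prefix}_edges.csv",
                           atlas=self.corr.atlas, value_name="r")
        self.nodal.to_csv(directory / f"{prefix}_nodal.csv", index=False)

    def plot_small_world(self, sparsities=None, seed=None, n_random: int = 20, ax=None):
        """Gamma/lambda versus sparsity for this cohort (see covnet.plotting)."""
        from . import plotting
        df = small_world_curve(self.cohort, sparsities=sparsities, seed=seed,
                               n_random=n_random, rank=self.rank)
        return plotting.plot_small_world_curve(df, ax=ax)


def small_world_curve(cohort: Cohort, sparsities=None, n_random: int = 20,
                      seed=None, rank: str = "absolute") -> pd.DataFrame:
    """Cp/Lp/gamma/lambda across a sparsity range for one cohort."""
    if sparsities is None:
        sparsities = np.arange(0.10, 0.31, 0.05)
    sparsities = [float(s) for s in sparsities]
    corr = network.cohort_correlation(cohort)
    ss = np.random.SeedSequence(seed)
    rows = []
    for s, child in zip(sparsities, ss.spawn(len(sparsities))):
        net = graph.threshold_by_sparsity(corr, float(s), rank=rank)
        gm = graph.small_world_indices(net, n_random=n_random, seed=child)
        rows.append({"sparsity": float(s), **gm.as_dict()})
    return pd.DataFrame(rows)
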