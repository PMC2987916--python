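"""Between-group inference on covariance networks.

Two procedures:

* **Edge-wise Fisher-z comparison.** Each group's correlation r is mapped to
  z = arctanh(r), approximately normal with variance 1/(n-3); the two-group
  statistic Z = (z_A - z_B) / sqrt(1/(n_A-3) + 1/(n_B-3)) is referred to the
  standard normal and the resulting p-values over all region pairs are
  corrected by the Benjamini–Hochberg false-discovery-rate procedure.

* **Label-permutation tests of network topology.** The observed between-group
  difference in a network statistic (Cp, Lp, or per-node normalized
  betweenness) is compared with its null distribution obtained by pooling the
  two cohorts, relabeling subjects at the original group sizes, and re-running
  the *entire* pipeline (confound regression → correlation → sparsity
  threshold → metric) for each pseudo-group. A difference outside the
  2.5th–97.5th percentile band of the null is significant at the two-tailed
  5% level.

Bootstrap resampling of subjects (again re-running the full pipeline per
resample) supplies standard errors and percentile intervals for Cp, Lp,
gamma and lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort
from .exceptions import ContractError, DegenerateDataError, DisconnectedNetworkError
from .graph import _cp_lp, edge_count_for_sparsity, top_k_adjacency, small_world_indices, \
    threshold_by_sparsity, nodal_metrics
from .network import CorrelationMatrix, ols_residuals, residualize, correlation_matrix

logger = logging.getLogger(__name__)

_FDR_METHODS = {"bh": "fdr_bh", "by": "fdr_by"}


# ---------------------------------------------------------------------------
# Fisher-z machinery
# ---------------------------------------------------------------------------

def fisher_z(r):
    """z = arctanh(r) = 0.5 ln((1+r)/(1-r)); domain |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ContractError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def compare_edge(r_a: float, n_a: int, r_b: float, n_b: int) -> tuple[float, float]:
    """Two-sample comparison of correlation coefficients.

    Returns ``(z_stat, p_value)`` with Z = (z(r_a) - z(r_b)) /
    sqrt(1/(n_a-3) + 1/(n_b-3)) and a two-tailed normal p-value.
    """
    if n_a <= 3 or n_b <= 3:
        raise ContractError("both group sizes must exceed 3 (variance 1/(n-3))")
    z = (fisher_z(r_a) - fisher_z(r_b)) / np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def fdr_mask(p_values, q: float, method: str = "bh") -> np.ndarray:
    """Benjamini–Hochberg (or Benjamini–Yekutieli) rejection mask at level q."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ContractError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ContractError("q must lie in (0, 1)")
    if method not in _FDR_METHODS:
        raise ContractError(f"method must be one of {sorted(_FDR_METHODS)}")
    reject, *_ = multipletests(p, alpha=q, method=_FDR_METHODS[method])
    return reject


@dataclass
class EdgeDifferenceResult:
    """Edge-wise between-group correlation differences (comparison B vs A).

    ``table`` has one row per unordered region pair (i < j) with the two
    correlations, the Fisher-z statistic, its p-value, the FDR decision at
    level ``q``, and for significant pairs the direction of change
    (sign of r_B - r_A).
    """

    table: pd.DataFrame
    q: float
    group_a: str
    group_b: str
    method: str = "bh"

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_edges(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)


def edge_difference_map(corr_a: CorrelationMatrix, corr_b: CorrelationMatrix,
                        q: float = 0.01, method: str = "bh") -> EdgeDifferenceResult:
    """Fisher-z comparison of every region pair between two groups, FDR at q."""
    if corr_a.atlas.abbreviations != corr_b.atlas.abbreviations:
        raise ContractError("correlation matrices are on different atlases")
    n = corr_a.r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    ra, rb = corr_a.r[iu, ju], corr_b.r[iu, ju]
    if np.any(np.abs(ra) >= 1) or np.any(np.abs(rb) >= 1):
        raise DegenerateDataError("degenerate correlation of magnitude 1 in input")
    if corr_a.n_subjects <= 3 or corr_b.n_subjects <= 3:
        raise ContractError("both group sizes must exceed 3")
    se = np.sqrt(1.0 / (corr_a.n_subjects - 3) + 1.0 / (corr_b.n_subjects - 3))
    z = (np.arctanh(ra) - np.arctanh(rb)) / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    significant = fdr_mask(p, q, method=method)
    labels = corr_a.atlas.abbreviations
    direction = np.where(significant, np.where(rb - ra > 0, "increase", "decrease"), "")
    table = pd.DataFrame(
        {
            "region_i": [labels[i] for i in iu],
            "region_j": [labels[j] for j in ju],
            "i": iu, "j": ju,
            "r_a": ra, "r_b": rb,
            "z_stat": z, "p_value": p,
            "significant": significant,
            "direction": direction,
        }
    )
    return EdgeDifferenceResult(table=table, q=q, group_a=corr_a.group_label,
                                group_b=corr_b.group_label, method=method)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _design_matrix(covs: np.ndarray) -> np.ndarray:
    """Intercept + non-constant covariate columns."""
    n = covs.shape[0]
    cols = [np.ones(n)]
    for k in range(covs.shape[1]):
        if np.ptp(covs[:, k]) > 0:
            cols.append(covs[:, k])
    return np.column_stack(cols)


def _pipeline_adjacency(volumes: np.ndarray, covs: np.ndarray, k_edges: int,
                        rank: str = "absolute") -> np.ndarray:
    """Residualize → correlate → threshold; the per-(pseudo-)group pipeline."""
    res = ols_residuals(volumes, _design_matrix(covs))
    sd = res.std(axis=0)
    if np.any(sd < 1e-13 * max(1.0, float(np.abs(res).max()))):
        raise DegenerateDataError("zero-variance region after residualization")
    r = np.corrcoef(res, rowvar=False)
    return top_k_adjacency(r, k_edges, rank=rank)


def _pipeline_cp_lp(volumes, covs, k_edges, rank="absolute") -> tuple[float, float]:
    return _cp_lp(_pipeline_adjacency(volumes, covs, k_edges, rank=rank))


@dataclass
class PermutationResult:
    """Permutation test of between-group differences in Cp and Lp.

    Differences are A minus B. ``significant`` per metric means the observed
    difference falls outside the [2.5%, 97.5%] percentile band of the null.
    """

    sparsity: float
    observed_dCp: float
    observed_dLp: float
    null_dCp: np.ndarray
    null_dLp: np.ndarray
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    significant: dict[str, bool]
    p_value: dict[str, float]
    n_perm: int
    seed: object
    group_a: str = ""
    group_b: str = ""
    n_redrawn: int = 0

    def as_dict(self) -> dict:
        return {
            "sparsity": self.sparsity,
            "observed_dCp": self.observed_dCp,
            "observed_dLp": self.observed_dLp,
            "ci_lower": dict(self.ci_lower),
            "ci_upper": dict(self.ci_upper),
            "significant": {k: bool(v) for k, v in self.significant.items()},
            "p_value": dict(self.p_value),
            "n_perm": self.n_perm,
            "n_redrawn": self.n_redrawn,
            "groups": [self.group_a, self.group_b],
        }


def _empirical_p(null: np.ndarray, observed: float) -> float:
    """Two-tailed permutation p with the +1 correction."""
    return float((1 + np.sum(np.abs(null) >= abs(observed))) / (len(null) + 1))


def permutation_test_metrics(cohort_a: Cohort, cohort_b: Cohort, sparsity: float,
                             n_perm: int = 1000, seed=None,
                             rank: str = "absolute") -> PermutationResult:
    """Label-permutation test of the Cp and Lp group differences.

    Pools the two cohorts, relabels subjects ``n_perm`` times at the original
    group sizes, and re-runs the full per-group pipeline (confound regression
    is refit within each pseudo-group) at the same sparsity. Permutations
    whose pseudo-networks are disconnected at this sparsity are redrawn (the
    count is logged and reported).
    """
    if cohort_a.atlas.abbreviations != cohort_b.atlas.abbreviations:
        raise ContractError("cohorts are on different atlases")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; percentile bounds will be unstable", n_perm)
    n_pairs = cohort_a.atlas.n_possible_edges
    k_edges = edge_count_for_sparsity(sparsity, n_pairs)
    if not 0 < sparsity <= 1 or k_edges == 0:
        raise ContractError(f"sparsity {sparsity} yields no edges")

    va, ca = cohort_a.volume_matrix(), cohort_a.covariate_matrix()
    vb, cb = cohort_b.volume_matrix(), cohort_b.covariate_matrix()
    cp_a, lp_a = _pipeline_cp_lp(va, ca, k_edges, rank)
    cp_b, lp_b = _pipeline_cp_lp(vb, cb, k_edges, rank)
    observed_dcp, observed_dlp = cp_a - cp_b, lp_a - lp_b

    pooled_v = np.vstack([va, vb])
    pooled_c = np.vstack([ca, cb])
    n_a, n_total = va.shape[0], pooled_v.shape[0]

    rng = np.random.default_rng(seed)
    null_dcp = np.empty(n_perm)
    null_dlp = np.empty(n_perm)
    redrawn = 0
    max_attempts = 20 * n_perm + 100
    attempts = 0
    k = 0
    while k < n_perm:
        if attempts >= max_attempts:
            raise DegenerateDataError(
                f"permutation redraw budget exhausted after {redrawn} disconnected draws; "
                "networks at this sparsity are too fragmented"
            )
        attempts += 1
        perm = rng.permutation(n_total)
        ia, ib = perm[:n_a], perm[n_a:]
        try:
            cp1, lp1 = _pipeline_cp_lp(pooled_v[ia], pooled_c[ia], k_edges, rank)
            cp2, lp2 = _pipeline_cp_lp(pooled_v[ib], pooled_c[ib], k_edges, rank)
        except (DisconnectedNetworkError, DegenerateDataError):
            redrawn += 1
            continue
        null_dcp[k] = cp1 - cp2
        null_dlp[k] = lp1 - lp2
        k += 1
    if redrawn:
        logger.info("redrew %d permutations with disconnected pseudo-networks", redrawn)

    ci_lower, ci_upper, significant, p_value = {}, {}, {}, {}
    for name, null, obs in (("Cp", null_dcp, observed_dcp), ("Lp", null_dlp, observed_dlp)):
        # order-statistic (non-interpolating) percentiles: the standard
        # conservative convention for empirical permutation bands
        lo = np.percentile(null, 2.5, method="lower")
        hi = np.percentile(null, 97.5, method="higher")
        ci_lower[name], ci_upper[name] = float(lo), float(hi)
        significant[name] = bool(obs < lo or obs > hi)
        p_value[name] = _empirical_p(null, obs)
    return PermutationResult(
        sparsity=sparsity, observed_dCp=observed_dcp, observed_dLp=observed_dlp,
        null_dCp=null_dcp, null_dLp=null_dlp,
        ci_lower=ci_lower, ci_upper=ci_upper, significant=significant, p_value=p_value,
        n_perm=n_perm, seed=seed, group_a=cohort_a.group_label,
        group_b=cohort_b.group_label, n_redrawn=redrawn,
    )


def permutation_test_nodal(cohort_a: Cohort, cohort_b: Cohort, sparsity: float,
                           n_perm: int = 1000, seed=None, q: float = 0.05,
                           rank: str = "absolute") -> pd.DataFrame:
    """Per-node permutation test of normalized betweenness differences.

    Same relabeling machinery as :func:`permutation_test_metrics` with the
    per-node normalized betweenness b_i as the statistic. Because the test is
    run at all nodes simultaneously, the table reports both uncorrected
    decisions at the two-tailed 5% level and Benjamini–Hochberg-corrected
    decisions at level ``q``; the corrected column is the conservative one.
    """
    if cohort_a.atlas.abbreviations != cohort_b.atlas.abbreviations:
        raise ContractError("cohorts are on different atlases")
    n_pairs = cohort_a.atlas.n_possible_edges
    k_edges = edge_count_for_sparsity(sparsity, n_pairs)

    def _node_betweenness(volumes, covs):
        from .graph import BinaryNetwork  # local import to avoid cycle at module load
        adj = _pipeline_adjacency(volumes, covs, k_edges, rank)
        net = BinaryNetwork(adjacency=adj, atlas=cohort_a.atlas)
        return nodal_metrics(net)["normalized_betweenness"].to_numpy()

    va, ca = cohort_a.volume_matrix(), cohort_a.covariate_matrix()
    vb, cb = cohort_b.volume_matrix(), cohort_b.covariate_matrix()
    observed = _node_betweenness(va, ca) - _node_betweenness(vb, cb)

    pooled_v = np.vstack([va, vb])
    pooled_c = np.vstack([ca, cb])
    n_a, n_total = va.shape[0], pooled_v.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, observed.size))
    k = 0
    attempts = 0
    while k < n_perm:
        if attempts >= 20 * n_perm + 100:
            raise DegenerateDataError("permutation redraw budget exhausted")
        attempts += 1
        perm = rng.permutation(n_total)
        try:
            d = (_node_betweenness(pooled_v[perm[:n_a]], pooled_c[perm[:n_a]])
                 - _node_betweenness(pooled_v[perm[n_a:]], pooled_c[perm[n_a:]]))
        except (DisconnectedNetworkError, DegenerateDataError):
            continue
        null[k] = d
        k += 1

    p = (1 + np.sum(np.abs(null) >= np.abs(observed)[None, :], axis=0)) / (n_perm + 1)
    atlas = cohort_a.atlas
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in atlas],
            "region": atlas.abbreviations,
            "observed_diff": observed,
            "p_uncorrected": p,
            "significant_uncorrected": p < 0.05,
            "significant_fdr": fdr_mask(p, q),
        }
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_metric_ci(cohort: Cohort, sparsity: float, n_boot: int = 1000,
                        seed=None, n_random: int = 10,
                        rank: str = "absolute") -> pd.DataFrame:
    """Bootstrap standard errors and 95% percentile intervals for Cp, Lp, gamma, lambda.

    Subjects are resampled with replacement ``n_boot`` times and the full
    pipeline — including ``n_random`` rewired surrogates for gamma/lambda —
    is re-run per resample. Resamples producing a zero-variance region or a
    disconnected network are redrawn (logged).
    """
    if n_boot < 1:
        raise ContractError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)

    def _metrics(c: Cohort) -> np.ndarray:
        corr = correlation_matrix(residualize(c))
        net = threshold_by_sparsity(corr, sparsity, rank=rank)
        gm = small_world_indices(net, n_random=n_random, seed=int(rng.integers(2**31)))
        return np.array([gm.Cp, gm.Lp, gm.gamma, gm.lam])

    estimate = _metrics(cohort)
    n = cohort.n_subjects
    draws = np.empty((n_boot, 4))
    b = 0
    attempts = 0
    redrawn = 0
    while b < n_boot:
        if attempts >= 20 * n_boot + 100:
            raise DegenerateDataError("bootstrap redraw budget exhausted")
        attempts += 1
        rows = rng.integers(0, n, size=n)
        try:
            draws[b] = _metrics(cohort.subset(rows))
        except (DisconnectedNetworkError, DegenerateDataError):
            redrawn += 1
            continue
        b += 1
    if redrawn:
        logger.info("redrew %d degenerate bootstrap resamples", redrawn)

    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    se = draws.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(4)
    return pd.DataFrame(
        {
            "estimate": estimate,
            "se": se,
            "ci_lower": lo,
            "ci_upper": hi,
        },
        index=["Cp", "Lp", "gamma", "lambda"],
    )
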