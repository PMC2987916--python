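"""Group-level structural covariance: confound regression and Pearson correlation.

The structural network of a group is built in two steps. First, each region's
volumes are regressed (ordinary least squares, one regression per region with
a shared design of intercept + age + sex + total gray-matter volume) and the
residuals retained: they are the regional volumes corrected for the nuisance
covariates. Second, the Pearson correlation across subjects between every
pair of residualized regions forms the interregional correlation matrix; for
90 regions that is 90 x 89 / 2 = 4005 distinct region pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .atlas import RegionAtlas, aal_region_table
from .cohort import Cohort
from .exceptions import DegenerateDataError

logger = logging.getLogger(__name__)

_COVARIATE_NAMES = ("intercept", "age", "sex", "total_gm_volume")


def ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Least-squares residuals of every column of ``y`` on the design ``x``."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


@dataclass
class ResidualMatrix:
    """Confound-corrected regional volumes.

    ``residuals`` is subjects × regions; ``design_rank`` is the number of
    linearly independent regressors actually used (intercept included), and
    ``dropped`` names any constant covariates removed from the design.
    """

    residuals: np.ndarray
    design_rank: int
    atlas: RegionAtlas = field(default_factory=aal_region_table)
    group_label: str = ""
    dropped: tuple[str, ...] = ()

    @property
    def n_subjects(self) -> int:
        return self.residuals.shape[0]


@dataclass
class CorrelationMatrix:
    """Interregional Pearson correlation matrix for one group.

    ``r`` is symmetric with unit diagonal; ``n_subjects`` is the sample size
    the correlations were estimated from (needed later for Fisher-z
    comparisons between groups).
    """

    r: np.ndarray
    n_subjects: int
    group_label: str = ""
    atlas: RegionAtlas = field(default_factory=aal_region_table)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.atlas.n_regions
        if self.r.shape != (n, n):
            raise DegenerateDataError(f"correlation matrix shape {self.r.shape} != ({n}, {n})")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise DegenerateDataError("correlation matrix must be symmetric")

    @property
    def n_pairs(self) -> int:
        """Number of distinct region pairs (off-diagonal upper triangle)."""
        return self.atlas.n_possible_edges

    def pair_values(self) -> np.ndarray:
        """Upper-triangle correlations in (i<j) lexicographic order."""
        iu = np.triu_indices(self.r.shape[0], k=1)
        return self.r[iu]


def residualize(cohort: Cohort) -> ResidualMatrix:
    """Remove age, sex and total gray-matter volume from every region.

    Constant covariates (e.g. a single-sex cohort) are dropped from the
    design with a logged warning rather than producing a rank-deficient fit.
    """
    y = cohort.volume_matrix()
    covs = cohort.covariate_matrix()  # age, sex, total_gm_volume
    n = y.shape[0]

    columns = [np.ones(n)]
    names = ["intercept"]
    dropped: list[str] = []
    for k, name in enumerate(_COVARIATE_NAMES[1:]):
        col = covs[:, k]
        if np.ptp(col) == 0:
            dropped.append(name)
            logger.warning("covariate %r is constant in group %r; dropped from the design",
                           name, cohort.group_label)
        else:
            columns.append(col)
            names.append(name)
    x = np.column_stack(columns)
    rank = int(np.linalg.matrix_rank(x))
    if rank < x.shape[1]:
        # collinear (non-constant) covariates: fall back to pseudo-inverse fit
        logger.warning("design matrix for group %r is rank-deficient (rank %d of %d)",
                       cohort.group_label, rank, x.shape[1])
    if n < rank + 2:
        raise DegenerateDataError(
            f"{n} subjects cannot support a {rank}-regressor confound model"
        )
    res = ols_residuals(y, x)
    return ResidualMatrix(residuals=res, design_rank=rank, atlas=cohort.atlas,
                          group_label=cohort.group_label, dropped=tuple(dropped))


def correlation_matrix(residuals: ResidualMatrix, group_label: str | None = None) -> CorrelationMatrix:
    """Pearson correlations across subjects for all region pairs."""
    res = residuals.residuals
    if res.shape[0] < 5:
        raise DegenerateDataError("at least 5 subjects are required for correlation estimation")
    sd = res.std(axis=0)
    zero = np.nonzero(sd < 1e-13 * max(1.0, float(np.abs(res).max())))[0]
    if zero.size:
        names = [residuals.atlas.abbreviations[i] for i in zero[:5]]
        raise DegenerateDataError(f"zero-variance region(s): {names}")
    r = np.corrcoef(res, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(
        r=r,
        n_subjects=res.shape[0],
        group_label=group_label if group_label is not None else residuals.group_label,
        atlas=residuals.atlas,
    )


def cohort_correlation(cohort: Cohort) -> CorrelationMatrix:
    """Convenience: ``correlation_matrix(residualize(cohort))``."""
    return correlation_matrix(residualize(cohort))
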