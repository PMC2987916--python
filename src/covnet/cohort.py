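"""The Cohort container: per-subject regional volumes plus nuisance covariates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, aal_region_table
from .exceptions import CohortFormatError

#: Required covariate columns, in canonical order.
COVARIATE_COLUMNS = ("age", "sex", "total_gm_volume")

#: Correlation estimation is refused below this many subjects.
MIN_SUBJECTS = 5


@dataclass
class Cohort:
    """Subjects × regions gray-matter volumes for one diagnostic group.

    Parameters
    ----------
    group_label
        Group name, e.g. ``"NC"``, ``"MCI"``, ``"AD"`` (free text allowed).
    volumes
        DataFrame of strictly positive mean regional gray-matter volumes
        (arbitrary but consistent units), one row per subject, columns in
        atlas order (abbreviations).
    covariates
        DataFrame aligned with ``volumes`` carrying ``age`` (years), ``sex``
        (0 = female, 1 = male) and ``total_gm_volume`` (same units as the
        volumes).
    atlas
        The region atlas the columns refer to; defaults to the AAL-90 table.
    """

    group_label: str
    volumes: pd.DataFrame
    covariates: pd.DataFrame
    atlas: RegionAtlas = field(default_factory=aal_region_table)

    def __post_init__(self) -> None:
        expected = self.atlas.abbreviations
        if list(self.volumes.columns) != expected:
            raise CohortFormatError(
                "volume columns must match atlas order; "
                f"got {list(self.volumes.columns)[:3]}... expected {expected[:3]}..."
            )
        if len(self.covariates) != len(self.volumes):
            raise CohortFormatError(
                f"covariate rows ({len(self.covariates)}) != volume rows ({len(self.volumes)})"
            )
        missing = [c for c in COVARIATE_COLUMNS if c not in self.covariates.columns]
        if missing:
            raise CohortFormatError(f"missing covariate column(s): {missing}")
        if len(self.volumes) < MIN_SUBJECTS:
            raise CohortFormatError(
                f"cohort has {len(self.volumes)} subjects; at least {MIN_SUBJECTS} required"
            )
        vals = self.volumes.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise CohortFormatError("volumes contain non-finite values")
        if np.any(vals <= 0):
            row, col = np.argwhere(vals <= 0)[0]
            raise CohortFormatError(
                f"non-positive volume for subject row {row}, region {expected[col]}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.volumes)

    @property
    def n_regions(self) -> int:
        return self.volumes.shape[1]

    @property
    def subject_ids(self) -> list[str]:
        return [str(i) for i in self.volumes.index]

    def volume_matrix(self) -> np.ndarray:
        """Volumes as a float array (subjects × regions, atlas order)."""
        return self.volumes.to_numpy(dtype=float)

    def covariate_matrix(self) -> np.ndarray:
        """(age, sex, total_gm_volume) as a float array, canonical order."""
        return self.covariates.loc[:, list(COVARIATE_COLUMNS)].to_numpy(dtype=float)

    def subset(self, rows: np.ndarray, group_label: str | None = None) -> "Cohort":
        """A new cohort restricted to (or resampled over) the given row positions."""
        return Cohort(
            group_label=group_label if group_label is not None else self.group_label,
            volumes=self.volumes.iloc[rows].reset_index(drop=True),
            covariates=self.covariates.iloc[rows].reset_index(drop=True),
            atlas=self.atlas,
        )
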