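"""Synthetic multi-group cohorts with controlled covariance structure.

The generator emulates the statistical structure that gray-matter covariance
analyses assume: 90 regions in 45 homotopic left/right pairs with strong
homotopic correlation, lobe-like community blocks with elevated within-block
correlation, weak between-block correlation, linear age/sex confound effects
on every region, a total gray-matter volume defined as the row sum, and
per-group overrides that strengthen local (within-block) covariance while
weakening long-range (between-block) covariance along the NC → MCI → AD
progression.

Volumes are affine transforms of latent multivariate-normal scores drawn
from the block-structured latent correlation matrix, so the ground-truth
Pearson correlation of the (confound-free) volumes equals the latent matrix
exactly — which is what makes downstream estimators testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .atlas import RegionAtlas, aal_region_table
from .cohort import Cohort
from .exceptions import ContractError, NotPositiveSemidefiniteError

#: Default lobe-like community blocks, as 1-based indices into the 45
#: bilateral structures; each block is mirrored across hemispheres (a block
#: contains both the left and right region of each of its structures).
#: Sub-lobar granularity keeps the within-block edge pool smaller than the
#: edge budget at 10% sparsity, so thresholded networks retain between-block
#: shortcuts (and hence stay connected with near-random path lengths) across
#: the whole working sparsity range.
DEFAULT_BLOCK_STRUCTURES: dict[str, tuple[int, ...]] = {
    "sensorimotor": (1, 9, 10, 29, 35),
    "frontal_dorsolateral": (2, 4, 6, 7),
    "frontal_orbital": (3, 5, 8, 11, 14),
    "frontal_medial": (12, 13),
    "insula_cingulate": (15, 16, 17, 18),
    "medial_temporal": (19, 20, 21, 28),
    "occipital_medial": (22, 23, 24),
    "occipital_lateral": (25, 26, 27),
    "parietal": (30, 31, 32, 33, 34),
    "subcortical": (36, 37, 38, 39),
    "temporal_lateral": (40, 41, 43, 45),
    "temporal_pole": (42, 44),
}

# Observed demographics of the three diagnostic groups: age ranges (years)
# and male fractions. Unknown group labels fall back to the generic entry.
AGE_RANGES: dict[str, tuple[float, float]] = {
    "NC": (70.02, 90.74),
    "MCI": (56.28, 89.40),
    "AD": (55.73, 90.20),
    "default": (56.0, 90.0),
}
MALE_FRACTIONS: dict[str, float] = {
    "NC": 49 / 98,
    "MCI": 79 / 113,
    "AD": 50 / 91,
    "default": 0.5,
}


def blocks_from_structures(atlas: RegionAtlas,
                           block_structures: dict[str, tuple[int, ...]]) -> list[list[int]]:
    """Expand structure-level blocks into region-id blocks (both hemispheres)."""
    blocks = []
    for structures in block_structures.values():
        block = []
        for s in structures:
            block.extend([2 * s - 1, 2 * s])
        blocks.append(sorted(block))
    return blocks


@dataclass
class GroupEffect:
    """Per-group overrides of the latent covariance and regional means.

    ``within_block_corr`` / ``between_block_corr`` / ``homotopic_corr``
    replace the spec-level values for this group when given. ``atrophy`` is
    a mean volume reduction fraction in [0, 1): either a scalar applied to
    every region or a mapping from region abbreviation to fraction.
    """

    within_block_corr: float | None = None
    between_block_corr: float | None = None
    homotopic_corr: float | None = None
    atrophy: float | dict[str, float] = 0.0


@dataclass
class SyntheticSpec:
    """Full description of a synthetic multi-group study.

    The latent correlation between regions i and j is ``homotopic_corr`` if
    j is i's homotopic partner, ``within_block_corr`` if they share a
    community block, and ``between_block_corr`` otherwise (group overrides
    applied first). The implied matrix must be positive semi-definite for
    every group; this is checked at construction.
    """

    n_subjects_per_group: dict[str, int]
    homotopic_corr: float = 0.8
    within_block_corr: float = 0.4
    between_block_corr: float = 0.2
    group_effects: dict[str, GroupEffect] = field(default_factory=dict)
    beta_age: float | np.ndarray = -0.01  # volume units per year, per region
    beta_sex: float | np.ndarray = 0.15  # male minus female offset, per region
    noise_sd: float = 0.5
    global_cv: float = 0.1  # per-subject brain-size factor (CV of volumes)
    seed: int = 0
    atlas: RegionAtlas = field(default_factory=aal_region_table)
    communities: list[list[int]] | None = None  # region-id blocks

    def __post_init__(self) -> None:
        if self.communities is None:
            if self.atlas.n_pairs == 45:
                self.communities = blocks_from_structures(self.atlas, DEFAULT_BLOCK_STRUCTURES)
            else:
                # generic fallback: two blocks of consecutive structures
                half = self.atlas.n_pairs // 2 or 1
                self.communities = [
                    sorted(i for s in range(half) for i in (2 * s + 1, 2 * s + 2)),
                    sorted(i for s in range(half, self.atlas.n_pairs) for i in (2 * s + 1, 2 * s + 2)),
                ]
            self.communities = [b for b in self.communities if b]
        covered = sorted(i for b in self.communities for i in b)
        if covered != list(range(1, self.atlas.n_regions + 1)):
            raise ContractError("communities must partition the atlas region ids")
        for level in ("homotopic_corr", "within_block_corr", "between_block_corr"):
            v = getattr(self, level)
            if not 0.0 <= v < 1.0:
                raise ContractError(f"{level} must be in [0, 1), got {v}")
        if self.noise_sd <= 0:
            raise ContractError("noise_sd must be positive")
        for group in self.n_subjects_per_group:
            build_latent_correlation(self, group)  # raises if not PSD

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        data = {
            "n_subjects_per_group": dict(self.n_subjects_per_group),
            "homotopic_corr": self.homotopic_corr,
            "within_block_corr": self.within_block_corr,
            "between_block_corr": self.between_block_corr,
            "group_effects": {g: asdict(e) for g, e in self.group_effects.items()},
            "beta_age": np.asarray(self.beta_age).tolist(),
            "beta_sex": np.asarray(self.beta_sex).tolist(),
            "noise_sd": self.noise_sd,
            "global_cv": self.global_cv,
            "seed": self.seed,
            "communities": self.communities,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, atlas: RegionAtlas | None = None) -> "SyntheticSpec":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        effects = {
            g: GroupEffect(**e) for g, e in (data.pop("group_effects", {}) or {}).items()
        }
        return cls(atlas=atlas or aal_region_table(), group_effects=effects, **data)


def _levels_for_group(spec: SyntheticSpec, group: str) -> tuple[float, float, float]:
    effect = spec.group_effects.get(group, GroupEffect())
    hom = effect.homotopic_corr if effect.homotopic_corr is not None else spec.homotopic_corr
    win = effect.within_block_corr if effect.within_block_corr is not None else spec.within_block_corr
    btw = effect.between_block_corr if effect.between_block_corr is not None else spec.between_block_corr
    return hom, win, btw


def build_latent_correlation(spec: SyntheticSpec, group: str) -> np.ndarray:
    """The group's latent correlation matrix implied by the block structure.

    Raises :class:`NotPositiveSemidefiniteError` (naming the smallest
    eigenvalue) if the requested correlation levels are incompatible.
    """
    if group not in spec.n_subjects_per_group:
        raise ContractError(f"unknown group {group!r}")
    hom, win, btw = _levels_for_group(spec, group)
    n = spec.atlas.n_regions
    r = np.full((n, n), btw)
    for block in spec.communities:
        idx = np.asarray(block, dtype=int) - 1
        r[np.ix_(idx, idx)] = win
    for left, right in spec.atlas.homotopic_pairs():
        r[left - 1, right - 1] = r[right - 1, left - 1] = hom
    np.fill_diagonal(r, 1.0)
    min_eig = float(np.linalg.eigvalsh(r)[0])
    if min_eig < -1e-10:
        raise NotPositiveSemidefiniteError(
            f"latent correlation matrix for group {group!r} is not positive "
            f"semi-definite (smallest eigenvalue {min_eig:.6g})",
            min_eigenvalue=min_eig,
        )
    return r


def _region_baselines(n: int) -> np.ndarray:
    # deterministic, mildly varied baselines in arbitrary volume units
    return 4.0 + 0.03 * np.arange(n)


def _atrophy_vector(spec: SyntheticSpec, group: str) -> np.ndarray:
    effect = spec.group_effects.get(group, GroupEffect())
    n = spec.atlas.n_regions
    if isinstance(effect.atrophy, dict):
        vec = np.zeros(n)
        for abbrev, frac in effect.atrophy.items():
            vec[spec.atlas.by_abbreviation(abbrev).region_id - 1] = frac
    else:
        vec = np.full(n, float(effect.atrophy))
    if np.any(vec < 0) or np.any(vec >= 1):
        raise ContractError("atrophy fractions must lie in [0, 1)")
    return vec


def generate_cohort(spec: SyntheticSpec, group: str) -> Cohort:
    """Draw one cohort for ``group``; bitwise reproducible under ``spec.seed``.

    Volumes are ``baseline * (1 - atrophy) * (1 + global_cv * g) + noise_sd
    * z + beta_age * (age - 73) + beta_sex * sex`` with z ~ MVN(0, latent
    correlation) and g ~ N(0, 1) a per-subject brain-size factor (the global
    scaling that total-gray-matter regression is meant to remove);
    ``total_gm_volume`` is the row sum over the regions.
    """
    groups = list(spec.n_subjects_per_group)
    if group not in groups:
        raise ContractError(f"unknown group {group!r}; expected one of {groups}")
    latent = build_latent_correlation(spec, group)
    n_subj = int(spec.n_subjects_per_group[group])
    n_reg = spec.atlas.n_regions
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) % (2**31), groups.index(group)])
    )

    lo, hi = AGE_RANGES.get(group, AGE_RANGES["default"])
    age = rng.uniform(lo, hi, size=n_subj)
    sex = (rng.random(n_subj) < MALE_FRACTIONS.get(group, MALE_FRACTIONS["default"])).astype(float)

    # factor the (possibly singular) PSD latent matrix via eigendecomposition
    w, v = np.linalg.eigh(latent)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_subj, n_reg)) @ factor.T

    baselines = _region_baselines(n_reg) * (1.0 - _atrophy_vector(spec, group))
    beta_age = np.broadcast_to(np.asarray(spec.beta_age, dtype=float), (n_reg,))
    beta_sex = np.broadcast_to(np.asarray(spec.beta_sex, dtype=float), (n_reg,))
    g = rng.standard_normal(n_subj)  # brain-size factor, shared by all regions
    volumes = (
        baselines[None, :] * (1.0 + spec.global_cv * g)[:, None]
        + spec.noise_sd * z
        + np.outer(age - 73.0, beta_age)
        + np.outer(sex, beta_sex)
    )
    if np.any(volumes <= 0):
        raise ContractError(
            "generated volumes are not strictly positive; reduce noise_sd or atrophy"
        )

    ids = [f"{group}{i + 1:04d}" for i in range(n_subj)]
    vol_df = pd.DataFrame(volumes, index=ids, columns=spec.atlas.abbreviations)
    cov_df = pd.DataFrame(
        {"age": age, "sex": sex, "total_gm_volume": volumes.sum(axis=1)}, index=ids
    )
    return Cohort(group_label=group, volumes=vol_df, covariates=cov_df, atlas=spec.atlas)


def generate_all(spec: SyntheticSpec) -> dict[str, Cohort]:
    """One cohort per group, keyed by group label."""
    return {g: generate_cohort(spec, g) for g in spec.n_subjects_per_group}


def default_three_group_spec(seed: int = 0) -> SyntheticSpec:
    """The built-in NC/MCI/AD preset (group sizes 98/113/91).

    Relative to the NC baseline, MCI and AD progressively strengthen
    within-block correlation and weaken between-block correlation — the
    "more local, less long-range" covariance shift — so that at a fixed
    sparsity the expected ordering is Cp(AD) > Cp(MCI) > Cp(NC) and
    Lp(AD) > Lp(MCI) > Lp(NC). Small mean atrophy fractions exercise the
    mean-shift path without affecting correlations.
    """
    return SyntheticSpec(
        n_subjects_per_group={"NC": 98, "MCI": 113, "AD": 91},
        homotopic_corr=0.8,
        within_block_corr=0.40,
        between_block_corr=0.24,
        group_effects={
            "MCI": GroupEffect(within_block_corr=0.45, between_block_corr=0.215, atrophy=0.03),
            "AD": GroupEffect(within_block_corr=0.50, between_block_corr=0.19, atrophy=0.08),
        },
        seed=seed,
    )
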