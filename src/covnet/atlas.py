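"""The 90-region AAL cortical parcellation (cerebellum excluded).

The atlas lists 45 bilateral structures; each structure contributes a left and
a right region, interleaved so that the left region of a pair immediately
precedes its right homolog (region ids: odd = left, even = right). Homotopic
partners — the mirror-image region in the opposite hemisphere — are recorded
explicitly because interhemispheric covariance between homologs is the
strongest feature of gray-matter covariance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

from .exceptions import AtlasError

#: (name, abbreviation) of the 45 bilateral AAL structures, cerebellum excluded.
AAL_STRUCTURES: tuple[tuple[str, str], ...] = (
    ("Precentral", "PreCG"),
    ("Frontal_Sup", "SFGdor"),
    ("Frontal_Sup_Orb", "ORBsup"),
    ("Frontal_Mid", "MFG"),
    ("Frontal_Mid_Orb", "ORBmid"),
    ("Frontal_Inf_Oper", "IFGoperc"),
    ("Frontal_Inf_Tri", "IFGtriang"),
    ("Frontal_Inf_Orb", "ORBinf"),
    ("Rolandic_Oper", "ROL"),
    ("Supp_Motor_Area", "SMA"),
    ("Olfactory", "OLF"),
    ("Frontal_Sup_Medial", "SFGmed"),
    ("Frontal_Med_Orb", "ORBsupmed"),
    ("Rectus", "REC"),
    ("Insula", "INS"),
    ("Cingulum_Ant", "ACG"),
    ("Cingulum_Mid", "DCG"),
    ("Cingulum_Post", "PCG"),
    ("Hippocampus", "HIP"),
    ("ParaHippocampal", "PHG"),
    ("Amygdala", "AMYG"),
    ("Calcarine", "CAL"),
    ("Cuneus", "CUN"),
    ("Lingual", "LING"),
    ("Occipital_Sup", "SOG"),
    ("Occipital_Mid", "MOG"),
    ("Occipital_Inf", "IOG"),
    ("Fusiform", "FFG"),
    ("Postcentral", "PoCG"),
    ("Parietal_Sup", "SPG"),
    ("Parietal_Inf", "IPL"),
    ("SupraMarginal", "SMG"),
    ("Angular", "ANG"),
    ("Precuneus", "PCUN"),
    ("Paracentral_Lobule", "PCL"),
    ("Caudate", "CAU"),
    ("Putamen", "PUT"),
    ("Pallidum", "PAL"),
    ("Thalamus", "THA"),
    ("Heschl", "HES"),
    ("Temporal_Sup", "STG"),
    ("Temporal_Pole_Sup", "TPOsup"),
    ("Temporal_Mid", "MTG"),
    ("Temporal_Pole_Mid", "TPOmid"),
    ("Temporal_Inf", "ITG"),
)


@dataclass(frozen=True)
class Region:
    """A single atlas region."""

    region_id: int  # 1-based
    name: str  # e.g. "Precentral_L"
    abbreviation: str  # e.g. "PreCG.L"
    hemisphere: str  # "L" or "R"
    homotopic_partner_id: int


@dataclass(frozen=True)
class RegionAtlas:
    """An ordered table of paired left/right regions.

    Invariants (checked at construction): even region count with half the
    regions in each hemisphere, unique abbreviations, and homotopic pairing
    forming an involution that always crosses hemispheres.
    """

    entries: tuple[Region, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.entries)
        if n == 0 or n % 2:
            raise AtlasError(f"atlas must contain an even, positive number of regions, got {n}")
        for expected, region in enumerate(self.entries, start=1):
            if region.region_id != expected:
                raise AtlasError(f"region ids must be 1..{n} in order, found {region.region_id} at position {expected}")
        n_left = sum(r.hemisphere == "L" for r in self.entries)
        if n_left * 2 != n:
            raise AtlasError(f"expected {n // 2} regions per hemisphere, found {n_left} left")
        abbrevs = [r.abbreviation for r in self.entries]
        if len(set(abbrevs)) != n:
            raise AtlasError("abbreviations are not unique")
        by_id = {r.region_id: r for r in self.entries}
        for r in self.entries:
            partner = by_id.get(r.homotopic_partner_id)
            if partner is None or partner.homotopic_partner_id != r.region_id:
                raise AtlasError(f"homotopic pairing is not an involution at region {r.region_id}")
            if partner.hemisphere == r.hemisphere:
                raise AtlasError(f"homotopic partner of region {r.region_id} is in the same hemisphere")
        object.__setattr__(self, "_index", {r.abbreviation: r for r in self.entries})

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.entries)

    @property
    def n_regions(self) -> int:
        return len(self.entries)

    @property
    def n_pairs(self) -> int:
        """Number of homotopic left/right pairs."""
        return len(self.entries) // 2

    @property
    def n_possible_edges(self) -> int:
        """Maximum number of undirected edges, N(N-1)/2."""
        n = len(self.entries)
        return n * (n - 1) // 2

    @property
    def abbreviations(self) -> list[str]:
        return [r.abbreviation for r in self.entries]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.entries]

    def partner(self, region_id: int) -> int:
        """Homotopic partner id of ``region_id``."""
        return self.entries[region_id - 1].homotopic_partner_id

    def by_abbreviation(self, abbreviation: str) -> Region:
        try:
            return self._index[abbreviation]
        except KeyError:
            raise AtlasError(f"unknown region abbreviation {abbreviation!r}") from None

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """All (left_id, right_id) homotopic pairs, left id first."""
        return [
            (r.region_id, r.homotopic_partner_id)
            for r in self.entries
            if r.region_id < r.homotopic_partner_id
        ]


def make_paired_atlas(structures: tuple[tuple[str, str], ...]) -> RegionAtlas:
    """Build an interleaved L/R atlas from (name, abbreviation) structures.

    Structure ``s`` (1-based) yields left region ``2s-1`` and right region
    ``2s``; names carry ``_L``/``_R`` suffixes and abbreviations ``.L``/``.R``.
    """
    entries = []
    for s, (name, abbrev) in enumerate(structures):
        left_id, right_id = 2 * s + 1, 2 * s + 2
        entries.append(Region(left_id, f"{name}_L", f"{abbrev}.L", "L", right_id))
        entries.append(Region(right_id, f"{name}_R", f"{abbrev}.R", "R", left_id))
    return RegionAtlas(tuple(entries))


@lru_cache(maxsize=1)
def aal_region_table() -> RegionAtlas:
    """The built-in 90-region AAL atlas (45 structures × 2 hemispheres)."""
    return make_paired_atlas(AAL_STRUCTURES)


def reduced_atlas(n_pairs: int, prefix: str = "ROI") -> RegionAtlas:
    """A generic paired atlas with ``n_pairs`` synthetic bilateral structures.

    Useful for small simulation studies where the full 90-region table is
    unnecessarily large; region semantics are placeholders (ROI1, ROI2, ...).
    """
    if n_pairs < 1:
        raise AtlasError("n_pairs must be >= 1")
    structures = tuple((f"{prefix}{k + 1}", f"{prefix}{k + 1}") for k in range(n_pairs))
    return make_paired_atlas(structures)
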