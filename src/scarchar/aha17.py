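"""AHA 17-segment partition of the LV myocardium and coronary territories.

Conventions (stated explicitly because chirality errors are silent):

* Angles are measured at each voxel center as ``phi = atan2(y - cy, x - cx)``
  in image-plane mm coordinates, and expressed relative to the ray from the
  LV center to the *anterior RV insertion* landmark:
  ``delta = (phi - phi_rv) mod 360``.  Increasing ``delta`` (counterclockwise
  in the (x, y) frame) runs from the insertion point into the anterior wall.
* Basal and mid tiers have six 60-degree sectors; walking counterclockwise
  from the insertion: anterior, anterolateral, inferolateral, inferior,
  inferoseptal, anteroseptal — segments [1, 6, 5, 4, 3, 2] basally and
  [7, 12, 11, 10, 9, 8] at mid-cavity.  The apical tier has four 90-degree
  sectors [13 (anterior), 16 (lateral), 15 (inferior), 14 (septal)].
* Slices are split into basal/mid/apical thirds by count, remainder slices
  assigned basal-ward.  The true apex cap (segment 17) is taken from the
  most apical slice(s) where the cavity has closed, supplied by the caller
  via ``apex_slices``; phantoms whose cavity never closes simply have no
  segment 17.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import LandmarkError, PartitionError

__all__ = [
    "SegmentMap",
    "TerritoryMap",
    "assign_segments",
    "default_territories",
    "slice_tiers",
    "BASAL_SEGMENTS",
    "MID_SEGMENTS",
    "APICAL_SEGMENTS",
]

# segment ids per 60-degree sector counterclockwise from the RV insertion
BASAL_SEGMENTS = (1, 6, 5, 4, 3, 2)
MID_SEGMENTS = (7, 12, 11, 10, 9, 8)
# per 90-degree sector, same origin
APICAL_SEGMENTS = (13, 16, 15, 14)

_DEFAULT_TERRITORIES: dict[str, frozenset[int]] = {
    "LAD": frozenset({1, 2, 7, 8, 13, 14, 17}),
    "RCA": frozenset({3, 4, 9, 10, 15}),
    "LCX": frozenset({5, 6, 11, 12, 16}),
}


@dataclass(frozen=True)
class TerritoryMap:
    """Coronary territory -> set of AHA segment ids; the sets partition 1..17."""

    territories: Mapping[str, frozenset[int]]
    include_apex: bool = True

    def __post_init__(self) -> None:
        all_ids: list[int] = []
        for ids in self.territories.values():
            all_ids.extend(ids)
        if sorted(all_ids) != list(range(1, 18)):
            raise PartitionError(
                "territory sets must partition segments 1..17 without overlap"
            )

    def segments(self, territory: str) -> frozenset[int]:
        ids = self.territories[territory]
        return ids if self.include_apex else ids - {17}


def default_territories(include_apex: bool = True) -> TerritoryMap:
    """Standard model assignment: LAD {1,2,7,8,13,14,17}, RCA {3,4,9,10,15},
    LCX {5,6,11,12,16}.  ``include_apex=False`` drops segment 17 from
    regional scores."""
    return TerritoryMap(dict(_DEFAULT_TERRITORIES), include_apex=include_apex)


def slice_tiers(n_slices: int) -> list[str]:
    """Tier label per slice, base -> apex; thirds by count, ties basal-ward."""
    q, rem = divmod(n_slices, 3)
    n_basal = q + (1 if rem >= 1 else 0)
    n_mid = q + (1 if rem >= 2 else 0)
    n_apical = q
    return ["basal"] * n_basal + ["mid"] * n_mid + ["apical"] * n_apical


@dataclass
class SegmentMap:
    """Per-voxel AHA segment labels (1-17; 0 = non-myocardium)."""

    labels: np.ndarray
    tiers: list[str]
    lv_center: tuple[float, float]
    rv_insertion: tuple[float, float]

    def segment_mask(self, segment_id: int) -> np.ndarray:
        return self.labels == segment_id

    def observed_segments(self) -> list[int]:
        return sorted(int(s) for s in np.unique(self.labels) if s > 0)


def _sector_lookup(delta_deg: np.ndarray, width: float, order: Sequence[int]) -> np.ndarray:
    k = np.floor_divide(delta_deg, width).astype(int) % len(order)
    return np.asarray(order, dtype=np.uint8)[k]


def assign_segments(
    myocardium_mask: np.ndarray,
    lv_center: tuple[float, float] | None,
    rv_insertion: tuple[float, float] | None,
    pixel_spacing_mm: tuple[float, float],
    apex_slices: Iterable[int] = (),
) -> SegmentMap:
    """Label every myocardial voxel with its AHA segment.

    ``myocardium_mask`` is (slice, row, col), slices ordered base -> apex.
    Slices listed in ``apex_slices`` (cavity closed) become segment 17
    wholesale; remaining slices are tiered by thirds and sectored by angle
    from the RV-insertion reference.  Deterministic; an empty mask yields an
    all-zero map.
    """
    if lv_center is None or rv_insertion is None:
        raise LandmarkError("LV center and anterior RV-insertion landmarks are required")
    mask = np.asarray(myocardium_mask, dtype=bool)
    if mask.ndim != 3:
        raise LandmarkError("myocardium mask must be (slice, row, col)")

    cx, cy = lv_center
    rs, cs = pixel_spacing_mm
    n_slices, rows, cols = mask.shape
    apex_set = set(int(i) for i in apex_slices)
    tiers = slice_tiers(n_slices - len(apex_set))
    # tier per actual slice index, skipping apex-cap slices
    tier_of: dict[int, str] = {}
    ti = 0
    for s in range(n_slices):
        if s in apex_set:
            tier_of[s] = "apex"
        else:
            tier_of[s] = tiers[ti] if ti < len(tiers) else "apical"
            ti += 1

    xx, yy = np.meshgrid(np.arange(cols) * cs, np.arange(rows) * rs)
    phi = np.degrees(np.arctan2(yy - cy, xx - cx))
    phi_rv = np.degrees(np.arctan2(rv_insertion[1] - cy, rv_insertion[0] - cx))
    delta = (phi - phi_rv) % 360.0

    seg6_basal = _sector_lookup(delta, 60.0, BASAL_SEGMENTS)
    seg6_mid = _sector_lookup(delta, 60.0, MID_SEGMENTS)
    seg4 = _sector_lookup(delta, 90.0, APICAL_SEGMENTS)

    labels = np.zeros(mask.shape, dtype=np.uint8)
    for s in range(n_slices):
        tier = tier_of[s]
        if tier == "apex":
            labels[s][mask[s]] = 17
        elif tier == "basal":
            labels[s][mask[s]] = seg6_basal[mask[s]]
        elif tier == "mid":
            labels[s][mask[s]] = seg6_mid[mask[s]]
        else:
            labels[s][mask[s]] = seg4[mask[s]]
    return SegmentMap(
        labels=labels,
        tiers=[tier_of[s] for s in range(n_slices)],
        lv_center=(float(cx), float(cy)),
        rv_insertion=(float(rv_insertion[0]), float(rv_insertion[1])),
    )
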