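"""Ordinal segment-level scores: scar score, transmural extent, regional
(coronary-territory) scar scores, and the wall motion score index.

Scar score per AHA segment (of segmental area occupied by total scar):
0 = no scar, 1 = 1-25%, 2 = 26-50%, 3 = 51-75%, 4 = 76-100%.  Segmental
percentages are continuous, so the printed integer bins are realized as the
half-open partition (0, 25], (25, 50], (50, 75], (75, 100] with 0 -> 0.

Transmural extent = number of segments scoring 3 or 4.  Regional scar score
= unweighted mean of segment scores over a coronary territory's observed
segments.  WMSI = sum of observed wall-motion scores (0 normal .. 4
dyskinesia) divided by the number of observed segments; unobserved segments
(NaN) are dropped, never counted as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aha17 import SegmentMap, TerritoryMap, default_territories
from .errors import AlignmentError, DomainError
from .io_formats import N_SEGMENTS
from .scar import ScarMap

__all__ = [
    "SegmentScores",
    "segment_scar_pct",
    "scar_score",
    "transmural_extent",
    "regional_scores",
    "wmsi",
    "compute_segment_scores",
]

_BIN_EDGES = (0.0, 25.0, 50.0, 75.0, 100.0)
_TOL = 1e-9


@dataclass
class SegmentScores:
    """Per-segment scar burden and the derived ordinal summaries."""

    scar_pct: np.ndarray          # 17-vector, % of segmental area; NaN unobserved
    scar_score: np.ndarray        # 17-vector in 0..4; NaN unobserved
    transmural_extent: int        # segments with score 3 or 4
    lad_score: float
    rca_score: float
    lcx_score: float
    wmsi: float | None = None


def segment_scar_pct(scar_map: ScarMap | np.ndarray, segment_map: SegmentMap | np.ndarray) -> np.ndarray:
    """Total scar (core + peri) as % of each segment's voxel count.

    Segments with no voxels in the map are NaN (unobserved).  The two label
    volumes must share a voxel grid.
    """
    scar_labels = scar_map.labels if isinstance(scar_map, ScarMap) else np.asarray(scar_map)
    seg_labels = segment_map.labels if isinstance(segment_map, SegmentMap) else np.asarray(segment_map)
    if scar_labels.shape != seg_labels.shape:
        raise AlignmentError("scar and segment label volumes differ in shape")
    scar = scar_labels > 0
    out = np.full(N_SEGMENTS, np.nan)
    for seg_id in range(1, N_SEGMENTS + 1):
        in_seg = seg_labels == seg_id
        count = int(in_seg.sum())
        if count:
            out[seg_id - 1] = 100.0 * scar[in_seg].sum() / count
    return out


def scar_score(pct):
    """Ordinal scar score 0-4 from a segmental scar percentage.

    Accepts a scalar or array; NaN passes through as NaN (unobserved).
    """
    arr = np.asarray(pct, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size and ((finite < -_TOL).any() or (finite > 100.0 + _TOL).any()):
        raise DomainError("segmental scar percentage must lie in [0, 100]")
    score = np.full(arr.shape, np.nan)
    with np.errstate(invalid="ignore"):
        score = np.where(arr <= 0, 0.0, score)
        score = np.where((arr > 0) & (arr <= 25), 1.0, score)
        score = np.where((arr > 25) & (arr <= 50), 2.0, score)
        score = np.where((arr > 50) & (arr <= 75), 3.0, score)
        score = np.where(arr > 75, 4.0, score)
    score[np.isnan(arr)] = np.nan
    if np.isscalar(pct) or np.asarray(pct).ndim == 0:
        return float(score) if np.isnan(score) else int(score)
    return score


def transmural_extent(scores) -> int:
    """Number of observed segments with scar score 3 or 4."""
    arr = np.asarray(scores, dtype=float)
    _check_scores(arr)
    return int(np.nansum(arr >= 3))


def regional_scores(
    scores, territory_map: TerritoryMap | None = None
) -> tuple[float, float, float]:
    """Mean scar score over each coronary territory's observed segments.

    Returns ``(lad, rca, lcx)``; a territory with zero observed segments is
    flagged NaN rather than raising, so tables can carry the gap forward.
    """
    arr = np.asarray(scores, dtype=float)
    _check_scores(arr)
    tmap = territory_map if territory_map is not None else default_territories()
    out = []
    for name in ("LAD", "RCA", "LCX"):
        ids = sorted(tmap.segments(name))
        vals = arr[[i - 1 for i in ids]]
        vals = vals[~np.isnan(vals)]
        out.append(float(vals.mean()) if vals.size else float("nan"))
    return tuple(out)  # type: ignore[return-value]


def wmsi(motion_scores) -> float:
    """Wall motion score index: sum of observed scores / observed count.

    Scores: 0 normal, 1 hypokinesia, 2 severe hypokinesia, 3 akinesia,
    4 dyskinesia; NaN = unobserved.
    """
    arr = np.asarray(motion_scores, dtype=float)
    _check_scores(arr)
    observed = arr[~np.isnan(arr)]
    if observed.size == 0:
        raise DomainError("WMSI undefined with zero observed segments")
    return float(observed.sum() / observed.size)


def _check_scores(arr: np.ndarray) -> None:
    if arr.shape != (N_SEGMENTS,):
        raise DomainError("expected a 17-segment score vector")
    finite = arr[~np.isnan(arr)]
    if finite.size and ((finite < 0).any() or (finite > 4).any()):
        raise DomainError("segment scores must lie in 0..4 (NaN = unobserved)")


def compute_segment_scores(
    scar_map: ScarMap,
    segment_map: SegmentMap,
    motion_scores=None,
    territory_map: TerritoryMap | None = None,
) -> SegmentScores:
    """Chain pct -> score -> transmural extent / regional means (+ WMSI)."""
    pct = segment_scar_pct(scar_map, segment_map)
    scores = scar_score(pct)
    lad, rca, lcx = regional_scores(scores, territory_map)
    return SegmentScores(
        scar_pct=pct,
        scar_score=scores,
        transmural_extent=transmural_extent(scores),
        lad_score=lad,
        rca_score=rca,
        lcx_score=lcx,
        wmsi=None if motion_scores is None else wmsi(motion_scores),
    )
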