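"""FWHM (full-width-at-half-maximum) infarct tissue quantification.

On a contrast-enhanced stack, infarcted myocardium hyperenhances against
dark-gray viable muscle.  After the analyst outlines the hyperenhanced
region of interest, the maximum signal intensity within ROI-and-myocardium
anchors two relative thresholds:

* infarct core:            SI >= 50% of the maximum
* peri-infarct (heterogeneous) zone:  35% <= SI < 50% of the maximum
* total scar = core + peri-infarct

Zone sizes are reported as percent of the LV myocardial voxel count of the
stack.  The thresholds are pure ratios to the maximum, so zone labels are
invariant under positive linear intensity rescaling (but not under an
additive baseline shift).  Hypo-enhanced microvascular obstruction is not
reclassified into the core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, DomainError, ROIError, ThresholdError
from .io_formats import ContourSet, ShortAxisStack, myocardium_mask, polygon_mask

CORE_FRACTION = 0.5   # SI >= 50% of max -> core
PERI_FRACTION = 0.35  # 35% <= SI < 50% of max -> peri-infarct

LABEL_NONE, LABEL_PERI, LABEL_CORE = 0, 1, 2

__all__ = [
    "ScarMap",
    "ZoneFractions",
    "max_signal_intensity",
    "classify_zones",
    "zone_fractions",
    "rasterize_masks",
    "analyze_stack",
    "CORE_FRACTION",
    "PERI_FRACTION",
    "LABEL_NONE",
    "LABEL_PERI",
    "LABEL_CORE",
]


@dataclass
class ScarMap:
    """Per-voxel zone labels (0 none / 1 peri / 2 core) within the myocardium,
    with the maximum SI and the two absolute thresholds that produced them."""

    labels: np.ndarray
    max_si: float
    core_si: float
    peri_si: float


@dataclass
class ZoneFractions:
    """Core / peri-infarct / total scar as % of LV myocardial voxels."""

    core_pct: float
    peri_pct: float
    total_pct: float


def max_signal_intensity(
    intensities: np.ndarray,
    myocardium: np.ndarray,
    roi: np.ndarray,
    top_k: int | None = None,
) -> float:
    """Maximum SI over ROI ∩ myocardium.

    The intersection is essential: blood pool or artifacts inside a
    generously drawn ROI must not inflate the reference maximum.  If the
    ROI excludes the true brightest myocardial voxel, the maximum over what
    it does cover is returned (that is the method's defined behavior — the
    ROI is the analyst's statement of where the scar is).  ``top_k``
    averages the k brightest voxels as a noise-robust variant (off by
    default).
    """
    sel = np.asarray(roi, dtype=bool) & np.asarray(myocardium, dtype=bool)
    if not sel.any():
        raise ROIError("hyperenhancement ROI does not intersect the myocardium")
    vals = np.asarray(intensities)[sel]
    if top_k is not None:
        if top_k < 1:
            raise DomainError("top_k must be >= 1")
        k = min(int(top_k), vals.size)
        return float(np.mean(np.sort(vals)[-k:]))
    return float(vals.max())


def classify_zones(
    intensities: np.ndarray,
    myocardium: np.ndarray,
    max_si: float,
    min_cluster_voxels: int | None = None,
) -> ScarMap:
    """Label every myocardial voxel core / peri / none by the FWHM thresholds.

    ``min_cluster_voxels`` optionally removes connected scar components
    smaller than the given voxel count (26-connectivity) before labeling —
    a cleanup for noisy data, off by default.
    """
    if not max_si > 0:
        raise ThresholdError("max SI must be positive to form relative thresholds")
    vol = np.asarray(intensities, dtype=float)
    myo = np.asarray(myocardium, dtype=bool)
    if vol.shape != myo.shape:
        raise AlignmentError("intensity volume and myocardium mask differ in shape")
    core_si = CORE_FRACTION * max_si
    peri_si = PERI_FRACTION * max_si
    labels = np.zeros(vol.shape, dtype=np.uint8)
    labels[myo & (vol >= core_si)] = LABEL_CORE
    labels[myo & (vol >= peri_si) & (vol < core_si)] = LABEL_PERI
    if min_cluster_voxels is not None and min_cluster_voxels > 1:
        scar = labels > 0
        comp, n_comp = ndimage.label(scar, structure=np.ones((3, 3, 3), dtype=int))
        if n_comp:
            sizes = np.bincount(comp.ravel())
            small_ids = np.nonzero(sizes < min_cluster_voxels)[0]
            small_ids = small_ids[small_ids != 0]  # 0 = background
            labels[np.isin(comp, small_ids)] = LABEL_NONE
    return ScarMap(labels=labels, max_si=float(max_si),
                   core_si=float(core_si), peri_si=float(peri_si))


def zone_fractions(scar_map: ScarMap, myocardium: np.ndarray) -> ZoneFractions:
    """Zone voxel counts over the myocardial voxel count, as percentages."""
    myo = np.asarray(myocardium, dtype=bool)
    n_myo = int(myo.sum())
    if n_myo == 0:
        raise DomainError("myocardium mask is empty")
    labels = scar_map.labels
    core = int(((labels == LABEL_CORE) & myo).sum())
    peri = int(((labels == LABEL_PERI) & myo).sum())
    core_pct = 100.0 * core / n_myo
    peri_pct = 100.0 * peri / n_myo
    return ZoneFractions(core_pct=core_pct, peri_pct=peri_pct,
                         total_pct=core_pct + peri_pct)


def rasterize_masks(
    stack: ShortAxisStack, contours: ContourSet
) -> tuple[np.ndarray, np.ndarray]:
    """Myocardium and ROI voxel masks for a stack from its contour set.

    Slices without a drawn ROI contribute myocardium to the denominator
    only.  Returns ``(myocardium, roi)``, both (slice, row, col) booleans.
    """
    shape2d = stack.intensities.shape[1:]
    myo = np.zeros(stack.intensities.shape, dtype=bool)
    roi = np.zeros(stack.intensities.shape, dtype=bool)
    for idx, sc in contours.slices.items():
        if idx < 0 or idx >= stack.n_slices:
            raise AlignmentError(f"contour slice index {idx} outside the stack")
        if sc.epicardium is not None:
            myo[idx] = myocardium_mask(sc, shape2d, stack.pixel_spacing_mm)
        if sc.roi is not None:
            roi[idx] = polygon_mask(sc.roi, shape2d, stack.pixel_spacing_mm)
    return myo, roi


def analyze_stack(
    stack: ShortAxisStack,
    contours: ContourSet,
    per_slice_max: bool = False,
    top_k: int | None = None,
    min_cluster_voxels: int | None = None,
) -> tuple[ScarMap, ZoneFractions, np.ndarray]:
    """Full FWHM pipeline: rasterize contours, find max SI, classify, size.

    The maximum SI is taken globally over the full-stack ROI by default
    (one reference region per study); ``per_slice_max=True`` thresholds
    each slice against its own ROI maximum instead.  Returns
    ``(scar_map, fractions, myocardium_mask)``.
    """
    myo, roi = rasterize_masks(stack, contours)
    if not per_slice_max:
        mx = max_signal_intensity(stack.intensities, myo, roi, top_k=top_k)
        smap = classify_zones(stack.intensities, myo, mx,
                              min_cluster_voxels=min_cluster_voxels)
    else:
        labels = np.zeros(stack.intensities.shape, dtype=np.uint8)
        mx_global = 0.0
        for s in range(stack.n_slices):
            if not (roi[s] & myo[s]).any():
                continue
            mx = max_signal_intensity(stack.intensities[s], myo[s], roi[s], top_k=top_k)
            mx_global = max(mx_global, mx)
            sm = classify_zones(stack.intensities[s], myo[s], mx)
            labels[s] = sm.labels
        smap = ScarMap(labels=labels, max_si=mx_global,
                       core_si=CORE_FRACTION * mx_global,
                       peri_si=PERI_FRACTION * mx_global)
    fractions = zone_fractions(smap, myo)
    return smap, fractions, myo
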