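"""Synthetic short-axis CE-CMR phantoms with analytically known ground truth.

The phantom emulates what a contrast-enhanced short-axis stack of an old
myocardial infarction looks like: an annular myocardium (endo/epi circles)
with dark-gray remote muscle, a bright hyperenhanced scar wedge, a bright
blood pool inside the cavity, and additive noise.  The scar wedge has a
core plateau at ``si_core`` and an intermediate-intensity rim at its outer
radial margin at ``si_border`` — the two-level structure the
full-width-at-half-maximum thresholds (50% / 35% of max SI) are designed to
separate into infarct core and peri-infarct (heterogeneous) zone.

Truth labels are decided at voxel centers from the voxel's polar coordinates
(no partial-volume sub-sampling), so an independent per-voxel loop can
re-derive every label exactly and the noiseless phantom is recovered
*exactly* by the FWHM pipeline.  All randomness flows from ``seed``; the same
seed yields a bit-identical stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import aha17
from .errors import DomainError, GeometryError
from .io_formats import ContourSet, ShortAxisStack, SliceContours, N_SEGMENTS

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "phantom_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, signal, and noise parameters of one synthetic stack.

    Defaults mimic a clinical CE stack: 10 mm slices, ~1.5 mm in-plane
    pixels, a mid-sized LV (endo radius 20 mm, epi 30 mm), and a 90-degree
    subendocardial scar at 60% transmurality with a 30% border rim.
    Signal plateaus are free parameters in arbitrary SI units; the defaults
    put the border rim (42) inside the 35-50% band of the core plateau (100)
    and remote myocardium (10) well below 35% — the inversion time of a CE
    acquisition is chosen to null viable myocardium, so remote muscle sits
    near the noise floor.  Blood (120) is brighter than the core, which
    makes sloppy ROI handling (forgetting to intersect the ROI with the
    myocardium) detectable as an inflated maximum SI.
    """

    n_slices: int = 8
    slice_thickness_mm: float = 10.0
    slice_gap_mm: float = 0.0
    pixel_spacing_mm: float = 1.5
    grid_size: int = 96
    endo_radius_mm: float | Sequence[float] = 20.0
    epi_radius_mm: float | Sequence[float] = 30.0
    scar_angular_extent_deg: float = 90.0
    scar_angular_center_deg: float = 90.0
    scar_transmurality: float = 0.6
    scar_slice_range: tuple[int, int] = (1, 7)  # half-open [start, stop)
    si_remote: float = 10.0
    si_core: float = 100.0
    si_border: float = 42.0
    si_blood: float = 120.0
    border_rim_fraction: float = 0.3
    noise_sd: float = 0.0
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0
    n_contour_vertices: int = 720

    def endo_radii(self) -> np.ndarray:
        return _per_slice(self.endo_radius_mm, self.n_slices)

    def epi_radii(self) -> np.ndarray:
        return _per_slice(self.epi_radius_mm, self.n_slices)

    def center_mm(self) -> tuple[float, float]:
        """LV center: the geometric center of the pixel grid."""
        c = (self.grid_size - 1) / 2.0 * self.pixel_spacing_mm
        return (c, c)

    def validate(self) -> None:
        if self.n_slices < 1 or self.grid_size < 4:
            raise GeometryError("need >=1 slice and a usable grid")
        if self.pixel_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise GeometryError("spacing and thickness must be positive")
        endo, epi = self.endo_radii(), self.epi_radii()
        if (endo <= 0).any() or (epi <= endo).any():
            raise GeometryError("need 0 < endo_radius < epi_radius on every slice")
        half_fov = (self.grid_size - 1) / 2.0 * self.pixel_spacing_mm
        if (epi >= half_fov).any():
            raise GeometryError("epicardium does not fit inside the pixel grid")
        if not 0.0 <= self.scar_transmurality <= 1.0:
            raise DomainError("scar_transmurality must be in [0, 1]")
        if not 0.0 <= self.border_rim_fraction <= 1.0:
            raise DomainError("border_rim_fraction must be in [0, 1]")
        lo = min(self.si_remote, self.si_core)
        hi = max(self.si_remote, self.si_core)
        if self.scar_angular_extent_deg > 0 and self.scar_transmurality > 0:
            if not lo < self.si_border < hi:
                raise DomainError("si_border must lie strictly between si_remote and si_core")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise DomainError("noise_model must be 'gaussian' or 'rician'")
        start, stop = self.scar_slice_range
        if not (0 <= start <= stop <= self.n_slices):
            raise DomainError("scar_slice_range must be within [0, n_slices]")


def _per_slice(value, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise GeometryError(f"per-slice radius needs {n} entries")
    return arr


@dataclass
class PhantomTruth:
    """Exact noiseless labels and summary percentages for one phantom.

    Masks are (slice, row, col) booleans; core and border are disjoint
    subsets of the myocardium.  Percentages are voxel counts over the
    myocardial voxel count of the whole stack.  ``per_segment_scar_pct`` is
    total scar (core + border) as % of each AHA segment's voxels, NaN for
    segments absent from the phantom (e.g. the apical cap when the cavity
    never closes).
    """

    myocardium_mask: np.ndarray
    core_mask: np.ndarray
    border_mask: np.ndarray
    true_core_pct: float
    true_peri_pct: float
    true_total_pct: float
    per_segment_scar_pct: np.ndarray
    contours: ContourSet
    segment_labels: np.ndarray | None = None


def _wrap_angle_deg(a: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180]."""
    return -((-a + 180.0) % 360.0 - 180.0)


def _circle(cx: float, cy: float, r: float, n: int) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def _roi_polygon(spec: PhantomSpec, cx: float, cy: float,
                 endo_r: float, epi_r: float) -> np.ndarray:
    """Annular-sector ROI generously covering the scar wedge (+10 deg, +1 mm)."""
    if spec.scar_angular_extent_deg >= 340.0:
        return _circle(cx, cy, epi_r + 1.0, spec.n_contour_vertices)
    half = spec.scar_angular_extent_deg / 2.0 + 10.0
    c = np.deg2rad(spec.scar_angular_center_deg)
    ang = c + np.deg2rad(np.linspace(-half, half, 90))
    r_out = epi_r + 1.0
    r_in = max(endo_r - 1.0, 0.5)
    outer = np.column_stack([cx + r_out * np.cos(ang), cy + r_out * np.sin(ang)])
    inner = np.column_stack([cx + r_in * np.cos(ang[::-1]), cy + r_in * np.sin(ang[::-1])])
    return np.vstack([outer, inner])


def generate_phantom(spec: PhantomSpec) -> tuple[ShortAxisStack, PhantomTruth]:
    """Generate a noisy stack plus its exact noiseless truth.

    Per voxel center at polar coordinates (r, theta) about the LV center:

    * myocardium:  ``endo_r <= r < epi_r``
    * scar wedge:  angular distance to the scar center in
      ``[-extent/2, extent/2)`` (whole annulus when extent >= 360) and
      ``r < endo_r + transmurality * wall`` (subendocardial growth)
    * border rim:  outer ``border_rim_fraction`` of the scar's radial
      thickness; the rest of the wedge is core.
    """
    spec.validate()
    n = spec.grid_size
    cx, cy = spec.center_mm()
    endo, epi = spec.endo_radii(), spec.epi_radii()
    xx, yy = np.meshgrid(
        np.arange(n) * spec.pixel_spacing_mm, np.arange(n) * spec.pixel_spacing_mm
    )
    r = np.hypot(xx - cx, yy - cy)
    theta = np.degrees(np.arctan2(yy - cy, xx - cx))
    dtheta = _wrap_angle_deg(theta - spec.scar_angular_center_deg)
    half = spec.scar_angular_extent_deg / 2.0
    full_ring = spec.scar_angular_extent_deg >= 360.0
    in_wedge_2d = (
        np.ones_like(r, dtype=bool)
        if full_ring
        else (dtheta >= -half) & (dtheta < half)
    )

    shape = (spec.n_slices, n, n)
    volume = np.zeros(shape)
    myo = np.zeros(shape, dtype=bool)
    core = np.zeros(shape, dtype=bool)
    border = np.zeros(shape, dtype=bool)
    start, stop = spec.scar_slice_range

    contours = ContourSet(
        phase="ED",
        lv_center=(cx, cy),
        rv_insertion=(cx + float(epi.max()) + 5.0, cy),
    )

    for s in range(spec.n_slices):
        myo_s = (r >= endo[s]) & (r < epi[s])
        blood_s = r < endo[s]
        slice_img = np.zeros((n, n))
        slice_img[myo_s] = spec.si_remote
        slice_img[blood_s] = spec.si_blood

        has_scar = (
            start <= s < stop
            and spec.scar_angular_extent_deg > 0
            and spec.scar_transmurality > 0
        )
        roi = None
        if has_scar:
            wall = epi[s] - endo[s]
            r_scar = endo[s] + spec.scar_transmurality * wall
            r_core = endo[s] + (1.0 - spec.border_rim_fraction) * spec.scar_transmurality * wall
            scar_s = myo_s & in_wedge_2d & (r < r_scar)
            core_s = scar_s & (r < r_core)
            border_s = scar_s & ~core_s
            slice_img[core_s] = spec.si_core
            slice_img[border_s] = spec.si_border
            core[s] = core_s
            border[s] = border_s
            roi = _roi_polygon(spec, cx, cy, endo[s], epi[s])

        volume[s] = slice_img
        myo[s] = myo_s
        contours.slices[s] = SliceContours(
            endocardium=_circle(cx, cy, endo[s], spec.n_contour_vertices),
            epicardium=_circle(cx, cy, epi[s], spec.n_contour_vertices),
            roi=roi,
        )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "gaussian":
            volume = volume + rng.normal(0.0, spec.noise_sd, size=shape)
        else:  # rician: magnitude of complex signal + noise
            n1 = rng.normal(0.0, spec.noise_sd, size=shape)
            n2 = rng.normal(0.0, spec.noise_sd, size=shape)
            volume = np.hypot(volume + n1, n2)

    n_myo = int(myo.sum())
    if n_myo == 0:
        raise GeometryError("phantom myocardium is empty")
    core_pct = 100.0 * core.sum() / n_myo
    peri_pct = 100.0 * border.sum() / n_myo

    seg = aha17.assign_segments(
        myo,
        lv_center=(cx, cy),
        rv_insertion=contours.rv_insertion,
        pixel_spacing_mm=(spec.pixel_spacing_mm, spec.pixel_spacing_mm),
    )
    scar_total = core | border
    per_seg = np.full(N_SEGMENTS, np.nan)
    for seg_id in range(1, N_SEGMENTS + 1):
        in_seg = seg.labels == seg_id
        count = int(in_seg.sum())
        if count:
            per_seg[seg_id - 1] = 100.0 * scar_total[in_seg].sum() / count

    stack = ShortAxisStack(
        intensities=volume,
        pixel_spacing_mm=(spec.pixel_spacing_mm, spec.pixel_spacing_mm),
        slice_thickness_mm=spec.slice_thickness_mm,
        slice_gap_mm=spec.slice_gap_mm,
    )
    truth = PhantomTruth(
        myocardium_mask=myo,
        core_mask=core,
        border_mask=border,
        true_core_pct=float(core_pct),
        true_peri_pct=float(peri_pct),
        true_total_pct=float(core_pct + peri_pct),
        per_segment_scar_pct=per_seg,
        contours=contours,
        segment_labels=seg.labels,
    )
    return stack, truth


def phantom_cohort(
    n_per_group: int,
    group_param_ranges: Mapping[str, Mapping[str, tuple[float, float]]],
    seed: int,
    base_spec: PhantomSpec | None = None,
) -> list[tuple[ShortAxisStack, PhantomTruth, str]]:
    """Generate a two-group cohort of phantoms with known effect sizes.

    ``group_param_ranges`` maps each group label to ``{param: (lo, hi)}``
    uniform sampling ranges over :class:`PhantomSpec` fields (e.g.
    ``scar_angular_extent_deg``).  Identical ranges for both groups yield a
    null cohort; disjoint ranges yield a known group difference.  The whole
    collection is reproducible from ``seed``.
    """
    if n_per_group < 1:
        raise DomainError("n_per_group must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    out: list[tuple[ShortAxisStack, PhantomTruth, str]] = []
    for group, ranges in group_param_ranges.items():
        for _ in range(n_per_group):
            params = {
                name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()
            }
            params["seed"] = int(rng.integers(0, 2**31 - 1))
            spec = replace(base, **params)
            stack, truth = generate_phantom(spec)
            out.append((stack, truth, group))
    return out
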