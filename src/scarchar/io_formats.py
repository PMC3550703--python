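"""Readers/writers and interchange types for the scar-characterization pipeline.

On-disk conventions
-------------------
* Short-axis stacks are NIfTI volumes (``.nii`` / ``.nii.gz``) stored with
  axes (x=column, y=row, z=slice) and a required JSON *geometry sidecar*
  (``<path>.json``) carrying the slice thickness, inter-slice gap, and slice
  ordering.  NIfTI headers default unset pixdims to 1.0, so the sidecar is the
  only reliable carrier of acquisition geometry; a stack without it is
  rejected with :class:`~scarchar.errors.MetadataError` rather than silently
  assuming defaults.
* Contours and landmarks travel as JSON (schema below), cohort tables as CSV.

Coordinate convention
---------------------
Contour coordinates are millimetres in the image plane, origin at the image
corner, 0-based pixel indexing with the *pixel-center* convention: the center
of pixel (row r, col c) sits at ``(x, y) = (c * col_spacing, r * row_spacing)``.
A voxel belongs to the myocardium iff its center lies inside the epicardial
polygon and not inside the endocardial polygon.

Contour JSON schema::

    {
      "phase": "ED",                      # or "ES"
      "landmarks": {                      # stack-level defaults, optional
        "lv_center": [x_mm, y_mm],
        "rv_insertion": [x_mm, y_mm]
      },
      "slices": [
        {
          "index": 0,
          "endocardium": [[x, y], ...],   # closed simple polygon (mm)
          "epicardium":  [[x, y], ...],
          "roi":         [[x, y], ...],   # hyperenhancement ROI, optional
          "lv_center":   [x, y],          # per-slice overrides, optional
          "rv_insertion": [x, y]
        }, ...
      ]
    }

Cohort CSV schema: columns ``id, group, height_cm, weight_kg,
followup_months, appropriate_therapy, death, wm1..wm17`` plus any derived
metric columns (``lvef_pct, edv_ml, ...``).  ``group`` must be ``primary`` or
``secondary``; blank ``wm*`` cells mean *unobserved* (never coded as 0,
because the wall-motion score index divides by the number of observed
segments).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .errors import (
    ContainmentError,
    DomainError,
    GeometryError,
    MetadataError,
    SchemaError,
)

GROUP_LABELS = ("primary", "secondary")
N_SEGMENTS = 17

__all__ = [
    "ShortAxisStack",
    "SliceContours",
    "ContourSet",
    "PatientRecord",
    "read_stack",
    "write_stack",
    "read_contours",
    "write_contours",
    "read_cohort",
    "write_cohort",
    "polygon_mask",
    "myocardium_mask",
    "GROUP_LABELS",
    "N_SEGMENTS",
]


# ---------------------------------------------------------------------------
# short-axis intensity stacks
# ---------------------------------------------------------------------------

@dataclass
class ShortAxisStack:
    """A short-axis signal-intensity volume with its acquisition geometry.

    ``intensities`` is indexed ``(slice, row, col)``; ``pixel_spacing_mm`` is
    ``(row_spacing, col_spacing)``.  ``slice_gap_mm`` is the gap between
    consecutive slices (0 for contiguous stacks); the center-to-center slice
    spacing is ``slice_thickness_mm + slice_gap_mm``.
    """

    intensities: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    slice_gap_mm: float = 0.0
    base_to_apex: bool = True

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.shape[0] < 1:
            raise MetadataError("intensity volume must be 3-D with >=1 slice")
        rs, cs = self.pixel_spacing_mm
        if not (rs > 0 and cs > 0 and self.slice_thickness_mm > 0):
            raise MetadataError("pixel spacing and slice thickness must be positive")
        if self.slice_gap_mm < 0:
            raise MetadataError("slice gap must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def slice_spacing_mm(self) -> float:
        """Center-to-center distance between consecutive slices."""
        return self.slice_thickness_mm + self.slice_gap_mm


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_stack(stack: ShortAxisStack, path: str | Path) -> None:
    """Write a stack as NIfTI plus its JSON geometry sidecar."""
    path = Path(path)
    rs, cs = stack.pixel_spacing_mm
    data = np.transpose(stack.intensities, (2, 1, 0))  # (x=col, y=row, z=slice)
    affine = np.diag([cs, rs, stack.slice_spacing_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms((cs, rs, stack.slice_spacing_mm))
    nib.save(img, str(path))
    sidecar = {
        "pixel_spacing_mm": [rs, cs],
        "slice_thickness_mm": stack.slice_thickness_mm,
        "slice_gap_mm": stack.slice_gap_mm,
        "base_to_apex": stack.base_to_apex,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_stack(path: str | Path) -> ShortAxisStack:
    """Read a NIfTI stack; its geometry sidecar is required."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise MetadataError(
            f"geometry sidecar {sidecar_path.name} not found; slice thickness "
            "cannot be recovered from the NIfTI header alone"
        )
    meta = json.loads(sidecar_path.read_text())
    for key in ("pixel_spacing_mm", "slice_thickness_mm"):
        if key not in meta:
            raise MetadataError(f"geometry sidecar lacks required field {key!r}")
    img = nib.load(str(path))
    data = np.transpose(np.asarray(img.dataobj, dtype=np.float64), (2, 1, 0))
    rs, cs = (float(v) for v in meta["pixel_spacing_mm"])
    return ShortAxisStack(
        intensities=data,
        pixel_spacing_mm=(rs, cs),
        slice_thickness_mm=float(meta["slice_thickness_mm"]),
        slice_gap_mm=float(meta.get("slice_gap_mm", 0.0)),
        base_to_apex=bool(meta.get("base_to_apex", True)),
    )


# ---------------------------------------------------------------------------
# contours and landmarks
# ---------------------------------------------------------------------------

def _as_polygon(coords: Sequence[Sequence[float]], name: str) -> Polygon:
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise SchemaError(f"{name} polygon needs >=3 (x, y) vertices")
    poly = Polygon(arr)
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError(f"{name} polygon is not simple/closed (self-intersecting or degenerate)")
    return poly


@dataclass
class SliceContours:
    """Per-slice contour polygons (mm coordinates) and optional landmarks."""

    endocardium: np.ndarray | None = None
    epicardium: np.ndarray | None = None
    roi: np.ndarray | None = None
    lv_center: tuple[float, float] | None = None
    rv_insertion: tuple[float, float] | None = None

    def validate(self) -> None:
        endo = epi = None
        if self.endocardium is not None:
            endo = _as_polygon(self.endocardium, "endocardial")
        if self.epicardium is not None:
            epi = _as_polygon(self.epicardium, "epicardial")
        if self.roi is not None:
            _as_polygon(self.roi, "hyperenhancement ROI")
        if endo is not None and epi is not None:
            # tiny buffer absorbs floating-point jitter on shared vertices
            if not epi.buffer(1e-9).covers(endo):
                raise ContainmentError(
                    "endocardial contour extends outside the epicardial contour"
                )


@dataclass
class ContourSet:
    """Contours for a whole stack: slice index -> :class:`SliceContours`."""

    slices: dict[int, SliceContours] = field(default_factory=dict)
    phase: str = "ED"
    lv_center: tuple[float, float] | None = None
    rv_insertion: tuple[float, float] | None = None

    def validate(self) -> None:
        if self.phase not in ("ED", "ES"):
            raise SchemaError(f"phase must be 'ED' or 'ES', got {self.phase!r}")
        for sc in self.slices.values():
            sc.validate()

    def landmark(self, slice_index: int, name: str) -> tuple[float, float] | None:
        """Per-slice landmark with fallback to the stack-level default."""
        sc = self.slices.get(slice_index)
        value = getattr(sc, name, None) if sc is not None else None
        return value if value is not None else getattr(self, name)

    def slice_indices(self) -> list[int]:
        return sorted(self.slices)


def read_contours(path: str | Path) -> ContourSet:
    raw = json.loads(Path(path).read_text())
    if "slices" not in raw or not isinstance(raw["slices"], list):
        raise SchemaError("contour JSON must contain a 'slices' list")
    lm = raw.get("landmarks", {})

    def _pt(v):
        return None if v is None else (float(v[0]), float(v[1]))

    cs = ContourSet(
        phase=raw.get("phase", "ED"),
        lv_center=_pt(lm.get("lv_center")),
        rv_insertion=_pt(lm.get("rv_insertion")),
    )
    for entry in raw["slices"]:
        if "index" not in entry:
            raise SchemaError("each slice entry needs an 'index'")
        idx = int(entry["index"])

        def _poly(key):
            v = entry.get(key)
            return None if v is None else np.asarray(v, dtype=float)

        cs.slices[idx] = SliceContours(
            endocardium=_poly("endocardium"),
            epicardium=_poly("epicardium"),
            roi=_poly("roi"),
            lv_center=_pt(entry.get("lv_center")),
            rv_insertion=_pt(entry.get("rv_insertion")),
        )
    cs.validate()
    return cs


def write_contours(contours: ContourSet, path: str | Path) -> None:
    def _pt(v):
        return None if v is None else [float(v[0]), float(v[1])]

    out = {
        "phase": contours.phase,
        "landmarks": {
            "lv_center": _pt(contours.lv_center),
            "rv_insertion": _pt(contours.rv_insertion),
        },
        "slices": [],
    }
    for idx in contours.slice_indices():
        sc = contours.slices[idx]
        out["slices"].append(
            {
                "index": idx,
                "endocardium": None if sc.endocardium is None else np.asarray(sc.endocardium).tolist(),
                "epicardium": None if sc.epicardium is None else np.asarray(sc.epicardium).tolist(),
                "roi": None if sc.roi is None else np.asarray(sc.roi).tolist(),
                "lv_center": _pt(sc.lv_center),
                "rv_insertion": _pt(sc.rv_insertion),
            }
        )
    Path(path).write_text(json.dumps(out))


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def polygon_mask(
    coords: Sequence[Sequence[float]],
    shape: tuple[int, int],
    pixel_spacing_mm: tuple[float, float],
) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon.

    Pixel-center convention: pixel (r, c) is tested at
    ``(x, y) = (c * col_spacing, r * row_spacing)``.
    """
    poly = _as_polygon(coords, "contour")
    rows, cols = shape
    rs, cs = pixel_spacing_mm
    xx, yy = np.meshgrid(np.arange(cols) * cs, np.arange(rows) * rs)
    return shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(shape)


def myocardium_mask(
    sc: SliceContours,
    shape: tuple[int, int],
    pixel_spacing_mm: tuple[float, float],
) -> np.ndarray:
    """Myocardium = inside epicardium, outside endocardium (voxel centers)."""
    if sc.epicardium is None:
        raise SchemaError("slice has no epicardial contour")
    epi = polygon_mask(sc.epicardium, shape, pixel_spacing_mm)
    if sc.endocardium is None:
        return epi
    endo = polygon_mask(sc.endocardium, shape, pixel_spacing_mm)
    return epi & ~endo


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """One ICD recipient: group label, anthropometrics, wall-motion labels,
    follow-up events, and slots for CMR-derived metrics.

    ``wall_motion`` is a length-17 float array; NaN marks an *unobserved*
    segment (explicitly distinct from score 0 = normal motion).
    """

    id: str
    group: str
    height_cm: float | None = None
    weight_kg: float | None = None
    wall_motion: np.ndarray = field(
        default_factory=lambda: np.full(N_SEGMENTS, np.nan)
    )
    appropriate_therapy: bool = False
    death: bool = False
    followup_months: float | None = None
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise SchemaError(
                f"unknown group label {self.group!r}; expected one of {GROUP_LABELS}"
            )
        wm = np.asarray(self.wall_motion, dtype=float)
        if wm.shape != (N_SEGMENTS,):
            raise SchemaError("wall_motion must have 17 entries")
        observed = wm[~np.isnan(wm)]
        if observed.size and (
            (observed < 0).any() or (observed > 4).any()
            or (observed != np.round(observed)).any()
        ):
            raise DomainError("wall-motion scores must be integers in 0..4 (4 = dyskinesia)")
        self.wall_motion = wm

    @property
    def mace(self) -> bool:
        """Major adverse cardiovascular event: appropriate ICD therapy and/or death."""
        return bool(self.appropriate_therapy or self.death)


_WM_COLS = [f"wm{i}" for i in range(1, N_SEGMENTS + 1)]
_CORE_COLS = {"id", "group", "height_cm", "weight_kg", "followup_months",
              "appropriate_therapy", "death", *_WM_COLS}


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects."""
    df = pd.read_csv(path)
    for col in ("id", "group"):
        if col not in df.columns:
            raise SchemaError(f"cohort CSV lacks required column {col!r}")
    records: list[PatientRecord] = []
    metric_cols = [c for c in df.columns if c not in _CORE_COLS]
    for _, row in df.iterrows():
        wm = np.full(N_SEGMENTS, np.nan)
        for i, col in enumerate(_WM_COLS):
            if col in df.columns and not pd.isna(row[col]):
                wm[i] = float(row[col])
        rec = PatientRecord(
            id=str(row["id"]),
            group=str(row["group"]),
            height_cm=None if "height_cm" not in df.columns or pd.isna(row.get("height_cm")) else float(row["height_cm"]),
            weight_kg=None if "weight_kg" not in df.columns or pd.isna(row.get("weight_kg")) else float(row["weight_kg"]),
            wall_motion=wm,
            appropriate_therapy=bool(row.get("appropriate_therapy", False)) if not pd.isna(row.get("appropriate_therapy", False)) else False,
            death=bool(row.get("death", False)) if not pd.isna(row.get("death", False)) else False,
            followup_months=None if pd.isna(row.get("followup_months", np.nan)) else float(row["followup_months"]),
            metrics={c: float(row[c]) for c in metric_cols if not pd.isna(row[c])},
        )
        records.append(rec)
    return records


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "id": rec.id,
            "group": rec.group,
            "height_cm": rec.height_cm,
            "weight_kg": rec.weight_kg,
            "followup_months": rec.followup_months,
            "appropriate_therapy": int(rec.appropriate_therapy),
            "death": int(rec.death),
        }
        for i, col in enumerate(_WM_COLS):
            v = rec.wall_motion[i]
            row[col] = "" if math.isnan(v) else int(v)
        row.update(rec.metrics)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def cohort_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten records (group, events, derived metrics) into a tidy DataFrame."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "id": rec.id,
            "group": rec.group,
            "appropriate_therapy": rec.appropriate_therapy,
            "death": rec.death,
            "mace": rec.mace,
        }
        row.update(rec.metrics)
        rows.append(row)
    return pd.DataFrame(rows)
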