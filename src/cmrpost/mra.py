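"""Angiographic post-processing primitives.

3D subtraction (post- minus pre-contrast), maximum-intensity projection,
maximal-caliper lumen diameters, and the standardized nine-level thoracic
aorta report (sinuses of Valsalva through the abdominal aorta above the
coeliac trunk). Sinus and sinotubular-junction diameters require ECG-gated
acquisitions and are suppressed otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform

from .errors import DomainError, GeometryError
from .geometry import ContourPolygon

AORTA_LEVELS: dict[int, str] = {
    1: "sinuses of Valsalva",
    2: "sinotubular junction",
    3: "mid-ascending aorta",
    4: "proximal to brachiocephalic trunk",
    5: "between left common carotid and left subclavian arteries",
    6: "distal to left subclavian artery",
    7: "mid-descending aorta",
    8: "diaphragm",
    9: "abdominal aorta above coeliac trunk",
}

GATING_REQUIRED_LEVELS = (1, 2)


@dataclass
class Volume3D:
    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise GeometryError("voxels must be a 3-D array")
        if min(self.spacing) <= 0:
            raise GeometryError("voxel spacing must be positive")


def subtract_mra(post: Volume3D, pre: Volume3D) -> Volume3D:
    """Voxelwise post-contrast minus pre-contrast volume."""
    if post.voxels.shape != pre.voxels.shape or post.spacing != pre.spacing:
        raise GeometryError("pre and post volumes must share shape and spacing")
    return Volume3D(post.voxels - pre.voxels, post.spacing)


def mip_projection(volume: Volume3D, axis: int = 0) -> np.ndarray:
    """Maximum intensity projection along one axis."""
    if axis not in (0, 1, 2):
        raise GeometryError("axis must be 0, 1 or 2")
    return volume.voxels.max(axis=axis)


def _region_points(
    region: ContourPolygon | np.ndarray, pixel_spacing: tuple[float, float]
) -> np.ndarray:
    if isinstance(region, ContourPolygon):
        return region.vertices
    mask = np.asarray(region, dtype=bool)
    if not mask.any():
        raise GeometryError("empty cross-section mask")
    rows, cols = np.nonzero(mask)
    sx, sy = pixel_spacing
    return np.column_stack([cols * sx, rows * sy])


def _max_caliper(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximal width of a point set and its direction (via the convex hull)."""
    if len(points) > 3:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # collinear degenerate sets fall through to brute force
            pass
    d = squareform(pdist(points))
    i, j = np.unravel_index(np.argmax(d), d.shape)
    width = float(d[i, j])
    if width <= 0:
        raise GeometryError("degenerate cross-section")
    u = (points[j] - points[i]) / width
    return width, u


def vessel_diameter(
    cross_section: ContourPolygon | np.ndarray,
    mode: str = "inner",
    wall: ContourPolygon | np.ndarray | None = None,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Widest diameter (mm) of a vessel cross-section perpendicular to its axis.

    ``inner`` returns the maximal caliper width of the lumen. ``outer``
    additionally includes the vessel wall, measured along the same
    direction as the widest inner diameter.
    """
    pts = _region_points(cross_section, pixel_spacing)
    inner, direction = _max_caliper(pts)
    if mode == "inner":
        return inner
    if mode == "outer":
        if wall is None:
            raise DomainError("outer mode requires a wall region")
        allpts = np.vstack([pts, _region_points(wall, pixel_spacing)])
        proj = allpts @ direction
        return float(proj.max() - proj.min())
    raise DomainError(f"unknown diameter mode {mode!r}")


@dataclass
class VesselLevelMeasurement:
    level_id: int
    inner_diameter_mm: float
    outer_diameter_mm: float | None = None
    gated: bool = False
    sinus_dimensions_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.level_id not in AORTA_LEVELS:
            raise DomainError(f"unknown aorta level id {self.level_id}")
        if (
            self.outer_diameter_mm is not None
            and self.outer_diameter_mm < self.inner_diameter_mm
        ):
            raise DomainError("outer diameter cannot be smaller than inner diameter")

    @property
    def label(self) -> str:
        return AORTA_LEVELS[self.level_id]


def aorta_level_report(
    measurements: list[VesselLevelMeasurement],
) -> list[dict]:
    """Standardized nine-row table of aortic diameters.

    Missing levels are marked; sinus/STJ values obtained without ECG gating
    are suppressed with an explanatory reason. For the sinus level all
    three sinus-commissure dimensions are carried when supplied.
    """
    by_level: dict[int, VesselLevelMeasurement] = {}
    for m in measurements:
        if m.level_id in by_level:
            raise DomainError(f"duplicate measurement for level {m.level_id}")
        by_level[m.level_id] = m
    rows = []
    for level in sorted(AORTA_LEVELS):
        row: dict = {"level": level, "label": AORTA_LEVELS[level], "unit": "mm"}
        m = by_level.get(level)
        if m is None:
            row.update(status="missing", inner_diameter_mm=None)
        elif level in GATING_REQUIRED_LEVELS and not m.gated:
            row.update(
                status="suppressed",
                reason="requires ECG gated acquisitions",
                inner_diameter_mm=None,
            )
        else:
            row.update(
                status="reported",
                inner_diameter_mm=m.inner_diameter_mm,
                outer_diameter_mm=m.outer_diameter_mm,
                gated=m.gated,
            )
            if level == 1 and m.sinus_dimensions_mm is not None:
                row["sinus_commissure_dimensions_mm"] = list(m.sinus_dimensions_mm)
        rows.append(row)
    return rows
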