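"""Shared geometric data model for cardiac MR post-processing.

Contours are planar polygons with vertices in millimetres; image coordinates
are 0-based with pixel centers on the integer grid scaled by the pixel
spacing (pixel (row, col) sits at ``(x, y) = (col * sx, row * sy)``).
Slice 0 is the most basal slice of a short-axis stack.

The myocardium of the left ventricle is divided according to the standard
16/17-segment model (basal and mid rings of six 60-degree segments, an
apical ring of four 90-degree segments, and an optional apical-cap segment
17), with the angular origin at the anterior RV insertion point and
segments counted counterclockwise as seen from the apex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

from .errors import (
    ContourTopologyError,
    GeometryError,
    InsufficientCoverageError,
    InvalidContourError,
    InvalidRingError,
)

CONTOUR_ROLES = frozenset(
    {
        "endocardial",
        "epicardial",
        "papillary",
        "blood_pool_roi",
        "remote_roi",
        "skeletal_muscle_roi",
        "scar_core_roi",
        "vessel_lumen",
        "generic",
    }
)

RINGS = ("basal", "mid", "apical", "apical_cap")


@dataclass(frozen=True)
class Point2D:
    """In-plane image coordinate in millimetres."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidContourError("Point2D coordinates must be finite")


@dataclass
class ContourPolygon:
    """A simple closed polygon (implicitly closed vertex ring) with a role.

    Parameters
    ----------
    vertices : (n, 2) array of float
        Ordered vertices in mm; the polygon is implicitly closed.
    role : str
        One of :data:`CONTOUR_ROLES`.
    """

    vertices: np.ndarray
    role: str = "generic"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise InvalidContourError("vertices must be an (n, 2) array")
        if self.vertices.shape[0] < 3:
            raise InvalidContourError("polygon needs at least 3 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise InvalidContourError("polygon vertices must be finite")
        if self.role not in CONTOUR_ROLES:
            raise InvalidContourError(f"unknown contour role {self.role!r}")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise InvalidContourError("polygon must be simple (non-self-intersecting)")
        if poly.area <= 0.0:
            raise InvalidContourError("polygon must enclose a positive area")

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_mm2(self) -> float:
        return polygon_area(self)

    def centroid(self) -> Point2D:
        c = self.as_shapely().centroid
        return Point2D(c.x, c.y)


@dataclass(frozen=True)
class SliceGeometry:
    """Geometry of one short-axis slice (index 0 = most basal)."""

    slice_index: int
    z_location: float
    thickness: float
    gap: float = 0.0
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise GeometryError("slice thickness must be positive")
        if self.gap < 0:
            raise GeometryError("interslice gap must be non-negative")
        if min(self.pixel_spacing) <= 0:
            raise GeometryError("pixel spacing must be positive")

    @property
    def step_mm(self) -> float:
        """Integration step used by slice-summation volumetry."""
        return self.thickness + self.gap


@dataclass
class StudyMeta:
    """Patient-level metadata; both fields manually overridable by the reader."""

    heart_rate: float | None = None
    body_surface_area: float | None = None
    acquisition_plane: str = "short_axis"

    def __post_init__(self) -> None:
        if self.heart_rate is not None and self.heart_rate <= 0:
            raise GeometryError("heart rate must be positive")
        if self.body_surface_area is not None and self.body_surface_area <= 0:
            raise GeometryError("body surface area must be positive")
        if self.acquisition_plane not in {"short_axis", "transaxial", "long_axis"}:
            raise GeometryError(f"unknown acquisition plane {self.acquisition_plane!r}")


ContourKey = tuple[int, int, str]


@dataclass
class ContourStack:
    """Per-slice, per-phase contours plus slice geometry.

    ``contours`` maps ``(slice_index, phase_index, role)`` to a list of
    polygons (most roles carry one polygon; papillary muscles may carry
    several).
    """

    slices: Sequence[SliceGeometry]
    contours: dict[ContourKey, list[ContourPolygon]]
    n_phases: int = 1
    meta: StudyMeta = field(default_factory=StudyMeta)

    def __post_init__(self) -> None:
        known = {s.slice_index for s in self.slices}
        for (s, p, role), polys in self.contours.items():
            if s not in known:
                raise GeometryError(f"contour references unknown slice {s}")
            if not 0 <= p < self.n_phases:
                raise GeometryError(f"contour references unknown phase {p}")
            if role not in CONTOUR_ROLES:
                raise GeometryError(f"unknown contour role {role!r}")
            if not isinstance(polys, list):
                raise GeometryError("contours must map to lists of polygons")
            endo = self.contours.get((s, p, "endocardial"))
            epi = self.contours.get((s, p, "epicardial"))
            if endo and epi and role in {"endocardial", "epicardial"}:
                if not epi[0].as_shapely().buffer(1e-6).contains(endo[0].as_shapely()):
                    raise ContourTopologyError(
                        f"epicardial contour does not enclose endocardial one "
                        f"on slice {s}, phase {p}"
                    )

    def geometry(self, slice_index: int) -> SliceGeometry:
        for s in self.slices:
            if s.slice_index == slice_index:
                return s
        raise GeometryError(f"no geometry for slice {slice_index}")

    def get(self, slice_index: int, phase: int, role: str) -> ContourPolygon | None:
        polys = self.contours.get((slice_index, phase, role))
        return polys[0] if polys else None

    def get_all(self, slice_index: int, phase: int, role: str) -> list[ContourPolygon]:
        return list(self.contours.get((slice_index, phase, role), []))

    def slices_with(self, role: str, phase: int) -> list[int]:
        return sorted(
            {s for (s, p, r) in self.contours if p == phase and r == role}
        )


@dataclass
class AHAModel:
    """Slice-to-ring assignment plus per-segment angular spans.

    ``segment_spans`` maps segment id to ``(ring, (start_deg, end_deg))``
    where angles are counterclockwise degrees relative to the per-slice
    anterior RV insertion reference.
    """

    n_segments: int
    ring_of_slice: Mapping[int, str]
    rv_insertion_angle: Mapping[int, float]
    segment_spans: Mapping[int, tuple[str, tuple[float, float]]]

    def segments_in_ring(self, ring: str) -> list[int]:
        return sorted(s for s, (r, _) in self.segment_spans.items() if r == ring)


def polygon_area(polygon: ContourPolygon) -> float:
    """Enclosed planar area in mm² by the shoelace formula (orientation-free)."""
    v = polygon.vertices
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _ring_sizes(n_usable: int) -> tuple[int, int, int]:
    # thirds base->apex; remainder slices go to the basal, then the mid ring
    base = n_usable // 3
    sizes = [base, base, base]
    for i in range(n_usable % 3):
        sizes[i] += 1
    return tuple(sizes)  # type: ignore[return-value]


def standard_segment_spans(
    n_segments: int,
) -> dict[int, tuple[str, tuple[float, float]]]:
    """Angular spans of the standard 16/17-segment model.

    Segment 1 is basal anterior, counting counterclockwise (viewed from the
    apex) from the anterior RV insertion reference; basal 1-6 and mid 7-12
    span 60° each, apical 13-16 span 90°, segment 17 is the apical cap.
    """
    if n_segments not in (16, 17):
        raise GeometryError("n_segments must be 16 or 17")
    spans: dict[int, tuple[str, tuple[float, float]]] = {}
    seg = 1
    for ring, count, width in (("basal", 6, 60.0), ("mid", 6, 60.0), ("apical", 4, 90.0)):
        for k in range(count):
            spans[seg] = (ring, (k * width, (k + 1) * width))
            seg += 1
    if n_segments == 17:
        spans[17] = ("apical_cap", (0.0, 360.0))
    return spans


def build_aha_model(
    stack: ContourStack,
    rv_insertion_angles: Mapping[int, float],
    n_segments: int = 17,
    phase: int = 0,
) -> AHAModel:
    """Build the 16/17-segment model from the slices carrying myocardium.

    Usable slices are those with both endocardial and epicardial contours at
    the given phase; they are partitioned base-to-apex into basal/mid/apical
    thirds (remainder to basal, then mid). With 17 segments the apical cap is
    a virtual ring with no short-axis slice of its own unless a slice is
    explicitly mapped there by the caller afterwards.
    """
    if n_segments not in (16, 17):
        raise GeometryError("n_segments must be 16 or 17")
    usable = [
        s
        for s in stack.slices_with("endocardial", phase)
        if stack.get(s, phase, "epicardial") is not None
    ]
    if len(usable) < 3:
        raise InsufficientCoverageError(
            f"need at least 3 slices with myocardium, got {len(usable)}"
        )
    nb, nm, na = _ring_sizes(len(usable))
    ring_of_slice: dict[int, str] = {}
    for i, s in enumerate(usable):
        if i < nb:
            ring_of_slice[s] = "basal"
        elif i < nb + nm:
            ring_of_slice[s] = "mid"
        else:
            ring_of_slice[s] = "apical"

    spans = standard_segment_spans(n_segments)

    missing = set(usable) - set(rv_insertion_angles)
    if missing:
        raise GeometryError(f"missing RV insertion angle for slices {sorted(missing)}")
    return AHAModel(
        n_segments=n_segments,
        ring_of_slice=ring_of_slice,
        rv_insertion_angle=dict(rv_insertion_angles),
        segment_spans=spans,
    )


def assign_pixels_to_segments(
    slice_mask: np.ndarray,
    model: AHAModel,
    slice_index: int,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Assign every myocardial pixel of one slice to an AHA segment.

    Returns an integer map of the mask's shape with segment ids (0 outside
    the mask). The angle of each pixel is measured counterclockwise about
    the myocardial centroid starting from the slice's RV insertion
    reference; a pixel exactly on a boundary angle belongs to the
    counterclockwise-following segment (half-open spans).
    """
    mask = np.asarray(slice_mask, dtype=bool)
    if not mask.any():
        raise GeometryError("empty myocardial mask")
    ring = model.ring_of_slice.get(slice_index)
    if ring is None:
        raise InvalidRingError(f"slice {slice_index} has no ring assignment")
    if ring == "apical_cap" and model.n_segments == 16:
        raise InvalidRingError("apical_cap ring invalid in a 16-segment model")

    out = np.zeros(mask.shape, dtype=np.int32)
    rows, cols = np.nonzero(mask)
    sx, sy = pixel_spacing
    x = cols * sx
    y = rows * sy
    cx, cy = x.mean(), y.mean()
    if ring == "apical_cap":
        out[rows, cols] = 17
        return out

    ref = model.rv_insertion_angle[slice_index]
    ang = (np.degrees(np.arctan2(y - cy, x - cx)) - ref) % 360.0
    segs = model.segments_in_ring(ring)
    width = 360.0 / len(segs)
    idx = np.floor(ang / width).astype(int)
    idx = np.clip(idx, 0, len(segs) - 1)  # guards ang == 360 after fp roundoff
    out[rows, cols] = np.asarray(segs, dtype=np.int32)[idx]
    return out


@dataclass(frozen=True)
class Chord:
    """A transmural chord from the endocardial to the epicardial boundary."""

    endo_point: Point2D
    epi_point: Point2D
    enhanced_fraction: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GeometryError("chord length must be positive")
        if not 0.0 <= self.enhanced_fraction <= 1.0:
            raise GeometryError("enhanced_fraction must lie in [0, 1]")

    @property
    def length(self) -> float:
        return math.hypot(
            self.epi_point.x - self.endo_point.x, self.epi_point.y - self.endo_point.y
        )


def _require_nested(endo: ContourPolygon, epi: ContourPolygon) -> None:
    if not epi.as_shapely().buffer(1e-6).contains(endo.as_shapely()):
        raise ContourTopologyError("endocardial contour must lie inside epicardial one")


def _ray_crossings(center: Point, direction: np.ndarray, boundary, reach: float) -> np.ndarray:
    """Sorted distances from center to crossings of a boundary along a ray."""
    end = (center.x + reach * direction[0], center.y + reach * direction[1])
    inter = LineString([(center.x, center.y), end]).intersection(boundary)
    if inter.is_empty:
        return np.empty(0)
    pts: list[Point] = []
    for geom in getattr(inter, "geoms", [inter]):
        if geom.geom_type == "Point":
            pts.append(geom)
        else:  # collinear overlap: keep its endpoints
            pts.extend(Point(c) for c in geom.coords)
    d = np.array([math.hypot(p.x - center.x, p.y - center.y) for p in pts])
    return np.sort(d)


def transmural_chords(
    endo: ContourPolygon,
    epi: ContourPolygon,
    mask: np.ndarray | None,
    n_chords: int = 100,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> list[Chord]:
    """Cast chords at equal angular increments from the myocardial centroid.

    Each chord runs from the endocardial to the epicardial boundary along
    the ray; ``enhanced_fraction`` is the fraction of the chord's length
    (measured from the endocardium) whose samples fall inside ``mask``.
    ``mask`` may be None, meaning no enhancement anywhere.
    """
    if n_chords < 12:
        raise GeometryError("n_chords must be at least 12")
    _require_nested(endo, epi)
    mask_arr = None if mask is None else np.asarray(mask, dtype=bool)
    sx, sy = pixel_spacing
    center = endo.as_shapely().centroid
    reach = 4.0 * max(epi.as_shapely().bounds[2] - epi.as_shapely().bounds[0],
                      epi.as_shapely().bounds[3] - epi.as_shapely().bounds[1])
    endo_b = endo.as_shapely().exterior
    epi_b = epi.as_shapely().exterior

    chords: list[Chord] = []
    step = min(sx, sy) / 4.0
    for k in range(n_chords):
        theta = 2.0 * math.pi * k / n_chords
        u = np.array([math.cos(theta), math.sin(theta)])
        d_endo = _ray_crossings(center, u, endo_b, reach)
        d_epi = _ray_crossings(center, u, epi_b, reach)
        if d_endo.size == 0 or d_epi.size == 0:
            raise GeometryError(f"chord ray {k} misses a boundary")
        r0 = d_endo[0]
        beyond = d_epi[d_epi > r0 + 1e-9]
        if beyond.size == 0:
            raise ContourTopologyError(f"chord ray {k}: epicardium not beyond endocardium")
        r1 = beyond[0]
        p0 = Point2D(center.x + r0 * u[0], center.y + r0 * u[1])
        p1 = Point2D(center.x + r1 * u[0], center.y + r1 * u[1])
        if mask_arr is None:
            frac = 0.0
        else:
            n_samp = max(int(math.ceil((r1 - r0) / step)), 8)
            t = (np.arange(n_samp) + 0.5) / n_samp
            xs = p0.x + t * (p1.x - p0.x)
            ys = p0.y + t * (p1.y - p0.y)
            rowi = np.rint(ys / sy).astype(int)
            coli = np.rint(xs / sx).astype(int)
            inside = (
                (rowi >= 0)
                & (rowi < mask_arr.shape[0])
                & (coli >= 0)
                & (coli < mask_arr.shape[1])
            )
            hit = np.zeros(n_samp, dtype=bool)
            hit[inside] = mask_arr[rowi[inside], coli[inside]]
            frac = float(hit.mean())
        chords.append(Chord(p0, p1, frac))
    return chords


def rasterize_polygon(
    polygon: ContourPolygon,
    shape: tuple[int, int],
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Pixel-center-in-polygon rasterization onto an image grid."""
    sx, sy = pixel_spacing
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    poly = polygon.as_shapely()
    return shapely.contains_xy(poly, cols * sx, rows * sy)


def myocardium_mask(
    endo: ContourPolygon,
    epi: ContourPolygon,
    shape: tuple[int, int],
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Pixels inside the epicardial but outside the endocardial contour."""
    _require_nested(endo, epi)
    return rasterize_polygon(epi, shape, pixel_spacing) & ~rasterize_polygon(
        endo, shape, pixel_spacing
    )


def split_endo_epi_layers(
    endo: ContourPolygon,
    epi: ContourPolygon,
    shape: tuple[int, int],
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Split the myocardium into endocardial and epicardial half layers.

    A pixel belongs to the endocardial layer when its transmural depth
    (distance to the endocardial boundary over total endo+epi boundary
    distance) is below 50%; the two layers partition the myocardial mask.
    """
    myo = myocardium_mask(endo, epi, shape, pixel_spacing)
    rows, cols = np.nonzero(myo)
    sx, sy = pixel_spacing
    endo_b = endo.as_shapely().exterior
    epi_b = epi.as_shapely().exterior
    pts = shapely.points(np.column_stack([cols * sx, rows * sy]))
    d_endo = shapely.distance(pts, endo_b)
    d_epi = shapely.distance(pts, epi_b)
    depth = d_endo / np.maximum(d_endo + d_epi, 1e-12)
    endo_layer = np.zeros(shape, dtype=bool)
    epi_layer = np.zeros(shape, dtype=bool)
    inner = depth < 0.5
    endo_layer[rows[inner], cols[inner]] = True
    epi_layer[rows[~inner], cols[~inner]] = True
    return endo_layer, epi_layer


def regular_polygon(
    cx: float, cy: float, radius: float, n: int = 128, role: str = "generic"
) -> ContourPolygon:
    """Convenience constructor: regular n-gon approximating a circle."""
    theta = 2.0 * np.pi * np.arange(n) / n
    verts = np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])
    return ContourPolygon(verts, role=role)


def ellipse_polygon(
    cx: float, cy: float, a: float, b: float, n: int = 128, role: str = "generic"
) -> ContourPolygon:
    """Convenience constructor: n-gon approximating an axis-aligned ellipse."""
    theta = 2.0 * np.pi * np.arange(n) / n
    verts = np.column_stack([cx + a * np.cos(theta), cy + b * np.sin(theta)])
    return ContourPolygon(verts, role=role)
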