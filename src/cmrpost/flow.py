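"""Phase-contrast flow quantification.

Velocity-encoded frames over one cardiac cycle are integrated to antegrade
and retrograde volumes; derived parameters follow the standard formulas
(net = antegrade − retrograde, regurgitant fraction = retrograde/antegrade
× 100, cardiac output = net × HR / 1000). Velocities beyond the VENC alias
by wraps of 2·VENC; the dynamic range may be shifted (e.g. −150/+150 to
−100/+200 cm/s) to unwrap them. A stationary-tissue first-order plane fit
or a phantom acquisition corrects background phase offsets, which corrupt
volumes far more than peak velocities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import (
    DomainError,
    GeometryError,
    InvalidWindowError,
    UndefinedRatioError,
    UnreliableFitError,
)
from .geometry import ContourPolygon, StudyMeta, rasterize_polygon

TE_QC_BOUND_MS = 3.5


@dataclass
class VelocityFrameSeries:
    """Velocity (cm/s) and magnitude frames over the cardiac cycle.

    ``rois`` holds one vessel-lumen contour per frame (a single contour is
    broadcast to all frames). ``velocity_window`` defaults to the symmetric
    (−VENC, +VENC) dynamic range; its width is always 2·VENC.
    """

    velocity: np.ndarray  # (n_frames, h, w), cm/s
    pixel_area_mm2: float
    trigger_times_ms: np.ndarray
    rr_ms: float
    venc: float
    rois: list[ContourPolygon]
    magnitude: np.ndarray | None = None
    velocity_window: tuple[float, float] | None = None
    te_ms: float | None = None
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.trigger_times_ms = np.asarray(self.trigger_times_ms, dtype=float)
        n = self.velocity.shape[0]
        if self.trigger_times_ms.shape != (n,):
            raise DomainError("one trigger time per frame required")
        if not np.all(np.diff(self.trigger_times_ms) > 0):
            raise DomainError("trigger times must be strictly increasing")
        if self.pixel_area_mm2 <= 0:
            raise DomainError("pixel area must be positive")
        if self.venc <= 0:
            raise DomainError("VENC must be positive")
        if self.velocity_window is None:
            self.velocity_window = (-self.venc, self.venc)
        lo, hi = self.velocity_window
        if not math.isclose(hi - lo, 2.0 * self.venc, rel_tol=1e-9):
            raise InvalidWindowError("velocity window width must equal 2·VENC")
        if len(self.rois) == 1:
            self.rois = list(self.rois) * n
        if len(self.rois) != n:
            raise DomainError("need one lumen ROI per frame (or a single shared one)")

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    def roi_mask(self, frame: int) -> np.ndarray:
        m = rasterize_polygon(
            self.rois[frame], self.velocity.shape[1:], self.pixel_spacing
        )
        if not m.any():
            raise GeometryError(f"lumen ROI rasterizes to no pixels on frame {frame}")
        return m


@dataclass
class FlowCurve:
    flux_ml_per_s: np.ndarray
    frame_duration_ms: np.ndarray

    def __post_init__(self) -> None:
        self.flux_ml_per_s = np.asarray(self.flux_ml_per_s, dtype=float)
        self.frame_duration_ms = np.asarray(self.frame_duration_ms, dtype=float)
        if self.flux_ml_per_s.shape != self.frame_duration_ms.shape:
            raise DomainError("flux and duration sequences must have equal length")
        if np.any(self.frame_duration_ms <= 0):
            raise DomainError("frame durations must be positive")


@dataclass
class FlowResult:
    antegrade_ml: float
    retrograde_ml: float
    net_ml: float
    regurgitant_fraction_pct: float | None
    cardiac_output_l_min: float | None
    cardiac_index_l_min_m2: float | None
    peak_velocity_cm_s: float | None = None
    peak_mode: str | None = None
    notes: list[str] = field(default_factory=list)


def shift_velocity_window(
    series: VelocityFrameSeries, new_window: tuple[float, float]
) -> VelocityFrameSeries:
    """Re-express every velocity inside a shifted dynamic range.

    Each value v becomes v + 2·VENC·k with the unique integer k placing it
    in [lower, upper); in-window values are untouched, so the operation is
    idempotent for the current window.
    """
    lo, hi = new_window
    if not math.isclose(hi - lo, 2.0 * series.venc, rel_tol=1e-9):
        raise InvalidWindowError(
            f"window width {hi - lo} differs from 2·VENC = {2 * series.venc}"
        )
    span = 2.0 * series.venc
    shifted = lo + np.mod(series.velocity - lo, span)
    return replace(series, velocity=shifted, velocity_window=(lo, hi))


def background_offset_correction(
    series: VelocityFrameSeries,
    method: str = "stationary_fit",
    stationary_mask: np.ndarray | None = None,
    phantom_series: VelocityFrameSeries | None = None,
    min_stationary_pixels: int = 100,
) -> VelocityFrameSeries:
    """Remove background phase offsets.

    ``stationary_fit``: a first-order 2D polynomial (a + b·x + c·y) is
    fitted per frame to the velocities inside a stationary-tissue mask
    (which must exclude the vessel) and subtracted everywhere.
    ``phantom``: the per-pixel temporal mean of a geometrically matched
    static-phantom acquisition is subtracted.
    """
    if method == "stationary_fit":
        if stationary_mask is None:
            raise DomainError("stationary_fit requires a stationary mask")
        mask = np.asarray(stationary_mask, dtype=bool)
        if mask.sum() < min_stationary_pixels:
            raise UnreliableFitError(
                f"stationary mask has {int(mask.sum())} pixels, "
                f"need {min_stationary_pixels}"
            )
        rows, cols = np.nonzero(mask)
        design = np.column_stack([np.ones(rows.size), cols, rows])
        h, w = series.velocity.shape[1:]
        gc, gr = np.meshgrid(np.arange(w), np.arange(h))
        corrected = np.empty_like(series.velocity)
        for i, frame in enumerate(series.velocity):
            coef, *_ = np.linalg.lstsq(design, frame[rows, cols], rcond=None)
            corrected[i] = frame - (coef[0] + coef[1] * gc + coef[2] * gr)
        return replace(series, velocity=corrected)
    if method == "phantom":
        if phantom_series is None:
            raise DomainError("phantom method requires a phantom series")
        if phantom_series.velocity.shape[1:] != series.velocity.shape[1:]:
            raise GeometryError("phantom series is not geometrically matched")
        offset = phantom_series.velocity.mean(axis=0)
        return replace(series, velocity=series.velocity - offset)
    raise DomainError(f"unknown correction method {method!r}")


def _frame_durations(trigger_times_ms: np.ndarray, rr_ms: float) -> np.ndarray:
    d = np.diff(trigger_times_ms)
    last = rr_ms - (trigger_times_ms[-1] - trigger_times_ms[0])
    if last <= 0:
        raise DomainError("trigger times span more than one RR interval")
    return np.append(d, last)


def flow_curve(series: VelocityFrameSeries) -> FlowCurve:
    """Per-frame flux in ml/s: Σ (pixel velocity × pixel area) over the lumen ROI."""
    flux = np.empty(series.n_frames)
    for i in range(series.n_frames):
        mask = series.roi_mask(i)
        # cm/s × mm² = 10 mm³/s; /1000 → ml/s
        flux[i] = float(series.velocity[i][mask].sum()) * series.pixel_area_mm2 * 0.01
    return FlowCurve(flux, _frame_durations(series.trigger_times_ms, series.rr_ms))


def _signed_volumes(curve: FlowCurve) -> tuple[float, float]:
    """Antegrade and retrograde volume (ml) by trapezoidal integration.

    Treats flux as piecewise linear between frame nodes; the last interval
    closes the RR cycle back to the first node. Sign crossings within an
    interval are split exactly, so net = antegrade − retrograde always.
    """
    f = curve.flux_ml_per_s
    dt = curve.frame_duration_ms / 1000.0
    ante = retro = 0.0
    n = f.size
    for i in range(n):
        f0, f1 = f[i], f[(i + 1) % n]
        h = dt[i]
        if f0 >= 0 and f1 >= 0:
            ante += 0.5 * (f0 + f1) * h
        elif f0 <= 0 and f1 <= 0:
            retro += -0.5 * (f0 + f1) * h
        else:
            t_cross = h * abs(f0) / (abs(f0) + abs(f1))
            a0 = 0.5 * f0 * t_cross
            a1 = 0.5 * f1 * (h - t_cross)
            ante += max(a0, 0.0) + max(a1, 0.0)
            retro += -min(a0, 0.0) - min(a1, 0.0)
    return ante, retro


def flow_volumes_and_derived(
    curve: FlowCurve,
    meta: StudyMeta | None = None,
    require_rf: bool = True,
) -> FlowResult:
    """Directly calculated and derived flow parameters for one vessel."""
    ante, retro = _signed_volumes(curve)
    net = ante - retro
    rf: float | None
    if ante > 0:
        rf = 100.0 * retro / ante
    elif require_rf:
        raise UndefinedRatioError("regurgitant fraction undefined: antegrade volume is 0")
    else:
        rf = None
    co = ci = None
    if meta is not None and meta.heart_rate is not None:
        co = net * meta.heart_rate / 1000.0
        if meta.body_surface_area is not None:
            ci = co / meta.body_surface_area
    return FlowResult(ante, retro, net, rf, co, ci)


def lung_flow_split(rpa_net_ml: float, lpa_net_ml: float) -> tuple[float, float]:
    """Percent of pulmonary flow to the right and left lungs."""
    total = rpa_net_ml + lpa_net_ml
    if total <= 0:
        raise UndefinedRatioError("total pulmonary flow must be positive")
    right = 100.0 * rpa_net_ml / total
    return right, 100.0 - right


def av_regurgitant_volume(
    method: str,
    semilunar_forward_ml: float,
    diastolic_inflow_ml: float | None = None,
    cine_stroke_volume_ml: float | None = None,
) -> float:
    """Atrioventricular-valve regurgitant volume.

    Method "direct" (A): diastolic inflow across the AV valve minus the
    systolic forward volume across the associated semilunar valve.
    Method "cine" (B): cine stroke volume minus the semilunar forward volume.
    """
    if method == "direct":
        if diastolic_inflow_ml is None:
            raise DomainError("direct method needs the diastolic AV inflow volume")
        return diastolic_inflow_ml - semilunar_forward_ml
    if method == "cine":
        if cine_stroke_volume_ml is None:
            raise DomainError("cine method needs the cine stroke volume")
        return cine_stroke_volume_ml - semilunar_forward_ml
    raise DomainError(f"unknown AV regurgitation method {method!r}")


def peak_velocity(
    series: VelocityFrameSeries,
    mode: str = "single_pixel",
    neighborhood: int = 3,
) -> tuple[float, int]:
    """Peak velocity magnitude over the ROI and the frame achieving it.

    ``single_pixel`` takes the largest |velocity| of any ROI pixel;
    ``neighborhood_mean`` averages an n×n block around each ROI pixel
    (blocks clipped to the ROI) before taking the maximum, trading noise
    robustness against underestimating the true peak. The mode must be
    carried into the report.
    """
    if mode not in {"single_pixel", "neighborhood_mean"}:
        raise DomainError(f"unknown peak-velocity mode {mode!r}")
    best, best_frame = -np.inf, 0
    for i in range(series.n_frames):
        mask = series.roi_mask(i)
        v = series.velocity[i]
        if mode == "single_pixel":
            val = float(np.abs(v[mask]).max())
        else:
            m = mask.astype(float)
            num = ndimage.uniform_filter(v * m, size=neighborhood, mode="constant")
            den = ndimage.uniform_filter(m, size=neighborhood, mode="constant")
            with np.errstate(invalid="ignore", divide="ignore"):
                block = np.where(den > 0, num / den, 0.0)
            val = float(np.abs(block[mask]).max())
        if val > best:
            best, best_frame = val, i
    return best, best_frame


@dataclass
class QCReport:
    te_exceeds_bound: bool
    aliasing_suspected: bool
    poor_velocity_contrast: bool
    flags: list[str]
    details: dict[str, float]


def qc_checks(
    series: VelocityFrameSeries,
    edge_fraction: float = 0.02,
    min_edge_pixels: int = 3,
    contrast_fraction: float = 0.40,
) -> QCReport:
    """Quality checks: TE bound, residual aliasing, and poor velocity contrast.

    Aliasing is suspected when at least ``min_edge_pixels`` ROI pixels sit
    within ``edge_fraction`` of the dynamic range of a window edge in any
    frame (edge pixels at the lumen rim are usually, but not always,
    outside the vessel and are down-weighted by requiring several pixels).
    A peak velocity below ``contrast_fraction`` of the VENC flags poor
    velocity-to-noise contrast (VENC set far too high).
    """
    flags: list[str] = []
    details: dict[str, float] = {}
    te_bad = series.te_ms is not None and series.te_ms > TE_QC_BOUND_MS
    if te_bad:
        flags.append(f"TE {series.te_ms} ms exceeds the {TE_QC_BOUND_MS} ms bound")
    lo, hi = series.velocity_window
    tol = edge_fraction * 2.0 * series.venc
    n_edge = 0
    for i in range(series.n_frames):
        v = series.velocity[i][series.roi_mask(i)]
        n_edge = max(n_edge, int(np.sum((v - lo <= tol) | (hi - v <= tol))))
    aliasing = n_edge >= min_edge_pixels
    if aliasing:
        flags.append(f"aliasing suspected: {n_edge} ROI pixels at the window edge")
    details["max_edge_pixels"] = float(n_edge)
    peak, _ = peak_velocity(series, "single_pixel")
    details["peak_velocity_cm_s"] = peak
    poor = peak < contrast_fraction * series.venc
    if poor:
        flags.append(
            f"peak velocity {peak:.1f} cm/s is below "
            f"{100 * contrast_fraction:.0f}% of VENC {series.venc:.0f} cm/s"
        )
    return QCReport(te_bad, aliasing, poor, flags, details)
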