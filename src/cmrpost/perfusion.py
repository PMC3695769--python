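"""Semi-quantitative first-pass perfusion analysis.

Signal-intensity–time curves are extracted per AHA segment (plus the LV
blood pool), summarized by maximal upslope, time to peak, and upslope
integral, and combined across stress and rest into the myocardial
perfusion reserve index (MPRI: the stress/rest ratio of blood-pool
normalized upslopes). A rule-based classifier separates true inducible
perfusion defects from subendocardial dark-banding artifacts using the
standard visual criteria: a defect begins when contrast arrives in the
myocardium, persists more than four RR intervals beyond peak enhancement,
is wider than one pixel, never drops below baseline signal, and is present
at stress only; dark banding begins at blood-pool contrast arrival, lasts
under about six RR intervals, is about one pixel wide, dips below
baseline, and runs along the phase-encoding direction. Stress-only dark
banding is, on its own, never called a defect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError, GeometryError, NoContrastArrivalError, UndefinedRatioError
from .geometry import (
    AHAModel,
    ContourPolygon,
    assign_pixels_to_segments,
    myocardium_mask,
    rasterize_polygon,
    split_endo_epi_layers,
    transmural_chords,
)

LABELS = ("normal", "inducible_defect", "dark_banding_artifact", "indeterminate")


@dataclass
class SICurve:
    """Mean signal intensity of one ROI across the dynamic frames."""

    roi_id: object
    frame_times_ms: np.ndarray
    si: np.ndarray
    n_baseline_frames: int = 3
    flagged: bool = False  # e.g. segment empty after exclusions

    def __post_init__(self) -> None:
        self.frame_times_ms = np.asarray(self.frame_times_ms, dtype=float)
        self.si = np.asarray(self.si, dtype=float)
        if self.frame_times_ms.shape != self.si.shape:
            raise DomainError("frame_times and si must have equal length")
        if not np.all(np.diff(self.frame_times_ms) > 0):
            raise DomainError("frame times must be strictly increasing")
        if self.n_baseline_frames < 1:
            raise DomainError("need at least one baseline frame")


@dataclass(frozen=True)
class PerfusionFeatures:
    baseline_si: float
    arrival_frame: int
    peak_frame: int
    max_upslope: float  # SI per frame
    max_upslope_per_s: float
    normalized_upslope: float | None
    time_to_peak_frames: int
    time_to_peak_s: float
    upslope_integral: float  # SI · frame


def extract_si_curves(
    frames: np.ndarray,
    endo: ContourPolygon,
    epi: ContourPolygon,
    blood_roi: ContourPolygon,
    model: AHAModel,
    slice_index: int = 0,
    frame_times_ms: np.ndarray | None = None,
    n_baseline_frames: int = 3,
    layers: str = "none",
    exclude: list[ContourPolygon] | None = None,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> dict[object, SICurve]:
    """Per-segment (and optionally per-layer) mean SI curves plus the blood pool.

    Contours are assumed propagated/registered across frames upstream.
    Papillary or fat polygons in ``exclude`` are removed from the
    myocardial ROIs. A segment left empty after exclusions yields a
    flagged all-NaN curve rather than disappearing silently.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise GeometryError("frames must be a (n_frames, h, w) array")
    n = frames.shape[0]
    times = (
        np.arange(n, dtype=float) if frame_times_ms is None else np.asarray(frame_times_ms)
    )
    shape = frames.shape[1:]
    myo = myocardium_mask(endo, epi, shape, pixel_spacing)
    for poly in exclude or []:
        myo &= ~rasterize_polygon(poly, shape, pixel_spacing)
    seg_map = assign_pixels_to_segments(myo, model, slice_index, pixel_spacing)

    if layers == "endo_epi":
        endo_layer, _ = split_endo_epi_layers(endo, epi, shape, pixel_spacing)
    elif layers != "none":
        raise DomainError(f"unknown layer mode {layers!r}")

    flat = frames.reshape(n, -1)
    out: dict[object, SICurve] = {}
    ring = model.ring_of_slice[slice_index]
    for seg in model.segments_in_ring(ring):
        if layers == "none":
            rois = {seg: seg_map == seg}
        else:
            rois = {
                (seg, "endo"): (seg_map == seg) & endo_layer,
                (seg, "epi"): (seg_map == seg) & ~endo_layer,
            }
        for key, mask in rois.items():
            idx = np.flatnonzero(mask.ravel())
            if idx.size == 0:
                out[key] = SICurve(key, times, np.full(n, np.nan), n_baseline_frames, True)
            else:
                out[key] = SICurve(key, times, flat[:, idx].mean(axis=1), n_baseline_frames)

    blood = rasterize_polygon(blood_roi, shape, pixel_spacing)
    if not blood.any():
        raise GeometryError("blood-pool ROI rasterizes to no pixels")
    bidx = np.flatnonzero(blood.ravel())
    out["lv_blood_pool"] = SICurve(
        "lv_blood_pool", times, flat[:, bidx].mean(axis=1), n_baseline_frames
    )
    return out


def _baseline_stats(curve: SICurve) -> tuple[float, float]:
    b = curve.si[: curve.n_baseline_frames]
    return float(b.mean()), float(b.std(ddof=0))


def _arrival_frame(curve: SICurve) -> int:
    # contrast arrival: first frame above baseline + 2·SD(baseline) that stays
    # above it on the following frame too (single noise crossings are ignored)
    base, sd = _baseline_stats(curve)
    thresh = base + 2.0 * sd
    above = curve.si[curve.n_baseline_frames :] > thresh + 1e-12
    sustained = above.copy()
    sustained[:-1] &= above[1:]
    later = np.flatnonzero(sustained)
    if later.size == 0:
        raise NoContrastArrivalError(f"no contrast arrival in ROI {curve.roi_id!r}")
    return int(later[0]) + curve.n_baseline_frames


def curve_features(
    curve: SICurve,
    blood: SICurve | None = None,
    upslope_window: int = 5,
) -> PerfusionFeatures:
    """Curve summary: baseline, arrival, maximal upslope, time to peak, integral.

    The maximal upslope is the steepest least-squares line over any
    ``upslope_window`` consecutive frames of the first pass, searched
    exhaustively from the last pre-contrast frame (arrival − 1) to the
    peak; the window shrinks when that span is shorter. The upslope
    integral is the trapezoidal area under SI − baseline from arrival to
    peak.
    """
    if upslope_window < 3:
        raise DomainError("upslope window must be at least 3 frames")
    base, _sd = _baseline_stats(curve)
    arrival = _arrival_frame(curve)
    peak = arrival + int(np.argmax(curve.si[arrival:]))

    # windows may start at the last pre-contrast frame: the rise begins
    # between arrival-1 and arrival, and anchoring there keeps the estimate
    # insensitive to one-frame jitter in arrival detection
    lo, hi = max(arrival - 1, 0), peak
    w = min(upslope_window, hi - lo + 1)
    best = -np.inf
    best_per_s = -np.inf
    for start in range(lo, hi - w + 2):
        seg = slice(start, start + w)
        frames_idx = np.arange(start, start + w, dtype=float)
        slope = np.polyfit(frames_idx, curve.si[seg], 1)[0]
        slope_s = np.polyfit(curve.frame_times_ms[seg] / 1000.0, curve.si[seg], 1)[0]
        if slope > best:
            best, best_per_s = float(slope), float(slope_s)

    normalized = None
    if blood is not None:
        bfeat = curve_features(blood, None, upslope_window)
        if bfeat.max_upslope <= 0:
            raise UndefinedRatioError("blood-pool upslope is not positive")
        normalized = best / bfeat.max_upslope

    rel = curve.si[arrival : peak + 1] - base
    integral = float(np.trapezoid(rel)) if rel.size > 1 else 0.0
    ttp_s = float(curve.frame_times_ms[peak] - curve.frame_times_ms[arrival]) / 1000.0
    return PerfusionFeatures(
        baseline_si=base,
        arrival_frame=arrival,
        peak_frame=peak,
        max_upslope=best,
        max_upslope_per_s=best_per_s,
        normalized_upslope=normalized,
        time_to_peak_frames=peak - arrival,
        time_to_peak_s=ttp_s,
        upslope_integral=integral,
    )


def mpri(stress: PerfusionFeatures, rest: PerfusionFeatures) -> float:
    """Myocardial perfusion reserve index: stress/rest normalized upslopes."""
    if stress.normalized_upslope is None or rest.normalized_upslope is None:
        raise DomainError("MPRI needs blood-pool normalized upslopes")
    if rest.normalized_upslope <= 0:
        raise UndefinedRatioError("rest normalized upslope must be positive")
    return stress.normalized_upslope / rest.normalized_upslope


@dataclass(frozen=True)
class PerfusionRuleConfig:
    """Thresholds of the defect/artifact decision rule (all configurable)."""

    hypo_factor: float = 0.75  # peak enhancement below this × reference = hypoenhanced
    deficit_fraction: float = 0.05  # deficit detection level, fraction of reference peak
    defect_min_persistence_rr: float = 4.0  # strict >
    artifact_max_duration_rr: float = 6.0  # strict <
    width_defect_min_px: float = 1.0  # strict >
    width_artifact_max_px: float = 1.5  # "approximately one pixel"
    onset_tolerance_frames: int = 2
    frames_per_rr: float = 1.0


@dataclass
class PerfusionFinding:
    segment_id: int
    label: str
    criteria: dict[str, bool] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class _Evidence:
    hypoenhanced: bool
    dip_below_baseline: bool
    onset_frame: int | None
    dip_start: int | None
    dip_run_frames: int
    persistence_after_peak_frames: int


def _reference_curve(curves: Mapping[object, SICurve]) -> SICurve:
    stacked = np.vstack([c.si for c in curves.values() if not c.flagged])
    first = next(iter(curves.values()))
    return SICurve(
        "reference", first.frame_times_ms, np.median(stacked, axis=0),
        first.n_baseline_frames,
    )


def _segment_evidence(
    curve: SICurve, reference: SICurve, cfg: PerfusionRuleConfig
) -> _Evidence:
    base, sd = _baseline_stats(curve)
    ref_base, _ = _baseline_stats(reference)
    rel = curve.si - base
    ref_rel = reference.si - ref_base
    ref_peak_val = float(ref_rel.max())
    ref_peak_frame = int(np.argmax(ref_rel))

    hypo = float(rel.max()) < cfg.hypo_factor * ref_peak_val

    dip_tol = max(3.0 * sd, 1e-6 * max(base, 1.0))
    dip_frames = np.flatnonzero(rel < -dip_tol)
    dip_start = int(dip_frames[0]) if dip_frames.size else None
    dip_run = 0
    if dip_frames.size:
        runs = np.split(dip_frames, np.flatnonzero(np.diff(dip_frames) > 1) + 1)
        dip_run = max(len(r) for r in runs)

    deficit = ref_rel - rel
    tol = max(3.0 * sd, cfg.deficit_fraction * ref_peak_val)
    deficit_frames = np.flatnonzero(deficit > tol)
    onset = int(deficit_frames[0]) if deficit_frames.size else None
    persistence = int(np.sum(deficit[ref_peak_frame + 1 :] > tol))

    return _Evidence(hypo, dip_start is not None, onset, dip_start, dip_run, persistence)


def classify_segment_finding(
    stress: Mapping[int, SICurve],
    rest: Mapping[int, SICurve],
    stress_blood: SICurve,
    rest_blood: SICurve,
    widths_px: Mapping[int, float],
    phase_encode_aligned: Mapping[int, bool] | None = None,
    lge_present: Mapping[int, bool] | None = None,
    config: PerfusionRuleConfig | None = None,
) -> dict[int, PerfusionFinding]:
    """Label every segment normal / inducible_defect / dark_banding_artifact.

    ``widths_px`` carries the measured transmural width of the
    hypoenhanced band per segment (see
    :func:`hypoenhancement_width_px`); ``phase_encode_aligned`` whether
    that band runs along the phase-encoding direction. Each finding
    carries its full boolean criteria vector for audit. Segments matching
    neither rule but showing a deficit are ``indeterminate``; a deficit
    present at both stress and rest over known scar (LGE) is reported as
    normal for ischemia with a scar-match note.
    """
    cfg = config or PerfusionRuleConfig()
    pe = phase_encode_aligned or {}
    scar = lge_present or {}
    ref_stress = _reference_curve(stress)
    ref_rest = _reference_curve(rest)
    myo_arrival = _arrival_frame(ref_stress)
    blood_arrival = _arrival_frame(stress_blood)

    out: dict[int, PerfusionFinding] = {}
    for seg in sorted(stress):
        s_curve = stress[seg]
        r_curve = rest.get(seg)
        if s_curve.flagged or r_curve is None or r_curve.flagged:
            out[seg] = PerfusionFinding(
                seg, "indeterminate", {"empty_roi": True},
                ["segment empty after exclusions"],
            )
            continue
        ev_s = _segment_evidence(s_curve, ref_stress, cfg)
        ev_r = _segment_evidence(r_curve, ref_rest, cfg)
        width = float(widths_px.get(seg, 0.0))

        criteria = {
            "hypoenhanced_at_stress": ev_s.hypoenhanced,
            "hypoenhanced_at_rest": ev_r.hypoenhanced,
            "onset_at_myocardial_arrival": (
                ev_s.onset_frame is not None
                and abs(ev_s.onset_frame - myo_arrival) <= cfg.onset_tolerance_frames
            ),
            "persists_gt_4rr_beyond_peak": (
                ev_s.persistence_after_peak_frames / cfg.frames_per_rr
                > cfg.defect_min_persistence_rr
            ),
            "width_gt_1px": width > cfg.width_defect_min_px,
            "no_signal_drop_below_baseline": not ev_s.dip_below_baseline,
            "stress_only": ev_s.hypoenhanced and not ev_r.hypoenhanced,
            "onset_at_blood_pool_arrival": (
                ev_s.dip_start is not None
                and ev_s.dip_start <= myo_arrival
                and abs(ev_s.dip_start - blood_arrival) <= cfg.onset_tolerance_frames
            ),
            "duration_lt_6rr": (
                ev_s.dip_run_frames > 0
                and ev_s.dip_run_frames / cfg.frames_per_rr < cfg.artifact_max_duration_rr
            ),
            "width_about_1px": 0.0 < width <= cfg.width_artifact_max_px,
            "signal_drop_below_baseline": ev_s.dip_below_baseline,
            "phase_encode_aligned": bool(pe.get(seg, False)),
        }

        defect = all(
            criteria[k]
            for k in (
                "hypoenhanced_at_stress",
                "onset_at_myocardial_arrival",
                "persists_gt_4rr_beyond_peak",
                "width_gt_1px",
                "no_signal_drop_below_baseline",
                "stress_only",
            )
        )
        artifact = all(
            criteria[k]
            for k in (
                "onset_at_blood_pool_arrival",
                "duration_lt_6rr",
                "width_about_1px",
                "signal_drop_below_baseline",
                "phase_encode_aligned",
            )
        )
        notes: list[str] = []
        if defect:
            label = "inducible_defect"
        elif artifact:
            label = "dark_banding_artifact"
        elif not ev_s.hypoenhanced and not ev_s.dip_below_baseline:
            label = "normal"
        elif ev_s.hypoenhanced and ev_r.hypoenhanced and scar.get(seg, False):
            label = "normal"
            notes.append(
                "matched stress/rest deficit over scar; extent relative to LGE "
                "should be reported from the LGE images"
            )
        else:
            label = "indeterminate"
        out[seg] = PerfusionFinding(seg, label, criteria, notes)
    return out


def hypoenhancement_width_px(
    image: np.ndarray,
    endo: ContourPolygon,
    epi: ContourPolygon,
    model: AHAModel,
    slice_index: int = 0,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
    threshold_factor: float = 0.75,
    n_chords: int = 100,
    reference_image: np.ndarray | None = None,
) -> dict[int, float]:
    """Transmural width (pixels) of the hypoenhanced band per segment.

    On the supplied frame (typically peak enhancement for defects, the dip
    frame for suspected dark banding) each transmural chord is sampled and
    the longest contiguous run of samples below ``threshold_factor`` × the
    myocardial median (of ``reference_image`` when given, e.g. the
    baseline for below-baseline banding) is converted to pixels; a
    segment's width is the maximum over its chords.
    """
    image = np.asarray(image, dtype=float)
    shape = image.shape
    myo = myocardium_mask(endo, epi, shape, pixel_spacing)
    ref = image if reference_image is None else np.asarray(reference_image, dtype=float)
    threshold = threshold_factor * float(np.median(ref[myo]))
    below = myo & (image < threshold)
    chords = transmural_chords(endo, epi, below, n_chords, pixel_spacing)

    px = min(pixel_spacing)
    widths: dict[int, list[float]] = {}
    for k, chord in enumerate(chords):
        seg = _segment_of_chord(k, n_chords, model, slice_index)
        if seg is None:
            continue
        run = _max_run_mm(chord, below, pixel_spacing)
        widths.setdefault(seg, []).append(run / px)
    return {seg: max(v) for seg, v in sorted(widths.items())}


def _segment_of_chord(k: int, n_chords: int, model: AHAModel, slice_index: int) -> int | None:
    ring = model.ring_of_slice.get(slice_index)
    if ring is None:
        return None
    if ring == "apical_cap":
        return 17
    angle = (360.0 * k / n_chords - model.rv_insertion_angle[slice_index]) % 360.0
    for seg in model.segments_in_ring(ring):
        lo, hi = model.segment_spans[seg][1]
        if lo <= angle < hi:
            return seg
    return None


def _max_run_mm(
    chord, mask: np.ndarray, pixel_spacing: tuple[float, float]
) -> float:
    sx, sy = pixel_spacing
    length = chord.length
    step = min(sx, sy) / 4.0
    n = max(int(np.ceil(length / step)), 8)
    t = (np.arange(n) + 0.5) / n
    xs = chord.endo_point.x + t * (chord.epi_point.x - chord.endo_point.x)
    ys = chord.endo_point.y + t * (chord.epi_point.y - chord.endo_point.y)
    rowi = np.rint(ys / sy).astype(int)
    coli = np.rint(xs / sx).astype(int)
    ok = (rowi >= 0) & (rowi < mask.shape[0]) & (coli >= 0) & (coli < mask.shape[1])
    hits = np.zeros(n, dtype=bool)
    hits[ok] = mask[rowi[ok], coli[ok]]
    best = cur = 0
    for h in hits:
        cur = cur + 1 if h else 0
        best = max(best, cur)
    return best * (length / n)
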