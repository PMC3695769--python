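"""Synthetic phantoms with analytic ground truth.

Every analysis module's inputs can be generated here with known truth, so
the whole package is testable without any acquisition data. Truth values
are computed from closed forms (ellipsoid volumes, gamma-variate curves,
mono-exponential decay, analytic flow profiles) and never by calling the
analysis code under test. Magnitude images carry Rician noise, velocity
maps Gaussian noise; regeneration from the same (scenario, seed) is
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .flow import VelocityFrameSeries
from .geometry import (
    AHAModel,
    ContourPolygon,
    ContourStack,
    SliceGeometry,
    StudyMeta,
    ellipse_polygon,
    regular_polygon,
    standard_segment_spans,
)
from .t2star import DecayCurve
from .volumetry import MYOCARDIUM_DENSITY_G_PER_ML


@dataclass
class PhantomTruth:
    """Analytic ground truth of a generated scenario."""

    scenario: str
    seed: int | None
    data: dict = field(default_factory=dict)


def _ellipsoid_ml(a: float, b: float, c: float) -> float:
    return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


def ellipsoid_ventricle_stack(
    ed_semi_axes: tuple[float, float, float] = (25.0, 25.0, 45.0),
    es_semi_axes: tuple[float, float, float] | None = (19.0, 19.0, 45.0),
    wall_thickness: float = 8.0,
    thickness: float = 8.0,
    gap: float = 2.0,
    n_phases: int = 20,
    papillary_area_mm2: float = 0.0,
    heart_rate: float = 70.0,
    body_surface_area: float = 1.9,
    center_mm: tuple[float, float] = (60.0, 60.0),
    n_vertices: int = 128,
) -> tuple[ContourStack, PhantomTruth]:
    """Short-axis contour stack of an ellipsoidal ventricle over a cycle.

    The endocardium is an ellipsoid with the given semi-axes (in-plane a,
    b and long-axis c); the epicardium adds a constant wall to each axis.
    The in-plane axes contract from ED to ES along a cosine volume curve
    (ED at phase 0, ES mid-cycle); the long axis is held so every phase
    covers the same slices. Slices sample the endocardial long axis at
    midpoints of steps of (thickness + gap), slice 0 most basal.
    """
    if wall_thickness <= 0:
        raise DomainError("wall thickness must be positive")
    a_ed, b_ed, c_ed = ed_semi_axes
    if es_semi_axes is None:
        es_semi_axes = ed_semi_axes
        n_phases = max(n_phases, 1)
    a_es, b_es, c_es = es_semi_axes
    if a_es > a_ed or b_es > b_ed or c_es > c_ed:
        raise DomainError("ES semi-axes must not exceed ED semi-axes")
    if c_es != c_ed:
        raise DomainError("the long axis is held fixed across phases")
    step = thickness + gap
    n_slices = int(math.floor(2.0 * c_ed / step))
    if n_slices < 1:
        raise DomainError("slice step exceeds the ventricle's long axis")
    # slice 0 most basal (largest z)
    z_centers = c_ed - (np.arange(n_slices) + 0.5) * step
    cx, cy = center_mm

    slices = [
        SliceGeometry(k, float(z_centers[k]), thickness, gap) for k in range(n_slices)
    ]
    contours: dict = {}
    es_phase = n_phases // 2 if n_phases > 1 else 0
    volume_curve = []
    for p in range(n_phases):
        w = 0.5 * (1.0 + math.cos(2.0 * math.pi * p / n_phases)) if n_phases > 1 else 1.0
        a = a_es + (a_ed - a_es) * w
        b = b_es + (b_ed - b_es) * w
        volume_curve.append(_ellipsoid_ml(a, b, c_ed))
        for k, z in enumerate(z_centers):
            f_endo = 1.0 - (z / c_ed) ** 2
            if f_endo > 0:
                fe = math.sqrt(f_endo)
                contours[(k, p, "endocardial")] = [
                    ellipse_polygon(cx, cy, a * fe, b * fe, n_vertices, "endocardial")
                ]
            c_epi = c_ed + wall_thickness
            f_epi = 1.0 - (z / c_epi) ** 2
            if f_epi > 0:
                fp = math.sqrt(f_epi)
                contours[(k, p, "epicardial")] = [
                    ellipse_polygon(
                        cx, cy, (a + wall_thickness) * fp, (b + wall_thickness) * fp,
                        n_vertices, "epicardial",
                    )
                ]
            if papillary_area_mm2 > 0 and f_endo > 0:
                r_pap = math.sqrt(papillary_area_mm2 / math.pi)
                if min(a, b) * math.sqrt(f_endo) > 2.0 * r_pap + 2.0:
                    contours[(k, p, "papillary")] = [
                        regular_polygon(cx, cy, r_pap, 64, "papillary")
                    ]

    stack = ContourStack(
        slices=slices,
        contours=contours,
        n_phases=n_phases,
        meta=StudyMeta(heart_rate=heart_rate, body_surface_area=body_surface_area),
    )
    edv = _ellipsoid_ml(a_ed, b_ed, c_ed)
    esv = _ellipsoid_ml(a_es, b_es, c_ed)
    myo_ml = _ellipsoid_ml(
        a_ed + wall_thickness, b_ed + wall_thickness, c_ed + wall_thickness
    ) - edv
    truth = PhantomTruth(
        "ellipsoid_ventricle",
        None,
        {
            "edv_ml": edv,
            "esv_ml": esv,
            "sv_ml": edv - esv,
            "ef_pct": 100.0 * (edv - esv) / edv,
            "ed_phase": 0,
            "es_phase": es_phase,
            "myocardial_volume_ml": myo_ml,
            "mass_g": myo_ml * MYOCARDIUM_DENSITY_G_PER_ML,
            "volume_curve_ml": volume_curve,
            "slice_step_mm": step,
        },
    )
    return stack, truth


def _single_slice_model(rv_insertion_deg: float = 90.0, ring: str = "basal") -> AHAModel:
    return AHAModel(
        n_segments=16,
        ring_of_slice={0: ring},
        rv_insertion_angle={0: rv_insertion_deg},
        segment_spans=standard_segment_spans(16),
    )


def _gamma_variate(t: np.ndarray, t0: float, tp: float, alpha: float) -> np.ndarray:
    """Normalized first-pass bolus shape: peak 1.0 at t0 + tp."""
    x = np.clip((t - t0) / tp, 0.0, None)
    with np.errstate(invalid="ignore"):
        g = x**alpha * np.exp(alpha * (1.0 - x))
    return np.where(x > 0, g, 0.0)


@dataclass
class PerfusionPhantom:
    frames_stress: np.ndarray
    frames_rest: np.ndarray
    frame_times_ms: np.ndarray
    endo: ContourPolygon
    epi: ContourPolygon
    blood_roi: ContourPolygon
    model: AHAModel
    n_baseline_frames: int
    rr_ms: float
    pixel_spacing: tuple[float, float]
    truth: PhantomTruth


def perfusion_curve_set(
    defect_segments: tuple[int, ...] = (4, 5),
    defect_amplitude_factor: float = 0.4,
    defect_width_px: int = 3,
    artifact_segments: tuple[int, ...] = (2,),
    artifact_width_px: int = 1,
    artifact_duration_frames: int = 4,
    artifact_depth: float = 30.0,
    stress_rest_flow_ratio: float = 2.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (80, 80),
    center: tuple[float, float] = (40.0, 40.0),
    endo_radius: float = 15.0,
    epi_radius: float = 25.0,
    blood_radius: float = 11.0,
    n_frames: int = 50,
    rr_ms: float = 800.0,
    baseline_si: float = 100.0,
    n_baseline_frames: int = 4,
    blood_amplitude: float = 400.0,
    myo_amplitude: float = 120.0,
    blood_arrival_frame: float = 6.0,
    myo_delay_frames: float = 4.0,
    blood_peak_delay: float = 5.0,
    myo_peak_delay: float = 8.0,
    gamma_alpha: float = 3.0,
) -> PerfusionPhantom:
    """Dynamic stress/rest first-pass series on a single mid-cavity slice.

    Pixelwise SI is built from gamma-variate curves: the blood pool leads,
    the myocardium follows after ``myo_delay_frames``. Inducible defects
    are subendocardial bands (``defect_width_px`` deep, stress only) with
    a reduced myocardial amplitude; dark-banding artifacts are
    ``artifact_width_px``-deep subendocardial bands dropping transiently
    *below* baseline for ``artifact_duration_frames`` starting at
    blood-pool arrival, aligned with the phase-encoding direction. Rest
    myocardial amplitude is stress divided by ``stress_rest_flow_ratio``,
    so the generating MPRI equals that ratio. Truth labels per segment
    are recorded in the manifest.
    """
    rng = np.random.default_rng(seed)
    cx, cy = center
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    r = np.hypot(cols - cx, rows - cy)
    myo = (r >= endo_radius) & (r < epi_radius)
    blood = r < blood_radius
    depth_px = r - endo_radius  # transmural depth of a myocardial pixel

    model = _single_slice_model()
    ang = (np.degrees(np.arctan2(rows - cy, cols - cx)) - model.rv_insertion_angle[0]) % 360.0
    seg_of = np.zeros(shape, dtype=int)
    for seg in model.segments_in_ring("basal"):
        lo, hi = model.segment_spans[seg][1]
        seg_of[(ang >= lo) & (ang < hi)] = seg
    seg_of[~myo] = 0

    t = np.arange(n_frames, dtype=float)
    t0_b = blood_arrival_frame
    t0_m = blood_arrival_frame + myo_delay_frames
    g_blood = _gamma_variate(t, t0_b, blood_peak_delay, gamma_alpha)
    g_myo = _gamma_variate(t, t0_m, myo_peak_delay, gamma_alpha)

    def build(condition: str) -> np.ndarray:
        amp = myo_amplitude if condition == "stress" else myo_amplitude / stress_rest_flow_ratio
        frames = np.full((n_frames, h, w), baseline_si, dtype=float)
        frames[:, blood] = baseline_si + blood_amplitude * g_blood[:, None]
        amp_map = np.where(myo, amp, 0.0)
        if condition == "stress":
            for seg in defect_segments:
                band = (seg_of == seg) & (depth_px < defect_width_px)
                amp_map[band] *= defect_amplitude_factor
        frames[:, myo] = baseline_si + amp_map[myo][None, :] * g_myo[:, None]
        if condition == "stress":
            dip = np.zeros(n_frames)
            w0 = int(round(t0_b))
            dip[w0 : w0 + artifact_duration_frames] = artifact_depth
            for seg in artifact_segments:
                band = (seg_of == seg) & (depth_px < artifact_width_px)
                frames[:, band] -= dip[:, None]
        if noise_sd > 0:
            frames = frames + rng.normal(0.0, noise_sd, frames.shape)
        return frames

    frames_stress = build("stress")
    frames_rest = build("rest")

    labels = {}
    for seg in model.segments_in_ring("basal"):
        if seg in defect_segments:
            labels[seg] = "inducible_defect"
        elif seg in artifact_segments:
            labels[seg] = "dark_banding_artifact"
        else:
            labels[seg] = "normal"

    truth = PhantomTruth(
        "perfusion_curve_set",
        seed,
        {
            "labels": labels,
            "mpri": stress_rest_flow_ratio,
            "defect_segments": list(defect_segments),
            "artifact_segments": list(artifact_segments),
            "defect_width_px": defect_width_px,
            "artifact_width_px": artifact_width_px,
            "phase_encode_aligned": {
                seg: seg in artifact_segments for seg in model.segments_in_ring("basal")
            },
            "myo_arrival_frame": t0_m,
            "blood_arrival_frame": t0_b,
            "ref_peak_frame": float(t0_m + myo_peak_delay),
            "time_to_peak_frames": myo_peak_delay,
        },
    )
    return PerfusionPhantom(
        frames_stress,
        frames_rest,
        t * rr_ms,
        regular_polygon(cx, cy, endo_radius, 128, "endocardial"),
        regular_polygon(cx, cy, epi_radius, 128, "epicardial"),
        regular_polygon(cx, cy, blood_radius - 2.0, 128, "blood_pool_roi"),
        model,
        n_baseline_frames,
        rr_ms,
        (1.0, 1.0),
        truth,
    )


@dataclass
class LGEPhantom:
    image: np.ndarray
    myo_mask: np.ndarray
    lesion_mask: np.ndarray  # includes the no-reflow core
    core_mask: np.ndarray
    endo: ContourPolygon
    epi: ContourPolygon
    remote_roi: ContourPolygon
    core_roi: ContourPolygon
    truth: PhantomTruth


def lge_phantom_image(
    transmural_fraction: float = 0.4,
    lesion_angle_deg: tuple[float, float] = (0.0, 90.0),
    remote_mean: float = 100.0,
    remote_sd: float = 0.0,
    lesion_si: float = 400.0,
    n_core_pixels: int = 0,
    core_si: float = 60.0,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    center: tuple[float, float] = (48.0, 48.0),
    endo_radius: float = 16.0,
    epi_radius: float = 28.0,
) -> LGEPhantom:
    """Annular myocardium with a bright lesion of known transmural fraction.

    The lesion occupies the subendocardial ``transmural_fraction`` of the
    wall over ``lesion_angle_deg``; remote myocardium is Gaussian around
    ``remote_mean``. An optional no-reflow core of exactly
    ``n_core_pixels`` dark pixels is embedded strictly inside the lesion
    so in-plane hole filling recovers it exactly.
    """
    if not 0.0 < transmural_fraction <= 1.0:
        raise DomainError("transmural fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    cx, cy = center
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    r = np.hypot(cols - cx, rows - cy)
    ang = np.degrees(np.arctan2(rows - cy, cols - cx)) % 360.0
    myo = (r >= endo_radius) & (r < epi_radius)
    lo, hi = lesion_angle_deg
    in_span = (ang >= lo) & (ang < hi) if lo <= hi else (ang >= lo) | (ang < hi)
    r_out = endo_radius + transmural_fraction * (epi_radius - endo_radius)
    lesion = myo & in_span & (r < r_out)
    if not lesion.any():
        raise DomainError("lesion lies outside the myocardium")

    core = np.zeros(shape, dtype=bool)
    if n_core_pixels > 0:
        from scipy import ndimage

        interior = ndimage.binary_erosion(lesion, iterations=2)
        if interior.sum() < n_core_pixels:
            raise DomainError("lesion too small for the requested no-reflow core")
        ir, ic = np.nonzero(interior)
        ccx, ccy = ic.mean(), ir.mean()
        order = np.argsort(np.hypot(ic - ccx, ir - ccy), kind="stable")
        core[ir[order[:n_core_pixels]], ic[order[:n_core_pixels]]] = True

    image = np.full(shape, remote_mean, dtype=float)
    if remote_sd > 0:
        image[myo] = rng.normal(remote_mean, remote_sd, int(myo.sum()))
    image[lesion] = lesion_si
    image[core] = core_si

    lesion_r_mid = 0.5 * (endo_radius + r_out)
    ang_mid = math.radians(0.5 * (lo + hi) if lo <= hi else ((lo + hi + 360) / 2) % 360)
    core_center = (
        cx + lesion_r_mid * math.cos(ang_mid),
        cy + lesion_r_mid * math.sin(ang_mid),
    )
    truth = PhantomTruth(
        "lge_phantom_image",
        seed,
        {
            "transmural_fraction": transmural_fraction,
            "lesion_pixels": int(lesion.sum()),
            "core_pixels": int(core.sum()),
            "lesion_angle_deg": list(lesion_angle_deg),
            "remote_mean": remote_mean,
            "remote_sd": remote_sd,
            "lesion_si": lesion_si,
        },
    )
    return LGEPhantom(
        image=image,
        myo_mask=myo,
        lesion_mask=lesion,
        core_mask=core,
        endo=regular_polygon(cx, cy, endo_radius, 128, "endocardial"),
        epi=regular_polygon(cx, cy, epi_radius, 128, "epicardial"),
        remote_roi=_remote_roi_polygon(center, endo_radius, epi_radius),
        core_roi=regular_polygon(core_center[0], core_center[1], 3.0, 64, "scar_core_roi"),
        truth=truth,
    )


def _remote_roi_polygon(
    center: tuple[float, float], endo_radius: float, epi_radius: float
) -> ContourPolygon:
    r_mid = 0.5 * (endo_radius + epi_radius)
    cx = center[0] + r_mid * math.cos(math.radians(225.0))
    cy = center[1] + r_mid * math.sin(math.radians(225.0))
    return regular_polygon(cx, cy, 0.35 * (epi_radius - endo_radius), 64, "remote_roi")


def t2star_series(
    s0: float = 1000.0,
    t2star_ms: float = 30.0,
    te_ms: tuple[float, ...] = (2.0, 4.6, 7.1, 9.7, 12.2, 14.8, 17.3, 19.9, 22.4, 25.0),
    noise_floor: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DecayCurve, PhantomTruth]:
    """Multi-echo septal decay curve with optional noise floor and noise.

    SI(TE) = sqrt((S0·e^(−TE/T2*))² + floor²) + Gaussian noise; a nonzero
    floor produces the late-echo plateau that biases a full mono-
    exponential fit upward and motivates the truncation method.
    """
    rng = np.random.default_rng(seed)
    te = np.asarray(te_ms, dtype=float)
    clean = np.sqrt((s0 * np.exp(-te / t2star_ms)) ** 2 + noise_floor**2)
    si = clean + (rng.normal(0.0, noise_sd, te.shape) if noise_sd > 0 else 0.0)
    si = np.maximum(si, 1e-9)
    truth = PhantomTruth(
        "t2star_series",
        seed,
        {"s0": s0, "t2star_ms": t2star_ms, "noise_floor": noise_floor, "noise_sd": noise_sd},
    )
    return DecayCurve(te, si), truth


def _wrap(v: np.ndarray, venc: float) -> np.ndarray:
    return np.mod(v + venc, 2.0 * venc) - venc


def flow_phantom_frames(
    vessel_radius_mm: float = 12.0,
    peak_velocity_cm_s: np.ndarray | None = None,
    profile: str = "parabolic",
    venc: float = 150.0,
    alias: bool = False,
    background_offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    center: tuple[float, float] = (32.0, 32.0),
    n_frames: int = 20,
    rr_ms: float = 857.0,
    te_ms: float = 2.5,
    heart_rate: float = 70.0,
) -> tuple[VelocityFrameSeries, PhantomTruth]:
    """Velocity-encoded frames of a circular vessel with analytic truth.

    ``peak_velocity_cm_s`` gives the per-frame centerline velocity
    (default: a systolic half-sine pulse with a small diastolic reverse
    wave). ``profile`` is uniform (plug) or parabolic (Poiseuille; spatial
    mean = peak/2). ``background_offset`` (a, b, c) adds a + b·x + c·y
    cm/s per mm; ``alias`` wraps velocities into (−VENC, +VENC] as the
    scanner records them. Truth volumes integrate the analytic flux over
    the cycle (trapezoid, last interval closing the cycle) before
    aliasing and offsets are applied.
    """
    rng = np.random.default_rng(seed)
    if peak_velocity_cm_s is None:
        t = np.arange(n_frames)
        sys_len = max(n_frames // 3, 3)
        wave = np.zeros(n_frames)
        wave[:sys_len] = 120.0 * np.sin(np.pi * t[:sys_len] / sys_len)
        wave[sys_len : sys_len + 4] = -8.0
        peak_velocity_cm_s = wave
    vp = np.asarray(peak_velocity_cm_s, dtype=float)
    n_frames = vp.size
    if profile not in {"uniform", "parabolic"}:
        raise DomainError(f"unknown velocity profile {profile!r}")

    cx, cy = center
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    r2 = ((cols - cx) ** 2 + (rows - cy) ** 2) / vessel_radius_mm**2
    inside = r2 < 1.0
    shape_map = np.where(inside, 1.0 if profile == "uniform" else 1.0 - r2, 0.0)

    velocity = vp[:, None, None] * shape_map[None, :, :]
    a, b, c = background_offset
    offset_plane = a + b * cols + c * rows
    velocity = velocity + offset_plane[None, :, :]
    if noise_sd > 0:
        velocity = velocity + rng.normal(0.0, noise_sd, velocity.shape)
    if alias:
        velocity = _wrap(velocity, venc)

    magnitude = np.where(inside, 300.0, 50.0)[None].repeat(n_frames, axis=0)
    trigger = np.arange(n_frames) * rr_ms / n_frames
    roi = regular_polygon(cx, cy, vessel_radius_mm, 128, "vessel_lumen")
    series = VelocityFrameSeries(
        velocity=velocity,
        pixel_area_mm2=1.0,
        trigger_times_ms=trigger,
        rr_ms=rr_ms,
        venc=venc,
        rois=[roi],
        magnitude=magnitude,
        te_ms=te_ms,
    )

    area_mm2 = math.pi * vessel_radius_mm**2
    mean_factor = 1.0 if profile == "uniform" else 0.5
    flux = vp * mean_factor * area_mm2 * 0.01  # ml/s
    dt = rr_ms / n_frames / 1000.0
    ante = retro = 0.0
    for i in range(n_frames):
        f0, f1 = flux[i], flux[(i + 1) % n_frames]
        if f0 >= 0 and f1 >= 0:
            ante += 0.5 * (f0 + f1) * dt
        elif f0 <= 0 and f1 <= 0:
            retro += -0.5 * (f0 + f1) * dt
        else:
            tc = dt * abs(f0) / (abs(f0) + abs(f1))
            a0, a1 = 0.5 * f0 * tc, 0.5 * f1 * (dt - tc)
            ante += max(a0, 0.0) + max(a1, 0.0)
            retro += -min(a0, 0.0) - min(a1, 0.0)
    net = ante - retro
    truth = PhantomTruth(
        "flow_phantom_frames",
        seed,
        {
            "antegrade_ml": ante,
            "retrograde_ml": retro,
            "net_ml": net,
            "regurgitant_fraction_pct": 100.0 * retro / ante if ante > 0 else None,
            "cardiac_output_l_min": net * heart_rate / 1000.0,
            "peak_velocity_cm_s": float(np.abs(vp).max()),
            "recorded_peak_after_alias": float(_wrap(np.array([np.abs(vp).max()]), venc)[0])
            if alias
            else float(np.abs(vp).max()),
            "aliased": alias,
            "background_offset": list(background_offset),
            "heart_rate": heart_rate,
            "vessel_area_mm2": area_mm2,
        },
    )
    return series, truth
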