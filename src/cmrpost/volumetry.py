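"""LV and RV chamber quantification from short-axis contour stacks.

Volumes follow slice summation (Simpson's rule): every contoured slice
contributes its cross-sectional area times the integration step
``thickness + gap``; end-diastole (ED) and end-systole (ES) are single
global phases chosen by the summed blood volume over the whole stack.
Myocardial mass is the epicardial-minus-endocardial volume times the
specific density of myocardium, 1.05 g/ml. Whether papillary muscles are
counted as blood (common clinical practice) or as myocardium must be
carried into the report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ContourTopologyError,
    DomainError,
    GeometryError,
    MissingContourError,
)
from .geometry import ContourPolygon, ContourStack, _ray_crossings, polygon_area

logger = logging.getLogger(__name__)

MYOCARDIUM_DENSITY_G_PER_ML = 1.05
AREA_LENGTH_COEFFICIENT = 0.85

PAPILLARY_MODES = ("included_in_blood", "included_in_myocardium")


@dataclass
class VolumetryResult:
    """Chamber quantification summary.

    Volumes in ml, mass in g, EF in percent, CO in L/min. ``indexed``
    holds BSA-indexed values (per m²) when a body surface area is known.
    ``mass_status`` is ``"not_computed"`` for the RV, which is usually not
    quantified in routine assessment — an explicit marker, never a zero.
    """

    chamber: str
    edv: float
    esv: float
    sv: float
    ef: float
    co: float | None
    mass: float | None
    mass_status: str
    ed_phase: int
    es_phase: int
    papillary_mode: str
    method: str
    indexed: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class BasalSliceClass:
    classification: str
    reason: str


def slice_blood_volume(
    stack: ContourStack, slice_index: int, phase: int, papillary_mode: str
) -> float:
    """Blood volume of one slice in ml: endocardial area × (thickness + gap).

    Papillary polygon areas are subtracted when the papillary muscles are
    counted as myocardium.
    """
    _check_papillary_mode(papillary_mode)
    endo = stack.get(slice_index, phase, "endocardial")
    if endo is None:
        raise MissingContourError(
            f"no endocardial contour on slice {slice_index}, phase {phase}"
        )
    area = polygon_area(endo)
    if papillary_mode == "included_in_myocardium":
        area -= sum(polygon_area(p) for p in stack.get_all(slice_index, phase, "papillary"))
    return area * stack.geometry(slice_index).step_mm / 1000.0


def _check_papillary_mode(mode: str) -> None:
    if mode not in PAPILLARY_MODES:
        raise DomainError(f"unknown papillary mode {mode!r}")


def _total_blood_volume(stack: ContourStack, phase: int, papillary_mode: str) -> float:
    total = 0.0
    for s in stack.slices_with("endocardial", phase):
        total += slice_blood_volume(stack, s, phase, papillary_mode)
    return total


def select_global_ed_es(
    stack: ContourStack,
    papillary_mode: str = "included_in_blood",
) -> tuple[int, int]:
    """Pick one global ED phase (largest summed blood volume) and ES (smallest).

    Phases whose contour coverage differs from the best-covered phase are
    excluded with a logged warning. Ties resolve to the earlier phase.
    """
    coverage = {
        p: len(stack.slices_with("endocardial", p)) for p in range(stack.n_phases)
    }
    full = max(coverage.values(), default=0)
    if full == 0:
        raise MissingContourError("no phase has endocardial contours")
    usable = [p for p, c in coverage.items() if c == full]
    if len(usable) < 2:
        raise MissingContourError("need at least 2 phases with complete contours")
    skipped = sorted(set(coverage) - set(usable))
    if skipped:
        logger.warning("phases %s excluded: incomplete contour coverage", skipped)
    volumes = {p: _total_blood_volume(stack, p, papillary_mode) for p in usable}
    ed = min(usable, key=lambda p: (-volumes[p], p))
    es = min(usable, key=lambda p: (volumes[p], p))
    return ed, es


def _myocardial_adjacency_fraction(
    endo: ContourPolygon, epi: ContourPolygon | None, max_dist_mm: float = 3.0
) -> float:
    """Fraction of the endocardial perimeter lying near myocardium.

    Operationalizes "blood volume surrounded by myocardium": the myocardium
    is the epicardial-minus-endocardial region; perimeter samples within
    ``max_dist_mm`` of it count as adjacent.
    """
    if epi is None:
        return 0.0
    ring = endo.as_shapely().exterior
    myo = epi.as_shapely().difference(endo.as_shapely().buffer(-1e-9))
    if myo.is_empty:
        return 0.0
    n = max(int(ring.length), 36)
    fracs = np.arange(n) / n
    hits = sum(
        1 for f in fracs if ring.interpolate(f, normalized=True).distance(myo) <= max_dist_mm
    )
    return hits / n


def classify_basal_slice(
    stack: ContourStack,
    slice_index: int,
    ed_phase: int,
    es_phase: int,
    adjacency_threshold: float = 0.5,
    adjacency_dist_mm: float = 3.0,
) -> dict[int, BasalSliceClass]:
    """Classify a basal (or apical) slice at ED and ES for inclusion rules.

    Basal descent can turn a slice that holds ventricular blood at ED into
    left atrium at ES: the atrium is recognized when less than half of the
    blood-pool boundary is adjacent to myocardium while the cavity expands
    during systole. An epicardial contour without a blood pool contributes
    to mass only (basal lateral crescent, or the apical cap).
    """
    contoured = stack.slices_with("endocardial", ed_phase) or stack.slices_with(
        "epicardial", ed_phase
    )
    most_apical = max(contoured) if contoured else slice_index
    out: dict[int, BasalSliceClass] = {}
    ed_endo = stack.get(slice_index, ed_phase, "endocardial")
    for phase in (ed_phase, es_phase):
        endo = stack.get(slice_index, phase, "endocardial")
        epi = stack.get(slice_index, phase, "epicardial")
        if endo is None and epi is not None:
            if slice_index == most_apical:
                out[phase] = BasalSliceClass(
                    "apical_mass_only", "apical myocardium without cavity"
                )
            else:
                out[phase] = BasalSliceClass(
                    "mass_only_crescent", "myocardial crescent without blood pool"
                )
            continue
        if endo is None:
            out[phase] = BasalSliceClass("atrium_exclude", "no contours at this phase")
            continue
        frac = _myocardial_adjacency_fraction(endo, epi, adjacency_dist_mm)
        expanding = (
            phase == es_phase
            and ed_endo is not None
            and polygon_area(endo) > polygon_area(ed_endo)
        )
        if frac < adjacency_threshold and expanding:
            out[phase] = BasalSliceClass(
                "atrium_exclude",
                f"boundary-myocardium fraction {frac:.2f} < {adjacency_threshold} "
                "and cavity expanding during systole",
            )
        else:
            out[phase] = BasalSliceClass(
                "ventricular_blood_and_mass",
                f"boundary-myocardium fraction {frac:.2f}",
            )
    return out


def _phase_volume_with_rules(
    stack: ContourStack,
    phase: int,
    ed_phase: int,
    es_phase: int,
    papillary_mode: str,
) -> float:
    """Summed blood volume at a phase, excluding slices classified non-ventricular."""
    slices = stack.slices_with("endocardial", phase)
    if not slices:
        raise MissingContourError(f"no endocardial contours at phase {phase}")
    basal_candidates = set(slices[:2])
    total = 0.0
    for s in slices:
        if s in basal_candidates:
            cls = classify_basal_slice(stack, s, ed_phase, es_phase)[phase]
            if cls.classification != "ventricular_blood_and_mass":
                logger.info("slice %d at phase %d: %s (%s)", s, phase, cls.classification, cls.reason)
                continue
        total += slice_blood_volume(stack, s, phase, papillary_mode)
    return total


def lv_mass(
    stack: ContourStack,
    papillary_mode: str = "included_in_blood",
    phase: int = 0,
) -> float:
    """LV myocardial mass in grams at one phase.

    (epicardial volume − endocardial volume) × 1.05 g/ml; papillary areas
    count as myocardium when so configured. Slices with an epicardial
    contour but no endocardial one contribute wall only.
    """
    _check_papillary_mode(papillary_mode)
    slices = stack.slices_with("epicardial", phase)
    if not slices:
        raise MissingContourError(f"no epicardial contours at phase {phase}")
    myo_mm3 = 0.0
    for s in slices:
        epi = stack.get(s, phase, "epicardial")
        endo = stack.get(s, phase, "endocardial")
        epi_area = polygon_area(epi)
        endo_area = polygon_area(endo) if endo is not None else 0.0
        if endo_area > epi_area:
            raise ContourTopologyError(f"endocardial area exceeds epicardial on slice {s}")
        wall = epi_area - endo_area
        if papillary_mode == "included_in_myocardium":
            wall += sum(polygon_area(p) for p in stack.get_all(s, phase, "papillary"))
        myo_mm3 += wall * stack.geometry(s).step_mm
    return myo_mm3 / 1000.0 * MYOCARDIUM_DENSITY_G_PER_ML


def _assemble_result(
    stack: ContourStack,
    chamber: str,
    papillary_mode: str,
    method: str,
    es_override: int | None = None,
) -> VolumetryResult:
    ed, es = select_global_ed_es(stack, papillary_mode)
    notes: list[str] = []
    if es_override is not None:
        notes.append(f"ES phase overridden by caller: {es_override} (volume-based pick was {es})")
        logger.info("ES override: %d", es_override)
        es = es_override
    edv = _phase_volume_with_rules(stack, ed, ed, es, papillary_mode)
    esv = _phase_volume_with_rules(stack, es, ed, es, papillary_mode)
    sv = edv - esv
    if edv <= 0:
        raise DomainError("end-diastolic volume must be positive")
    ef = 100.0 * sv / edv
    hr = stack.meta.heart_rate
    co = sv * hr / 1000.0 if hr is not None else None

    if chamber == "lv" and stack.slices_with("epicardial", ed):
        mass = lv_mass(stack, papillary_mode, ed)
        mass_status = "computed"
    elif chamber == "lv":
        mass, mass_status = None, "no_epicardial_contours"
    else:
        mass, mass_status = None, "not_computed"
        notes.append("RV mass not quantified in routine assessment")

    indexed: dict[str, float] = {}
    bsa = stack.meta.body_surface_area
    if bsa is not None:
        indexed["edv_ml_m2"] = edv / bsa
        indexed["esv_ml_m2"] = esv / bsa
        indexed["sv_ml_m2"] = sv / bsa
        if co is not None:
            indexed["ci_l_min_m2"] = co / bsa
        if mass is not None:
            indexed["mass_g_m2"] = mass / bsa

    return VolumetryResult(
        chamber=chamber,
        edv=edv,
        esv=esv,
        sv=sv,
        ef=ef,
        co=co,
        mass=mass,
        mass_status=mass_status,
        ed_phase=ed,
        es_phase=es,
        papillary_mode=papillary_mode,
        method=method,
        indexed=indexed,
        notes=notes,
    )


def lv_assessment(
    stack: ContourStack,
    papillary_mode: str = "included_in_blood",
    es_override: int | None = None,
) -> VolumetryResult:
    """Full LV work-flow: ED/ES selection, basal-slice rules, Simpson volumes, mass.

    End-systole is normally the smallest-volume phase; aortic valve closure
    (not computable from contours) may be supplied as ``es_override`` and is
    logged in the result notes.
    """
    _check_papillary_mode(papillary_mode)
    return _assemble_result(stack, "lv", papillary_mode, "simpson_stack", es_override)


def rv_assessment(
    stack: ContourStack,
    plane: str = "short_axis",
    es_override: int | None = None,
) -> VolumetryResult:
    """RV quantification: same slice-summation path as the LV, no mass.

    RV trabeculations are expected to be included in the blood pool by the
    smooth-contour convention (drawn upstream); mass is reported as
    explicitly not computed.
    """
    if plane not in {"short_axis", "transaxial"}:
        raise GeometryError(f"unsupported RV analysis plane {plane!r}")
    return _assemble_result(stack, "rv", "included_in_blood", "simpson_stack", es_override)


def area_length_volume(
    mode: str,
    area1_cm2: float,
    length_cm: float,
    area2_cm2: float | None = None,
) -> float:
    """Area-length LV volume in ml.

    single: V = 0.85·A²/L (4-chamber view); biplane: V = 0.85·A1·A2/L with
    the 2-chamber area as A2. Reports using this method must mention the
    analysis technique explicitly; callers get the method tag back in
    :func:`cmrpost.io_bundle.write_report`.
    """
    if area1_cm2 <= 0 or length_cm <= 0:
        raise DomainError("areas and length must be positive")
    if mode == "single":
        return AREA_LENGTH_COEFFICIENT * area1_cm2**2 / length_cm
    if mode == "biplane":
        if area2_cm2 is None or area2_cm2 <= 0:
            raise DomainError("biplane mode needs a positive second area")
        return AREA_LENGTH_COEFFICIENT * area1_cm2 * area2_cm2 / length_cm
    raise DomainError(f"unknown area-length mode {mode!r}")


@dataclass(frozen=True)
class ConsistencyReport:
    lv_sv_ml: float
    rv_sv_ml: float
    relative_difference: float
    tolerance: float
    consistent: bool
    note: str = "LV stroke volume can be used to validate RV data"


def stroke_volume_consistency(
    lv_sv: float, rv_sv: float, tolerance_fraction: float = 0.10
) -> ConsistencyReport:
    """LV and RV stroke volumes should be nearly equal absent shunt/regurgitation."""
    if lv_sv <= 0 or rv_sv <= 0:
        raise DomainError("stroke volumes must be positive")
    rel = abs(lv_sv - rv_sv) / lv_sv
    return ConsistencyReport(lv_sv, rv_sv, rel, tolerance_fraction, rel <= tolerance_fraction)


def linear_dimensions(
    endo: ContourPolygon,
    epi: ContourPolygon,
    direction_deg: float,
) -> tuple[float, float, float]:
    """Cavity diameter and both wall thicknesses along a line through the cavity centroid.

    Returns ``(cavity_mm, wall_plus_mm, wall_minus_mm)`` where the walls are
    measured on the +direction and −direction sides (e.g. septal and
    lateral for an appropriately chosen direction).
    """
    center = endo.as_shapely().centroid
    theta = math.radians(direction_deg)
    u = np.array([math.cos(theta), math.sin(theta)])
    b = epi.as_shapely().bounds
    reach = 4.0 * max(b[2] - b[0], b[3] - b[1])
    sides = []
    for sign in (1.0, -1.0):
        d_endo = _ray_crossings(center, sign * u, endo.as_shapely().exterior, reach)
        d_epi = _ray_crossings(center, sign * u, epi.as_shapely().exterior, reach)
        if d_endo.size == 0 or d_epi.size == 0:
            raise GeometryError("direction line misses a contour")
        r_endo = d_endo[0]
        beyond = d_epi[d_epi > r_endo + 1e-9]
        if beyond.size == 0:
            raise GeometryError("epicardium not beyond endocardium along direction")
        sides.append((r_endo, beyond[0]))
    (rp_endo, rp_epi), (rm_endo, rm_epi) = sides
    cavity = rp_endo + rm_endo
    return cavity, rp_epi - rp_endo, rm_epi - rm_endo
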