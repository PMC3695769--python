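"""First-pass perfusion: curve extraction, features, MPRI, classification."""

import numpy as np
import pytest

from cmrpost import perfusion
from cmrpost.errors import DomainError, NoContrastArrivalError, UndefinedRatioError
from cmrpost.perfusion import (
    PerfusionFeatures,
    SICurve,
    classify_segment_finding,
    curve_features,
    extract_si_curves,
    hypoenhancement_width_px,
    mpri,
)
from cmrpost.phantom import perfusion_curve_set


def _curve(si, nb=3):
    si = np.asarray(si, dtype=float)
    return SICurve("test", np.arange(si.size) * 1000.0, si, nb)


def analyze_phantom(ph):
    """Standard phantom work-flow: endo-layer curves, widths, classification."""
    cs = extract_si_curves(
        ph.frames_stress, ph.endo, ph.epi, ph.blood_roi, ph.model, 0,
        ph.frame_times_ms, ph.n_baseline_frames, layers="endo_epi",
    )
    cr = extract_si_curves(
        ph.frames_rest, ph.endo, ph.epi, ph.blood_roi, ph.model, 0,
        ph.frame_times_ms, ph.n_baseline_frames, layers="endo_epi",
    )
    stress = {s: cs[(s, "endo")] for s in range(1, 7)}
    rest = {s: cr[(s, "endo")] for s in range(1, 7)}
    peak_frame = int(round(ph.truth.data["ref_peak_frame"]))
    dip_frame = int(round(ph.truth.data["blood_arrival_frame"])) + 1
    w_peak = hypoenhancement_width_px(ph.frames_stress[peak_frame], ph.endo, ph.epi, ph.model)
    w_dip = hypoenhancement_width_px(
        ph.frames_stress[dip_frame], ph.endo, ph.epi, ph.model,
        reference_image=ph.frames_stress[0],
    )
    widths = {s: max(w_peak.get(s, 0.0), w_dip.get(s, 0.0)) for s in range(1, 7)}
    return classify_segment_finding(
        stress, rest, cs["lv_blood_pool"], cr["lv_blood_pool"], widths,
        ph.truth.data["phase_encode_aligned"],
    )


class TestExtraction:
    def test_uniform_image_constant_curves(self, single_slice_model):
        from cmrpost.geometry import regular_polygon

        frames = np.full((10, 80, 80), 100.0)
        endo = regular_polygon(40, 40, 15, 128, "endocardial")
        epi = regular_polygon(40, 40, 25, 128, "epicardial")
        blood = regular_polygon(40, 40, 10, 128, "blood_pool_roi")
        curves = extract_si_curves(frames, endo, epi, blood, single_slice_model)
        for c in curves.values():
            assert np.allclose(c.si, 100.0)

    def test_segment_scaling_linearity(self):
        ph = perfusion_curve_set(defect_segments=(), artifact_segments=())
        frames = ph.frames_stress.copy()
        # scale every pixel of segment 4's angular sector by 0.5
        curves0 = extract_si_curves(
            frames, ph.endo, ph.epi, ph.blood_roi, ph.model, 0, ph.frame_times_ms
        )
        frames4 = frames.copy()
        from cmrpost.geometry import assign_pixels_to_segments, myocardium_mask

        myo = myocardium_mask(ph.endo, ph.epi, frames.shape[1:])
        seg_map = assign_pixels_to_segments(myo, ph.model, 0)
        frames4[:, seg_map == 4] *= 0.5
        curves4 = extract_si_curves(
            frames4, ph.endo, ph.epi, ph.blood_roi, ph.model, 0, ph.frame_times_ms
        )
        assert np.allclose(curves4[4].si, 0.5 * curves0[4].si)
        assert np.allclose(curves4[3].si, curves0[3].si)

    def test_empty_segment_flagged_not_dropped(self, single_slice_model):
        from cmrpost.geometry import regular_polygon

        frames = np.full((8, 80, 80), 50.0)
        endo = regular_polygon(40, 40, 15, 128, "endocardial")
        epi = regular_polygon(40, 40, 25, 128, "epicardial")
        blood = regular_polygon(40, 40, 10, 128, "blood_pool_roi")
        # excluding the inner half of the wall empties every endocardial layer
        blocker = regular_polygon(40, 40, 22, 128, "papillary")
        curves = extract_si_curves(
            frames, endo, epi, blood, single_slice_model, exclude=[blocker],
            layers="endo_epi",
        )
        flagged = [
            c for k, c in curves.items()
            if k != "lv_blood_pool" and k[1] == "endo" and c.flagged
        ]
        assert len(flagged) == 6, "all endocardial layers should be flagged empty"
        assert all(np.isnan(c.si).all() for c in flagged)


class TestCurveFeatures:
    def test_constant_curve_no_arrival(self):
        with pytest.raises(NoContrastArrivalError):
            curve_features(_curve(np.full(20, 100.0)))

    def test_exact_ramp_slope(self):
        # flat at 100 through frame 4, then +10/frame
        si = np.concatenate([np.full(5, 100.0), 100.0 + 10.0 * np.arange(1, 12)])
        f = curve_features(_curve(si, nb=4), upslope_window=3)
        assert f.max_upslope == pytest.approx(10.0)
        assert f.arrival_frame == 5

    def test_matches_brute_force_window_search(self):
        rng = np.random.default_rng(5)
        t = np.arange(40, dtype=float)
        si = 100.0 + 80.0 * np.clip((t - 6) / 8, 0, None) ** 2 * np.exp(
            2 * (1 - np.clip((t - 6) / 8, 0, None))
        )
        si += rng.normal(0, 0.8, si.shape)
        curve = _curve(si, nb=4)
        feats = curve_features(curve, upslope_window=5)
        # independent oracle: enumerate every admissible 5-frame window
        base = si[:4].mean()
        thr = base + 2 * si[:4].std() + 1e-12
        arrival = next(
            i for i in range(4, 40)
            if si[i] > thr and (i == 39 or si[i + 1] > thr)
        )
        peak = arrival + int(np.argmax(si[arrival:]))
        best = -np.inf
        for start in range(max(arrival - 1, 0), peak - 5 + 2):
            best = max(best, np.polyfit(np.arange(start, start + 5), si[start : start + 5], 1)[0])
        assert feats.arrival_frame == arrival
        assert feats.peak_frame == peak
        assert feats.max_upslope == pytest.approx(best)
        assert feats.time_to_peak_frames == peak - arrival

    def test_affine_rescaling_invariances(self):
        si = np.concatenate([np.full(4, 100.0), 100 + 15 * np.arange(1, 15),
                             np.full(10, 310.0) - 5 * np.arange(10)])
        blood_si = np.concatenate([np.full(4, 100.0), 100 + 60 * np.arange(1, 25)])
        f1 = curve_features(_curve(si, 4), _curve(blood_si, 4))
        a, b = 2.5, 40.0
        f2 = curve_features(_curve(a * si + b, 4), _curve(a * blood_si + b, 4))
        assert f2.normalized_upslope == pytest.approx(f1.normalized_upslope)
        assert f2.time_to_peak_frames == f1.time_to_peak_frames
        assert f2.max_upslope == pytest.approx(a * f1.max_upslope)
        assert f2.upslope_integral == pytest.approx(a * f1.upslope_integral)


class TestMPRI:
    def _features(self, norm):
        return PerfusionFeatures(100, 5, 12, 10.0, 10.0, norm, 7, 7.0, 50.0)

    def test_ratio_and_identity(self):
        assert mpri(self._features(0.30), self._features(0.15)) == pytest.approx(2.0)
        f = self._features(0.2)
        assert mpri(f, f) == 1.0

    def test_zero_rest_upslope(self):
        with pytest.raises(UndefinedRatioError):
            mpri(self._features(0.3), self._features(0.0))

    def test_phantom_flow_ratio_recovered(self):
        ph = perfusion_curve_set(
            defect_segments=(), artifact_segments=(), stress_rest_flow_ratio=2.5,
            noise_sd=2.0, seed=11,
        )
        cs = extract_si_curves(
            ph.frames_stress, ph.endo, ph.epi, ph.blood_roi, ph.model, 0,
            ph.frame_times_ms, ph.n_baseline_frames,
        )
        cr = extract_si_curves(
            ph.frames_rest, ph.endo, ph.epi, ph.blood_roi, ph.model, 0,
            ph.frame_times_ms, ph.n_baseline_frames,
        )
        for seg in range(1, 7):
            fs = curve_features(cs[seg], cs["lv_blood_pool"])
            fr = curve_features(cr[seg], cr["lv_blood_pool"])
            assert mpri(fs, fr) == pytest.approx(2.5, rel=0.05)


class TestClassifier:
    def test_phantom_defect_and_artifact_labels(self):
        ph = perfusion_curve_set(seed=2)
        findings = analyze_phantom(ph)
        for seg in range(1, 7):
            assert findings[seg].label == ph.truth.data["labels"][seg]

    def test_no_lesions_all_normal(self):
        ph = perfusion_curve_set(defect_segments=(), artifact_segments=(), seed=3)
        findings = analyze_phantom(ph)
        assert all(f.label == "normal" for f in findings.values())

    def test_criteria_vector_is_audit_complete(self):
        ph = perfusion_curve_set(seed=4)
        findings = analyze_phantom(ph)
        defect_seg = ph.truth.data["defect_segments"][0]
        crit = findings[defect_seg].criteria
        for name in (
            "onset_at_myocardial_arrival",
            "persists_gt_4rr_beyond_peak",
            "width_gt_1px",
            "no_signal_drop_below_baseline",
            "stress_only",
        ):
            assert crit[name] is True or crit[name] is np.True_

    def test_stress_only_banding_not_a_defect(self):
        """A one-pixel transient dip misaligned with phase encoding is never a defect."""
        ph = perfusion_curve_set(defect_segments=(), artifact_segments=(2,), seed=5)
        # claim the band is NOT phase-encode aligned -> cannot be called artifact,
        # but must not become a defect either
        cs = extract_si_curves(
            ph.frames_stress, ph.endo, ph.epi, ph.blood_roi, ph.model, 0,
            ph.frame_times_ms, ph.n_baseline_frames, layers="endo_epi",
        )
        cr = extract_si_curves(
            ph.frames_rest, ph.endo, ph.epi, ph.blood_roi, ph.model, 0,
            ph.frame_times_ms, ph.n_baseline_frames, layers="endo_epi",
        )
        stress = {s: cs[(s, "endo")] for s in range(1, 7)}
        rest = {s: cr[(s, "endo")] for s in range(1, 7)}
        findings = classify_segment_finding(
            stress, rest, cs["lv_blood_pool"], cr["lv_blood_pool"],
            {2: 1.0}, {s: False for s in range(1, 7)},
        )
        assert findings[2].label in {"indeterminate", "normal"}
        assert findings[2].label != "inducible_defect"

    def test_matched_deficit_with_scar_reported_normal(self):
        si_norm = np.concatenate([np.full(4, 100.0), 100 + 50 * np.arange(1, 17)])
        si_low = np.concatenate([np.full(4, 100.0), 100 + 25 * np.arange(1, 17)])
        blood = np.concatenate([np.full(4, 100.0), 100 + 200 * np.arange(1, 17)])
        t = np.arange(20) * 1000.0
        stress = {s: SICurve(s, t, si_norm if s > 1 else si_low, 4) for s in range(1, 7)}
        rest = {s: SICurve(s, t, si_norm if s > 1 else si_low, 4) for s in range(1, 7)}
        bloodc = SICurve("lv_blood_pool", t, blood, 4)
        findings = classify_segment_finding(
            stress, rest, bloodc, bloodc, {1: 4.0}, None, {1: True}
        )
        assert findings[1].label == "normal"
        assert any("scar" in n for n in findings[1].notes)

    def test_deterministic_and_total(self):
        ph = perfusion_curve_set(seed=6)
        f1 = analyze_phantom(ph)
        f2 = analyze_phantom(ph)
        assert set(f1) == set(range(1, 7))
        for seg in f1:
            assert f1[seg].label == f2[seg].label
            assert f1[seg].label in perfusion.LABELS


class TestWidthMeasurement:
    def test_phantom_widths(self):
        ph = perfusion_curve_set(seed=7)
        peak = int(round(ph.truth.data["ref_peak_frame"]))
        dip = int(round(ph.truth.data["blood_arrival_frame"])) + 1
        w_peak = hypoenhancement_width_px(ph.frames_stress[peak], ph.endo, ph.epi, ph.model)
        w_dip = hypoenhancement_width_px(
            ph.frames_stress[dip], ph.endo, ph.epi, ph.model,
            reference_image=ph.frames_stress[0],
        )
        for seg in ph.truth.data["defect_segments"]:
            assert w_peak[seg] == pytest.approx(ph.truth.data["defect_width_px"], abs=0.75)
        for seg in ph.truth.data["artifact_segments"]:
            assert w_dip[seg] == pytest.approx(ph.truth.data["artifact_width_px"], abs=0.5)


def test_upslope_window_validation():
    with pytest.raises(DomainError):
        curve_features(_curve([1, 2, 3, 4, 5.0]), upslope_window=2)
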