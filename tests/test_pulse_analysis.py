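"""Beat segmentation, filtering, calibration and PWA feature extraction."""

import numpy as np
import pytest

from radarbp import pulse_analysis as pa
from radarbp.synthetic import (
    DisplacementTrace,
    PulseModelParams,
    synth_displacement,
)

SPS = 250.0


@pytest.fixture(scope="module")
def beats72():
    trace = synth_displacement(PulseModelParams(), duration=30.0, rate=SPS, seed=0)
    return pa.segment_waves(trace)


@pytest.fixture(scope="module")
def calibrated_beat(beats72):
    ref = pa.build_reference(beats72[:5])
    waves = pa.label_waves(list(beats72), ref, threshold=0.8)
    usable = [w for w in waves if w.usable]
    sf = pa.compute_scaling_factor(usable[0], 120.0, 80.0)
    return pa.calibrate_wave(usable[1], sf)


class TestDetectInversion:
    def test_upright_trace(self, pulse_trace):
        assert pa.detect_inversion(pulse_trace) is False

    def test_negated_trace(self, pulse_trace):
        neg = DisplacementTrace(samples=-pulse_trace.samples, rate=SPS)
        assert pa.detect_inversion(neg) is True

    def test_constant_trace_warns_false(self):
        flat = DisplacementTrace(samples=np.zeros(int(3 * SPS)), rate=SPS)
        with pytest.warns(UserWarning, match="indeterminate"):
            assert pa.detect_inversion(flat) is False


class TestSegmentWaves:
    def test_count_at_60_bpm(self):
        tr = synth_displacement(
            PulseModelParams(heart_rate_bpm=60.0), duration=10.0, rate=SPS, seed=0
        )
        assert len(pa.segment_waves(tr)) == 9

    def test_flat_trace_yields_nothing(self):
        assert pa.segment_waves(DisplacementTrace(samples=np.zeros(1000), rate=SPS)) == []

    def test_mean_duration_tracks_heart_rate(self, beats72):
        durations = [w.duration for w in beats72]
        assert np.mean(durations) == pytest.approx(60.0 / 72.0, rel=0.02)


class TestScaleAndReference:
    def test_scale01_hand_values(self):
        np.testing.assert_allclose(pa.scale01([2, 4, 6]), [0, 0.5, 1])
        np.testing.assert_allclose(pa.scale01([5, 1, 3]), [1, 0, 0.5])

    def test_scale01_idempotent(self):
        x = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(pa.scale01(x), x)

    def test_scale01_constant_rejected(self):
        with pytest.raises(ValueError):
            pa.scale01(np.ones(5))

    def test_reference_of_identical_waves_is_the_wave(self, beats72):
        w = beats72[0]
        ref = pa.build_reference([w] * 5, length=len(w))
        np.testing.assert_allclose(ref.samples, pa.scale01(w.samples), atol=1e-12)

    def test_mirror_ramps_degenerate(self):
        up = pa.PulseWave(samples=np.linspace(0, 1, 50), start_index=0, rate=SPS)
        down = pa.PulseWave(samples=np.linspace(1, 0, 50), start_index=0, rate=SPS)
        with pytest.raises(ValueError, match="degenerate"):
            pa.build_reference([up, down])

    def test_reference_from_jittered_beats_matches_template(self, beats72):
        ref = pa.build_reference(beats72[:5])
        score = pa.quality_score(beats72[10], ref)
        assert score > 0.99


class TestQualityScore:
    def test_self_correlation_is_one(self, beats72):
        ref = pa.build_reference(beats72[:5])
        wave = pa.PulseWave(samples=ref.samples.copy(), start_index=0, rate=SPS)
        assert pa.quality_score(wave, ref) == pytest.approx(1.0)

    def test_negated_reference_scores_minus_one(self, beats72):
        ref = pa.build_reference(beats72[:5])
        wave = pa.PulseWave(samples=1.0 - ref.samples, start_index=0, rate=SPS)
        assert pa.quality_score(wave, ref) == pytest.approx(-1.0)

    def test_textbook_pearson_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 2.0, 3.0, 5.0])
        ref = pa.ReferenceWave(samples=pa.scale01(b), source_count=1)
        wave = pa.PulseWave(samples=a, start_index=0, rate=SPS)
        sa, sb = pa.scale01(a), pa.scale01(b)
        expected = (np.sum((sa - sa.mean()) * (sb - sb.mean()))
                    / np.sqrt(np.sum((sa - sa.mean()) ** 2)
                              * np.sum((sb - sb.mean()) ** 2)))
        # wave is resampled to the reference length (here equal lengths)
        assert pa.quality_score(wave, ref) == pytest.approx(expected)


class TestLabelWaves:
    def _waves_with_scores(self, ref, targets):
        """Blend the reference with an anti-correlated ramp to hit a target score."""
        out = []
        n = len(ref)
        ramp = pa.scale01(np.abs(np.linspace(-1, 1, n)))
        for t in targets:
            best, best_d = None, np.inf
            for alpha in np.linspace(0, 1, 201):
                cand = (1 - alpha) * ref.samples + alpha * ramp
                r = np.corrcoef(pa.scale01(cand), ref.samples)[0, 1]
                if abs(r - t) < best_d:
                    best, best_d = cand, abs(r - t)
            out.append(pa.PulseWave(samples=best, start_index=0, rate=SPS))
        return out

    def test_strict_threshold_labels(self, beats72):
        ref = pa.build_reference(beats72[:5])
        waves = self._waves_with_scores(ref, [0.95, 0.85, 0.75, 0.5])
        labeled = pa.label_waves(waves, ref, threshold=0.8)
        assert [w.usable for w in labeled] == [True, True, False, False]
        labeled = pa.label_waves(waves, ref, threshold=0.9)
        assert [w.usable for w in labeled] == [True, False, False, False]

    def test_usable_count_monotone_in_threshold(self, beats72):
        ref = pa.build_reference(beats72[:5])
        waves = self._waves_with_scores(
            ref, [0.95, 0.92, 0.88, 0.85, 0.78, 0.72, 0.6]
        )
        counts = [
            sum(w.usable for w in pa.label_waves(waves, ref, threshold=th))
            for th in (0.7, 0.8, 0.9)
        ]
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[0] > counts[2]


class TestCalibration:
    def test_scaling_factor_hand_values(self):
        w = pa.PulseWave(samples=np.array([0.0, 50.0]), start_index=0, rate=SPS)
        assert pa.compute_scaling_factor(w, 120.0, 80.0) == pytest.approx(0.8)
        w2 = pa.PulseWave(samples=np.array([0.0, 40.0]), start_index=0, rate=SPS)
        assert pa.compute_scaling_factor(w2, 120.0, 80.0) == pytest.approx(1.0)

    def test_inverted_refs_rejected(self):
        w = pa.PulseWave(samples=np.array([0.0, 40.0]), start_index=0, rate=SPS)
        with pytest.raises(ValueError):
            pa.compute_scaling_factor(w, 80.0, 120.0)

    def test_identity_scaling(self):
        w = pa.PulseWave(samples=np.array([3.0, 7.0, 5.0]), start_index=0, rate=SPS)
        out = pa.calibrate_wave(w, 1.0)
        np.testing.assert_allclose(out.samples, w.samples)
        assert out.calibrated

    def test_hand_scaling_preserves_minimum(self):
        w = pa.PulseWave(samples=np.array([10.0, 60.0]), start_index=0, rate=SPS)
        out = pa.calibrate_wave(w, 0.8)
        np.testing.assert_allclose(out.samples, [10.0, 50.0])

    def test_first_good_wave_span_equals_cuff_span(self, beats72):
        ref = pa.build_reference(beats72[:5])
        waves = pa.label_waves(list(beats72), ref, threshold=0.8)
        first = next(w for w in waves if w.usable)
        sf = pa.compute_scaling_factor(first, 120.0, 80.0)
        out = pa.calibrate_wave(first, sf)
        assert np.ptp(out.samples) == pytest.approx(40.0, abs=1e-12)


class TestFindIntersections:
    def test_hand_enumeration(self):
        w = pa.PulseWave(
            samples=np.array([0, 0.2, 0.6, 1, 0.7, 0.4, 0.1, 0]), start_index=0,
            rate=SPS,
        )
        assert pa.find_intersections(w, 0.5) == (2, 5)

    def test_symmetric_triangle(self):
        tri = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
        w = pa.PulseWave(samples=tri, start_index=0, rate=SPS)
        i1, i2 = pa.find_intersections(w, 0.5)
        peak = int(np.argmax(tri))
        # equidistant up to the one-sample asymmetry of the sign-change
        # convention: the down-crossing is the first sample strictly below
        # the level, one later than the mirrored up-crossing
        assert (i2 - peak) - (peak - i1) == 1

    def test_level_outside_range_rejected(self):
        w = pa.PulseWave(samples=np.array([0.0, 1.0, 0.0]), start_index=0, rate=SPS)
        with pytest.raises(pa.FeatureUndefinedError):
            pa.find_intersections(w, 1.5)


class TestFeatures:
    def test_amplitude_identities(self, calibrated_beat):
        f = pa.amplitude_features(calibrated_beat)
        assert f["pp"] == f["sbp_f"] - f["dbp_f"]
        assert f["sbp_f"] == calibrated_beat.samples.max()
        assert f["dbp_f"] == calibrated_beat.samples.min()
        assert f["dbp_f"] <= f["dicrotic_notch"] <= f["sbp_f"]

    def test_ap_sign_follows_reflection_timing(self, calibrated_beat):
        f = pa.amplitude_features(calibrated_beat)
        marks = pa._locate_landmarks(calibrated_beat)
        expected_sign = 1.0 if marks.pr_idx < marks.peak_idx else -1.0
        assert np.sign(f["ap"]) in (expected_sign, 0.0)
        assert abs(f["ap"]) == pytest.approx(f["sbp_f"] - f["pr"], abs=1e-12)

    def test_notch_located_at_template_trough(self, calibrated_beat):
        """The detected notch matches the generator template's own trough."""
        from scipy.signal import find_peaks

        params = PulseModelParams()
        from radarbp.synthetic import _beat_template

        g = _beat_template(params)
        gg = np.r_[g, g]
        mins, _ = find_peaks(-gg, prominence=0.02)
        mins_u = sorted({(m % g.size) / g.size for m in mins})
        foot_u = min(mins_u, key=lambda u: g[int(u * g.size)])
        notch_u = next(u for u in mins_u if u != foot_u)
        expected_wave_u = (notch_u - foot_u) % 1.0

        marks = pa._locate_landmarks(calibrated_beat)
        detected_u = marks.notch_idx / len(calibrated_beat)
        assert detected_u == pytest.approx(expected_wave_u, abs=0.05)

    def test_timing_identities(self, calibrated_beat):
        f = pa.timing_features(calibrated_beat)
        assert f["sut"] + f["dt"] == pytest.approx(
            len(calibrated_beat) / calibrated_beat.rate
        )
        marks = pa._locate_landmarks(calibrated_beat)
        assert f["sut"] == marks.peak_idx / SPS
        assert f["tr"] == marks.pr_idx / SPS

    def test_widths_match_brute_force_scan(self, calibrated_beat):
        f = pa.timing_features(calibrated_beat)
        w = calibrated_beat.samples
        peak = int(np.argmax(w))
        dbp, pp = w.min(), np.ptp(w)
        for x in pa.WIDTH_LEVELS_PCT:
            h = dbp + x / 100.0 * pp
            # independent scan: all indices where the sign flips
            signs = [1 if v >= h else -1 for v in w]
            flips = [i for i in range(1, len(w)) if signs[i] != signs[i - 1]]
            assert f[f"sw{x}"] == (peak - flips[0]) / SPS
            assert f[f"dw{x}"] == (flips[1] - peak) / SPS

    def test_width_nesting(self, calibrated_beat):
        f = pa.timing_features(calibrated_beat)
        assert f["sw75"] <= f["sw50"] <= f["sw25"] <= f["sw10"]
        assert f["dw75"] <= f["dw50"] <= f["dw25"] <= f["dw10"]

    def test_sut_matches_systolic_component_center(self, beats72):
        """SUT reflects the template's systolic peak position."""
        from radarbp.synthetic import _beat_template

        params = PulseModelParams()
        g = _beat_template(params)
        peak_u = np.argmax(g) / g.size
        foot_u = np.argmin(g) / g.size
        expected_sut = ((peak_u - foot_u) % 1.0) * (60.0 / params.heart_rate_bpm)
        ref = pa.build_reference(beats72[:5])
        waves = pa.label_waves(list(beats72), ref, 0.8)
        usable = [w for w in waves if w.usable]
        sf = pa.compute_scaling_factor(usable[0], 120, 80)
        suts = [pa.timing_features(pa.calibrate_wave(w, sf))["sut"] for w in usable[:10]]
        assert np.mean(suts) == pytest.approx(expected_sut, abs=2 / SPS + 0.01)


class TestFeatureVector:
    def test_25_inputs_plus_targets(self, calibrated_beat):
        cal = pa.CalibrationInfo(ref_sys=120, ref_dia=80, age=30, gender="male",
                                 height=180, weight=75)
        fv = pa.feature_vector(calibrated_beat, cal, target_sbp=118.0, target_dbp=79.0)
        d = fv.to_dict()
        inputs = {k: v for k, v in d.items() if k not in ("target_sbp", "target_dbp")}
        assert len(inputs) == 25
        assert d["gender"] == 1.0
        assert d["pp"] == d["sbp_f"] - d["dbp_f"]
        assert d["target_sbp"] == 118.0

    def test_gender_encoding(self):
        for gender, code in [("female", 0.0), ("male", 1.0), ("other", 0.5)]:
            cal = pa.CalibrationInfo(ref_sys=120, ref_dia=80, age=30, gender=gender,
                                     height=170, weight=60)
            assert cal.gender_encoded == code

    def test_dataframe_layout(self, calibrated_beat):
        cal = pa.CalibrationInfo(ref_sys=120, ref_dia=80, age=40, gender="female",
                                 height=165, weight=60)
        df = pa.features_dataframe([pa.feature_vector(calibrated_beat, cal)])
        assert df.shape == (1, 27)
        assert list(df.columns[:3]) == ["sbp_f", "dbp_f", "pp"]
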