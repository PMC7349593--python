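"""Feature catalogue: EMA, crossing times, exponential fits, moments."""

import numpy as np
import pytest

from enose import features
from enose.curves import CurveSegment
from enose.features import (EmaParams, FeatureId, build_feature_table,
                            crossing_time, ema_transform, extract_features,
                            fit_exponential, full_catalogue,
                            segment_features)


def make_segment(values, dt=1.0, signal="G", segment="ads"):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.shape[0]) * dt
    return CurveSegment(1, signal, segment, values, t, dt)


class TestEmaTransform:
    def test_alpha_one_returns_raw_increments(self):
        y = ema_transform(np.array([0.0, 1.0, 2.0]), 1.0, 1.0)
        assert np.allclose(y, [0.0, 1.0, 1.0])

    def test_constant_series_is_zero(self):
        y = ema_transform(np.full(50, 3.3), 1.0, 0.1)
        assert np.allclose(y, 0.0)

    def test_step_input_decays_geometrically(self):
        # hand-iterated recurrence for x = [0, 1, 1, 1, ...], alpha = 1/2
        x = np.concatenate([[0.0], np.ones(6)])
        y = ema_transform(x, 1.0, 0.5)
        assert np.allclose(y, [0.0, 0.5, 0.25, 0.125, 0.0625, 0.03125,
                               0.015625])

    def test_rejects_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            ema_transform(np.arange(5.0), 1.0, 0.0)
        with pytest.raises(ValueError):
            ema_transform(np.arange(5.0), 1.0, 1.5)


class TestCrossingTime:
    def test_linear_ramp_half_range(self):
        seg = make_segment(np.linspace(0.0, 1.0, 101), dt=0.1)
        assert crossing_time(seg, 0.5) == pytest.approx(5.0)

    def test_constant_segment_falls_back_to_zero(self):
        seg = make_segment(np.full(20, 2.0))
        assert crossing_time(seg, 0.5) == 0.0

    def test_exponential_rise_half_time_is_tau_ln2(self):
        tau = 10.0
        t = np.arange(0.0, 2000.0, 0.01)
        seg = make_segment(1.0 - np.exp(-t / tau), dt=0.01)
        assert crossing_time(seg, 0.5) == pytest.approx(tau * np.log(2),
                                                        rel=1e-3)

    def test_decaying_curve_uses_downward_range(self):
        seg = make_segment(np.linspace(1.0, 0.0, 101), dt=0.1)
        assert crossing_time(seg, 0.25) == pytest.approx(2.5)


class TestFitExponential:
    def test_noiseless_recovery(self):
        t = np.arange(0.0, 60.0, 0.2)
        y = 1.0 + (-0.5) * np.exp(-t / 20.0)
        a, tau, c = fit_exponential(make_segment(y, dt=0.2))
        assert a == pytest.approx(-0.5, rel=1e-6)
        assert tau == pytest.approx(20.0, rel=1e-6)
        assert c == pytest.approx(1.0, rel=1e-6)

    def test_constant_segment_gives_zero_amplitude(self):
        a, tau, c = fit_exponential(make_segment(np.full(50, 4.2)))
        assert a == pytest.approx(0.0, abs=1e-8)
        assert c == pytest.approx(4.2)

    def test_tau_recovered_within_ten_percent_under_noise(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 90.0, 0.2)
        y = (1.0 + 0.8 * np.exp(-t / 30.0)) * (1 + 0.01 * rng.normal(
            size=t.shape))
        _, tau, _ = fit_exponential(make_segment(y, dt=0.2))
        assert tau == pytest.approx(30.0, rel=0.10)

    def test_never_raises_on_degenerate_input(self):
        # wild oscillation: solver may fail, fallback must be returned
        seg = make_segment(np.resize([0.0, 1e6], 50))
        a, tau, c = fit_exponential(seg)
        assert np.isfinite([a, tau, c]).all()


class TestSegmentFeatures:
    def test_returns_23_values(self, fast_measurement):
        from enose.curves import baseline_normalize, segment_curve
        norm = baseline_normalize(fast_measurement)
        seg = segment_curve(norm, 1, "G", "ads")
        assert segment_features(seg).shape == (23,)

    def test_constant_segment_closed_forms(self):
        vals = segment_features(make_segment(np.ones(100), dt=1.0))
        named = dict(zip(features.FEATURE_TYPES, vals))
        assert named["mean"] == 1.0
        assert named["std"] == 0.0
        assert named["skewness"] == 0.0
        assert named["kurtosis"] == 0.0
        assert named["integral"] == 100.0
        for a in ("0.1", "0.01", "0.001"):
            assert named[f"ema_a{a}_max"] == 0.0
            assert named[f"ema_a{a}_min"] == 0.0

    def test_shift_invariance_and_equivariance(self):
        rng = np.random.default_rng(3)
        v = np.cumsum(rng.normal(size=200)) * 0.01 + 1.0
        base = segment_features(make_segment(v, dt=0.5))
        shifted = segment_features(make_segment(v + 5.0, dt=0.5))
        named_b = dict(zip(features.FEATURE_TYPES, base))
        named_s = dict(zip(features.FEATURE_TYPES, shifted))
        invariant = ["std", "skewness", "kurtosis", "deriv_max", "deriv_min",
                     "t_deriv_max_s", "t_deriv_min_s", "t_frac10_s",
                     "t_frac25_s", "t_frac50_s", "ema_a0.1_max",
                     "ema_a0.1_min", "expfit_A", "expfit_tau_s"]
        for name in invariant:
            assert named_s[name] == pytest.approx(named_b[name], rel=1e-4,
                                                  abs=1e-8), name
        assert named_s["mean"] == pytest.approx(named_b["mean"] + 5.0)
        assert named_s["final_value"] == pytest.approx(
            named_b["final_value"] + 5.0)
        assert named_s["integral"] == pytest.approx(
            named_b["integral"] + 5.0 * 200 * 0.5)
        assert named_s["expfit_c"] == pytest.approx(named_b["expfit_c"] + 5.0,
                                                    rel=1e-3)


class TestExtractFeatures:
    def test_full_catalogue_length_828(self, fast_measurement):
        vec, ids = extract_features(fast_measurement)
        assert vec.shape == (828,)
        assert len(ids) == 828

    def test_one_sensor_gives_138(self, fast_measurement):
        vec, _ = extract_features(fast_measurement, sensors=[3])
        assert vec.shape == (138,)

    def test_single_cell_gives_23(self, fast_measurement):
        vec, _ = extract_features(fast_measurement, sensors=[1],
                                  signals=["G"], segments=["ads"])
        assert vec.shape == (23,)

    def test_ids_are_unique_and_lexicographic(self, fast_measurement):
        _, ids = extract_features(fast_measurement)
        rendered = [f.render() for f in ids]
        assert len(set(rendered)) == 828
        # (sensor, signal, segment) blocks in lexicographic order
        blocks = [r.rsplit("|", 1)[0] for r in rendered[::23]]
        assert blocks == sorted(blocks)

    def test_integral_additivity_over_partition(self, fast_measurement):
        vec, ids = extract_features(fast_measurement)
        named = dict(zip((f.render() for f in ids), vec))
        for s in range(1, 7):
            for sig in ("G", "R"):
                full = named[f"S{s}|{sig}|full|integral"]
                parts = (named[f"S{s}|{sig}|ads|integral"]
                         + named[f"S{s}|{sig}|des|integral"])
                assert full == pytest.approx(parts, rel=1e-12)


class TestFeatureTable:
    def test_shape_and_metadata(self, fast_table, fast_dataset):
        assert fast_table.values.shape == (len(fast_dataset), 828)
        assert len(set(fast_table.id_strings())) == 828
        assert np.all(np.isfinite(fast_table.values))

    def test_rebuild_is_deterministic(self, fast_dataset, fast_table):
        again = build_feature_table(fast_dataset)
        assert np.array_equal(again.values, fast_table.values)

    def test_csv_roundtrip(self, tmp_path, fast_table):
        path = tmp_path / "table.csv"
        fast_table.to_csv(path)
        back = features.FeatureTable.from_csv(path)
        assert back.ids == fast_table.ids
        assert np.allclose(back.values, fast_table.values)
        assert np.array_equal(back.groups, fast_table.groups)

    def test_restrict_by_source(self, fast_table):
        g_ads = fast_table.restrict(signals=["G"], segments=["ads"])
        assert g_ads.n_features == 6 * 23
        one = fast_table.restrict(sensors=[2])
        assert one.n_features == 138
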