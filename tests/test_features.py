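import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import moxnose as mx
from moxnose.design import Process, SampleLabel, Seasoning, SensorSpec
from moxnose.features import (
    FeatureError,
    NormalizedCurve,
    area_to_extremum,
    delta_r,
    deriv_extremum,
    extract_table,
    feature_vector,
    normalize,
    total_area,
    transition_time,
)
from moxnose.simulate import AcquisitionProtocol, GeneratorParams, ResponseCurve, simulate_curve


def make_nc(t, r, polarity="n", onset=None, end=None):
    t = np.asarray(t, float)
    return NormalizedCurve(
        t=t,
        r=np.asarray(r, float),
        polarity=polarity,
        exposure_onset_s=t[0] if onset is None else onset,
        exposure_end_s=t[-1] if end is None else end,
    )


class TestNormalize:
    def test_divides_by_first_value(self):
        curve = ResponseCurve("r", "s", [0, 1, 2], [100.0, 90.0, 80.0], 0, 2)
        nc = normalize(curve)
        assert np.allclose(nc.r, [1.0, 0.9, 0.8])
        assert nc.r[0] == 1.0

    def test_constant_curve_normalizes_to_one(self):
        curve = ResponseCurve("r", "s", [0, 1, 2], [5e4] * 3, 0, 2)
        assert np.allclose(normalize(curve).r, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(c=st.floats(min_value=1e-3, max_value=1e6))
    def test_scale_invariance(self, c):
        R = np.array([100.0, 70.0, 60.0, 80.0])
        a = normalize(ResponseCurve("r", "s", np.arange(4.0), R, 0, 3))
        b = normalize(ResponseCurve("r", "s", np.arange(4.0), c * R, 0, 3))
        assert np.allclose(a.r, b.r, rtol=1e-12)

    def test_nonpositive_first_value_rejected(self):
        curve = ResponseCurve("r", "s", [0, 1], [1e-12, 1.0], 0, 1)
        curve.R[0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            normalize(curve)


class TestDeltaR:
    def test_constant_gives_zero(self):
        assert delta_r(make_nc([0, 1, 2], [1, 1, 1])) == 0.0

    def test_n_type_depth(self):
        assert delta_r(make_nc([0, 1, 2], [1.0, 0.4, 0.7])) == pytest.approx(0.6)

    def test_p_type_height(self):
        nc = make_nc([0, 1, 2], [1.0, 1.5, 1.2], polarity="p")
        assert delta_r(nc) == pytest.approx(0.5)

    def test_restricted_to_exposure_window(self):
        # the deepest point lies after the exposure; delta_r ignores it
        nc = make_nc([0, 1, 2, 3], [1.0, 0.8, 0.6, 0.2], onset=0, end=2)
        assert delta_r(nc) == pytest.approx(0.4)

    def test_empty_window_rejected(self):
        nc = make_nc([0, 1, 2], [1, 0.9, 0.8], onset=10, end=12)
        with pytest.raises(FeatureError, match="window"):
            delta_r(nc)


class TestDerivExtremum:
    def test_linear_ramp_exact(self):
        t = np.arange(0, 21.0)
        nc = make_nc(t, 1 - 0.1 * t, onset=5, end=15)
        assert deriv_extremum(nc) == pytest.approx(-0.1, rel=1e-9)

    def test_constant_gives_zero(self):
        nc = make_nc(np.arange(10.0), np.ones(10))
        assert deriv_extremum(nc) == 0.0

    def test_exponential_matches_analytic_same_scheme(self):
        # oracle: central differences applied to the analytic r(t) = e^{-t/10}
        tau = 10.0
        t = np.arange(0, 61.0)
        r = np.exp(-t / tau)
        central = (np.exp(-(t[2:]) / tau) - np.exp(-(t[:-2]) / tau)) / 2.0
        forward_at_start = np.exp(-t[1] / tau) - np.exp(-t[0] / tau)
        expected = min(np.min(central), forward_at_start)
        nc = make_nc(t, r, onset=0, end=60)
        got = deriv_extremum(nc, smooth_s=0.0)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(-1.0 / tau, rel=0.05)

    def test_p_type_takes_maximum(self):
        t = np.arange(0, 21.0)
        nc = make_nc(t, 1 + 0.05 * t, polarity="p", onset=5, end=15)
        assert deriv_extremum(nc) == pytest.approx(0.05, rel=1e-9)

    def test_recovery_spike_excluded(self, rng):
        spec = SensorSpec("RGTO_SnO2_400", "n", "RGTO", 400)
        label = SampleLabel(Seasoning.M24, Process.WR, 32.0)
        params = dataclasses.replace(GeneratorParams.default(), noise_sd=0.0, replica_cv=0.0)
        nc = normalize(simulate_curve(spec, label, params, AcquisitionProtocol(), rng))
        d = deriv_extremum(nc)
        assert d < 0  # n-type: the positive recovery spike never wins

    def test_window_too_short_rejected(self):
        nc = make_nc([0, 1, 2, 3], [1, 0.9, 0.8, 0.7], onset=1, end=2)
        with pytest.raises(FeatureError, match="short"):
            deriv_extremum(nc)


class TestAreas:
    def test_constant_curve_degenerate_window(self):
        nc = make_nc(np.arange(5.0), np.ones(5))
        assert area_to_extremum(nc) == 0.0

    def test_linear_fall_triangle(self):
        t = np.arange(0, 11.0)
        nc = make_nc(t, 1 - 0.1 * t)
        assert area_to_extremum(nc) == pytest.approx(5.0)
        assert total_area(nc) == pytest.approx(5.0)

    def test_total_area_of_constant(self):
        t = np.arange(0, 301.0)
        assert total_area(make_nc(t, np.ones(301))) == pytest.approx(300.0)

    def test_containment(self, small_dataset):
        for curve in small_dataset.curves[:32]:
            nc = normalize(curve)
            assert area_to_extremum(nc) <= total_area(nc) + 1e-9

    def test_fine_grid_oracle(self, rng, noise_free_params):
        # brute-force quadrature of the same response sampled 100x finer
        spec = SensorSpec("RGTO_SnO2_400", "n", "RGTO", 400)
        label = SampleLabel(Seasoning.M12, Process.SR, 45.0)
        coarse = AcquisitionProtocol(sample_rate_hz=1.0)
        fine = AcquisitionProtocol(sample_rate_hz=100.0)
        nc = normalize(simulate_curve(spec, label, noise_free_params, coarse, rng))
        nf = normalize(simulate_curve(spec, label, noise_free_params, fine, rng))
        assert total_area(nc) == pytest.approx(total_area(nf), rel=0.01)
        assert area_to_extremum(nc) == pytest.approx(area_to_extremum(nf), rel=0.01)


class TestTransitionTime:
    def test_linear_fall_crossings(self):
        t = np.arange(0, 11.0)
        nc = make_nc(t, 1 - 0.1 * t)
        # levels at 10% and 90% of the unit amplitude: crossings at t=1 and t=9
        assert transition_time(nc) == pytest.approx(8.0)

    def test_exponential_closed_form(self):
        tau = 10.0
        t = np.arange(0, 301.0)
        nc = make_nc(t, np.exp(-t / tau))
        assert transition_time(nc) == pytest.approx(tau * math.log(9), rel=5e-3)

    def test_p_type_mirror_symmetry(self):
        t = np.arange(0, 61.0)
        fall = 1 - 0.5 * (1 - np.exp(-t / 8.0))
        rise = 1 + 0.5 * (1 - np.exp(-t / 8.0))
        a = transition_time(make_nc(t, fall, polarity="n"))
        b = transition_time(make_nc(t, rise, polarity="p"))
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_amplitude_undefined(self):
        with pytest.raises(FeatureError, match="amplitude"):
            transition_time(make_nc(np.arange(5.0), np.ones(5)))


class TestInvariances:
    def test_features_scale_invariant_in_resistance(self, rng, noise_free_params):
        spec = SensorSpec("NW_SnO2Au_350", "n", "nanowire", 350)
        label = SampleLabel(Seasoning.M24, Process.WR, 20.0)
        curve = simulate_curve(spec, label, noise_free_params, AcquisitionProtocol(), rng)
        scaled = ResponseCurve(
            curve.replica_id, curve.sensor_id, curve.t, 37.5 * curve.R,
            curve.exposure_onset_s, curve.exposure_end_s, curve.polarity,
        )
        a = feature_vector(normalize(curve))
        b = feature_vector(normalize(scaled))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)

    def test_rate_doubling_changes_features_under_two_percent(self):
        # band-limited (smooth-onset) response: discretization robustness
        def r_of_t(t):
            gate = 1 / (1 + np.exp(-(t - 30) / 4.0))
            rec = 1 / (1 + np.exp((t - 90) / 4.0))
            depth = 0.5 * (1 - np.exp(-np.maximum(t - 30, 0) / 7.0))
            return 1 - depth * gate * rec

        out = {}
        for rate in (1.0, 2.0):
            t = np.arange(0, 300.0 + 1e-9, 1 / rate)
            out[rate] = feature_vector(
                make_nc(t, r_of_t(t), onset=30, end=90)
            )
        for k in out[1.0]:
            assert abs(out[2.0][k] - out[1.0][k]) / abs(out[1.0][k]) < 0.02, k

    def test_n_type_feature_ranges(self, small_dataset):
        duration = small_dataset.protocol.duration_s
        for curve in small_dataset.curves[:40]:
            if curve.polarity != "n":
                continue
            nc = normalize(curve)
            assert 0 <= delta_r(nc) < 1
            assert transition_time(nc) <= duration


class TestExtractTable:
    def test_shape_and_labels(self, small_manifest, small_table):
        assert small_table.shape == (len(small_manifest), 1 + 40 + 4)
        feat_cols = [c for c in small_table.columns if "." in c]
        assert len(feat_cols) == 40
        assert not small_table[feat_cols].isna().any().any()

    def test_single_replica(self, small_manifest):
        head = mx.DesignManifest(rows=small_manifest.rows[:1], provenance="custom")
        table = extract_table(mx.simulate_dataset(head, seed=0))
        assert table.shape[0] == 1
        assert len([c for c in table.columns if "." in c]) == 40

    def test_channel_permutation_invariance(self, small_manifest):
        head = mx.DesignManifest(rows=small_manifest.rows[:3], provenance="custom")
        ds = mx.simulate_dataset(head, seed=0)
        a = extract_table(ds)
        shuffled = dataclasses.replace(ds, curves=list(reversed(ds.curves)))
        b = extract_table(shuffled)
        assert list(a.columns) == list(b.columns)
        assert a.equals(b)

    def test_missing_channel_excludes_replica(self, small_manifest):
        head = mx.DesignManifest(rows=small_manifest.rows[:3], provenance="custom")
        ds = mx.simulate_dataset(head, seed=0)
        drop_rid = head.rows[1][0]
        ds = dataclasses.replace(
            ds,
            curves=[c for c in ds.curves if not (c.replica_id == drop_rid and c.sensor_id == "TGS2611")],
        )
        table = extract_table(ds)
        assert drop_rid not in set(table.replica_id)
        assert len(table) == 2

    def test_csv_roundtrip(self, tmp_path, small_table):
        from moxnose.features import read_feature_csv, write_feature_csv

        path = tmp_path / "features.csv"
        write_feature_csv(small_table, path)
        back = read_feature_csv(path)
        feat_cols = [c for c in small_table.columns if "." in c]
        assert np.allclose(back[feat_cols].to_numpy(), small_table[feat_cols].to_numpy(), rtol=1e-15)
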