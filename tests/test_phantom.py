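import dataclasses

import numpy as np
import pytest

from aosoct import (ScanProtocol, TruthParams, make_mb_series,
                    make_pressure_series, make_static_volume, true_volume)
from aosoct.phantom import (LABEL_CCE, LABEL_ISCC, LABEL_SC, NL_PER_UM3,
                            opening_fraction)

try:
    from hypothesis import given, strategies as st
    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


class TestPressureVolumeLaw:
    def test_limits(self):
        p = TruthParams()
        assert true_volume(p, 0.0) == pytest.approx(p.v_min)
        assert true_volume(p, 1e6) == pytest.approx(p.v_max, rel=1e-6)

    def test_monotone_and_bounded(self):
        p = TruthParams()
        ps = np.linspace(0, 80, 50)
        v = [true_volume(p, x) for x in ps]
        assert all(b > a for a, b in zip(v, v[1:]))
        assert all(p.v_min <= x < p.v_max for x in v)

    def test_hysteresis_ordering(self):
        p = TruthParams(hysteresis_factor=1.5)
        for pr in (5.0, 20.0, 40.0):
            assert true_volume(p, pr, "descending") > true_volume(p, pr)

    def test_no_hysteresis_when_factor_one(self):
        p = TruthParams(hysteresis_factor=1.0)
        assert true_volume(p, 20.0, "descending") == true_volume(p, 20.0)

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            true_volume(TruthParams(), -1.0)

    def test_opening_fraction_range(self):
        p = TruthParams()
        assert opening_fraction(p, 0.0) == 0.0
        assert 0 < opening_fraction(p, 30.0) < 1

    if HAVE_HYPOTHESIS:
        @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
        def test_monotone_property(self, p1, p2):
            params = TruthParams()
            lo, hi = sorted((p1, p2))
            assert true_volume(params, lo) <= true_volume(params, hi)


class TestTruthParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"v_min": 5.0, "v_max": 1.0}, {"v_min": -0.1},
        {"p_half": 0.0}, {"tau": -1.0}, {"hysteresis_factor": 0.9},
        {"speckle_looks": 0.5}, {"tm_thickness": 0.0}, {"sc_aspect": -2.0},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            TruthParams(**kwargs)

    def test_roundtrip_dict(self):
        p = TruthParams(v_max=10.0, rng_seed=3)
        assert TruthParams.from_dict(p.to_dict()) == p


class TestStaticVolume:
    def test_shapes_and_metadata(self, volume_30, small_protocol):
        vol, truth = volume_30
        shape = (small_protocol.n_bscans, small_protocol.n_alines,
                 small_protocol.n_depth)
        assert vol.intensity.shape == shape
        assert truth.masks.shape == shape
        assert vol.intensity.dtype == np.float32
        assert truth.masks.dtype == np.uint8
        assert vol.pressure == 30.0
        assert vol.metadata["seed"] == 11

    def test_labels_present(self, volume_30):
        _, truth = volume_30
        present = set(np.unique(truth.masks))
        assert {0, LABEL_SC, LABEL_CCE, LABEL_ISCC} <= present

    def test_truth_volume_matches_mask_integral(self, small_protocol,
                                                noiseless_volume_30):
        """Brute-force voxel integral of the SC truth mask matches the
        analytic pressure-volume law within discretization error."""
        vol, truth = noiseless_volume_30
        voxel_nl = (small_protocol.pitch_y * small_protocol.pitch_x *
                    small_protocol.pitch_z) * NL_PER_UM3
        v_mask = np.count_nonzero(truth.masks == LABEL_SC) * voxel_nl
        assert v_mask == pytest.approx(truth.true_volume, rel=0.05)

    def test_determinism(self, small_protocol, default_params):
        a, _ = make_static_volume(small_protocol, default_params, 30.0)
        b, _ = make_static_volume(small_protocol, default_params, 30.0)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_seed_changes_noise_not_truth(self, small_protocol):
        a, ta = make_static_volume(small_protocol, TruthParams(rng_seed=1), 30.0)
        b, tb = make_static_volume(small_protocol, TruthParams(rng_seed=2), 30.0)
        assert not np.array_equal(a.intensity, b.intensity)
        np.testing.assert_array_equal(ta.masks, tb.masks)

    def test_noiseless_is_piecewise_clean(self, noiseless_volume_30,
                                          default_params):
        vol, truth = noiseless_volume_30
        sc = truth.masks == 1
        assert np.allclose(vol.intensity[sc], default_params.lumen_intensity)

    def test_speckle_statistics(self, small_protocol):
        """Multiplicative gamma speckle is mean-preserving in flat regions."""
        params = TruthParams(rng_seed=4, noise_floor_sigma=0.0)
        vol, truth = make_static_volume(small_protocol, params, 30.0)
        sc = truth.masks == 1
        vals = vol.intensity[sc]
        assert vals.mean() == pytest.approx(params.lumen_intensity, rel=0.05)
        # L=4 looks: relative std = 1/sqrt(L) = 0.5
        assert vals.std() / vals.mean() == pytest.approx(0.5, rel=0.15)

    def test_seed_points_center_in_truth(self, volume_30):
        _, truth = volume_30
        pts = truth.seed_points(8)
        assert set(pts) == {"SC", "CCE", "ISCC"}
        x, z = pts["SC"]
        assert truth.masks[8, x, z] == LABEL_SC

    def test_geometry_guard(self, small_protocol):
        with pytest.raises(ValueError, match="exceeds"):
            make_static_volume(small_protocol,
                               TruthParams(v_max=5000.0), 30.0)


class TestPressureSeries:
    def test_loop_structure(self, small_protocol, default_params):
        pressures = [5.0, 15.0, 30.0]
        out = make_pressure_series(small_protocol, default_params, pressures,
                                   loop=True)
        assert len(out) == 6
        assert [v.pressure for v, _ in out] == pressures + pressures[::-1]
        assert [v.metadata["direction"] for v, _ in out] == \
            ["ascending"] * 3 + ["descending"] * 3

    def test_descending_truth_larger(self, small_protocol, default_params):
        out = make_pressure_series(small_protocol, default_params,
                                   [15.0], loop=True)
        (_, asc), (_, desc) = out
        assert desc.true_volume > asc.true_volume

    def test_empty_pressures_raise(self, small_protocol, default_params):
        with pytest.raises(ValueError):
            make_pressure_series(small_protocol, default_params, [])


class TestMBSeries:
    def test_truth_trace_first_order(self, mb_small):
        protocol, series, truth = mb_small
        assert series.frames.shape[0] == protocol.n_frames == 300
        h = truth.true_height_trace
        t = series.times_ms
        sel = t >= series.switch_time
        tau = 15.0
        expected = h[0] + (h[-1] - h[0]) * (
            1 - np.exp(-(t[sel] - series.switch_time) / tau)) / (
            1 - np.exp(-(t[sel][-1] - series.switch_time) / tau))
        np.testing.assert_allclose(h[sel], expected, rtol=1e-6)
        assert np.all(h[~sel] == h[0])

    def test_onset_frame_is_first_moved_frame(self, mb_small):
        _, series, truth = mb_small
        h = truth.true_height_trace
        assert truth.onset_frame == np.nonzero(h != h[0])[0][0]

    def test_no_step_no_onset(self, default_params):
        protocol = ScanProtocol(n_bscans=2, n_alines=180, mb_duration=0.5)
        _, truth = make_mb_series(protocol, default_params, 10.0, 10.0, 100.0)
        assert truth.onset_frame is None
        assert np.ptp(truth.true_height_trace) == 0

    def test_switch_outside_record_rejected(self, default_params):
        protocol = ScanProtocol(n_bscans=2, n_alines=180, mb_duration=0.5)
        with pytest.raises(ValueError):
            make_mb_series(protocol, default_params, 0.0, 30.0, 9999.0)

    def test_determinism(self, default_params):
        protocol = ScanProtocol(n_bscans=2, n_alines=180, mb_duration=0.25)
        a, _ = make_mb_series(protocol, default_params, 0.0, 30.0, 100.0)
        b, _ = make_mb_series(protocol, default_params, 0.0, 30.0, 100.0)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_speckle_independent_per_frame(self, default_params):
        protocol = ScanProtocol(n_bscans=2, n_alines=180, mb_duration=0.25)
        series, _ = make_mb_series(protocol, default_params, 10.0, 10.0, 100.0)
        assert not np.array_equal(series.frames[0], series.frames[1])
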