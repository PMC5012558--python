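import numpy as np
import pytest

from aosoct import (ScanProtocol, SeedPoint, SegParams, TruthParams, dice,
                    detect_tm_surface, make_static_volume, propagate_mb,
                    propagate_volume, segment_bscan)
from aosoct.phantom import LABEL_NAMES, make_mb_series

try:
    from hypothesis import given, strategies as st
    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


class TestSeedAndParams:
    def test_invalid_label(self):
        with pytest.raises(ValueError):
            SeedPoint("XYZ", 1, 1)

    @pytest.mark.parametrize("kwargs", [
        {"threshold_method": "magic"}, {"threshold_percentile": 0.0},
        {"threshold_percentile": 1.5}, {"min_region": 0},
        {"connectivity": 5},
    ])
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            SegParams(**kwargs)


class TestTMSurface:
    def test_flat_surface_recovered(self, noiseless_volume_30,
                                    small_protocol, noiseless_params):
        vol, _ = noiseless_volume_30
        surf = detect_tm_surface(vol.intensity[0])
        # TM top is at tm_top_um for every A-line
        expected = noiseless_params.tm_top_um / small_protocol.pitch_z
        assert np.all(np.abs(surf - expected) <= 2)

    def test_noisy_surface_within_tolerance(self, volume_30, small_protocol,
                                            default_params):
        vol, _ = volume_30
        surf = detect_tm_surface(vol.intensity[0])
        expected = default_params.tm_top_um / small_protocol.pitch_z
        assert np.median(np.abs(surf - expected)) <= 3

    def test_no_bright_band_raises(self):
        with pytest.raises(ValueError):
            detect_tm_surface(np.zeros((32, 64)))


class TestSegmentBscan:
    def _seeds(self, truth, plane):
        return [SeedPoint(lb, x, z, y_or_frame=plane)
                for lb, (x, z) in truth.seed_points(plane).items()]

    def test_single_plane_dice(self, volume_30):
        vol, truth = volume_30
        plane = 8
        out = segment_bscan(vol.intensity[plane], self._seeds(truth, plane))
        for m in out:
            d = dice(m.mask, truth.masks[plane] == LABEL_NAMES[m.label])
            assert d >= 0.85, (m.label, d)

    def test_masks_disjoint_after_watershed(self, volume_30):
        """SC and the connected CCE channel must be separated."""
        vol, truth = volume_30
        plane = 8
        out = segment_bscan(vol.intensity[plane], self._seeds(truth, plane))
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert not np.any(out[i].mask & out[j].mask)

    def test_masks_below_surface(self, volume_30):
        vol, truth = volume_30
        plane = 8
        surf = detect_tm_surface(vol.intensity[plane])
        out = segment_bscan(vol.intensity[plane], self._seeds(truth, plane))
        for m in out:
            xs, zs = np.nonzero(m.mask)
            assert np.all(zs > surf[xs])

    def test_bright_seed_yields_empty_mask(self, volume_30):
        vol, _ = volume_30
        # a seed inside the bright TM band
        seed = SeedPoint("SC", 90, 140)
        (m,) = segment_bscan(vol.intensity[0], [seed])
        assert m.is_empty

    def test_scale_invariance(self, volume_30):
        """The local threshold tracks positive rescaling of the image."""
        vol, truth = volume_30
        plane = 8
        seeds = self._seeds(truth, plane)
        a = segment_bscan(vol.intensity[plane], seeds)
        b = segment_bscan(vol.intensity[plane] * 7.5, seeds)
        for ma, mb in zip(a, b):
            assert dice(ma.mask, mb.mask) >= 0.99

    def test_percentile_method_runs(self, volume_30):
        vol, truth = volume_30
        plane = 8
        params = SegParams(threshold_method="percentile")
        out = segment_bscan(vol.intensity[plane], self._seeds(truth, plane),
                            params)
        assert len(out) == 3


class TestPropagation:
    def test_dice_against_truth(self, volume_30, segmented_30):
        _, truth = volume_30
        for lb, code in LABEL_NAMES.items():
            d = dice(segmented_30.stack(lb), truth.masks == code)
            assert d >= 0.9, (lb, d)

    def test_one_mask_per_plane(self, volume_30, segmented_30):
        vol, _ = volume_30
        n = vol.intensity.shape[0]
        for lb, ms in segmented_30.masks.items():
            assert len(ms) == n
            assert [m.y_or_frame for m in ms] == list(range(n))

    def test_duplicate_seed_labels_rejected(self, volume_30):
        vol, _ = volume_30
        seeds = [SeedPoint("SC", 90, 180), SeedPoint("SC", 91, 181)]
        with pytest.raises(ValueError, match="duplicate"):
            propagate_volume(vol, seeds)

    def test_reference_out_of_range(self, volume_30):
        vol, _ = volume_30
        with pytest.raises(ValueError):
            propagate_volume(vol, [SeedPoint("SC", 90, 180)], reference=999)

    def test_gap_rule_stops_spatial_sweep(self, small_protocol):
        """An SC closed over > max_gap planes halts the sweep with a warning."""
        vol, truth = make_static_volume(small_protocol,
                                        TruthParams(rng_seed=5), 30.0)
        ref = 8
        seeds = [SeedPoint("SC", *truth.seed_points(ref)["SC"],
                           y_or_frame=ref)]
        res = propagate_volume(vol, seeds, max_gap=0,
                               params=SegParams(min_region=10 ** 6))
        # every non-reference plane is empty and the sweep reports the stop
        assert all(m.is_empty for m in res.masks["SC"])
        assert any("stopped" in w for w in res.warnings)


class TestPropagateMB:
    def test_closed_baseline_recovers_after_step(self, mb_small):
        """A lumen closed at baseline must still be picked up post-step."""
        protocol, series, truth = mb_small
        last = series.frames.shape[0] - 1
        x, z = truth.seed_points(last)["SC"]
        res = propagate_mb(series, [SeedPoint("SC", x, z, y_or_frame=0)])
        areas = np.array([m.area_voxels() for m in res.masks["SC"]])
        switch_frame = int(series.switch_time / series.frame_interval)
        assert areas[:switch_frame].max() <= areas[switch_frame + 20:].min()
        assert areas[switch_frame + 20:].min() > 0

    def test_mb_dice_post_step(self, mb_small):
        protocol, series, truth = mb_small
        last = series.frames.shape[0] - 1
        seeds = [SeedPoint(lb, x, z, y_or_frame=0)
                 for lb, (x, z) in truth.seed_points(last).items()]
        res = propagate_mb(series, seeds)
        post = slice(100, None)  # settled region
        d = dice(res.stack("SC")[post], (truth.masks == 1)[post])
        assert d >= 0.9


class TestDice:
    def test_identity_and_disjoint(self):
        a = np.zeros((4, 4), bool)
        a[1:3, 1:3] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        assert dice(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 1.0

    if HAVE_HYPOTHESIS:
        @given(st.integers(0, 2 ** 16 - 1), st.integers(0, 2 ** 16 - 1))
        def test_symmetry_and_range(self, seed_a, seed_b):
            rng_a = np.random.default_rng(seed_a)
            rng_b = np.random.default_rng(seed_b)
            a = rng_a.random((8, 8)) > 0.5
            b = rng_b.random((8, 8)) > 0.5
            d = dice(a, b)
            assert 0.0 <= d <= 1.0
            assert d == dice(b, a)
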