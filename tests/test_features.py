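"""Dominant frequency, phase singularities, PSD maps, and GT labels."""

import math

import numpy as np
import pytest

from fibrotwin import ep, features
from fibrotwin.features import (FeatureStack, OutcomeLabel,
                                build_feature_stack, dominant_frequency_map,
                                find_phase_singularities, ground_truth_label,
                                last_peak_fractions, phase_and_singularities,
                                psd_map)
from fibrotwin.remodeling import STRATEGY_ORDER


def make_result(volts_fn, shape=(8, 8), duration_ms=2000.0, down_ms=1.0):
    """SimulationResult with per-node voltage traces from volts_fn(t_ms, y, x)."""
    n_frames = int(duration_ms / down_ms) + 1
    t = np.arange(n_frames) * down_ms
    y, x = np.mgrid[0:shape[0], 0:shape[1]]
    volts = volts_fn(t[:, None, None], y[None], x[None]).astype(np.float32)
    return ep.SimulationResult(
        voltages=[volts], last_activation=[np.zeros(shape)],
        conducting=[np.ones(shape, bool)], duration_ms=duration_ms,
        dt_ms=0.02, downsample_ms=down_ms, sheet_names=["LA"])


class TestDominantFrequency:
    def test_pure_sinusoid(self):
        res = make_result(lambda t, y, x: 40 * np.sin(2 * math.pi * 7 * t / 1000)
                          + 0 * y)
        df = dominant_frequency_map(res)
        assert np.allclose(df, 7.0, atol=0.5)

    def test_above_cap_excluded(self):
        res = make_result(lambda t, y, x: (
            50 * np.sin(2 * math.pi * 25 * t / 1000)
            + 10 * np.sin(2 * math.pi * 6 * t / 1000) + 0 * y))
        df = dominant_frequency_map(res)
        assert np.allclose(df, 6.0, atol=0.5)

    def test_action_potential_train(self):
        # upstrokes every 250 ms -> 4 Hz
        def ap(t, y, x):
            return np.where((t % 250) < 100, 10.0, -80.0) + 0 * y
        df = dominant_frequency_map(make_result(ap))
        assert np.allclose(df, 4.0, atol=0.5)

    def test_quiescent_node_zero(self):
        res = make_result(lambda t, y, x: np.full_like(t + y + x, -80.0,
                                                       dtype=float))
        assert np.all(dominant_frequency_map(res) == 0.0)

    def test_cap_respected_everywhere(self, rng):
        res = make_result(lambda t, y, x: 40 * np.sin(
            2 * math.pi * (5 + 3 * y) * t / 1000))
        assert dominant_frequency_map(res).max() <= features.DEFAULT_F_MAX_HZ

    def test_short_trace_rejected(self):
        res = make_result(lambda t, y, x: 0 * (t + y + x), duration_ms=500.0)
        with pytest.raises(ValueError):
            dominant_frequency_map(res)


from tests_oracles import brute_force_winding


class TestPhaseSingularities:
    def test_ideal_vortex(self):
        y, x = np.mgrid[0:32, 0:32]
        phase = np.arctan2(y - 15.5, x - 15.5)
        ps = find_phase_singularities(phase)
        assert len(ps) == 1
        r, c, q = ps[0]
        assert q == 1
        assert abs(r - 15.5) <= 1 and abs(c - 15.5) <= 1

    def test_uniform_phase_none(self):
        assert find_phase_singularities(np.full((16, 16), 0.3)) == []

    def test_figure_of_eight_matches_brute_force(self):
        y, x = np.mgrid[0:32, 0:32]
        phase = np.angle(np.exp(1j * (np.arctan2(y - 15.5, x - 7.5)
                                      - np.arctan2(y - 15.5, x - 23.5))))
        ps = find_phase_singularities(phase)
        assert sorted(ps) == sorted(brute_force_winding(phase))
        assert len(ps) == 2
        assert sum(q for _, _, q in ps) == 0

    def test_matches_brute_force_on_spiral_fields(self):
        for seed in range(3):
            rngl = np.random.default_rng(seed)
            cores = [(rngl.uniform(8, 24), rngl.uniform(8, 24))
                     for _ in range(2)]
            phase = ep.spiral_phase_field((32, 32), cores)
            assert sorted(find_phase_singularities(phase)) == \
                sorted(brute_force_winding(phase))

    def test_frame_out_of_range(self):
        res = make_result(lambda t, y, x: 0.0 * (t + y + x),
                          duration_ms=1500.0)
        with pytest.raises(IndexError):
            phase_and_singularities(res, 10 ** 6)


class TestPsdMap:
    def test_quiescent_all_zero(self):
        res = make_result(lambda t, y, x: np.full_like(t + y + x, -80.0,
                                                       dtype=float))
        assert np.all(psd_map(res) == 0)

    def test_stationary_rotor_counts_and_mass(self):
        # rotating vortex: phase singularity fixed at the grid center
        def vortex(t, y, x):
            return 40 * np.cos(np.arctan2(y - 7.5, x - 7.5)
                               - 2 * math.pi * 5 * t / 1000) + 0.0
        res = make_result(vortex, shape=(16, 16), duration_ms=1200.0)
        raw = psd_map(res, smoothing_sigma=0)
        # detections live on the four plaquette corners around the center
        total = raw.sum()
        n_frames = res.voltages[0].shape[0]
        assert total >= 0.9 * n_frames
        core = raw[6:10, 6:10].sum()
        assert core == total  # all mass at the fixed core

    def test_mass_conserved_before_smoothing(self):
        def vortex(t, y, x):
            return 40 * np.cos(np.arctan2(y - 7.5, x - 7.5)
                               - 2 * math.pi * 5 * t / 1000) + 0.0
        res = make_result(vortex, shape=(16, 16), duration_ms=1200.0)
        ph = features.phase_map(res.voltages[0])
        detections = sum(len(find_phase_singularities(ph[f]))
                         for f in range(ph.shape[0]))
        assert psd_map(res, smoothing_sigma=0).sum() == pytest.approx(detections)

    def test_too_few_frames(self):
        res = make_result(lambda t, y, x: 0.0 * (t + y + x), duration_ms=5.0)
        with pytest.raises(ValueError):
            psd_map(res)


class TestGroundTruth:
    @staticmethod
    def result_with_last_activity(frac_active, duration_ms=1000.0):
        """All nodes beat until frac_active of the duration, then go silent."""
        def fn(t, y, x):
            beating = 40 * np.sign(np.sin(2 * math.pi * 5 * t / 1000)) - 40
            return np.where(t <= frac_active * duration_ms, beating, -80.0) \
                + 0 * y
        return make_result(fn, duration_ms=duration_ms)

    def make_all(self, frac):
        return {s: self.result_with_last_activity(frac) for s in STRATEGY_ORDER}

    def test_early_silence_terminated(self):
        labels = ground_truth_label(self.make_all(0.5))
        assert all(lab.terminated for lab in labels.values())
        assert all(lab.mean_last_peak_fraction <= 0.6
                   for lab in labels.values())

    def test_persistent_activity_sustained(self):
        labels = ground_truth_label(self.make_all(0.98))
        assert not any(lab.terminated for lab in labels.values())

    def test_missing_strategy_rejected(self):
        partial = self.make_all(0.5)
        partial.pop(STRATEGY_ORDER[-1])
        with pytest.raises(KeyError):
            ground_truth_label(partial)

    def test_boundary_inclusive(self):
        lab = OutcomeLabel(terminated=True, mean_last_peak_fraction=0.6)
        assert lab.terminated
        with pytest.raises(ValueError):
            OutcomeLabel(terminated=False, mean_last_peak_fraction=0.6)

    def test_silent_nodes_count_zero(self):
        res = self.result_with_last_activity(0.9)
        # silence half the sheet entirely
        res.voltages[0][:, :, :4] = -80.0
        fracs = last_peak_fractions(res)[0]
        assert np.all(fracs[:, :4] == 0.0)
        assert np.all(fracs[:, 4:] > 0.6)


class TestFeatureStack:
    def test_assembly_and_normalization(self, rng):
        shape = (24, 24)
        fib = rng.uniform(0, 2, shape)
        psd = rng.uniform(0, 7, shape)
        df = rng.uniform(0, 12, shape)
        stack = build_feature_stack(fib, np.zeros(shape), fib > 1.22,
                                    psd, df, "LA")
        assert stack.channels.shape == (5, 24, 24)
        assert stack.channels[2].max() == pytest.approx(1.0)
        assert stack.channels[3].max() <= 1.0
        assert stack.channels[4].max() <= 1.0
        assert set(np.unique(stack.channels[1])) <= {0.0, 1.0}

    def test_empty_psd_handled(self):
        shape = (8, 8)
        stack = build_feature_stack(np.ones(shape), np.zeros(shape),
                                    np.zeros(shape), np.zeros(shape),
                                    np.zeros(shape), "RA")
        assert np.all(stack.channels[2] == 0)

    def test_five_channel_invariant(self, rng):
        with pytest.raises(ValueError):
            FeatureStack(rng.uniform(0, 1, (4, 8, 8)), "LA", {})
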