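"""Envelope chain: channel repair, high-pass, moving average, normalization."""

import numpy as np
import pytest
from scipy import signal as sps

from emgforce import (
    EnvelopeMatrix,
    MuscleModel,
    ForceProfile,
    envelope,
    highpass,
    normalize_cycle,
    preprocess_cycle,
    repair_bad_channels,
    synthesize_cycle,
)
from emgforce.synthetic import GRID_COLS


def _active_grid(rng, n=2000, scale=1.0):
    return scale * rng.standard_normal((32, n))


class TestRepairBadChannels:
    def test_clean_grid_untouched(self, rng):
        raw = _active_grid(rng)
        repaired, flags = repair_bad_channels(raw)
        assert flags == []
        np.testing.assert_array_equal(repaired, raw)

    def test_dead_channel_flagged_and_replaced(self, rng):
        raw = _active_grid(rng)
        raw[10] = 0.0
        repaired, flags = repair_bad_channels(raw)
        assert flags == [10]
        assert np.abs(repaired[10]).max() > 0

    def test_saturated_channel_neighbor_mean(self, rng):
        """A channel 10x above the ceiling is replaced by the hand-computed
        sample-wise mean of its valid 4-neighbors on the 4x8 grid."""
        raw = _active_grid(rng)
        hi = 100.0
        raw[12] = 10.0 * hi  # row 1, col 4: neighbors 4, 20, 11, 13
        repaired, flags = repair_bad_channels(raw, lo=1e-7, hi=hi)
        assert flags == [12]
        expected = raw[[12 - GRID_COLS, 12 + GRID_COLS, 11, 13]].mean(axis=0)
        np.testing.assert_allclose(repaired[12], expected, rtol=1e-12)

    def test_corner_channel_uses_existing_neighbors(self, rng):
        raw = _active_grid(rng)
        raw[0] = 0.0  # corner: neighbors are channels 8 and 1 only
        repaired, flags = repair_bad_channels(raw)
        expected = raw[[GRID_COLS, 1]].mean(axis=0)
        np.testing.assert_allclose(repaired[0], expected, rtol=1e-12)

    def test_variance_outlier_flagged(self, rng):
        raw = _active_grid(rng)
        raw[5] = 40.0 * rng.standard_normal(raw.shape[1])  # in-range but wild
        _, flags = repair_bad_channels(raw, lo=1e-7, hi=1e6)
        assert 5 in flags

    def test_all_bad_unrecoverable(self):
        with pytest.raises(ValueError, match="unrecoverable"):
            repair_bad_channels(np.zeros((32, 100)))


class TestHighpass:
    def test_dc_rejected(self):
        x = np.full(4000, 3.0)
        out = highpass(x, 1000.0)
        assert np.abs(out).max() < 1e-6 * 3.0

    def test_passband_and_stopband_gain(self):
        """Designed filter response: ~unity at 50 Hz, < 0.1 at 5 Hz."""
        from emgforce.preprocessing import highpass_taps
        taps = highpass_taps(1000.0)
        w, h = sps.freqz(taps, worN=[5.0, 50.0], fs=1000.0)
        assert abs(h[1]) == pytest.approx(1.0, abs=0.05)
        assert abs(h[0]) < 0.1

    def test_applied_gain_at_50hz(self):
        t = np.arange(6000) / 1000.0
        out = highpass(np.sin(2 * np.pi * 50.0 * t), 1000.0)
        amp = np.abs(out[1000:-1000]).max()
        assert 0.9 < amp < 1.1  # forward-backward squares the design response

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            highpass(np.ones(100), 1000.0)

    def test_zero_phase_alignment(self, clean_cycle):
        """Envelope of a filtered clean channel stays time-aligned with the
        ground-truth activation (lag 0 +/- 1 sample)."""
        ch = clean_cycle.grids[0].values[0]
        env = envelope(highpass(ch, 1000.0), 1000.0)
        act = clean_cycle.true_activations[0]
        e = env - env.mean()
        a = act - act.mean()
        lags = np.arange(-5, 6)
        xc = [np.dot(e[max(0, k):len(e) + min(0, k)], a[max(0, -k):len(a) - max(0, k)]) for k in lags]
        assert abs(lags[int(np.argmax(xc))]) <= 1


class TestEnvelope:
    def test_constant_passthrough(self):
        out = envelope(np.full(500, -2.5), 1000.0)
        np.testing.assert_allclose(out, 2.5, rtol=1e-12)

    def test_all_zero(self):
        assert np.all(envelope(np.zeros(300), 1000.0) == 0.0)

    def test_mean_of_abs_sine(self):
        """100 ms window over a 100 Hz sinusoid spans integer periods, so the
        interior envelope equals mean|sin| = 2/pi within 2 %."""
        t = np.arange(50_000) / 10_000.0  # fine sampling so the discrete
        out = envelope(np.sin(2 * np.pi * 100.0 * t), 10_000.0, 100.0)  # mean matches the integral
        interior = out[2000:-2000]
        np.testing.assert_allclose(interior, 2.0 / np.pi, rtol=0.02)

    def test_output_bounded_by_peak(self, rng):
        x = rng.standard_normal(1000)
        out = envelope(x, 1000.0)
        assert np.all(out >= 0.0)
        assert out.max() <= np.abs(x).max() + 1e-12

    def test_matches_shrinking_window_oracle(self, rng):
        """Brute-force centered mean with edge shrinkage."""
        x = rng.standard_normal(257)
        win = 100
        out = envelope(x, 1000.0, 100.0)
        rect = np.abs(x)
        left = (win - 1) // 2
        expected = np.array(
            [rect[max(0, i + left + 1 - win): i + left + 1].mean() for i in range(x.size)]
        )
        np.testing.assert_allclose(out, expected, rtol=1e-12)


class TestNormalizeCycle:
    def _envs(self, rng, scale=1.0):
        return [
            EnvelopeMatrix(values=scale * np.abs(rng.standard_normal((32, 200))), grid_id=g, rate_hz=1000.0)
            for g in range(4)
        ]

    def test_force_max_becomes_one(self, rng):
        envs = self._envs(rng)
        _, force = normalize_cycle(envs, 42.0 * np.abs(rng.standard_normal(200)))
        assert force.max() == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        force = np.abs(np.random.default_rng(0).standard_normal(200))
        envs = self._envs(rng)
        scaled = [
            EnvelopeMatrix(values=7.0 * e.values, grid_id=e.grid_id, rate_hz=e.rate_hz)
            for e in envs
        ]
        n1, _ = normalize_cycle(envs, force)
        n2, _ = normalize_cycle(scaled, force)
        for a, b in zip(n1, n2):
            np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_single_global_maximum(self, rng):
        envs = self._envs(rng)
        normed, _ = normalize_cycle(envs, np.abs(rng.standard_normal(200)) + 0.1)
        stacked = np.concatenate([e.values.ravel() for e in normed])
        assert stacked.max() == pytest.approx(1.0)
        assert int((stacked == stacked.max()).sum()) == 1

    def test_degenerate_inputs_rejected(self, rng):
        envs = self._envs(rng)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_cycle(envs, np.zeros(200))
        silent = [
            EnvelopeMatrix(values=np.zeros((32, 200)), grid_id=g, rate_hz=1000.0)
            for g in range(4)
        ]
        with pytest.raises(ValueError, match="degenerate"):
            normalize_cycle(silent, np.ones(200))


class TestPipeline:
    def test_scale_equivariance_end_to_end(self):
        """Pre-scaling the raw recording leaves normalized envelopes unchanged."""
        model = MuscleModel(seed=21)
        cyc = synthesize_cycle(model, ForceProfile(duration_s=2.0), seed=21)
        envs1, force1, _ = preprocess_cycle(cyc)
        scaled = type(cyc)(
            force=cyc.force,
            target_force=cyc.target_force,
            grids=tuple(
                type(g)(values=5.0 * g.values, grid_id=g.grid_id, muscle=g.muscle, rate_hz=g.rate_hz)
                for g in cyc.grids
            ),
            rate_hz=cyc.rate_hz,
            level=cyc.level,
        )
        envs2, force2, _ = preprocess_cycle(scaled)
        np.testing.assert_allclose(force1, force2, rtol=1e-12)
        for a, b in zip(envs1, envs2):
            np.testing.assert_allclose(a.values, b.values, rtol=1e-9)

    def test_bad_channel_repaired_in_pipeline(self):
        model = MuscleModel(seed=22, bad_channels=((2, 7),))
        cyc = synthesize_cycle(model, ForceProfile(duration_s=2.0), seed=22)
        envs, _, repaired = preprocess_cycle(cyc)
        assert 7 in repaired[2]
        assert envs[2].values.max() <= 1.0
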