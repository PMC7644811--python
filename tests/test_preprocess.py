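"""Tests of the envelope / normalization / time-normalization chain."""

import numpy as np
import pytest
from scipy import signal

from synlab import preprocess, synthetic
from synlab.datatypes import EnvelopeMatrix, GaitCycleTimes, RawEmgRecording


def _raw(samples, fs=2000.0):
    return RawEmgRecording(samples=samples, fs=fs)


class TestEnvelope:
    def test_zero_channel_stays_zero(self, rng):
        x = rng.standard_normal((13, 4000))
        x[4] = 0.0
        env = preprocess.envelope(_raw(x))
        np.testing.assert_allclose(env.values[4], 0.0, atol=1e-12)

    def test_sinusoid_envelope_level_and_ripple(self):
        # a 100 Hz unit sinusoid: the envelope should sit at the
        # rectified mean 2/pi scaled by the high-pass magnitude
        # response (applied twice, forward-backward) at 100 Hz
        fs = 2000.0
        t = np.arange(int(4 * fs)) / fs
        x = np.tile(np.sin(2 * np.pi * 100 * t), (13, 1))
        env = preprocess.envelope(_raw(x, fs)).values[0]
        sos_hp = signal.butter(2, 50.0, btype="highpass", fs=fs, output="sos")
        w, h = signal.sosfreqz(sos_hp, worN=[100.0], fs=fs)
        expected = 2.0 / np.pi * np.abs(h[0]) ** 2
        interior = env[1000:-1000]
        assert interior.mean() == pytest.approx(expected, rel=0.02)
        ripple = (interior.max() - interior.min()) / interior.mean()
        assert ripple < 0.05

    def test_matches_independent_filter_chain(self, rng):
        # same chain built from transfer-function filtfilt as oracle
        fs = 2000.0
        x = rng.standard_normal((13, 6000))
        env = preprocess.envelope(_raw(x, fs)).values

        b_hp, a_hp = signal.butter(2, 50.0, btype="highpass", fs=fs)
        b_lp, a_lp = signal.butter(2, 20.0, btype="lowpass", fs=fs)
        ref = signal.filtfilt(b_hp, a_hp, x, axis=1)
        ref = np.abs(ref)
        ref = signal.filtfilt(b_lp, a_lp, ref, axis=1)
        ref = np.clip(ref, 0.0, None)
        rms = np.sqrt(np.mean((env - ref) ** 2))
        assert rms < 1e-9 * np.sqrt(np.mean(ref**2))

    def test_rejects_nan_and_low_fs(self, rng):
        x = rng.standard_normal((13, 1000))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            preprocess.envelope(_raw(x))
        with pytest.raises(ValueError, match="too low"):
            preprocess.envelope(_raw(rng.standard_normal((13, 1000)), fs=80.0))


class TestNormalizeAmplitude:
    def test_affine_example(self):
        v = np.tile([2.0, 4.0, 6.0], (13, 1))
        out = preprocess.normalize_amplitude(EnvelopeMatrix(values=v, fs=2000.0))
        np.testing.assert_allclose(out.values[0], [0.0, 0.5, 1.0])

    def test_constant_channel_warns_and_zeroes(self):
        v = np.ones((13, 10)) * 3.0
        v[1:] = np.linspace(0, 1, 10)
        with pytest.warns(UserWarning, match="constant"):
            out = preprocess.normalize_amplitude(EnvelopeMatrix(values=v, fs=2000.0))
        np.testing.assert_allclose(out.values[0], 0.0)

    def test_range_and_idempotence(self, rng):
        v = rng.random((13, 500)) * 5 + 1
        once = preprocess.normalize_amplitude(EnvelopeMatrix(values=v, fs=2000.0))
        twice = preprocess.normalize_amplitude(once)
        np.testing.assert_allclose(once.values.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(once.values.max(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)


class TestTimeNormalize:
    @staticmethod
    def _events(n_cycles, cycle=1.0, stance=0.6):
        td = np.arange(n_cycles + 1) * cycle
        return GaitCycleTimes(touchdown=td, stance_duration=np.full(n_cycles + 1, stance))

    def test_linear_ramp_maps_to_linear_ramp(self):
        fs = 2000.0
        ev = self._events(2)
        t = np.arange(int(2.5 * fs)) / fs
        env = EnvelopeMatrix(values=np.tile(t, (13, 1)), fs=fs)
        out = preprocess.time_normalize(env, ev, max_cycles=2)
        stance = out.values[0, :100]
        # linear interpolation of a ramp stays an exact ramp
        np.testing.assert_allclose(np.diff(stance), np.diff(stance)[0], rtol=1e-9)
        assert stance[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_cycles, expected_cols", [(35, 6000), (21, 4200)])
    def test_thirty_cycle_cap_and_short_trials(self, rng, n_cycles, expected_cols):
        fs = 500.0
        ev = self._events(n_cycles)
        n = int((ev.touchdown[-1] + 0.5) * fs)
        env = EnvelopeMatrix(values=rng.random((13, n)), fs=fs)
        out = preprocess.time_normalize(env, ev)
        assert out.values.shape == (13, expected_cols)
        assert out.n_cycles == expected_cols // 200

    def test_boundary_outside_recording_rejected(self, rng):
        ev = self._events(5)
        env = EnvelopeMatrix(values=rng.random((13, 600)), fs=200.0)  # 3 s < 5 cycles
        with pytest.raises(ValueError, match="outside"):
            preprocess.time_normalize(env, ev)

    def test_band_limited_extrema_preserved(self):
        # slowly varying signal: per-cycle max within 1% after resampling
        fs = 2000.0
        ev = self._events(3)
        t = np.arange(int(3.5 * fs)) / fs
        sig = 1.0 + np.sin(2 * np.pi * 1.0 * t)
        env = EnvelopeMatrix(values=np.tile(sig, (13, 1)), fs=fs)
        out = preprocess.time_normalize(env, ev, max_cycles=3)
        for c in range(3):
            seg_t = (t >= ev.touchdown[c]) & (t < ev.touchdown[c + 1])
            true_max = sig[seg_t].max()
            got = out.values[0, c * 200 : (c + 1) * 200].max()
            assert got == pytest.approx(true_max, rel=0.01)


def test_full_chain_recovers_envelope_shape(noisy_trial):
    """Raw carrier-modulated EMG -> chain output correlates strongly
    with the ground-truth envelopes cycle grid."""
    V = preprocess.preprocess_trial(noisy_trial.raw, noisy_trial.events)
    assert V.values.shape == (13, 6000)
    truth = noisy_trial.envelopes
    for i in range(13):
        r = np.corrcoef(V.values[i], truth[i])[0, 1]
        assert r > 0.85
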