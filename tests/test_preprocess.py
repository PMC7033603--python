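"""Filter response, trimming arithmetic, gravity/heading recovery."""

import math

import numpy as np
import pytest
import scipy.signal as sps

from gaitenv.errors import AlignmentError, FilterError, SignalError
from gaitenv.preprocess import (align_gravity, align_heading,
                                butterworth_lowpass, preprocess_run,
                                trim_segments)
from gaitenv.runs import ANAT_TO_SENSOR, RawRun
from gaitenv.synth import generate_run, mounting_rotation


def _sine_run(freq_hz, fs=201.03, dur=5.0, amp=1.0, dc=(0.0, 9.81, 0.0)):
    t = np.arange(int(dur * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    samples = np.column_stack([x + dc[0], x + dc[1], x + dc[2]])
    return RawRun(samples=samples, fs_hz=fs, segments=[(0, len(t))],
                  condition="treadmill", participant="p", speed_mps=3.0)


class TestFilter:
    def test_dc_gain_unity(self):
        run = _sine_run(0.0)
        out = butterworth_lowpass(run)
        assert np.allclose(out.samples, run.samples, atol=1e-9)

    @pytest.mark.parametrize("freq, check", [
        (50.0, lambda ratio: ratio < 0.01),
        (1.0, lambda ratio: ratio >= 0.99),
    ])
    def test_magnitude_response(self, freq, check):
        run = _sine_run(freq, dur=10.0)
        out = butterworth_lowpass(run)
        mid = slice(200, -200)  # avoid edge transients
        ratio = (np.abs(out.samples[mid, 0] - 0.0).max()
                 / np.abs(run.samples[mid, 0]).max())
        assert check(ratio)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(FilterError):
            butterworth_lowpass(_sine_run(1.0), cutoff_hz=101.0)

    def test_idempotent_in_band(self):
        """Re-filtering a signal whose content sits well inside the passband
        changes it by < 1% RMS."""
        fs = 201.03
        t = np.arange(int(20 * fs)) / fs
        x = (np.sin(2 * np.pi * 1.3 * t) + 0.5 * np.sin(2 * np.pi * 2.9 * t)
             + 0.25 * np.sin(2 * np.pi * 4.7 * t))
        samples = np.column_stack([x, 9.81 + x, 0.3 * x])
        run = RawRun(samples, fs_hz=fs, segments=[(0, len(t))],
                     condition="treadmill", participant="p", speed_mps=3.0)
        once = butterworth_lowpass(run)
        twice = butterworth_lowpass(once)
        num = np.sqrt(np.mean((twice.samples - once.samples) ** 2))
        den = np.sqrt(np.mean((once.samples - once.samples.mean(0)) ** 2))
        assert num / den < 0.01


class TestTrim:
    def test_five_percent_rule(self):
        run = _sine_run(2.0, fs=100.0, dur=10.0)  # 1000 samples
        out = trim_segments(run, fraction=0.05)
        assert out.n_samples == 900
        assert np.allclose(out.samples, run.samples[50:950])

    def test_per_segment_independence(self):
        fs = 100.0
        t = np.arange(2000) / fs
        samples = np.column_stack([t, 9.81 + 0 * t, t])
        run = RawRun(samples, fs_hz=fs, segments=[(0, 1000), (1000, 2000)],
                     condition="sidewalk", participant="p", speed_mps=3.0)
        out = trim_segments(run, fraction=0.05)
        assert out.segments == [(0, 900), (900, 1800)]
        assert np.allclose(out.samples[:900], run.samples[50:950])
        assert np.allclose(out.samples[900:], run.samples[1050:1950])

    def test_zero_fraction_identity(self):
        run = _sine_run(2.0)
        out = trim_segments(run, fraction=0.0)
        assert np.array_equal(out.samples, run.samples)

    def test_too_short_rejected(self):
        run = _sine_run(2.0, dur=2.05)
        with pytest.raises(SignalError):
            trim_segments(run, fraction=0.05)


class TestGravityAlignment:
    def test_planted_tilt_recovered(self, noiseless_cfg):
        cfg = noiseless_cfg.replace(tilt_deg=(10.0, 5.0))
        run = generate_run(cfg, seed=2)
        sig = align_gravity(run)
        R = mounting_rotation(cfg.tilt_deg, 0.0)
        true_tilt = math.degrees(math.acos((R @ np.array([0, 1, 0]))[1]))
        assert abs(sig.tilt_deg - true_tilt) < 0.5

    def test_already_aligned_identity(self):
        """A signal whose mean acceleration is exactly vertical gets the
        identity gravity rotation (only the fixed axis permutation)."""
        fs = 200.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 2.0 * t)  # integer cycles: exactly zero mean
        samples = np.column_stack([0.2 * x, 9.81 + 3 * x, 0.5 * x])
        run = RawRun(samples, fs_hz=fs, segments=[(0, len(t))],
                     condition="treadmill", participant="p", speed_mps=3.0)
        sig = align_gravity(run)
        assert np.allclose(sig.rotation_applied @ ANAT_TO_SENSOR,
                           np.eye(3), atol=1e-6)
        assert sig.tilt_deg < 1e-4

    def test_vt_mean_near_zero_after_subtraction(self, noiseless_cfg):
        run = generate_run(noiseless_cfg.replace(tilt_deg=(8.0, 4.0)), seed=5)
        sig = align_gravity(run)
        for lo, hi in sig.segments:
            assert abs(sig.samples[lo:hi, 0].mean()) < 0.05

    def test_weightless_signal_rejected(self):
        run = _sine_run(2.0, dc=(0.0, 0.0, 0.0))
        with pytest.raises(AlignmentError):
            align_gravity(run)


class TestHeadingAlignment:
    @pytest.mark.parametrize("heading", [0.0, 15.0, 30.0, -25.0])
    def test_planted_heading_recovered(self, noiseless_cfg, heading):
        cfg = noiseless_cfg.replace(heading_deg=heading)
        run = generate_run(cfg, seed=2)
        sig = align_heading(align_gravity(run))
        assert abs(sig.heading_deg - heading) < 1.0

    def test_resultant_magnitude_preserved(self, noiseless_cfg):
        run = generate_run(noiseless_cfg.replace(heading_deg=20.0), seed=2)
        before = align_gravity(run)
        after = align_heading(before)
        assert np.allclose(np.linalg.norm(before.samples, axis=1),
                           np.linalg.norm(after.samples, axis=1), atol=1e-9)

    def test_isotropic_horizontal_warns_identity(self):
        rng = np.random.default_rng(0)
        n = 2000
        # perfectly isotropic horizontal variance: two orthogonal sinusoids
        # of identical amplitude
        t = np.arange(n) / 200.0
        ml = np.sin(2 * np.pi * 3.0 * t)
        ap = np.cos(2 * np.pi * 3.0 * t)
        from gaitenv.runs import AlignedSignal

        sig = AlignedSignal(
            samples=np.column_stack([rng.normal(size=n) * 0 + np.sin(t), ml, ap]),
            fs_hz=200.0, segments=[(0, n)], rotation_applied=np.eye(3),
            condition="treadmill", participant="p", speed_mps=3.0)
        with pytest.warns(UserWarning):
            out = align_heading(sig)
        assert out.status == "degenerate_horizontal"
        assert np.array_equal(out.samples, sig.samples)


class TestFullChain:
    def test_recovers_anatomical_frame(self, noiseless_cfg):
        """Filter+trim+align on a tilted, yawed, noise-free run recovers the
        generator's pre-rotation signal to within 2% RMS."""
        cfg = noiseless_cfg.replace(tilt_deg=(10.0, 5.0), heading_deg=25.0)
        run = generate_run(cfg, seed=6)
        sig = preprocess_run(run)
        sos = sps.butter(4, 10, btype="low", fs=run.fs_hz, output="sos")
        anat = sps.sosfiltfilt(sos, run.truth["anatomical"], axis=0)
        k = math.floor(0.05 * run.n_samples)
        expected = anat[k:run.n_samples - k]
        err = np.sqrt(np.mean((sig.samples - expected) ** 2))
        scale = np.sqrt(np.mean(expected**2))
        assert err / scale < 0.02
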