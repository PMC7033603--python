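"""Generator contracts: determinism, archetype structure, planted truth."""

import dataclasses

import numpy as np
import pytest

from gaitenv.errors import ConfigError, UnknownConditionError
from gaitenv.features import extract_feature_vector
from gaitenv.preprocess import preprocess_run
from gaitenv.stepseg import segment_run
from gaitenv.synth import (CohortDesign, SynthConfig, generate_cohort,
                           generate_run, make_archetype)


class TestArchetypes:
    def test_null_effect_identical(self):
        assert make_archetype("consistent", 0.0) == make_archetype("variable", 0.0)

    def test_contrast_fields_only(self):
        c = make_archetype("consistent", 1.0)
        v = make_archetype("variable", 1.0)
        differing = {
            f.name
            for f in dataclasses.fields(SynthConfig)
            if getattr(c, f.name) != getattr(v, f.name)
        }
        assert differing == {
            "timing_jitter_sd", "amp_jitter_sd", "amp_vt", "amp_ap",
            "slow_mod_depth", "speed_mps",
        }
        assert c.timing_jitter_sd < v.timing_jitter_sd
        assert c.amp_jitter_sd < v.amp_jitter_sd
        assert c.amp_vt > v.amp_vt and c.amp_ap < v.amp_ap

    def test_unknown_condition_rejected(self):
        with pytest.raises(UnknownConditionError):
            make_archetype("downhill", 1.0)

    def test_variable_has_larger_ap_share(self):
        """Averaged over seeds, the variable archetype generates a larger
        AP-to-resultant RMS ratio than the consistent one."""
        ratios = {}
        for arch in ("consistent", "variable"):
            cfg = make_archetype(arch, 1.0).replace(duration_s=15.0)
            vals = []
            for seed in range(20):
                run = generate_run(cfg, seed=seed, store_truth_signal=False)
                vals.append(extract_feature_vector(run)["ratio_ap"])
            ratios[arch] = np.mean(vals)
        assert ratios["variable"] > ratios["consistent"]


class TestGenerateRun:
    def test_determinism(self):
        cfg = SynthConfig()
        a = generate_run(cfg, seed=5)
        b = generate_run(cfg, seed=5)
        assert np.array_equal(a.samples, b.samples)
        assert a.segments == b.segments

    def test_noiseless_periodicity(self, noiseless_cfg):
        """With zero jitter/asymmetry/tilt the anatomical signal is exactly
        T0-periodic in VT and AP and 2*T0-periodic in ML."""
        fs = 200.0  # integer samples per step for exact comparison
        cfg = noiseless_cfg.replace(fs_hz=fs, step_period_s=0.35)
        run = generate_run(cfg, seed=0)
        anat = run.truth["anatomical"]
        lag = int(round(cfg.step_period_s * fs))
        n = 20 * lag
        vt, ml, ap = anat[:n, 0], anat[:n, 1], anat[:n, 2]
        assert np.allclose(vt[:-lag], vt[lag:], atol=1e-9)
        assert np.allclose(ap[:-lag], ap[lag:], atol=1e-9)
        assert not np.allclose(ml[:-lag], ml[lag:], atol=1e-3)  # alternates
        assert np.allclose(ml[:- 2 * lag], ml[2 * lag:], atol=1e-9)

    def test_planted_contacts_recovered(self, noiseless_cfg):
        run = generate_run(noiseless_cfg, seed=3)
        sig = preprocess_run(run)
        seg = segment_run(sig)
        detected = np.concatenate(seg.contacts)
        planted = np.concatenate(sig.truth["contacts"])
        assert len(detected) == len(planted)
        assert np.max(np.abs(detected - planted)) <= 2

    def test_too_short_duration_rejected(self):
        with pytest.raises(ConfigError):
            SynthConfig(duration_s=5.0).validate()

    def test_gravity_in_raw_vertical(self, noiseless_cfg):
        run = generate_run(noiseless_cfg, seed=1)
        assert run.samples[:, 1].mean() == pytest.approx(9.81, abs=0.05)


class TestMonotonicity:
    @staticmethod
    def _mean_feature(cfg, feature, n_seeds=20):
        vals = []
        for seed in range(n_seeds):
            run = generate_run(cfg, seed=seed, store_truth_signal=False)
            vals.append(extract_feature_vector(run)[feature])
        return float(np.mean(vals))

    def test_timing_jitter_lowers_vt_step_regularity(self):
        base = SynthConfig(duration_s=15.0, noise_sd=0.1)
        lo = self._mean_feature(base.replace(timing_jitter_sd=0.01),
                                "regularity_step_vt")
        hi = self._mean_feature(base.replace(timing_jitter_sd=0.06),
                                "regularity_step_vt")
        assert hi < lo

    def test_amp_jitter_raises_vt_rms_cv(self):
        base = SynthConfig(duration_s=15.0, noise_sd=0.1)
        lo = self._mean_feature(base.replace(amp_jitter_sd=0.02), "rms_cv_vt")
        hi = self._mean_feature(base.replace(amp_jitter_sd=0.08), "rms_cv_vt")
        assert hi > lo

    def test_ml_stride_beats_step_regularity(self, noiseless_cfg):
        """ML alternates sign by foot, so it anti-correlates at the step lag
        and correlates at the stride lag."""
        run = generate_run(noiseless_cfg, seed=7)
        vec = extract_feature_vector(run)
        assert vec["regularity_stride_ml"] > vec["regularity_step_ml"]


class TestCohort:
    def test_default_design_arithmetic(self):
        ds = generate_cohort(CohortDesign(seed=0))
        assert len(ds.runs) == 28 + 25 + 16 * 2 == 85
        assert len(ds.training_runs) == 53
        assert len(ds.testing_runs) == 32

    def test_cohort_determinism(self):
        a = generate_cohort(CohortDesign(seed=9, n_treadmill_only=3,
                                         n_sidewalk_only=3, n_both=2))
        b = generate_cohort(CohortDesign(seed=9, n_treadmill_only=3,
                                         n_sidewalk_only=3, n_both=2))
        for ra, rb in zip(a.runs, b.runs):
            assert np.array_equal(ra.samples, rb.samples)

    def test_adding_participants_preserves_existing(self):
        small = generate_cohort(CohortDesign(seed=9, n_treadmill_only=3,
                                             n_sidewalk_only=3, n_both=2))
        big = generate_cohort(CohortDesign(seed=9, n_treadmill_only=4,
                                           n_sidewalk_only=3, n_both=2))
        a = next(r for r in small.runs if r.participant == "tm01")
        b = next(r for r in big.runs if r.participant == "tm01")
        assert np.array_equal(a.samples, b.samples)

    def test_both_group_shares_participant_effects(self):
        ds = generate_cohort(CohortDesign(seed=3, n_treadmill_only=2,
                                          n_sidewalk_only=2, n_both=2))
        both = [r for r in ds.runs if r.participant == "both01"]
        assert {r.condition for r in both} == {"treadmill", "sidewalk"}

    def test_sidewalk_runs_have_two_segments(self):
        ds = generate_cohort(CohortDesign(seed=3, n_treadmill_only=2,
                                          n_sidewalk_only=2, n_both=2))
        for r in ds.runs:
            assert len(r.segments) == (2 if r.condition == "sidewalk" else 1)
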