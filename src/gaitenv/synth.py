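"""Synthetic running-acceleration generator.

Emulates lower-back (center-of-mass) tri-axial accelerometry of running as a
quasi-periodic train of alternating left/right step pulses with controllable
step period, stride-to-stride timing jitter, per-step amplitude variability,
left/right asymmetry, per-axis energy shares, sensor tilt/heading
misalignment, gravity offset and additive white noise.

Two archetypes encode the contrast between a *consistent* regime (constant
belt speed, flat uniform surface: low timing/amplitude jitter, vertically
dominated acceleration) and a *variable* regime (overground running with
curves, incline and speed drift: higher jitter, a larger anterior-posterior
share, and a slow amplitude modulation).  ``effect_scale`` interpolates the
contrast; at 0 the two archetypes are identical, so the two conditions are
exchangeable and any downstream classifier should be at chance.

Waveforms (within step *i* of duration ``T_i``, phase ``tau = t/T_i``):

* VT: ``amp_vt * m_i * (sin(pi tau) - 2/pi)`` — an impact half-sine, mean-
  removed per step so that gravity is the only DC component of the vertical
  axis (periodic CoM motion has zero net vertical acceleration).
* AP: ``amp_ap * m_i * (sin(2 pi tau) - 0.3 cos(4 pi tau))`` — biphasic
  braking/propulsion with a quadrature harmonic giving the positive skew
  along the direction of travel that real AP traces show; zero mean.
* ML: ``s_i * amp_ml * m_i * sin(pi tau)`` with ``s_i`` alternating by foot.

``m_i = (1 + eps_i) * (1 +/- gamma)`` carries per-step amplitude jitter and
left/right asymmetry.  Gravity (+9.81 m/s^2) is added along true vertical,
the whole signal is rotated into the (mis)mounted sensor frame, and white
noise is added last.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import TESTING, TRAINING, Dataset
from .errors import ConfigError, UnknownConditionError
from .runs import ANAT_TO_SENSOR, GRAVITY, RawRun

CONSISTENT = "consistent"
VARIABLE = "variable"

TREADMILL = "treadmill"
SIDEWALK = "sidewalk"

#: Which archetype generates which environment analog.
CONDITION_ARCHETYPE = {TREADMILL: CONSISTENT, SIDEWALK: VARIABLE}

# Baseline (effect_scale = 0) parameters shared by both archetypes.
_BASE = dict(
    step_period_s=0.35,
    timing_jitter_sd=0.03,
    amp_vt=8.0,
    amp_ml=1.5,
    amp_ap=2.5,
    amp_jitter_sd=0.05,
    lr_asymmetry=0.05,
    tilt_deg=(5.0, 3.0),
    heading_deg=8.0,
    noise_sd=0.4,
    duration_s=40.0,
    fs_hz=201.03,
    speed_mps=2.78,
    n_segments=1,
)

# Treadmill/sidewalk mean speeds reproduced at effect_scale = 1.
_SPEED_CONSISTENT = 2.78
_SPEED_VARIABLE = 3.24

_AP_SKEW_HARMONIC = 0.3  # quadrature 2nd harmonic weight in the AP pulse


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of one synthetic run."""

    step_period_s: float = 0.35
    timing_jitter_sd: float = 0.03
    amp_vt: float = 8.0
    amp_ml: float = 1.5
    amp_ap: float = 2.5
    amp_jitter_sd: float = 0.05
    lr_asymmetry: float = 0.05
    tilt_deg: tuple[float, float] = (5.0, 3.0)
    heading_deg: float = 8.0
    noise_sd: float = 0.4
    duration_s: float = 40.0
    fs_hz: float = 201.03
    speed_mps: float = 2.78
    n_segments: int = 1
    slow_mod_depth: float = 0.0
    slow_mod_hz: float = 0.05

    def validate(self) -> None:
        if self.step_period_s <= 0:
            raise ConfigError("step_period_s must be > 0")
        if self.fs_hz <= 0:
            raise ConfigError("fs_hz must be > 0")
        if not 0 <= self.timing_jitter_sd < 0.2:
            raise ConfigError("timing_jitter_sd must lie in [0, 0.2)")
        if not 0 <= self.lr_asymmetry < 1:
            raise ConfigError("lr_asymmetry must lie in [0, 1)")
        if self.amp_jitter_sd < 0 or self.noise_sd < 0:
            raise ConfigError("jitter/noise SDs must be non-negative")
        if self.n_segments not in (1, 2):
            raise ConfigError("n_segments must be 1 or 2")
        if self.duration_s < 30 * self.step_period_s:
            raise ConfigError(
                "duration_s too short: need at least 30 step periods "
                f"({30 * self.step_period_s:.2f} s) for stride-lag features"
            )

    def replace(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class CohortDesign:
    """Sizes and contrast of a synthetic cohort.

    Defaults mirror the study design: 28 treadmill-only and 25 sidewalk-only
    participants form the training split; 16 participants who ran in both
    environments form the independent testing split.
    """

    n_treadmill_only: int = 28
    n_sidewalk_only: int = 25
    n_both: int = 16
    effect_scale: float = 1.0
    seed: int = 0
    duration_s: float = 40.0

    def validate(self) -> None:
        if min(self.n_treadmill_only, self.n_sidewalk_only, self.n_both) < 0:
            raise ConfigError("cohort counts must be non-negative")
        if self.n_both < 2:
            raise ConfigError("n_both >= 2 required for paired testing")
        if self.effect_scale < 0:
            raise ConfigError("effect_scale must be >= 0")


def make_archetype(condition: str, effect_scale: float = 1.0) -> SynthConfig:
    """Return the generator preset for one gait regime.

    ``condition`` is ``"consistent"`` (treadmill-like) or ``"variable"``
    (sidewalk-like).  ``effect_scale`` scales every between-regime contrast;
    at 0 the two presets are identical.
    """
    if effect_scale < 0:
        raise ConfigError("effect_scale must be >= 0")
    e = float(effect_scale)
    base = dict(_BASE)
    if condition == CONSISTENT:
        base.update(
            timing_jitter_sd=_BASE["timing_jitter_sd"] * (1 - 0.3 * e),
            amp_jitter_sd=_BASE["amp_jitter_sd"] * (1 - 0.3 * e),
            amp_vt=_BASE["amp_vt"] * (1 + 0.05 * e),
            amp_ap=_BASE["amp_ap"] * (1 - 0.05 * e),
            slow_mod_depth=0.0,
            speed_mps=_SPEED_CONSISTENT,
        )
    elif condition == VARIABLE:
        base.update(
            timing_jitter_sd=_BASE["timing_jitter_sd"] * (1 + 0.5 * e),
            amp_jitter_sd=_BASE["amp_jitter_sd"] * (1 + 0.4 * e),
            amp_vt=_BASE["amp_vt"] * (1 - 0.05 * e),
            amp_ap=_BASE["amp_ap"] * (1 + 0.10 * e),
            slow_mod_depth=0.05 * e,
            speed_mps=_SPEED_CONSISTENT + (_SPEED_VARIABLE - _SPEED_CONSISTENT) * e,
        )
    else:
        raise UnknownConditionError(
            f"unknown archetype {condition!r}; expected "
            f"{CONSISTENT!r} or {VARIABLE!r}"
        )
    return SynthConfig(**base)


def _rot_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def mounting_rotation(tilt_deg: tuple[float, float], heading_deg: float) -> np.ndarray:
    """Rotation from ideal sensor coordinates to the mis-mounted sensor frame.

    Heading (about vertical) is applied first, then roll (about the
    posterior axis) and pitch (about the lateral axis).
    """
    roll, pitch = tilt_deg
    return _rot_x(pitch) @ _rot_z(roll) @ _rot_y(heading_deg)


def _default_effects() -> dict[str, float]:
    return dict(period_mult=1.0, amp_vt_mult=1.0, amp_ml_mult=1.0,
                amp_ap_mult=1.0, speed_mult=1.0,
                timing_jitter_mult=1.0, amp_jitter_mult=1.0)


def _segment_steps(cfg: SynthConfig, seg_dur: float, rng: np.random.Generator):
    """Draw step onsets/durations/feet/amplitude multipliers for one segment."""
    t0 = cfg.step_period_s
    onsets, durations, feet, mults = [], [], [], []
    foot = int(rng.integers(2))  # 0 = left, 1 = right
    t = 0.0
    gamma = cfg.lr_asymmetry
    while t < seg_dur:
        eta = rng.normal(0.0, cfg.timing_jitter_sd) if cfg.timing_jitter_sd else 0.0
        T = t0 * max(0.5, 1.0 + eta)
        eps = rng.normal(0.0, cfg.amp_jitter_sd) if cfg.amp_jitter_sd else 0.0
        m = (1.0 + eps) * ((1.0 + gamma) if foot == 1 else (1.0 - gamma))
        onsets.append(t)
        durations.append(T)
        feet.append(foot)
        mults.append(m)
        t += T
        foot = 1 - foot
    return (np.array(onsets), np.array(durations), np.array(feet, dtype=int),
            np.array(mults))


def _segment_signal(cfg: SynthConfig, seg_dur: float, rng: np.random.Generator):
    """Anatomical-frame (VT, ML, AP) signal for one segment plus planted truth."""
    n = int(round(seg_dur * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz
    onsets, durations, feet, mults = _segment_steps(cfg, seg_dur, rng)
    idx = np.searchsorted(onsets, t, side="right") - 1
    tau = (t - onsets[idx]) / durations[idx]
    m = mults[idx]
    s = np.where(feet[idx] == 1, 1.0, -1.0)

    vt = cfg.amp_vt * m * (np.sin(np.pi * tau) - 2.0 / np.pi)
    ap = cfg.amp_ap * m * (np.sin(2 * np.pi * tau)
                           - _AP_SKEW_HARMONIC * np.cos(4 * np.pi * tau))
    ml = s * cfg.amp_ml * m * np.sin(np.pi * tau)
    anat = np.column_stack([vt, ml, ap])

    if cfg.slow_mod_depth > 0:
        phase = rng.uniform(0, 2 * np.pi)
        g = 1.0 + cfg.slow_mod_depth * np.sin(2 * np.pi * cfg.slow_mod_hz * t + phase)
        anat *= g[:, None]

    # Planted contact events: VT pulse peaks (mid-pulse), whole steps only.
    peak_t = onsets + durations / 2.0
    inside = (onsets + durations) <= seg_dur
    contacts = np.round(peak_t[inside] * cfg.fs_hz).astype(int)
    contacts = contacts[contacts < n]
    truth = dict(
        contacts=contacts,
        feet=feet[inside][: len(contacts)],
        onsets_s=onsets[inside][: len(contacts)],
        durations_s=durations[inside][: len(contacts)],
    )
    return anat, truth


def generate_run(
    config: SynthConfig,
    participant_effects: dict[str, float] | None = None,
    seed: int | np.random.SeedSequence = 0,
    condition: str = TREADMILL,
    participant: str = "p00",
    store_truth_signal: bool = True,
) -> RawRun:
    """Generate one participant-run with planted ground truth.

    The returned :class:`RawRun` is in the sensor frame (gravity included,
    mounting misalignment applied, noise added).  ``run.truth`` carries the
    planted contact indices, foot labels, the pre-rotation anatomical signal
    (if ``store_truth_signal``) and the mounting rotation.
    """
    config.validate()
    eff = dict(_default_effects(), **(participant_effects or {}))
    cfg = config.replace(
        step_period_s=config.step_period_s * eff["period_mult"],
        amp_vt=config.amp_vt * eff["amp_vt_mult"],
        amp_ml=config.amp_ml * eff["amp_ml_mult"],
        amp_ap=config.amp_ap * eff["amp_ap_mult"],
        timing_jitter_sd=min(0.199, config.timing_jitter_sd
                             * eff["timing_jitter_mult"]),
        amp_jitter_sd=config.amp_jitter_sd * eff["amp_jitter_mult"],
        slow_mod_depth=config.slow_mod_depth * eff["amp_jitter_mult"],
    )
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(int(seed)))

    seg_dur = cfg.duration_s / cfg.n_segments
    anat_parts, segments, contacts, feet = [], [], [], []
    offset = 0
    for _ in range(cfg.n_segments):
        anat, truth = _segment_signal(cfg, seg_dur, rng)
        anat_parts.append(anat)
        segments.append((offset, offset + anat.shape[0]))
        contacts.append(truth["contacts"] + offset)
        feet.append(truth["feet"])
        offset += anat.shape[0]
    anat = np.vstack(anat_parts)

    R = mounting_rotation(cfg.tilt_deg, cfg.heading_deg)
    ideal = anat @ ANAT_TO_SENSOR.T
    ideal[:, 1] += GRAVITY
    sensor = ideal @ R.T
    if cfg.noise_sd > 0:
        sensor = sensor + rng.normal(0.0, cfg.noise_sd, size=sensor.shape)

    truth = dict(
        contacts=contacts,
        feet=feet,
        n_steps=int(sum(len(c) for c in contacts)),
        rotation=R @ ANAT_TO_SENSOR,
        tilt_deg=cfg.tilt_deg,
        heading_deg=cfg.heading_deg,
        step_period_s=cfg.step_period_s,
        config=asdict(cfg),
    )
    if store_truth_signal:
        truth["anatomical"] = anat
    speed = cfg.speed_mps * eff["speed_mult"]
    return RawRun(
        samples=sensor,
        fs_hz=cfg.fs_hz,
        segments=segments,
        condition=condition,
        participant=participant,
        speed_mps=speed,
        truth=truth,
    )


def _participant_effects(rng: np.random.Generator) -> dict[str, float]:
    """Log-normal between-participant multipliers.

    Period varies with SD ~0.05, per-axis amplitudes with SD ~0.12, speed with SD
    ~0.09 (matching the between-runner speed spread); stride-to-stride
    timing and amplitude variability differ more strongly between runners
    (SD ~0.4), which keeps the archetype feature distributions overlapping
    rather than trivially separable.
    """
    return dict(
        period_mult=float(rng.lognormal(0.0, 0.05)),
        amp_vt_mult=float(rng.lognormal(0.0, 0.12)),
        amp_ml_mult=float(rng.lognormal(0.0, 0.12)),
        amp_ap_mult=float(rng.lognormal(0.0, 0.12)),
        speed_mult=float(rng.lognormal(0.0, 0.09)),
        timing_jitter_mult=float(rng.lognormal(0.0, 0.4)),
        amp_jitter_mult=float(rng.lognormal(0.0, 0.4)),
    )


def _demographics(rng: np.random.Generator) -> dict[str, float]:
    return dict(
        height_m=float(rng.normal(1.73, 0.09)),
        mass_kg=float(rng.normal(69.5, 10.5)),
        age_yr=float(max(18.0, rng.normal(33.5, 11.0))),
    )


_COND_CODE = {TREADMILL: 0, SIDEWALK: 1}


def generate_cohort(design: CohortDesign) -> Dataset:
    """Generate a full cohort: training runs from the two single-environment
    groups, testing runs from the both-environments group.

    Per-participant random effects are drawn once and shared across that
    participant's runs.  Each run's RNG stream is derived from (cohort seed,
    participant index, condition) so adding participants never perturbs
    existing ones.
    """
    design.validate()
    groups = (
        [("tm", 1, [TREADMILL], TRAINING)] * design.n_treadmill_only
        + [("sw", 2, [SIDEWALK], TRAINING)] * design.n_sidewalk_only
        + [("both", 3, [TREADMILL, SIDEWALK], TESTING)] * design.n_both
    )
    runs, manifest_rows = [], []
    counters: dict[str, int] = {}
    for idx, (prefix, protocol, conditions, role) in enumerate(groups):
        counters[prefix] = counters.get(prefix, 0) + 1
        pid = f"{prefix}{counters[prefix]:02d}"
        eff_rng = np.random.default_rng(
            np.random.SeedSequence([design.seed, idx, 1_000_003])
        )
        effects = _participant_effects(eff_rng)
        demo = _demographics(eff_rng)
        manifest_rows.append(dict(participant=pid, protocol=protocol, role=role, **demo))
        for cond in conditions:
            arch = make_archetype(CONDITION_ARCHETYPE[cond], design.effect_scale)
            cfg = arch.replace(
                duration_s=design.duration_s,
                n_segments=2 if cond == SIDEWALK else 1,
            )
            run = generate_run(
                cfg,
                participant_effects=effects,
                seed=np.random.SeedSequence([design.seed, idx, _COND_CODE[cond]]),
                condition=cond,
                participant=pid,
                store_truth_signal=False,
            )
            runs.append(run)
    manifest = pd.DataFrame(manifest_rows)
    return Dataset(runs=runs, manifest=manifest, provenance=dict(design=asdict(design)))
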