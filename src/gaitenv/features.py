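"""The 25-feature gait description of one run.

Per axis a in {AP, ML, VT}: step and stride regularity (unbiased
autocorrelation of the mean-removed axis signal at the mean step and stride
lags), symmetry (step regularity / stride regularity; 1 for perfectly
left/right-symmetric gait), peak (mean over steps of the per-step maximum
absolute acceleration), RMS, RMS CV (coefficient of variation of per-step
RMS across steps) and ratio (axis RMS / resultant RMS).  Axis-independent:
step-time CV, stride-time CV, resultant RMS, and mean running speed.

Regularity and whole-signal RMS are computed on the continuous mean-removed
aligned signal, per segment (autocorrelation at the stride lag needs the raw
time base); multi-segment runs average regularity across segments weighted
by segment length.  Per-step statistics (peak, per-step RMS) come from the
time-normalized step matrix.  Because each axis is mean-removed, the squared
ratios obey the Pythagorean identity ratio_AP^2 + ratio_ML^2 + ratio_VT^2 = 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FeatureError, StageError
from .preprocess import preprocess_run
from .runs import AlignedSignal, RawRun, StepSegmentation
from .stepseg import segment_run

#: Canonical feature order; also the tie-break order for forward selection.
FEATURE_NAMES = (
    "speed",
    "step_time_cv",
    "stride_time_cv",
    "rms_resultant",
    "regularity_step_ap", "regularity_step_ml", "regularity_step_vt",
    "regularity_stride_ap", "regularity_stride_ml", "regularity_stride_vt",
    "symmetry_ap", "symmetry_ml", "symmetry_vt",
    "peak_ap", "peak_ml", "peak_vt",
    "rms_ap", "rms_ml", "rms_vt",
    "rms_cv_ap", "rms_cv_ml", "rms_cv_vt",
    "ratio_ap", "ratio_ml", "ratio_vt",
)

KEY_COLUMNS = ("participant", "condition", "role")

_AXIS_COL = {"vt": 0, "ml": 1, "ap": 2}


def unbiased_autocorr(x: np.ndarray, lag: int) -> float:
    """Unbiased autocorrelation coefficient of a mean-removed signal at ``lag``.

    ``[sum_t x_t x_{t+lag} / (n - lag)] / [sum_t x_t^2 / n]``.  The input is
    expected to be mean-removed by the caller; a zero-variance input is
    rejected.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if not 0 <= lag < n / 2:
        raise FeatureError(f"lag {lag} outside [0, n/2) for n={n}")
    denom = float(np.dot(x, x)) / n
    if denom <= 0:
        raise FeatureError("zero-variance input")
    return float(np.dot(x[: n - lag], x[lag:])) / (n - lag) / denom


def _segmentwise_autocorr(sig: AlignedSignal, col: int, lag: int) -> float:
    """Length-weighted average of the per-segment unbiased autocorrelation."""
    num, den = 0.0, 0
    for lo, hi in sig.segments:
        x = sig.samples[lo:hi, col]
        x = x - x.mean()
        num += unbiased_autocorr(x, lag) * (hi - lo)
        den += hi - lo
    return num / den


def regularity_and_symmetry(sig: AlignedSignal, axis: str,
                            step_lag: int, stride_lag: int
                            ) -> tuple[float, float, float]:
    """(step regularity, stride regularity, symmetry) for one axis.

    Lags are the mean step and stride durations rounded to samples.  Symmetry
    is the step/stride regularity ratio; if stride regularity is zero the
    symmetry is undefined and reported as NaN.
    """
    col = _AXIS_COL[axis]
    reg_step = _segmentwise_autocorr(sig, col, step_lag)
    reg_stride = _segmentwise_autocorr(sig, col, stride_lag)
    symmetry = np.nan if reg_stride == 0 else reg_step / reg_stride
    return reg_step, reg_stride, symmetry


def temporal_cv(durations_s: np.ndarray) -> float:
    """Sample coefficient of variation (SD with n-1 denominator over mean)."""
    d = np.asarray(durations_s, dtype=float)
    if len(d) < 2:
        raise FeatureError("need at least 2 durations")
    mean = d.mean()
    if mean == 0:
        raise FeatureError("zero mean duration")
    return float(d.std(ddof=1) / mean)


def magnitude_features(seg: StepSegmentation, sig: AlignedSignal) -> dict[str, float]:
    """Peaks, RMS, resultant RMS, ratios and RMS CVs.

    Whole-signal RMS per axis is computed on the per-segment mean-removed
    continuous signal; the resultant RMS is the RMS of the per-sample
    Euclidean norm of the three mean-removed axes.  Per-step peak and RMS
    statistics use the step matrix.
    """
    if seg.n_steps < 2:
        raise FeatureError("need at least 2 retained steps")
    centered = sig.samples.copy()
    for lo, hi in sig.segments:
        centered[lo:hi] -= centered[lo:hi].mean(axis=0)
    out: dict[str, float] = {}
    rms_resultant = float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
    if rms_resultant == 0:
        raise FeatureError("zero resultant RMS")
    out["rms_resultant"] = rms_resultant
    for axis, col in _AXIS_COL.items():
        rms = float(np.sqrt(np.mean(centered[:, col] ** 2)))
        per_step = seg.step_matrix[:, :, col]
        per_step_rms = np.sqrt(np.mean(per_step**2, axis=1))
        out[f"rms_{axis}"] = rms
        out[f"ratio_{axis}"] = rms / rms_resultant
        out[f"peak_{axis}"] = float(np.mean(np.max(np.abs(per_step), axis=1)))
        out[f"rms_cv_{axis}"] = float(
            per_step_rms.std(ddof=1) / per_step_rms.mean())
    return out


def features_from_aligned(sig: AlignedSignal, seg: StepSegmentation | None = None
                          ) -> pd.Series:
    """Compute the 25-feature vector from an aligned, segmented run."""
    if seg is None:
        seg = segment_run(sig)
    vec: dict[str, float] = {
        "speed": float(sig.speed_mps),
        "step_time_cv": temporal_cv(seg.step_durations_s),
        "stride_time_cv": temporal_cv(seg.stride_durations_s),
    }
    vec.update(magnitude_features(seg, sig))
    for axis in ("ap", "ml", "vt"):
        rs, rst, sym = regularity_and_symmetry(
            sig, axis, seg.step_lag, seg.stride_lag)
        vec[f"regularity_step_{axis}"] = rs
        vec[f"regularity_stride_{axis}"] = rst
        vec[f"symmetry_{axis}"] = sym
    return pd.Series({name: vec[name] for name in FEATURE_NAMES})


def extract_feature_vector(run: RawRun) -> pd.Series:
    """Full chain on a raw run: preprocess, segment, 25 features.

    Any stage failure is re-raised as :class:`StageError` naming the failing
    stage and the run.
    """
    run_id = f"{run.participant}/{run.condition}"
    try:
        sig = preprocess_run(run)
    except Exception as exc:  # noqa: BLE001 - rewrapped with context
        raise StageError("preprocess", run_id, exc) from exc
    try:
        seg = segment_run(sig)
    except Exception as exc:
        raise StageError("stepseg", run_id, exc) from exc
    try:
        return features_from_aligned(sig, seg)
    except Exception as exc:
        raise StageError("features", run_id, exc) from exc


def extract_feature_table(runs, roles: dict[str, str] | None = None) -> pd.DataFrame:
    """Feature table for many runs: key columns plus the 25 features.

    ``roles`` maps participant to training/testing; omitted roles are empty.
    """
    rows = []
    for run in runs:
        vec = extract_feature_vector(run)
        row = {
            "participant": run.participant,
            "condition": run.condition,
            "role": (roles or {}).get(run.participant, ""),
        }
        row.update(vec.to_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=list(KEY_COLUMNS) + list(FEATURE_NAMES))
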