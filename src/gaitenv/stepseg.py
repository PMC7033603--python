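"""Step detection and the 50-point time-normalized step matrix.

Initial contacts are taken as prominent vertical-acceleration maxima: peaks
above the 60th percentile of the VT signal, separated by at least half the
dominant step period (itself estimated from the unbiased VT autocorrelation
within the physiological band 0.25-1.0 s).  Inter-contact intervals whose
duration falls outside [0.5, 1.5] times the dominant period are treated as
detection dropouts or artifacts and excluded; a stride is two consecutive
retained steps.  Each retained step is linearly resampled to 50 points per
axis.  Segments are processed independently: no step spans a segment
boundary.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .errors import SegmentationError
from .runs import AlignedSignal, StepSegmentation

PHYSIO_BAND_S = (0.25, 1.0)

#: Retained step durations relative to the dominant period.  The upper bound
#: excludes the ~2x interval produced by a single missed pulse.
DURATION_BAND = (0.5, 1.5)


def _unbiased_autocorr_curve(x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    n = len(x)
    denom = float(np.dot(x, x)) / n
    if denom <= 0:
        raise SegmentationError("zero-variance signal")
    vals = np.empty(len(lags))
    for i, lag in enumerate(lags):
        vals[i] = float(np.dot(x[: n - lag], x[lag:])) / (n - lag) / denom
    return vals


def dominant_step_period(vt: np.ndarray, fs_hz: float,
                         band_s: tuple[float, float] = PHYSIO_BAND_S) -> float:
    """Lag (s) of the first dominant peak of the VT autocorrelation in-band.

    "Dominant" means a local maximum reaching at least 70% of the largest
    in-band autocorrelation value; the earliest such peak is the step period
    (the stride peak, at twice the lag, may be higher under left/right
    asymmetry).
    """
    vt = np.asarray(vt, dtype=float)
    if len(vt) < 10 * fs_hz:
        raise SegmentationError("need at least 10 s of signal")
    lo = max(1, int(np.floor(band_s[0] * fs_hz)))
    hi = int(np.ceil(band_s[1] * fs_hz))
    if hi >= len(vt) // 2:
        raise SegmentationError("band exceeds half the signal length")
    lags = np.arange(lo, hi + 1)
    ac = _unbiased_autocorr_curve(vt, lags)
    peaks, _ = sps.find_peaks(ac)
    if len(peaks) == 0:
        # a peak at the band edge still counts if the curve rises into it
        if ac[-1] > ac[-2]:
            peaks = np.array([len(ac) - 1])
        else:
            raise SegmentationError("no autocorrelation peak in 0.25-1.0 s band")
    vals = ac[peaks]
    # a gait signal is strongly self-similar at its step lag; sub-0.2 peaks
    # are indistinguishable from white-noise autocorrelation fluctuations
    if np.max(vals) < 0.2:
        raise SegmentationError(
            "no autocorrelation peak above 0.2 in the 0.25-1.0 s band; "
            "signal is not gait-like")
    dominant = peaks[vals >= 0.7 * np.max(vals)]
    return float(lags[dominant[0]] / fs_hz)


def detect_initial_contacts(vt: np.ndarray, fs_hz: float, period_s: float,
                            min_contacts: int = 30) -> np.ndarray:
    """Peak-picking contact detector on one segment's VT signal."""
    vt = np.asarray(vt, dtype=float)
    height = float(np.percentile(vt, 60))
    distance = max(1, int(round(0.5 * period_s * fs_hz)))
    contacts, _ = sps.find_peaks(vt, height=height, distance=distance)
    if len(contacts) < min_contacts:
        raise SegmentationError(
            f"only {len(contacts)} contacts detected; need >= {min_contacts}"
        )
    return contacts


def build_step_matrix(sig: AlignedSignal, contacts: list[np.ndarray],
                      n_points: int = 50,
                      period_s: float | None = None) -> StepSegmentation:
    """Assemble durations, outlier exclusions and the time-normalized matrix.

    ``contacts`` holds global sample indices, one array per segment.  Axes
    are mean-removed per segment before resampling so that per-step
    statistics downstream are taken about the run's dynamic baseline.
    """
    total = sum(len(c) for c in contacts)
    if total < 2:
        raise SegmentationError("need at least 2 contacts")
    samples = sig.samples.copy()
    for lo, hi in sig.segments:
        samples[lo:hi] -= samples[lo:hi].mean(axis=0)

    if period_s is None:
        all_d = np.concatenate(
            [np.diff(c) for c in contacts if len(c) >= 2]) / sig.fs_hz
        period_s = float(np.median(all_d))

    steps, durations, strides = [], [], []
    n_excluded = 0
    lo_d, hi_d = DURATION_BAND[0] * period_s, DURATION_BAND[1] * period_s
    for c in contacts:
        keep = []
        for a, b in zip(c[:-1], c[1:]):
            d = (b - a) / sig.fs_hz
            if not lo_d <= d <= hi_d:
                n_excluded += 1
                keep.append(None)
                continue
            keep.append(d)
            durations.append(d)
            src = np.arange(a, b + 1)
            tgt = np.linspace(a, b, n_points)
            step = np.column_stack(
                [np.interp(tgt, src, samples[a:b + 1, ax]) for ax in range(3)]
            )
            steps.append(step)
        for d1, d2 in zip(keep[:-1], keep[1:]):
            if d1 is not None and d2 is not None:
                strides.append(d1 + d2)
    if not steps:
        raise SegmentationError("no steps retained after outlier exclusion")
    return StepSegmentation(
        contacts=[np.asarray(c) for c in contacts],
        step_durations_s=np.asarray(durations),
        stride_durations_s=np.asarray(strides),
        step_matrix=np.stack(steps),
        dominant_period_s=period_s,
        fs_hz=sig.fs_hz,
        n_steps_excluded=n_excluded,
    )


def segment_run(sig: AlignedSignal, n_points: int = 50,
                min_contacts: int = 30) -> StepSegmentation:
    """Detect contacts per segment and build the step matrix for one run."""
    seg_arrays = sig.segment_arrays()
    longest = max(seg_arrays, key=len)
    period = dominant_step_period(longest[:, 0], sig.fs_hz)
    contacts = []
    total = 0
    for (lo, hi), arr in zip(sig.segments, seg_arrays):
        c = detect_initial_contacts(arr[:, 0], sig.fs_hz, period, min_contacts=0)
        contacts.append(c + lo)
        total += len(c)
    if total < min_contacts:
        raise SegmentationError(
            f"only {total} contacts across segments; need >= {min_contacts}"
        )
    return build_step_matrix(sig, contacts, n_points=n_points, period_s=period)
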