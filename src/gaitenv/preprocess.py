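"""Filtering, trimming, and alignment into anatomical axes.

Pipeline order follows data-collection practice for lower-back accelerometry:
low-pass filter, trim segment edges (start/stop transients), align with
gravity, then align the horizontal axes with the direction of motion.  Each
segment (e.g. the two legs of an out-and-back sidewalk run) is handled
independently by the filter and the trim; one rotation per run is used for
alignment, since the mounting is fixed within a run.

The filter is applied forward-backward (zero phase) so step-event timing is
not biased; the effective attenuation is therefore that of the squared
magnitude response.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import signal as sps

from .errors import AlignmentError, FilterError, SignalError
from .runs import ANAT_TO_SENSOR, GRAVITY, AlignedSignal, RawRun


def butterworth_lowpass(run: RawRun, cutoff_hz: float = 10.0, order: int = 4) -> RawRun:
    """Zero-phase 4th-order Butterworth low-pass, applied per segment.

    Rejects a cutoff at or above the Nyquist frequency.
    """
    nyq = run.fs_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise FilterError(f"cutoff {cutoff_hz} Hz not below Nyquist {nyq} Hz")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=run.fs_hz, output="sos")
    out = run.samples.copy()
    for lo, hi in run.segments:
        out[lo:hi] = sps.sosfiltfilt(sos, run.samples[lo:hi], axis=0)
    return run.replace(samples=out)


def trim_segments(run: RawRun, fraction: float = 0.05) -> RawRun:
    """Drop ``floor(fraction * len)`` samples from each end of every segment.

    Removes start/stop transients; each segment is trimmed independently so a
    turnaround pause never leaks into the retained signal.
    """
    if not 0 <= fraction < 0.5:
        raise SignalError("trim fraction must lie in [0, 0.5)")
    parts, segments, truth = [], [], run.truth
    new_contacts = [] if truth is not None and "contacts" in truth else None
    offset = 0
    for i, (lo, hi) in enumerate(run.segments):
        k = math.floor(fraction * (hi - lo))
        a, b = lo + k, hi - k
        if (b - a) < 2 * run.fs_hz:
            raise SignalError(
                f"segment {i} shorter than 2 s after trimming ({b - a} samples)"
            )
        parts.append(run.samples[a:b])
        segments.append((offset, offset + (b - a)))
        if new_contacts is not None:
            c = np.asarray(truth["contacts"][i])
            kept = c[(c >= a) & (c < b)]
            new_contacts.append(kept - a + offset)
        offset += b - a
    out_truth = truth
    if new_contacts is not None:
        out_truth = dict(truth, contacts=new_contacts)
        out_truth.pop("anatomical", None)  # index base no longer matches
    return run.replace(samples=np.vstack(parts), segments=segments, truth=out_truth)


def _minimal_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Shortest rotation taking unit vector ``u`` onto unit vector ``v``."""
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-15:
        return np.eye(3) if c > 0 else -np.eye(3)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + K + K @ K * ((1 - c) / s**2)


def align_gravity(run: RawRun) -> AlignedSignal:
    """Rotate so the mean acceleration direction is vertical; subtract gravity.

    The quasi-static assumption: averaged over many strides, the only DC
    component of the measured acceleration is the gravitational reaction, so
    the per-segment mean direction estimates the true vertical in sensor
    coordinates.  After rotation the signal is re-ordered to anatomical
    columns (VT, ML, AP-provisional) and 9.81 m/s^2 is subtracted from VT.
    """
    dirs = []
    for lo, hi in run.segments:
        m = run.samples[lo:hi].mean(axis=0)
        mag = np.linalg.norm(m)
        if mag < 5.0:
            raise AlignmentError(
                f"mean acceleration magnitude {mag:.2f} m/s^2 < 5; "
                "sensor is not capturing gravity"
            )
        dirs.append(m / mag)
    u = np.mean(dirs, axis=0)
    u /= np.linalg.norm(u)
    G = _minimal_rotation(u, np.array([0.0, 1.0, 0.0]))
    tilt = math.degrees(math.acos(np.clip(u[1], -1.0, 1.0)))
    # sensor -> ideal-sensor -> anatomical column order
    R = ANAT_TO_SENSOR.T @ G
    aligned = run.samples @ R.T
    aligned[:, 0] -= GRAVITY
    return AlignedSignal(
        samples=aligned,
        fs_hz=run.fs_hz,
        segments=list(run.segments),
        rotation_applied=R,
        condition=run.condition,
        participant=run.participant,
        speed_mps=run.speed_mps,
        tilt_deg=tilt,
        truth=run.truth,
        meta=dict(run.meta),
    )


def align_heading(sig: AlignedSignal) -> AlignedSignal:
    """Rotate the horizontal axes so AP carries the dominant horizontal variance.

    The principal axis of the horizontal (ML, AP) covariance estimates the
    direction of travel.  Orientation along that axis is fixed by requiring
    the mean signed skewness of AP to be non-negative (the braking/propulsion
    waveform of forward running is positively skewed); the 180-degree
    alternative flips both horizontal axes, preserving handedness.  If the
    horizontal variance is isotropic the rotation is the identity and
    ``status`` is set to ``"degenerate_horizontal"``.
    """
    hor = sig.samples[:, 1:3]  # (ML, AP)
    hc = hor - hor.mean(axis=0)
    C = hc.T @ hc / hc.shape[0]
    if abs(C[0, 0] - C[1, 1]) < 1e-12 and abs(C[0, 1]) < 1e-12:
        warnings.warn("horizontal variance isotropic; heading left unchanged")
        return sig.replace(status="degenerate_horizontal")
    evals, evecs = np.linalg.eigh(C)
    v = evecs[:, int(np.argmax(evals))]  # (ml, ap) components
    theta = math.atan2(v[0], v[1])  # angle of principal axis from the AP axis

    def _project(th: float) -> np.ndarray:
        # express horizontal samples in the basis whose AP axis lies at
        # angle th from the current AP axis (coordinate change)
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, s], [-s, c]])

    out = sig.samples.copy()
    out[:, 1:3] = sig.samples[:, 1:3] @ _project(theta)
    skews = []
    for lo, hi in sig.segments:
        ap = out[lo:hi, 2]
        apc = ap - ap.mean()
        sd = apc.std()
        skews.append(0.0 if sd < 1e-15 else float(np.mean(apc**3)) / sd**3)
    if np.mean(skews) < 0:
        out[:, 1:3] *= -1.0
        theta = theta - math.pi if theta > 0 else theta + math.pi
    # heading is reported so that it round-trips with the mounting rotation:
    # a sensor yawed by +h about vertical yields a principal axis at -h here
    heading = -math.degrees(theta)
    Q = np.eye(3)
    Q[1:3, 1:3] = _project(theta).T
    return sig.replace(
        samples=out,
        rotation_applied=Q @ sig.rotation_applied,
        heading_deg=heading,
    )


def preprocess_run(
    run: RawRun,
    cutoff_hz: float = 10.0,
    order: int = 4,
    trim_fraction: float = 0.05,
) -> AlignedSignal:
    """Full chain: filter, trim, gravity alignment, heading alignment."""
    run = butterworth_lowpass(run, cutoff_hz=cutoff_hz, order=order)
    run = trim_segments(run, fraction=trim_fraction)
    sig = align_gravity(run)
    return align_heading(sig)
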