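"""Gait-event detection and paretic limb-axis kinematics.

Computes the signed limb-axis angle (angle between the downward
vertical through the hip and the hip-to-ankle vector, flexion/anterior
positive), detects heel contacts and toe-offs from insole pressure with
cross-validation against shank anterior-posterior acceleration and
twice-differentiated ankle keypoints, and derives peak flexion /
extension angles, cadence and the single-support symmetry index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preproc import resample_segments, segment_strides

__all__ = [
    "KeypointTrace",
    "GaitEvents",
    "LimbAngleTrace",
    "interpolate_gaps",
    "limb_angle",
    "detect_events",
    "events_from_ankle_accel",
    "angle_per_stride",
    "peak_angles",
    "symmetry_index",
    "cadence",
    "cadence_from_events",
]


@dataclass
class KeypointTrace:
    """2-D hip and ankle keypoint trajectories (frames x 2)."""

    hip_xy: np.ndarray
    ankle_xy: np.ndarray
    fs: float
    y_axis: str = "up"  # "up" (metric) or "down" (image coordinates)

    def __post_init__(self) -> None:
        self.hip_xy = np.asarray(self.hip_xy, dtype=float)
        self.ankle_xy = np.asarray(self.ankle_xy, dtype=float)
        if self.hip_xy.shape != self.ankle_xy.shape:
            raise ValueError("hip and ankle traces must have equal frame counts")
        if self.y_axis not in ("up", "down"):
            raise ValueError("y_axis must be 'up' or 'down'")


@dataclass
class GaitEvents:
    """Detected gait events, as sample indices at ``fs``.

    Single-support durations are per paretic stride: the paretic
    single-support phase is the contralateral swing (non-paretic
    toe-off to non-paretic heel contact), and vice versa.
    """

    fs: float
    paretic_hc: np.ndarray
    nonparetic_hc: np.ndarray
    paretic_to: np.ndarray
    nonparetic_to: np.ndarray
    single_support_p: np.ndarray = field(default_factory=lambda: np.array([]))
    single_support_np: np.ndarray = field(default_factory=lambda: np.array([]))

    def times(self, which: str) -> np.ndarray:
        return np.asarray(getattr(self, which), dtype=float) / self.fs


@dataclass
class LimbAngleTrace:
    """Gait-normalized limb angle (strides x 100, degrees) with peaks."""

    angle_deg: np.ndarray
    peak_flexion_deg: float
    peak_extension_deg: float
    per_stride_flexion: np.ndarray
    per_stride_extension: np.ndarray


def interpolate_gaps(xy: np.ndarray, max_gap: int = 5) -> np.ndarray:
    """Fill NaN runs of up to ``max_gap`` frames by linear interpolation.

    Longer dropouts are left as NaN (callers discard affected strides).
    """
    out = np.array(xy, dtype=float)
    for col in range(out.shape[1]):
        y = out[:, col]
        bad = np.isnan(y)
        if not bad.any():
            continue
        # identify runs of NaN
        edges = np.flatnonzero(np.diff(np.concatenate([[0], bad.view(np.int8), [0]])))
        good_idx = np.flatnonzero(~bad)
        if good_idx.size == 0:
            continue
        filled = np.interp(np.arange(y.size), good_idx, y[good_idx])
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start <= max_gap and start > 0 and stop < y.size:
                y[start:stop] = filled[start:stop]
        out[:, col] = y
    return out


def limb_angle(
    trace: KeypointTrace, lowpass: float | None = 6.0, order: int = 4
) -> np.ndarray:
    """Signed limb-axis angle in degrees, flexion (ankle anterior) positive.

    The angle is measured between the downward vertical through the hip
    and the hip-to-ankle vector; positive x is the walking direction.
    The series is then low-pass filtered at 6 Hz with a zero-phase
    4th-order Butterworth filter (skipped when ``lowpass`` is None or
    the trace is too short for stable filtering).
    """
    v = trace.ankle_xy - trace.hip_xy
    norms = np.hypot(v[:, 0], v[:, 1])
    if np.any(norms == 0):
        raise ValueError("zero-length hip-to-ankle vector")
    vy_down = v[:, 1] if trace.y_axis == "down" else -v[:, 1]
    ang = np.degrees(np.arctan2(v[:, 0], vy_down))
    if lowpass is not None:
        sos = signal.butter(order, lowpass, btype="lowpass", fs=trace.fs, output="sos")
        padlen = 3 * (2 * sos.shape[0] + 1)
        if ang.size > padlen:
            ang = signal.sosfiltfilt(sos, ang)
    return ang


def _pulse_edges(pressure: np.ndarray, threshold_frac: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Onset (rising) and offset (falling) threshold crossings."""
    p = np.asarray(pressure, dtype=float)
    peak = p.max()
    if peak <= 0:
        raise ValueError("no pressure signal: all samples <= 0")
    above = p >= threshold_frac * peak
    d = np.diff(above.astype(np.int8))
    onsets = np.flatnonzero(d == 1) + 1
    offsets = np.flatnonzero(d == -1) + 1
    return onsets, offsets


def events_from_ankle_accel(
    ankle_xy: np.ndarray, fs: float, min_stride_s: float = 0.5
) -> np.ndarray:
    """Heel-contact candidates from twice-differentiated ankle keypoints.

    The ankle coordinates are differentiated twice; the magnitude of the
    resulting acceleration peaks at the heel-strike transient.  Returns
    peak sample indices.
    """
    a = np.gradient(np.gradient(np.asarray(ankle_xy, float), axis=0), axis=0) * fs**2
    mag = np.hypot(a[:, 0], a[:, 1])
    peaks, _ = signal.find_peaks(
        mag, height=0.5 * mag.max(), distance=max(1, int(min_stride_s * fs))
    )
    return peaks


def _single_support(
    hc_ipsi_t: np.ndarray, to_contra_t: np.ndarray, hc_contra_t: np.ndarray
) -> np.ndarray:
    """Ipsilateral single-support durations: contralateral swing times
    falling inside each ipsilateral stride."""
    out = []
    for t0, t1 in zip(hc_ipsi_t[:-1], hc_ipsi_t[1:]):
        tos = to_contra_t[(to_contra_t >= t0) & (to_contra_t < t1)]
        if tos.size == 0:
            continue
        to = tos[0]
        hcs = hc_contra_t[hc_contra_t > to]
        if hcs.size == 0:
            continue
        out.append(hcs[0] - to)
    return np.asarray(out)


def detect_events(
    pressure_p: np.ndarray,
    pressure_np: np.ndarray,
    fs: float,
    accel_ap: np.ndarray | None = None,
    ankle_trace: KeypointTrace | None = None,
    threshold_frac: float = 0.2,
    tolerance_s: float = 0.03,
) -> GaitEvents:
    """Detect heel contacts and toe-offs, insole pressure authoritative.

    Heel contacts are rising threshold crossings of each side's insole
    pressure and toe-offs the falling crossings.  When shank
    anterior-posterior acceleration and/or ankle keypoints are supplied,
    paretic heel contacts are cross-validated against acceleration peaks
    (accelerometer at ``fs``, keypoints at their own rate); source
    disagreement beyond ``tolerance_s`` produces a warning, and the
    insole events are kept.
    """
    hc_p, to_p = _pulse_edges(pressure_p, threshold_frac)
    hc_np, to_np = _pulse_edges(pressure_np, threshold_frac)
    if hc_p.size == 0 or hc_np.size == 0:
        raise ValueError("no heel contacts detected from insole pressure")

    hc_p_t = hc_p / fs
    # Validate only interior events: transients at the very ends of a
    # finite stream are not detectable as peaks by the secondary sources.
    t_end = pressure_p.size / fs
    interior = hc_p_t[(hc_p_t > 0.25) & (hc_p_t < t_end - 0.25)]
    if accel_ap is not None:
        stride = np.median(np.diff(hc_p_t)) if hc_p.size > 1 else 1.0
        peaks, _ = signal.find_peaks(
            accel_ap, height=0.5 * np.max(accel_ap), distance=max(1, int(0.5 * stride * fs))
        )
        _validate_events(interior, peaks / fs, tolerance_s, "shank AP acceleration")
    if ankle_trace is not None:
        kp = events_from_ankle_accel(ankle_trace.ankle_xy, ankle_trace.fs)
        _validate_events(interior, kp / ankle_trace.fs, tolerance_s,
                         "ankle keypoint acceleration")

    ev = GaitEvents(
        fs=fs,
        paretic_hc=hc_p,
        nonparetic_hc=hc_np,
        paretic_to=to_p,
        nonparetic_to=to_np,
    )
    ev.single_support_p = _single_support(hc_p / fs, to_np / fs, hc_np / fs)
    ev.single_support_np = _single_support(hc_np / fs, to_p / fs, hc_p / fs)
    return ev


def _validate_events(
    primary_t: np.ndarray, other_t: np.ndarray, tol: float, source: str
) -> None:
    if other_t.size == 0:
        warnings.warn(f"no events found in {source}", stacklevel=3)
        return
    errs = [np.min(np.abs(other_t - t)) for t in primary_t]
    worst = float(np.max(errs))
    if worst > tol:
        warnings.warn(
            f"{source} events deviate from insole events by up to {worst * 1e3:.0f} ms "
            f"(tolerance {tol * 1e3:.0f} ms); insole events kept",
            stacklevel=3,
        )


def angle_per_stride(
    angle_deg: np.ndarray,
    events: np.ndarray,
    trim: int = 3,
    max_strides: int = 20,
    n_points: int = 100,
) -> np.ndarray:
    """Segment an angle series at heel contacts and time-normalize.

    Returns a strides x ``n_points`` array using the same trimming and
    stride-count rules as the EMG chain.
    """
    segs = segment_strides(np.asarray(angle_deg, float)[None, :], events,
                           trim=trim, max_strides=max_strides)
    flat = resample_segments(segs, n_points)
    return flat[0].reshape(len(segs), n_points)


def peak_angles(angle_cycles: np.ndarray) -> LimbAngleTrace:
    """Peak flexion (max) and extension (min) per stride and their means.

    ``angle_cycles`` is strides x points (degrees, flexion positive).
    """
    a = np.atleast_2d(np.asarray(angle_cycles, dtype=float))
    flex = a.max(axis=1)
    ext = a.min(axis=1)
    return LimbAngleTrace(
        angle_deg=a,
        peak_flexion_deg=float(flex.mean()),
        peak_extension_deg=float(ext.mean()),
        per_stride_flexion=flex,
        per_stride_extension=ext,
    )


def symmetry_index(ss_p: float, ss_np: float) -> float:
    """Single-support symmetry index, percent.

    ``SI = 100 * (ss_p - ss_np) / (0.5 * (ss_p + ss_np))``; negative
    means the paretic single-support phase is shorter than the
    non-paretic one.
    """
    if ss_p <= 0 or ss_np <= 0:
        raise ValueError("single-support durations must be positive")
    return 100.0 * (ss_p - ss_np) / (0.5 * (ss_p + ss_np))


def cadence(events: GaitEvents, duration_s: float) -> float:
    """Steps per minute: heel-contact intervals of both sides over time.

    Each heel-contact interval on either side is one step; with two
    steps per stride, 20 strides of 1.2 s give 100 steps/min.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    steps = max(len(events.paretic_hc) - 1, 0) + max(len(events.nonparetic_hc) - 1, 0)
    if steps < 1:
        raise ValueError("need at least 2 heel contacts to compute cadence")
    return steps / duration_s * 60.0


def cadence_from_events(events: GaitEvents) -> float:
    """Steps per minute from the detected events alone.

    Each side's heel-contact intervals are counted over that side's own
    first-to-last contact span, so lead-in and run-out outside the
    counted steps do not dilute the rate.
    """
    rate = 0.0
    any_side = False
    for side in ("paretic_hc", "nonparetic_hc"):
        t = events.times(side)
        if t.size >= 2 and t[-1] > t[0]:
            rate += (t.size - 1) / (t[-1] - t[0])
            any_side = True
    if not any_side:
        raise ValueError("need at least 2 heel contacts on one side")
    return rate * 60.0
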