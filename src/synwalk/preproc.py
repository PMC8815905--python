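"""Surface-EMG envelope preprocessing for gait-cycle synergy analysis.

The chain transforms raw multi-channel EMG into the nonnegative,
amplitude- and time-normalized envelope matrix that non-negative matrix
factorization consumes:

1. zero-phase 4th-order Butterworth band-pass, 20-500 Hz;
2. de-mean, full-wave rectify, zero-phase 4th-order Butterworth
   low-pass at 10 Hz, negative filter ripple clipped to 0;
3. amplitude normalization by each muscle's maximum over the whole
   recording session (all walking conditions pooled, configurable);
4. stride segmentation at paretic heel contacts, dropping the first and
   last three gait cycles and keeping 20 strides;
5. linear time-normalization of each stride to a 100-point gait-cycle
   base, strides concatenated along time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

log = logging.getLogger("synwalk")

__all__ = [
    "RawEmg",
    "EnvelopeMatrix",
    "bandpass_emg",
    "envelope",
    "normalize_amplitude",
    "segment_strides",
    "time_normalize",
    "preprocess",
]

N_POINTS = 100


@dataclass
class RawEmg:
    """Raw multi-channel EMG recording (channels x samples)."""

    samples: np.ndarray
    fs: float
    muscle_names: tuple[str, ...]
    condition: str = "cws"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if len(self.muscle_names) != self.samples.shape[0]:
            raise ValueError("muscle_names length must match channel count")
        if np.isnan(self.samples).any():
            raise ValueError("raw EMG contains NaN")


@dataclass
class EnvelopeMatrix:
    """Nonnegative muscles x (100 * n_strides) normalized envelope matrix."""

    values: np.ndarray
    muscle_names: tuple[str, ...]
    n_strides: int
    condition: str = "cws"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != N_POINTS * self.n_strides:
            raise ValueError(
                f"expected {N_POINTS * self.n_strides} columns, got {self.values.shape[1]}"
            )
        if (self.values < 0).any():
            raise ValueError("envelope matrix must be nonnegative")


def _sos_filtfilt(x: np.ndarray, sos: np.ndarray) -> np.ndarray:
    # sosfiltfilt's default padding is 3 * (number of second-order
    # sections * 2 + 1) samples of odd-reflection on each end.
    n = x.shape[-1]
    padlen = 3 * (2 * sos.shape[0] + 1)
    if n <= padlen:
        raise ValueError(
            f"signal too short for stable zero-phase filtering "
            f"({n} samples, need > {padlen})"
        )
    return signal.sosfiltfilt(sos, x, axis=-1)


def bandpass_emg(
    raw: RawEmg, low: float = 20.0, high: float = 500.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of each EMG channel.

    The filter is designed at the requested order and applied forward
    and backward (zero lag).  If the high cutoff is not below the
    Nyquist frequency (fs <= 1000 Hz for the 500 Hz default), it is
    clamped to 0.45 * fs with a warning.
    """
    high_eff = high
    if high >= raw.fs / 2:
        high_eff = 0.45 * raw.fs
        warnings.warn(
            f"band-pass high cutoff {high} Hz >= Nyquist ({raw.fs / 2} Hz); "
            f"clamped to {high_eff} Hz",
            stacklevel=2,
        )
    sos = signal.butter(order, [low, high_eff], btype="bandpass", fs=raw.fs, output="sos")
    return _sos_filtfilt(raw.samples, sos)


def envelope(
    filtered: np.ndarray, fs: float, lowpass: float = 10.0, order: int = 4
) -> np.ndarray:
    """Linear envelope: de-mean, rectify, 10 Hz zero-phase low-pass.

    Negative ripple introduced by the low-pass is clipped to zero so the
    result is a valid NNMF input; the clipped magnitude is reported via
    a warning when it is non-trivial.
    """
    x = np.asarray(filtered, dtype=float)
    x = x - x.mean(axis=-1, keepdims=True)
    x = np.abs(x)
    sos = signal.butter(order, lowpass, btype="lowpass", fs=fs, output="sos")
    env = _sos_filtfilt(x, sos)
    clipped = -env[env < 0].sum()
    if clipped > 0:
        log.debug("clipped negative envelope ripple (total magnitude %.3g)", clipped)
    return np.clip(env, 0.0, None)


def normalize_amplitude(
    envelopes: np.ndarray | list[np.ndarray], scope: str = "session"
) -> np.ndarray | list[np.ndarray]:
    """Divide each muscle by its maximum amplitude recorded.

    Parameters
    ----------
    envelopes
        One channels x time envelope array, or a list of them (one per
        walking condition).
    scope
        ``"session"`` (default): the per-muscle maximum is taken over
        all supplied conditions pooled, so envelopes stay comparable
        across conditions.  ``"condition"``: each array is normalized by
        its own maxima.

    All-zero channels are left unchanged with a warning.
    """
    single = isinstance(envelopes, np.ndarray)
    arrs = [np.asarray(envelopes, dtype=float)] if single else [np.asarray(a, float) for a in envelopes]
    if scope not in ("session", "condition"):
        raise ValueError("scope must be 'session' or 'condition'")

    def _scale(a: np.ndarray, maxima: np.ndarray) -> np.ndarray:
        m = maxima.copy()
        zero = m == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} all-zero channel(s) left unnormalized",
                          stacklevel=3)
            m[zero] = 1.0
        return a / m[:, None]

    if scope == "session":
        maxima = np.max([a.max(axis=1) for a in arrs], axis=0)
        out = [_scale(a, maxima) for a in arrs]
    else:
        out = [_scale(a, a.max(axis=1)) for a in arrs]
    return out[0] if single else out


def segment_strides(
    env: np.ndarray,
    events: np.ndarray,
    trim: int = 3,
    max_strides: int = 20,
) -> list[np.ndarray]:
    """Cut an envelope array into per-stride segments at heel contacts.

    ``events`` are paretic heel-contact sample indices; consecutive
    events bound one gait cycle.  The first and last ``trim`` cycles are
    removed (walkway acceleration/deceleration) and the first
    ``max_strides`` remaining cycles are returned.  Fewer surviving
    strides produce a warning; none is an error.
    """
    events = np.asarray(events, dtype=int)
    n_cycles = len(events) - 1
    if n_cycles < 1:
        raise ValueError("need at least two heel-contact events")
    keep = range(trim, n_cycles - trim)
    segments = [env[:, events[i] : events[i + 1]] for i in keep
                if events[i + 1] - events[i] >= 2]
    if not segments:
        raise ValueError(
            f"no strides remain after trimming {trim} cycles from each end "
            f"of {n_cycles} cycles"
        )
    if len(segments) < max_strides:
        warnings.warn(
            f"only {len(segments)} strides available after trimming "
            f"(wanted {max_strides})",
            stacklevel=2,
        )
    return segments[:max_strides]


def resample_segments(segments: list[np.ndarray], n_points: int = N_POINTS) -> np.ndarray:
    """Linear interpolation of each channels x samples segment onto a
    common ``n_points`` base, concatenated along time."""
    if not segments:
        raise ValueError("empty segment list")
    out = []
    for seg in segments:
        seg = np.atleast_2d(np.asarray(seg, dtype=float))
        if seg.shape[1] < 2:
            raise ValueError("each stride segment needs at least 2 samples")
        src = np.linspace(0.0, 1.0, seg.shape[1])
        dst = np.linspace(0.0, 1.0, n_points)
        out.append(np.vstack([np.interp(dst, src, ch) for ch in seg]))
    return np.hstack(out)


def time_normalize(
    segments: list[np.ndarray],
    muscle_names: tuple[str, ...] | None = None,
    condition: str = "cws",
    n_points: int = N_POINTS,
) -> EnvelopeMatrix:
    """Linearly interpolate each stride to ``n_points`` and concatenate.

    Each segment (channels x samples, samples >= 2) is resampled onto a
    common ``n_points`` gait-cycle base by linear interpolation, with
    the first and last samples mapped to cycle 0% and 100%; segments are
    then concatenated along time into a channels x (n_points * strides)
    matrix.
    """
    values = resample_segments(segments, n_points)
    if muscle_names is None:
        muscle_names = tuple(f"ch{i}" for i in range(values.shape[0]))
    return EnvelopeMatrix(
        values=values,
        muscle_names=tuple(muscle_names),
        n_strides=len(segments),
        condition=condition,
    )


def preprocess(
    raw: RawEmg,
    events: np.ndarray,
    band: tuple[float, float] = (20.0, 500.0),
    envelope_lp: float = 10.0,
    filter_order: int = 4,
    trim: int = 3,
    max_strides: int = 20,
    precomputed_max: np.ndarray | None = None,
) -> EnvelopeMatrix:
    """Full chain: band-pass -> envelope -> normalize -> segment -> 100-pt.

    ``precomputed_max`` supplies session-pooled per-muscle maxima (from
    :func:`session_maxima`) when several conditions share one
    normalization; otherwise this recording's own maxima are used.
    """
    filt = bandpass_emg(raw, band[0], band[1], filter_order)
    env = envelope(filt, raw.fs, envelope_lp, filter_order)
    if precomputed_max is not None:
        m = np.where(precomputed_max > 0, precomputed_max, 1.0)
        env = env / m[:, None]
    else:
        env = normalize_amplitude(env)
    segments = segment_strides(env, events, trim=trim, max_strides=max_strides)
    return time_normalize(segments, raw.muscle_names, raw.condition)


def session_maxima(envelopes: list[np.ndarray]) -> np.ndarray:
    """Per-muscle maxima pooled over all conditions of one session."""
    return np.max([np.asarray(a).max(axis=1) for a in envelopes], axis=0)
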