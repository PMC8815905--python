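"""Synthetic hemiparetic-gait generator.

Produces multi-channel EMG envelopes (and optional raw EMG carriers),
2-D hip/ankle keypoint trajectories, insole foot-pressure and shank
accelerometer streams with known ground truth, so that the whole
analysis chain — envelope preprocessing, gait-event detection, NNMF
synergy extraction, VAF model selection and merging-subtype
classification — can be exercised and validated without patient data.

The forward model mirrors the factorization the analysis assumes:
``V = W · C + noise`` with nonnegative synergy weights ``W`` (muscles x k)
and activations ``C`` (k x time).  Activations are truncated Gaussian
bursts on the circular 0-100% gait cycle, one set per canonical module;
a merged subtype replaces two parent modules by a single synergy whose
weight vector is the normalized sum of the parents and whose activation
is the pointwise maximum of the parent activations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .templates import (
    MUSCLES,
    ModuleTemplateSet,
    SUBTYPE_OF_PAIR,
    make_canonical_modules,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "KinematicsData",
    "make_canonical_modules",
    "make_activation_profiles",
    "synthesize_envelopes",
    "synthesize_raw_emg",
    "synthesize_kinematics",
    "stride_timeline",
    "config_for_condition",
]

N_POINTS = 100  # points per normalized gait cycle

# Activation bursts per module: (center %, sigma %, amplitude) on the
# circular 0-100 cycle.  Module 1 fires in early stance, module 2 in
# late stance (push-off), module 3 twice (weight acceptance + early
# swing), module 4 in terminal swing wrapping into initial contact.
DEFAULT_BUMPS: dict[int, tuple[tuple[float, float, float], ...]] = {
    1: ((15.0, 8.0, 1.0),),
    2: ((45.0, 8.0, 1.0),),
    3: ((5.0, 5.0, 1.0), (70.0, 8.0, 1.0)),
    4: ((92.0, 8.0, 1.0),),
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic gait generator.

    Defaults emulate the recording setup of a hemiparetic-gait study:
    8 paretic-side EMG channels at 1926 Hz, sagittal video keypoints at
    60 Hz, insole pressure / shank accelerometer at 100 Hz, ~1.2 s
    strides, peak limb flexion/extension of +14.5 / -14.4 degrees.
    """

    n_strides: int = 20
    stride_duration_s: float = 1.2
    emg_fs: float = 1926.0
    kin_fs: float = 60.0
    insole_fs: float = 100.0
    merge_pair: tuple[int, int] | None = None
    noise_sd: float = 0.0
    stride_jitter_cv: float = 0.03
    peak_flexion_deg: float = 14.5
    peak_extension_deg: float = -14.4
    stance_frac_p: float = 0.60
    stance_frac_np: float = 0.60
    limb_length_m: float = 0.85
    bump_width_scale: float = 1.0
    bumps: dict[int, tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_BUMPS)
    )
    condition: str = "cws"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.stride_jitter_cv < 0:
            raise ValueError("stride_jitter_cv must be >= 0")
        if self.merge_pair is not None:
            a, b = self.merge_pair
            if a == b or not {a, b} <= {1, 2, 3, 4}:
                raise ValueError("merge_pair must be two distinct module ids in 1..4")
            object.__setattr__(self, "merge_pair", tuple(sorted((a, b))))


@dataclass
class GroundTruth:
    """True factorization underlying a synthetic envelope matrix.

    ``W_true`` (muscles x k, unit-norm columns) and ``C_true`` (k x
    100*n_strides) satisfy ``V = W_true @ C_true`` exactly at zero
    noise, expressed on the same per-muscle-normalized scale as the
    emitted envelope matrix.
    """

    W_true: np.ndarray
    C_true: np.ndarray
    k: int
    subtype_true: str
    merge_pair: tuple[int, int] | None
    module_order: tuple[object, ...]


def _circular_bump(p: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    d = np.mod(p - center + 50.0, 100.0) - 50.0
    return amp * np.exp(-0.5 * (d / sigma) ** 2)


def _module_profile(config: SynthConfig, module_id: int, p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    for center, sigma, amp in config.bumps[module_id]:
        np.maximum(out, _circular_bump(p, center, sigma * config.bump_width_scale, amp),
                   out=out)
    return out


def _module_order(config: SynthConfig) -> tuple[object, ...]:
    """Row order of the true activation matrix: unmerged ids ascending,
    the merged pair (as a tuple) last."""
    if config.merge_pair is None:
        return (1, 2, 3, 4)
    a, b = config.merge_pair
    return tuple([m for m in (1, 2, 3, 4) if m not in (a, b)] + [(a, b)])


def make_activation_profiles(config: SynthConfig) -> np.ndarray:
    """Per-stride activation templates on the 100-point cycle.

    Returns a k x (100 * n_strides) nonnegative matrix; each stride
    repeats the same deterministic template.  A merged module's row is
    the pointwise maximum of its two parents' profiles.
    """
    p = np.arange(N_POINTS, dtype=float)
    rows = []
    for entry in _module_order(config):
        if isinstance(entry, tuple):
            prof = np.maximum(
                _module_profile(config, entry[0], p),
                _module_profile(config, entry[1], p),
            )
        else:
            prof = _module_profile(config, entry, p)
        rows.append(prof)
    one_cycle = np.vstack(rows)
    return np.tile(one_cycle, (1, config.n_strides))


def _true_weights(config: SynthConfig, templates: ModuleTemplateSet) -> np.ndarray:
    cols = []
    for entry in _module_order(config):
        if isinstance(entry, tuple):
            cols.append(templates.merged_column(entry))
        else:
            cols.append(templates.module_column(entry))
    return np.column_stack(cols)


def synthesize_envelopes(
    config: SynthConfig, muscle_names: tuple[str, ...] = MUSCLES
) -> tuple[np.ndarray, GroundTruth]:
    """Generate a normalized 8 x (100 * n_strides) envelope matrix.

    The matrix is the forward model ``W @ C`` plus additive Gaussian
    noise (``noise_sd`` is a fraction of each channel's envelope peak),
    clipped at zero, then scaled so each muscle's maximum is 1 — the
    same amplitude normalization the preprocessing chain applies to
    recorded EMG.  Ground truth is returned on the emitted scale.
    """
    templates = make_canonical_modules(muscle_names)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))

    W0 = _true_weights(config, templates)
    C0 = make_activation_profiles(config)
    V0 = W0 @ C0

    if config.noise_sd > 0:
        peaks = V0.max(axis=1, keepdims=True)
        peaks[peaks == 0] = 1.0
        V = V0 + rng.normal(0.0, config.noise_sd, V0.shape) * peaks
        np.clip(V, 0.0, None, out=V)
    else:
        V = V0.copy()

    row_max = V.max(axis=1, keepdims=True)
    scale = np.where(row_max > 0, row_max, 1.0)
    V /= scale

    # Ground truth on the emitted (row-scaled) scale.
    W_scaled = W0 / scale
    col_norms = np.linalg.norm(W_scaled, axis=0, keepdims=True)
    col_norms[col_norms == 0] = 1.0
    W_true = W_scaled / col_norms
    C_true = C0 * col_norms.T

    pair = config.merge_pair
    subtype = SUBTYPE_OF_PAIR.get(pair, "other_merge") if pair else "non_merged"
    gt = GroundTruth(
        W_true=W_true,
        C_true=C_true,
        k=W_true.shape[1],
        subtype_true=subtype,
        merge_pair=pair,
        module_order=_module_order(config),
    )
    return V, gt


def stride_timeline(config: SynthConfig, n_extra: int = 1) -> np.ndarray:
    """Jittered stride durations (seconds), length ``n_strides + n_extra``.

    Durations are drawn once from the config seed so EMG, keypoint and
    insole synthesis share one consistent timeline.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7]))
    n = config.n_strides + n_extra
    if config.stride_jitter_cv > 0:
        durs = config.stride_duration_s * (
            1.0 + config.stride_jitter_cv * rng.standard_normal(n)
        )
        durs = np.clip(durs, 0.5 * config.stride_duration_s, 1.5 * config.stride_duration_s)
    else:
        durs = np.full(n, config.stride_duration_s)
    return durs


def _cycle_phase(t: np.ndarray, starts: np.ndarray, durs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map times to (stride index, cycle percent in [0, 100))."""
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(durs) - 1)
    phase = (t - starts[idx]) / durs[idx] * 100.0
    return idx, np.clip(phase, 0.0, 100.0 - 1e-9)


def synthesize_raw_emg(
    envelopes: np.ndarray, config: SynthConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude-modulated broadband carriers from envelope ground truth.

    Each channel is zero-mean Gaussian noise band-limited to 20-450 Hz
    at ``emg_fs``, multiplied by the channel's envelope resampled onto
    the jittered stride timeline.  Returns ``(raw, t)`` with raw shaped
    channels x samples.
    """
    if config.emg_fs < 1000.0:
        raise ValueError("emg_fs must be >= 1000 Hz for raw-carrier synthesis")
    n_ch = envelopes.shape[0]
    n_strides = envelopes.shape[1] // N_POINTS
    durs = stride_timeline(config)[:n_strides]
    starts = np.concatenate([[0.0], np.cumsum(durs)])[:-1]
    total = starts[-1] + durs[-1]
    t = np.arange(0.0, total, 1.0 / config.emg_fs)

    idx, phase = _cycle_phase(t, starts, durs)
    p_grid = np.arange(N_POINTS, dtype=float)
    env_t = np.empty((n_ch, t.size))
    for s in range(n_strides):
        sel = idx == s
        seg = envelopes[:, s * N_POINTS : (s + 1) * N_POINTS]
        for ch in range(n_ch):
            env_t[ch, sel] = np.interp(phase[sel], p_grid, seg[ch])

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 13]))
    carrier = rng.standard_normal((n_ch, t.size))
    sos = signal.butter(4, [20.0, 450.0], btype="bandpass", fs=config.emg_fs, output="sos")
    carrier = signal.sosfiltfilt(sos, carrier, axis=1)
    std = carrier.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    carrier /= std
    return env_t * carrier, t


@dataclass
class KinematicsData:
    """Synthetic keypoint, insole and accelerometer streams with truth."""

    t_kin: np.ndarray
    hip_xy: np.ndarray      # frames x 2, metric, y up
    ankle_xy: np.ndarray    # frames x 2
    kin_fs: float
    t_insole: np.ndarray
    pressure_p: np.ndarray
    pressure_np: np.ndarray
    accel: np.ndarray       # samples x 3 (AP, ML, vertical)
    insole_fs: float
    true_hc_p: np.ndarray   # heel-contact times (s), paretic
    true_hc_np: np.ndarray
    true_to_p: np.ndarray   # toe-off times (s)
    true_to_np: np.ndarray
    angle_true: np.ndarray  # limb angle (deg) at t_kin, before any filtering


def _stance_pulse(phase_frac: np.ndarray, stance_frac: float, ramp: float = 0.01) -> np.ndarray:
    """Squarish stance pulse on cycle fraction in [0, 1): smooth ramps
    at contact and toe-off."""
    up = np.clip(phase_frac / ramp, 0.0, 1.0)
    down = np.clip((stance_frac - phase_frac) / ramp, 0.0, 1.0)
    pulse = np.minimum(up, down)
    pulse[phase_frac >= stance_frac] = 0.0
    return 0.5 - 0.5 * np.cos(np.pi * np.clip(pulse, 0.0, 1.0))


def synthesize_kinematics(config: SynthConfig) -> KinematicsData:
    """Generate keypoints, insole pressures, shank acceleration and truth.

    The paretic limb angle follows a smooth periodic curve attaining the
    configured peak flexion (late swing, ~90% cycle) and peak extension
    once per stride; hip and ankle keypoints are back-computed from the
    angle with a fixed limb length in a metric y-up frame.  A small
    damped 15 Hz oscillation is added to the ankle trajectory at each
    paretic heel contact so keypoint-derived accelerations carry the
    heel-strike transient real data shows.  Exactly ``n_strides`` true
    heel-contact intervals per side are produced.
    """
    durs = stride_timeline(config, n_extra=1)
    starts = np.concatenate([[0.0], np.cumsum(durs)])
    n = config.n_strides

    hc_p = starts[: n + 1]                                   # n intervals
    hc_np = starts[:-1] + 0.5 * durs                         # n+1 events, n intervals
    to_p = starts[:-1] + config.stance_frac_p * durs
    to_np = hc_np + config.stance_frac_np * durs

    total = hc_np[-1] + (config.stance_frac_np + 0.05) * durs[-1]
    t_kin = np.arange(0.0, total, 1.0 / config.kin_fs)
    t_ins = np.arange(0.0, total, 1.0 / config.insole_fs)

    # Limb angle: mid + amp*cos peaks once at p=90 (flexion) and once at
    # p=40 (extension) per cycle.
    mid = 0.5 * (config.peak_flexion_deg + config.peak_extension_deg)
    amp = 0.5 * (config.peak_flexion_deg - config.peak_extension_deg)
    _, phase = _cycle_phase(t_kin, starts[:-1], durs)
    angle = mid + amp * np.cos(2.0 * np.pi * (phase - 90.0) / 100.0)

    L = config.limb_length_m
    theta = np.deg2rad(angle)
    hip = np.tile([0.0, L], (t_kin.size, 1))
    ankle = hip + L * np.column_stack([np.sin(theta), -np.cos(theta)])

    # Heel-strike transient: a brief impact dip of the ankle trajectory
    # centred on each contact, so keypoint-derived acceleration peaks at
    # the heel strike itself.
    for t0 in hc_p:
        ankle[:, 1] -= 0.006 * np.exp(-0.5 * ((t_kin - t0) / 0.015) ** 2)

    # Insole pressures: stance pulses per side.
    idx_i, phase_i = _cycle_phase(t_ins, starts[:-1], durs)
    press_p = _stance_pulse(phase_i / 100.0, config.stance_frac_p)
    frac_np = np.mod(phase_i / 100.0 - 0.5, 1.0)
    press_np = _stance_pulse(frac_np, config.stance_frac_np)

    # Shank AP acceleration (paretic): sharp peak at each heel contact.
    ax = np.zeros_like(t_ins)
    for t0 in hc_p:
        ax += 30.0 * np.exp(-0.5 * ((t_ins - t0) / 0.03) ** 2)
    ax += 2.0 * np.sin(2.0 * np.pi * phase_i / 100.0)
    accel = np.column_stack([ax, 0.2 * np.cos(2 * np.pi * phase_i / 100.0), np.full_like(ax, 9.81)])

    return KinematicsData(
        t_kin=t_kin,
        hip_xy=hip,
        ankle_xy=ankle,
        kin_fs=config.kin_fs,
        t_insole=t_ins,
        pressure_p=press_p,
        pressure_np=press_np,
        accel=accel,
        insole_fs=config.insole_fs,
        true_hc_p=hc_p,
        true_hc_np=hc_np,
        true_to_p=to_p,
        true_to_np=to_np,
        angle_true=angle,
    )


# Walking-condition presets.  The experimental manipulation increases
# paretic-side limb flexion (p-long) or extension via the contralateral
# long step (np-long); in the generator the p-long condition also
# sharpens activation bursts (less temporal overlap -> more complex
# synergy structure, lower VAF1), emulating the direction of the
# condition effect seen in swing-phase-impaired gait.
_CONDITION_PRESETS: dict[str, dict] = {
    "cws": {},
    "p-long": {"peak_flexion_deg": +2.0, "peak_extension_deg": -1.0, "bump_width_scale": 0.75},
    "np-long": {"peak_flexion_deg": +0.9, "peak_extension_deg": -3.7},
}


def config_for_condition(base: SynthConfig, condition: str) -> SynthConfig:
    """Derive a condition-specific config from a base (cws) config.

    Angle offsets are applied relative to the base peaks; each condition
    also gets its own seed stream so noise realizations differ.
    """
    if condition not in _CONDITION_PRESETS:
        raise ValueError(f"unknown condition {condition!r}; expected one of "
                         f"{sorted(_CONDITION_PRESETS)}")
    preset = _CONDITION_PRESETS[condition]
    cond_index = sorted(_CONDITION_PRESETS).index(condition)
    return replace(
        base,
        condition=condition,
        peak_flexion_deg=base.peak_flexion_deg + preset.get("peak_flexion_deg", 0.0),
        peak_extension_deg=base.peak_extension_deg + preset.get("peak_extension_deg", 0.0),
        bump_width_scale=base.bump_width_scale * preset.get("bump_width_scale", 1.0),
        seed=int(base.seed) * 8 + cond_index + 1,
    )
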