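"""Muscle-synergy extraction by multiplicative-update NNMF.

Factorizes a nonnegative envelope matrix ``V`` (muscles x time) as
``V ~ W @ C`` with Lee-Seung multiplicative updates minimizing the
Frobenius reconstruction error, repeated from many random
initializations with the lowest root-mean-square residual kept.  Model
quality is quantified by the variance accounted for,

    VAF_n = 1 - sum(error^2) / sum(EMG^2),

globally and per muscle.  The number of synergies is the smallest n
whose global VAF exceeds 90%, whose increment to n+1 is at most 5
percentage points, and whose per-muscle VAF is at least 75% for every
muscle.  VAF1 — the VAF of a one-synergy model — summarizes synergy
complexity: high VAF1 means one synergy explains most of the variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NmfSettings",
    "SynergySet",
    "nmf_factorize",
    "multi_restart",
    "compute_vaf",
    "select_from_curve",
    "select_num_synergies",
    "vaf1",
    "order_synergies",
]

_EPS = 1e-12


@dataclass(frozen=True)
class NmfSettings:
    """Stopping rules and restart scheme of the factorization.

    ``tol_residual`` stops iteration when the RMS residual improves by
    less; ``tol_relative_change`` when no element of W or C changes by
    more (relatively).  ``n_restarts`` random initializations are run
    and the best (lowest RMS residual) kept; 1000 restarts is the
    analysis default, smaller values are appropriate for synthetic
    desk-scale runs.
    """

    tol_residual: float = 1e-6
    tol_relative_change: float = 1e-4
    n_restarts: int = 1000
    max_iter: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol_residual <= 0 or self.tol_relative_change <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class SynergySet:
    """Result of synergy extraction at the selected model order."""

    W: np.ndarray                 # muscles x n, unit-norm columns
    C: np.ndarray                 # n x time
    n: int
    vaf_curve: np.ndarray         # global VAF for k = 1..len(vaf_curve)
    per_muscle_vaf: np.ndarray    # at the selected n
    vaf1: float
    rms_residual: float
    muscle_names: tuple[str, ...] | None = None
    selection_fallback: bool = False


def _check_input(V: np.ndarray) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be 2-D (muscles x time)")
    if (V < 0).any():
        raise ValueError("V must be nonnegative")
    if not V.any():
        raise ValueError("V is all zero; factorization undefined")
    return V


def _rms(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    R = V - W @ H
    return float(np.sqrt(np.mean(R * R)))


def nmf_factorize(
    V: np.ndarray,
    k: int,
    settings: NmfSettings | None = None,
    restart_seed: int | np.random.SeedSequence = 0,
    track_residuals: bool = False,
) -> tuple[np.ndarray, np.ndarray, float] | tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """One multiplicative-update factorization from a random start.

    Initial W and C entries are i.i.d. uniform on (0, 1] (strictly
    positive, so no element is locked at zero).  Updates are the
    standard Lee-Seung rules for the Frobenius objective, under which
    the residual is non-increasing.  Iteration stops when the RMS
    residual improves by less than ``tol_residual``, when the largest
    relative element change drops below ``tol_relative_change``, or at
    ``max_iter``.  Returns ``(W, C, rms_residual)`` with unit-norm W
    columns (C rescaled reciprocally); with ``track_residuals`` the
    per-iteration RMS residual sequence is appended.
    """
    settings = settings or NmfSettings()
    V = _check_input(V)
    m, t = V.shape
    if not 1 <= k <= m:
        raise ValueError(f"k must be in 1..{m}")

    rng = np.random.default_rng(restart_seed)
    W = 1.0 - rng.random((m, k))   # uniform on (0, 1]
    H = 1.0 - rng.random((k, t))

    # Residual tolerance on the signal's own RMS scale, so stopping is
    # invariant to the amplitude units of V.
    res_thr = settings.tol_residual * float(np.sqrt(np.mean(V * V)))
    rms_prev = _rms(V, W, H)
    history = [rms_prev] if track_residuals else None
    for _ in range(settings.max_iter):
        W_old, H_old = W, H
        H = H * (W.T @ V) / (W.T @ W @ H + _EPS)
        W = W * (V @ H.T) / (W @ (H @ H.T) + _EPS)
        rms = _rms(V, W, H)
        if track_residuals:
            history.append(rms)
        rel = max(
            np.max(np.abs(W - W_old) / (np.abs(W_old) + _EPS)),
            np.max(np.abs(H - H_old) / (np.abs(H_old) + _EPS)),
        )
        if rms_prev - rms < res_thr or rel < settings.tol_relative_change:
            rms_prev = rms
            break
        rms_prev = rms

    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    H = H * norms[:, None]
    if track_residuals:
        return W, H, rms_prev, np.asarray(history)
    return W, H, rms_prev


def multi_restart(
    V: np.ndarray, k: int, settings: NmfSettings | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``n_restarts`` factorization (lowest RMS residual).

    Restart i uses the seed stream ``[settings.seed, k, i]``, so results
    are deterministic given the master seed, and the restart sequence
    for a smaller ``n_restarts`` is a prefix of that for a larger one.
    """
    settings = settings or NmfSettings()
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for i in range(settings.n_restarts):
        seq = np.random.SeedSequence([int(settings.seed), int(k), i])
        W, H, rms = nmf_factorize(V, k, settings, restart_seed=seq)
        if best is None or rms < best[2]:
            best = (W, H, rms)
    return best


def compute_vaf(V: np.ndarray, W: np.ndarray, C: np.ndarray) -> tuple[float, np.ndarray]:
    """Global and per-muscle variance accounted for.

    ``VAF = 1 - sum(error^2) / sum(EMG^2)`` with the sums over all
    muscles and time points (global) or over one muscle's row
    (per-muscle).  All-zero V (or an all-zero muscle row, for the
    per-muscle variant) is undefined.
    """
    V = np.asarray(V, dtype=float)
    err = V - W @ C
    sst = float((V * V).sum())
    if sst == 0:
        raise ValueError("VAF undefined for all-zero V")
    vaf_global = 1.0 - float((err * err).sum()) / sst
    row_sst = (V * V).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_muscle = 1.0 - (err * err).sum(axis=1) / row_sst
    per_muscle[row_sst == 0] = np.nan
    return vaf_global, per_muscle


def order_synergies(W: np.ndarray, C: np.ndarray, n_points: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Order synergies by activation-peak timing within the mean cycle.

    The factorization is identifiable only up to column permutation and
    scale; reporting orders columns by the gait-cycle percent at which
    the stride-averaged activation peaks.
    """
    t = C.shape[1]
    if t % n_points == 0 and t >= n_points:
        mean_cycle = C.reshape(C.shape[0], -1, n_points).mean(axis=1)
    else:
        mean_cycle = C
    order = np.argsort(np.argmax(mean_cycle, axis=1), kind="stable")
    return W[:, order], C[order]


def select_from_curve(
    vaf_curve,
    per_muscle_min,
    global_thr: float = 0.90,
    increment_thr: float = 0.05,
    local_thr: float = 0.75,
    complete: bool = False,
) -> int | None:
    """The synergy-count rule, applied to a VAF curve.

    Returns the smallest k (1-based) whose global VAF exceeds
    ``global_thr``, whose increment to k+1 is at most ``increment_thr``,
    and whose worst per-muscle VAF (``per_muscle_min[k-1]``) is at least
    ``local_thr``.  ``complete=True`` marks the curve as extending to
    the maximum possible model order, making the increment criterion
    vacuous at the last entry.  Returns None when this curve prefix does
    not yet decide a k.
    """
    vaf_curve = list(vaf_curve)
    per_muscle_min = list(per_muscle_min)
    K = len(vaf_curve)
    for k in range(1, K + 1):
        if vaf_curve[k - 1] <= global_thr:
            continue
        if per_muscle_min[k - 1] < local_thr:
            continue
        if k < K:
            if vaf_curve[k] - vaf_curve[k - 1] <= increment_thr:
                return k
        elif complete:
            return k
    return None


def select_num_synergies(
    V: np.ndarray,
    settings: NmfSettings | None = None,
    global_thr: float = 0.90,
    increment_thr: float = 0.05,
    local_thr: float = 0.75,
    max_k: int | None = None,
    full_curve: bool = False,
    muscle_names: tuple[str, ...] | None = None,
) -> SynergySet:
    """Select the number of synergies and return the chosen factorization.

    The selected n is the smallest k such that (a) global VAF_k exceeds
    ``global_thr``, (b) the increment VAF_{k+1} - VAF_k is at most
    ``increment_thr`` (vacuously true at k = muscles), and (c) every
    per-muscle VAF at k is at least ``local_thr``.  If no k satisfies
    all three, the smallest k meeting the global criterion alone is
    returned with ``selection_fallback=True``.  Model orders are fitted
    incrementally and fitting stops as soon as the selection is decided,
    unless ``full_curve`` requests the whole VAF curve up to ``max_k``.
    """
    settings = settings or NmfSettings()
    V = _check_input(V)
    m = V.shape[0]
    kmax = min(max_k or m, m)

    results: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    vaf: dict[int, float] = {}
    local: dict[int, np.ndarray] = {}

    def fit(k: int) -> None:
        if k in results:
            return
        results[k] = multi_restart(V, k, settings)
        g, pm = compute_vaf(V, results[k][0], results[k][1])
        vaf[k] = g
        local[k] = pm

    selected: int | None = None
    for k in range(1, kmax + 1):
        fit(k)
        if selected is None:
            curve = [vaf[j] for j in range(1, k + 1)]
            pm_min = [float(np.nanmin(np.nan_to_num(local[j], nan=1.0)))
                      for j in range(1, k + 1)]
            selected = select_from_curve(
                curve, pm_min, global_thr, increment_thr, local_thr,
                complete=(k == m),
            )
            if selected is not None and not full_curve:
                break

    fallback = False
    if selected is None:
        candidates = [k for k in sorted(vaf) if vaf[k] > global_thr]
        if candidates:
            selected = candidates[0]
        else:
            selected = max(vaf, key=vaf.get)
        fallback = True
        warnings.warn(
            f"no model order satisfies all selection criteria; "
            f"falling back to n = {selected}",
            stacklevel=2,
        )

    fit(1)
    W, C, rms = results[selected]
    W, C = order_synergies(W, C)
    curve = np.array([vaf[k] for k in sorted(vaf)])
    return SynergySet(
        W=W,
        C=C,
        n=selected,
        vaf_curve=curve,
        per_muscle_vaf=local[selected],
        vaf1=vaf[1],
        rms_residual=rms,
        muscle_names=muscle_names,
        selection_fallback=fallback,
    )


def vaf1(V: np.ndarray, settings: NmfSettings | None = None) -> float:
    """Global VAF of the best one-synergy factorization (0..1).

    A scalar index of synergy complexity: high VAF1 means a single
    synergy explains most of the muscle-activity variance (simpler
    control); lower VAF1 means more complex, higher-dimensional control.
    """
    settings = settings or NmfSettings()
    W, C, _ = multi_restart(V, 1, settings)
    return compute_vaf(V, W, C)[0]
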