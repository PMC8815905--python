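"""Per-participant, per-condition orchestration of the analysis chain.

For each walking condition (comfortable walking speed ``cws``, long
stepping on the paretic side ``p-long``, long stepping on the
non-paretic side ``np-long``) the pipeline runs EMG preprocessing,
gait-event detection and kinematics, and NNMF synergy extraction with
VAF model selection; amplitude normalization pools the per-muscle
maxima over the whole session.  The merging subtype is classified from
the comfortable-walking solution only, and a participant is
analysis-eligible when that condition yields exactly three synergies.
Conditions are labels on the input data, not behavior switches: every
condition goes through the identical processing chain.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import kinematics as kin
from . import preproc
from .classify import SubtypeLabel, classify
from .nmf import NmfSettings, SynergySet, select_num_synergies
from .preproc import RawEmg
from .synth import (
    KinematicsData,
    SynthConfig,
    config_for_condition,
    synthesize_envelopes,
    synthesize_kinematics,
    synthesize_raw_emg,
)
from .templates import MUSCLES, PAIR_OF_SUBTYPE, make_canonical_modules

log = logging.getLogger("synwalk")

CONDITIONS = ("cws", "p-long", "np-long")

__all__ = [
    "PipelineConfig",
    "ConditionInputs",
    "ConditionResult",
    "ParticipantResult",
    "run_participant",
    "run_synthetic_participant",
    "cohort_summary",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every analysis threshold, as a named key (YAML-serializable)."""

    band: tuple[float, float] = (20.0, 500.0)
    envelope_lp: float = 10.0
    filter_order: int = 4
    norm_scope: str = "session"
    angle_lp: float = 6.0
    n_points: int = 100
    strides: int = 20
    trim: int = 3
    tol_residual: float = 1e-6
    tol_change: float = 1e-4
    restarts: int = 1000
    max_iter: int = 2000
    vaf_global: float = 0.90
    vaf_increment: float = 0.05
    vaf_local: float = 0.75
    weight_thr: float = 0.3
    y_axis: str = "up"
    seed: int = 0

    def nmf_settings(self) -> NmfSettings:
        return NmfSettings(
            tol_residual=self.tol_residual,
            tol_relative_change=self.tol_change,
            n_restarts=self.restarts,
            max_iter=self.max_iter,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "band" in data:
            data["band"] = tuple(data["band"])
        return cls(**data)


@dataclass
class ConditionInputs:
    """Raw streams for one walking condition."""

    raw_emg: RawEmg
    keypoints: kin.KeypointTrace
    pressure_p: np.ndarray
    pressure_np: np.ndarray
    insole_fs: float
    accel_ap: np.ndarray | None = None


@dataclass
class ConditionResult:
    condition: str
    n_synergies: int | None = None
    vaf1: float | None = None          # fraction, 0..1
    peak_flexion_deg: float | None = None
    peak_extension_deg: float | None = None
    cadence_spm: float | None = None
    symmetry_index_pct: float | None = None
    synergies: SynergySet | None = None
    error: str | None = None


@dataclass
class ParticipantResult:
    participant_id: str
    conditions: dict[str, ConditionResult]
    subtype: SubtypeLabel | None = None
    eligible: bool = False
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One tidy row per condition."""
        rows = []
        for cond in CONDITIONS:
            r = self.conditions.get(cond)
            if r is None:
                rows.append({"participant": self.participant_id, "condition": cond,
                             "status": "absent"})
                continue
            rows.append({
                "participant": self.participant_id,
                "condition": cond,
                "status": "error" if r.error else "ok",
                "n_synergies": r.n_synergies,
                "vaf1_pct": None if r.vaf1 is None else 100.0 * r.vaf1,
                "peak_flexion_deg": r.peak_flexion_deg,
                "peak_extension_deg": r.peak_extension_deg,
                "cadence_spm": r.cadence_spm,
                "symmetry_index_pct": r.symmetry_index_pct,
                "subtype": self.subtype.label if self.subtype else None,
                "eligible": self.eligible,
            })
        return pd.DataFrame(rows)


def _emg_envelope(inputs: ConditionInputs, cfg: PipelineConfig) -> np.ndarray:
    filt = preproc.bandpass_emg(inputs.raw_emg, cfg.band[0], cfg.band[1], cfg.filter_order)
    return preproc.envelope(filt, inputs.raw_emg.fs, cfg.envelope_lp, cfg.filter_order)


def _condition_metrics(
    inputs: ConditionInputs,
    env_normed: np.ndarray,
    cfg: PipelineConfig,
) -> ConditionResult:
    cond = inputs.raw_emg.condition
    events = kin.detect_events(
        inputs.pressure_p,
        inputs.pressure_np,
        inputs.insole_fs,
        accel_ap=inputs.accel_ap,
        ankle_trace=inputs.keypoints,
    )
    hc_t = events.times("paretic_hc")

    # Segment the (already amplitude-normalized) envelope at heel contacts.
    hc_emg = np.round(hc_t * inputs.raw_emg.fs).astype(int)
    hc_emg = hc_emg[hc_emg < env_normed.shape[1]]
    segments = preproc.segment_strides(env_normed, hc_emg, trim=cfg.trim,
                                       max_strides=cfg.strides)
    V = preproc.time_normalize(segments, inputs.raw_emg.muscle_names, cond,
                               n_points=cfg.n_points)

    syn = select_num_synergies(
        V.values,
        cfg.nmf_settings(),
        global_thr=cfg.vaf_global,
        increment_thr=cfg.vaf_increment,
        local_thr=cfg.vaf_local,
        muscle_names=V.muscle_names,
    )

    # Limb angle on the paretic side, per stride.
    angle = kin.limb_angle(inputs.keypoints, lowpass=cfg.angle_lp, order=cfg.filter_order)
    hc_kin = np.round(hc_t * inputs.keypoints.fs).astype(int)
    hc_kin = hc_kin[hc_kin < angle.size]
    cycles = kin.angle_per_stride(angle, hc_kin, trim=cfg.trim,
                                  max_strides=cfg.strides, n_points=cfg.n_points)
    peaks = kin.peak_angles(cycles)

    cad = kin.cadence_from_events(events)
    si = None
    if events.single_support_p.size and events.single_support_np.size:
        si = kin.symmetry_index(
            float(events.single_support_p.mean()),
            float(events.single_support_np.mean()),
        )

    return ConditionResult(
        condition=cond,
        n_synergies=syn.n,
        vaf1=syn.vaf1,
        peak_flexion_deg=peaks.peak_flexion_deg,
        peak_extension_deg=peaks.peak_extension_deg,
        cadence_spm=cad,
        symmetry_index_pct=si,
        synergies=syn,
    )


def run_participant(
    inputs: dict[str, ConditionInputs],
    cfg: PipelineConfig | None = None,
    participant_id: str = "P01",
) -> ParticipantResult:
    """Run the full analysis for one participant.

    ``inputs`` maps condition labels (a subset of ``cws``, ``p-long``,
    ``np-long``) to raw streams.  Missing conditions yield a partial
    result with a warning; a failing condition records its error and
    the remaining conditions still run.  The subtype is classified from
    the ``cws`` solution; eligibility requires exactly three synergies
    there.
    """
    cfg = cfg or PipelineConfig()
    unknown = set(inputs) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    missing = [c for c in CONDITIONS if c not in inputs]
    if missing:
        log.warning("participant %s: missing conditions %s", participant_id, missing)

    # Envelopes first, so amplitude normalization can pool the session.
    envelopes = {c: _emg_envelope(ci, cfg) for c, ci in inputs.items()}
    if cfg.norm_scope == "session":
        maxima = preproc.session_maxima(list(envelopes.values()))
    results: dict[str, ConditionResult] = {}
    for cond, ci in inputs.items():
        env = envelopes[cond]
        if cfg.norm_scope == "session":
            m = np.where(maxima > 0, maxima, 1.0)
            env = env / m[:, None]
        else:
            env = preproc.normalize_amplitude(env)
        try:
            results[cond] = _condition_metrics(ci, env, cfg)
        except Exception as exc:  # record and continue with other conditions
            log.warning("participant %s condition %s failed: %s",
                        participant_id, cond, exc)
            results[cond] = ConditionResult(condition=cond, error=str(exc))

    subtype = None
    eligible = False
    cws = results.get("cws")
    if cws is not None and cws.synergies is not None:
        templates = make_canonical_modules(inputs["cws"].raw_emg.muscle_names)
        subtype = classify(cws.synergies.W, templates, threshold=cfg.weight_thr)
        eligible = cws.n_synergies == 3

    return ParticipantResult(
        participant_id=participant_id,
        conditions=results,
        subtype=subtype,
        eligible=eligible,
        provenance={"config": cfg.to_dict(), "seed": cfg.seed},
    )


def synthetic_condition_inputs(scfg: SynthConfig) -> ConditionInputs:
    """Generate one condition's raw streams from the gait generator."""
    env, _ = synthesize_envelopes(scfg)
    raw, _ = synthesize_raw_emg(env, scfg)
    kd: KinematicsData = synthesize_kinematics(scfg)
    return ConditionInputs(
        raw_emg=RawEmg(samples=raw, fs=scfg.emg_fs, muscle_names=MUSCLES,
                       condition=scfg.condition),
        keypoints=kin.KeypointTrace(hip_xy=kd.hip_xy, ankle_xy=kd.ankle_xy,
                                    fs=kd.kin_fs, y_axis="up"),
        pressure_p=kd.pressure_p,
        pressure_np=kd.pressure_np,
        insole_fs=kd.insole_fs,
        accel_ap=kd.accel[:, 0],
    )


def run_synthetic_participant(
    subtype: int | None,
    seed: int,
    cfg: PipelineConfig | None = None,
    n_strides: int = 27,
    noise_sd: float = 0.05,
    participant_id: str | None = None,
) -> ParticipantResult:
    """One-call synthetic demonstration of the full workflow.

    Generates all three walking conditions for a participant of the
    requested merging subtype (1, 2, 3, or None for a non-merged
    4-module pattern) and runs the complete analysis on them.  27
    strides are generated so that 20 survive the 3+3-cycle trimming.
    """
    cfg = cfg or PipelineConfig()
    pair = PAIR_OF_SUBTYPE[f"subtype{subtype}"] if subtype else None
    base = SynthConfig(n_strides=n_strides, merge_pair=pair, noise_sd=noise_sd,
                       seed=seed)
    inputs = {
        cond: synthetic_condition_inputs(config_for_condition(base, cond))
        for cond in CONDITIONS
    }
    pid = participant_id or f"SYN-{subtype or 'none'}-{seed}"
    result = run_participant(inputs, replace(cfg, seed=seed), participant_id=pid)
    result.provenance["generator"] = {
        "subtype": subtype, "noise_sd": noise_sd, "n_strides": n_strides,
    }
    return result


def cohort_summary(results: list[ParticipantResult]) -> pd.DataFrame:
    """Per-subtype, per-condition descriptive table (long format).

    Mean, SD and SE of VAF1 (percent), peak flexion/extension angles,
    cadence and the symmetry index across participants.
    """
    if not results:
        raise ValueError("cohort_summary needs at least one participant result")
    frames = [r.to_frame() for r in results]
    df = pd.concat(frames, ignore_index=True)
    df = df[df["status"] == "ok"]
    metrics = ["vaf1_pct", "peak_flexion_deg", "peak_extension_deg",
               "cadence_spm", "symmetry_index_pct"]
    long = df.melt(
        id_vars=["subtype", "condition", "participant"],
        value_vars=metrics,
        var_name="metric",
    ).dropna(subset=["value"])
    out = (
        long.groupby(["subtype", "condition", "metric"], dropna=False)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out
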