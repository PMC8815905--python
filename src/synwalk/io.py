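"""Delimited-file readers and writers.

All streams travel as wide CSV: one header row of channel names, one
column per channel, and the sampling rate in a ``# fs=<Hz>`` comment on
the first line.  Envelope matrices, synergy weights/activations and VAF
reports use the same plain-text conventions so every stage's output can
be re-read by the next stage or by external tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .nmf import SynergySet
from .preproc import EnvelopeMatrix

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_envelopes",
    "read_envelopes",
    "write_synergies",
    "read_weights",
]


def write_timeseries(path: str | Path, data: np.ndarray, names: list[str], fs: float) -> None:
    """Write channels x samples data as wide CSV with an fs comment."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(data).T, columns=list(names))
    with open(path, "w") as fh:
        fh.write(f"# fs={fs}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_timeseries(path: str | Path) -> tuple[np.ndarray, list[str], float | None]:
    """Read a wide CSV; returns (channels x samples, names, fs or None)."""
    path = Path(path)
    fs = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].replace(",", " ").split():
                if token.startswith("fs="):
                    fs = float(token[3:])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return df.to_numpy().T, list(df.columns), fs


def write_envelopes(path: str | Path, env: EnvelopeMatrix) -> None:
    """Envelope matrix as long CSV with a (stride, point) index."""
    n = env.values.shape[1]
    strides = np.repeat(np.arange(env.n_strides), n // env.n_strides)
    points = np.tile(np.arange(n // env.n_strides), env.n_strides)
    df = pd.DataFrame(env.values.T, columns=list(env.muscle_names))
    df.insert(0, "point", points)
    df.insert(0, "stride", strides)
    df.insert(0, "condition", env.condition)
    df.to_csv(path, index=False, lineterminator="\n")


def read_envelopes(path: str | Path) -> EnvelopeMatrix:
    df = pd.read_csv(path)
    condition = str(df.pop("condition").iloc[0]) if "condition" in df else "cws"
    n_strides = int(df["stride"].nunique())
    values = df.drop(columns=["stride", "point"]).to_numpy().T
    names = tuple(c for c in df.columns if c not in ("stride", "point"))
    return EnvelopeMatrix(values=values, muscle_names=names,
                          n_strides=n_strides, condition=condition)


def write_synergies(outdir: str | Path, syn: SynergySet, seed: int | None = None) -> None:
    """Write W, C and the VAF report of one extraction."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = list(syn.muscle_names) if syn.muscle_names else \
        [f"ch{i}" for i in range(syn.W.shape[0])]
    w = pd.DataFrame(syn.W, index=names,
                     columns=[f"synergy{j + 1}" for j in range(syn.n)])
    w.to_csv(outdir / "weights.csv", index_label="muscle", lineterminator="\n")
    c = pd.DataFrame(syn.C.T, columns=[f"synergy{j + 1}" for j in range(syn.n)])
    c.to_csv(outdir / "activations.csv", index_label="t", lineterminator="\n")
    report = {
        "n_synergies": int(syn.n),
        "vaf_curve": [round(float(v), 6) for v in syn.vaf_curve],
        "per_muscle_vaf": {m: round(float(v), 6)
                           for m, v in zip(names, syn.per_muscle_vaf)},
        "vaf1": round(float(syn.vaf1), 6),
        "rms_residual": float(syn.rms_residual),
        "selection_fallback": bool(syn.selection_fallback),
        "seed": seed,
    }
    with open(outdir / "vaf_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")


def read_weights(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a weights CSV back as (muscles x n array, muscle names)."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), tuple(df.index)
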