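"""Readers and writers for all interchange formats.

All pipeline file I/O goes through this module: plain CSV/TSV with
unit-suffixed headers for tables, JSON for fitted models and statistics.
Readers validate schemas (a missing column raises ``SchemaError`` naming
it) and uniform time sampling (a skipped frame raises ``ValidationError``
citing the gap index); writes round-trip losslessly at full float
precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .locomotion import (
    BoutInterval,
    BoutSegmentation,
    HmmModel,
    SurvivalCurve,
    WormTrack,
)
from .repetitive import RiFit
from .synthdata import FluorescenceTrace

__all__ = [
    "SchemaError",
    "ValidationError",
    "TRACK_COLUMNS",
    "TRACE_COLUMNS",
    "read_tracks",
    "write_tracks",
    "read_traces",
    "write_traces",
    "write_survival",
    "read_survival",
    "write_bouts",
    "write_posterior",
    "write_model",
    "read_model",
    "write_fit",
    "read_expression_table",
    "write_expression_table",
    "read_ortholog_map",
    "write_ortholog_map",
    "sha256_of",
]


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class ValidationError(ValueError):
    """Structurally valid file with invalid contents (e.g. a time gap)."""


TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_mm", "y_mm",
                 "axis_x", "axis_y", "elongation_mm"]
TRACE_COLUMNS = ["animal_id", "genotype", "channel", "time_s", "F", "cue_flag"]
SURVIVAL_COLUMNS = ["t_s", "p_f", "sd", "n_at_risk"]


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_uniform_time(time: np.ndarray, path, label: str) -> None:
    if len(time) < 2:
        return
    steps = np.diff(time)
    dt = steps[0]
    bad = np.flatnonzero(~np.isclose(steps, dt, rtol=1e-6, atol=1e-9))
    if len(bad):
        raise ValidationError(
            f"{path}: non-uniform time step in {label} at index {int(bad[0]) + 1} "
            f"(step {steps[bad[0]]:g} s, expected {dt:g} s)")


def write_tracks(tracks, path) -> None:
    frames = []
    for tr in tracks:
        frames.append(pd.DataFrame({
            "track_id": tr.track_id,
            "frame": np.arange(tr.n_frames),
            "time_s": tr.time,
            "x_mm": tr.position[:, 0],
            "y_mm": tr.position[:, 1],
            "axis_x": tr.axis[:, 0],
            "axis_y": tr.axis[:, 1],
            "elongation_mm": tr.elongation,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_tracks(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACK_COLUMNS, path)
    tracks = []
    for tid, g in df.groupby("track_id", sort=False):
        g = g.sort_values("frame")
        time = g["time_s"].to_numpy(float)
        _check_uniform_time(time, path, f"track {tid}")
        tracks.append(WormTrack(
            track_id=str(tid),
            time=time,
            position=g[["x_mm", "y_mm"]].to_numpy(float),
            axis=g[["axis_x", "axis_y"]].to_numpy(float),
            elongation=g["elongation_mm"].to_numpy(float),
        ))
    return tracks


def write_traces(traces, path) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "animal_id": tr.animal_id,
            "genotype": tr.genotype,
            "channel": tr.channel,
            "time_s": tr.time,
            "F": tr.F,
            "cue_flag": _cue_flag(tr),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def _cue_flag(tr: FluorescenceTrace) -> np.ndarray:
    flag = np.ones(len(tr.time), dtype=int)
    starts = list(tr.cue_removal_times)
    for i, s in enumerate(starts):
        end = starts[i + 1] if i + 1 < len(starts) else tr.time[-1] + 1
        width = min(20.0, end - s)  # removal window; exact width is cosmetic
        flag[(tr.time >= s) & (tr.time < s + width)] = 0
    return flag


def read_traces(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACE_COLUMNS, path)
    traces = []
    for (aid, geno, chan), g in df.groupby(["animal_id", "genotype", "channel"],
                                           sort=False):
        g = g.sort_values("time_s")
        time = g["time_s"].to_numpy(float)
        _check_uniform_time(time, path, f"trace {aid}/{chan}")
        flag = g["cue_flag"].to_numpy(int)
        removals = time[1:][(flag[1:] == 0) & (flag[:-1] == 1)]
        traces.append(FluorescenceTrace(
            time=time, F=g["F"].to_numpy(float), channel=str(chan),
            animal_id=str(aid), genotype=str(geno),
            cue_removal_times=tuple(float(t) for t in removals),
        ))
    return traces


def write_survival(curve: SurvivalCurve, path, sd: np.ndarray | None = None) -> None:
    n = len(curve.p_f)
    sd_col = np.full(n, np.nan) if sd is None else np.asarray(sd, float)
    at_risk = np.concatenate([[curve.at_risk[0] if len(curve.at_risk) else 0],
                              curve.at_risk])
    pd.DataFrame({
        "t_s": curve.times, "p_f": curve.p_f,
        "sd": sd_col, "n_at_risk": at_risk.astype(int),
    }).to_csv(path, index=False, float_format="%.17g")


def read_survival(path):
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SURVIVAL_COLUMNS, path)
    t = df["t_s"].to_numpy(float)
    _check_uniform_time(t, path, "survival grid")
    pf = df["p_f"].to_numpy(float)
    at_risk = df["n_at_risk"].to_numpy(float)[1:]
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    hazard = np.zeros(len(pf) - 1)
    nz = pf[:-1] > 0
    hazard[nz] = 1.0 - pf[1:][nz] / pf[:-1][nz]
    sd = df["sd"].to_numpy(float)
    curve = SurvivalCurve(p_f=pf, hazard=hazard, at_risk=at_risk,
                          events=np.round(hazard * at_risk), dt=dt)
    return curve, sd


def write_bouts(segmentations, track_ids, path) -> None:
    rows = []
    for tid, seg in zip(track_ids, segmentations):
        for iv in seg.intervals:
            rows.append({"track_id": tid, "start_frame": iv.start,
                         "end_frame": iv.end, "label": iv.label,
                         "censored_start": int(iv.censored_start),
                         "censored_end": int(iv.censored_end)})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_posterior(posteriors, track_ids, path) -> None:
    from .locomotion import STATES
    frames = []
    for tid, post in zip(track_ids, posteriors):
        df = pd.DataFrame(post.gamma, columns=[f"p_{s}" for s in STATES])
        df.insert(0, "frame", np.arange(len(df)))
        df.insert(0, "track_id", tid)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def write_model(model: HmmModel, path) -> None:
    payload = {
        "states": list(model.states),
        "transition": model.transition.tolist(),
        "initial": model.initial.tolist(),
        "sigma_r": model.sigma_r,
        "c": model.c,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model(path) -> HmmModel:
    payload = json.loads(Path(path).read_text())
    model = HmmModel(
        transition=np.asarray(payload["transition"], float),
        initial=np.asarray(payload["initial"], float),
        sigma_r=float(payload["sigma_r"]), c=float(payload["c"]),
        states=tuple(payload["states"]),
    )
    model.validate()
    return model


def write_fit(fit: RiFit, path) -> None:
    payload = {
        "r0_per_s": fit.r0, "delta_l": fit.delta_l, "RI": fit.ri,
        "se_r0": fit.se_r0, "se_delta_l": fit.se_delta_l, "se_RI": fit.se_ri,
        "tau_s": fit.tau, "model": fit.model,
        "S_min": fit.s_min, "dof": fit.dof, "p_value": fit.p_value,
        "anti_repetitive": bool(fit.anti_repetitive),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_expression_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["gene_id"], path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: need at least one cell-type FE column")
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids")
    return df.set_index("gene_id")


def write_expression_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_ortholog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["worm_gene_id", "mouse_gene_id"], path)
    return df


def write_ortholog_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
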