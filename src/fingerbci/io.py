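"""Serialization: JSON-lines trial logs, population files, metric tables.

Trial logs are one JSON object per line (streamable and greppable), with
per-bin arrays inlined as number lists; desk-scale sessions stay small.
Populations and decoders are stored as portable .npz array containers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decoder import Decoder  # noqa: F401  (re-exported save/load surface)
from .dsnr import DsnrCurve, PowerLawFit
from .metrics import trial_metrics
from .population import TuningModel
from .tasks import TargetSet, TrialRecord

__all__ = [
    "write_trial_log",
    "read_trial_log",
    "save_population",
    "load_population",
    "metrics_table",
    "dsnr_curve_table",
    "fit_report",
]


def _record_to_dict(rec: TrialRecord) -> dict:
    ts = rec.target_set
    return {
        "task_kind": rec.task_kind,
        "target_set": {
            "centers": ts.centers.tolist(),
            "width": ts.width,
            "hold_required": ts.hold_required,
            "timeout": ts.timeout,
            "kind": ts.kind,
            "cued_groups": list(ts.cued_groups),
            "frozen_dofs": list(ts.frozen_dofs),
        },
        "positions": np.asarray(rec.positions).tolist(),
        "decoded_velocities": np.asarray(rec.decoded_velocities).tolist(),
        "intents": None if rec.intents is None else np.asarray(rec.intents).tolist(),
        "sbp": None if rec.sbp is None else np.asarray(rec.sbp).tolist(),
        "cue_time": rec.cue_time,
        "first_entry_time": rec.first_entry_time,
        "last_entry_time": rec.last_entry_time,
        "completion_time": rec.completion_time,
        "success": rec.success,
        "cued_groups": list(rec.cued_groups),
        "trial_index": rec.trial_index,
        "dof_labels": list(rec.dof_labels),
    }


def _record_from_dict(d: dict) -> TrialRecord:
    ts = d["target_set"]
    return TrialRecord(
        task_kind=d["task_kind"],
        target_set=TargetSet(
            centers=np.array(ts["centers"]),
            width=ts["width"],
            hold_required=ts["hold_required"],
            timeout=ts["timeout"],
            kind=ts["kind"],
            cued_groups=tuple(ts["cued_groups"]),
            frozen_dofs=tuple(ts["frozen_dofs"]),
        ),
        positions=np.array(d["positions"]),
        decoded_velocities=np.array(d["decoded_velocities"]),
        intents=None if d["intents"] is None else np.array(d["intents"]),
        sbp=None if d["sbp"] is None else np.array(d["sbp"]),
        cue_time=d["cue_time"],
        first_entry_time=d["first_entry_time"],
        last_entry_time=d["last_entry_time"],
        completion_time=d["completion_time"],
        success=d["success"],
        cued_groups=tuple(d["cued_groups"]),
        trial_index=d["trial_index"],
        dof_labels=tuple(d["dof_labels"]),
    )


def write_trial_log(path, records: list[TrialRecord]) -> None:
    """One trial per line, JSON-lines."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(_record_to_dict(rec)) + "\n")


def read_trial_log(path) -> list[TrialRecord]:
    """Read a JSON-lines trial log; malformed lines raise with their number."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                records.append(_record_from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: malformed trial at line {lineno}: {exc}") from exc
    return records


def save_population(path, model: TuningModel) -> None:
    np.savez(
        path,
        version=np.array(1),
        n_channels=np.array(model.n_channels),
        dof=np.array(model.dof),
        baseline=model.baseline,
        tuning_matrix=model.tuning_matrix,
        noise_sd=model.noise_sd,
        seed=np.array(model.seed),
        has_interaction=np.array(int(model.interaction_matrix is not None)),
        interaction_matrix=(
            model.interaction_matrix
            if model.interaction_matrix is not None
            else np.zeros((0, 0))
        ),
    )


def load_population(path) -> TuningModel:
    d = np.load(path, allow_pickle=False)
    return TuningModel(
        n_channels=int(d["n_channels"]),
        dof=int(d["dof"]),
        baseline=d["baseline"],
        tuning_matrix=d["tuning_matrix"],
        noise_sd=d["noise_sd"],
        interaction_matrix=d["interaction_matrix"] if int(d["has_interaction"]) else None,
        seed=int(d["seed"]),
    )


def metrics_table(records: list[TrialRecord]) -> pd.DataFrame:
    """One row per trial: timing metrics, Fitts bits, outcome."""
    rows = []
    for rec in records:
        m = trial_metrics(rec)
        rows.append(
            {
                "trial_index": rec.trial_index,
                "task_kind": rec.task_kind,
                "success": m.success,
                "acquisition_time_s": m.acquisition_time,
                "time_to_target_s": m.time_to_target,
                "orbiting_time_s": m.orbiting_time,
                "path_length_efficiency": m.path_length_efficiency,
                "fitts_bits": m.fitts_bits,
                "cued_groups": "+".join(rec.cued_groups),
            }
        )
    return pd.DataFrame(rows)


def dsnr_curve_table(curve: DsnrCurve) -> pd.DataFrame:
    """Long format: (channel_count, repetition, dsnr)."""
    rows = []
    for i, c in enumerate(curve.channel_counts):
        for r in range(curve.per_subset.shape[1]):
            rows.append(
                {"channel_count": int(c), "repetition": r, "dsnr": curve.per_subset[i, r]}
            )
    return pd.DataFrame(rows)


def fit_report(fit: PowerLawFit) -> str:
    return (
        "power-law fit dSNR = B * N_c^m\n"
        f"m         = {fit.m:.4f}\n"
        f"B         = {fit.B:.4f}\n"
        f"r_squared = {fit.r_squared:.4f}\n"
        f"channel_counts = {', '.join(str(int(c)) for c in fit.channel_counts)}\n"
    )
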