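"""Serialization: decoder models (JSON), session tables (CSV), manifests.

Everything a run produces is plain text: one bins table per session segment
(cursor/hand and intended kinematics plus per-bin target), one counts table,
one trials table, JSON decoder models, and a JSON manifest carrying the
scenario, seeds and output references needed to replay the run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kalman import DecoderModel
from .tasks import Scenario, SessionResult, TrialRecord


def save_decoder(model: DecoderModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_decoder(path: str | Path) -> DecoderModel:
    return DecoderModel.from_dict(json.loads(Path(path).read_text()))


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario.to_dict()))


def load_scenario(path: str | Path) -> Scenario:
    d = yaml.safe_load(Path(path).read_text())
    if "seed" not in d or d["seed"] is None:
        raise ValueError("scenario file must carry an explicit seed")
    from .tasks import TaskConfig, UserModel
    d["task_train"] = TaskConfig(**d["task_train"])
    d["task_eval"] = TaskConfig(**d["task_eval"])
    d["user"] = UserModel(**d["user"])
    return Scenario(**d)


def bins_frame(result: SessionResult) -> pd.DataFrame:
    """Per-bin session trace: cursor/hand and intended kinematics, targets."""
    k = result.kinematics
    d = {"bin": np.arange(k.n_bins)}
    for j in range(k.n_dof):
        d[f"pos{j}"] = k.positions[:, j]
        d[f"vel{j}"] = k.velocities[:, j]
        d[f"intended_pos{j}"] = result.intended.positions[:, j]
        d[f"intended_vel{j}"] = result.intended.velocities[:, j]
        d[f"target{j}"] = result.target_centers[:, j]
    return pd.DataFrame(d)


def counts_frame(result: SessionResult) -> pd.DataFrame | None:
    if result.counts is None:
        return None
    df = pd.DataFrame(result.counts.counts,
                      columns=[f"ch{c}" for c in result.counts.channel_ids])
    df.insert(0, "bin", np.arange(result.counts.n_bins))
    return df


def trials_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        r = dataclasses.asdict(t)
        r["target_center"] = ";".join(f"{v:.6g}" for v in t.target_center)
        r["start_pos"] = ";".join(f"{v:.6g}" for v in t.start_pos)
        rows.append(r)
    return pd.DataFrame(rows)


def bins_frame_from_arrays(kinematics, active_dof: np.ndarray) -> pd.DataFrame:
    """Per-bin table for concatenated multi-block kinematics (2-DOF sessions)."""
    d = {"bin": np.arange(kinematics.n_bins), "active_dof": active_dof}
    for j in range(kinematics.n_dof):
        d[f"pos{j}"] = kinematics.positions[:, j]
        d[f"vel{j}"] = kinematics.velocities[:, j]
    return pd.DataFrame(d)


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    """Rebuild TrialRecords from a trials CSV (inverse of trials_frame)."""
    recs = []
    for _, r in df.iterrows():
        recs.append(TrialRecord(
            trial_index=int(r["trial_index"]),
            block_id=int(r["block_id"]),
            decoder_id=str(r["decoder_id"]),
            target_center=np.array([float(v) for v in
                                    str(r["target_center"]).split(";")]),
            target_width=float(r["target_width"]),
            start_pos=np.array([float(v) for v in
                                str(r["start_pos"]).split(";")]),
            bin_start=int(r["bin_start"]),
            bin_end=int(r["bin_end"]),
            success=bool(r["success"]),
            first_contact=None if pd.isna(r["first_contact"])
            else float(r["first_contact"]),
            acquire_time=None if pd.isna(r["acquire_time"])
            else float(r["acquire_time"]),
            elapsed=float(r["elapsed"]),
            hold_time=float(r["hold_time"]),
            timeout=float(r["timeout"]),
        ))
    return recs


def save_session(result: SessionResult, outdir: str | Path, prefix: str) -> dict:
    """Write bins/counts/trials CSVs for one session segment; return refs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = {}
    for name, df in (("bins", bins_frame(result)),
                     ("counts", counts_frame(result)),
                     ("trials", trials_frame(result.trials))):
        if df is None:
            continue
        p = outdir / f"{prefix}_{name}.csv"
        df.to_csv(p, index=False)
        refs[name] = p.name
    return refs


def scenario_hash(scenario: Scenario) -> str:
    blob = json.dumps(scenario.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_manifest(path: str | Path, scenario: Scenario, seed: int,
                  refs: dict) -> None:
    manifest = {
        "software_version": __version__,
        "scenario": scenario.to_dict(),
        "scenario_hash": scenario_hash(scenario),
        "seed": seed,
        "bit_rate_formula": "shannon: ID = log2(1 + D/w)",
        "outputs": refs,
    }
    Path(path).write_text(json.dumps(manifest, indent=1))
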