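"""Trajectory files, model checkpoints, run manifests, and seeding.

Trajectories are CSV with header ``t,prop_1..prop_P,vis_1..vis_V[,label]``;
checkpoints are HDF5 with one group per expert plus a gating group and a
format-version attribute; run manifests are JSON with config snapshots,
per-stage seeds and content hashes of the files a run produced.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from . import __version__
from .learning import GateVariableSequence, NoiseModel, TrainingSet
from .model import (
    ExpertParams,
    GatingParams,
    ModelParams,
    TimescaleProfile,
    Trajectory,
)

CHECKPOINT_FORMAT_VERSION = 1


class TrajectoryParseError(ValueError):
    """Malformed trajectory CSV; message carries the offending line number."""


# ---------------------------------------------------------------------------
# Trajectory CSV
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    P = traj.proprio_dim
    V = traj.n_dim - P
    header = (["t"] + [f"prop_{i + 1}" for i in range(P)]
              + [f"vis_{i + 1}" for i in range(V)])
    if traj.labels is not None:
        header.append("label")
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for t, row in enumerate(traj.values):
            out = [t] + [f"{x:.12g}" for x in row]
            if traj.labels is not None:
                out.append(traj.labels[t])
            w.writerow(out)


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TrajectoryParseError(f"{path}: line 1: empty file") from None
        if not header or header[0] != "t":
            raise TrajectoryParseError(f"{path}: line 1: header must start with 't'")
        has_label = header[-1] == "label"
        cols = header[1:-1] if has_label else header[1:]
        P = sum(1 for c in cols if c.startswith("prop_"))
        V = sum(1 for c in cols if c.startswith("vis_"))
        if P + V != len(cols) or P + V == 0:
            raise TrajectoryParseError(
                f"{path}: line 1: expected prop_*/vis_* columns, got {cols}")
        values, labels = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            want = 1 + P + V + (1 if has_label else 0)
            if len(row) != want:
                raise TrajectoryParseError(
                    f"{path}: line {lineno}: expected {want} cells, got {len(row)}")
            try:
                values.append([float(x) for x in row[1:1 + P + V]])
            except ValueError as err:
                raise TrajectoryParseError(f"{path}: line {lineno}: {err}") from None
            if has_label:
                labels.append(row[-1])
        if not values:
            raise TrajectoryParseError(f"{path}: no data rows")
    return Trajectory(np.array(values), P, labels=labels if has_label else None)


# ---------------------------------------------------------------------------
# HDF5 checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(m: ModelParams, path: str | Path,
                    training_state: Optional[TrainingSet] = None) -> None:
    """Write the model (and optionally the learned per-sequence training
    state) to an HDF5 checkpoint."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = CHECKPOINT_FORMAT_VERSION
        f.attrs["software_version"] = __version__
        f.attrs["tau_low"] = m.timescales.tau_low
        f.attrs["tau_mid"] = m.timescales.tau_mid
        f.attrs["tau_high"] = m.timescales.tau_high
        f.attrs["step_size"] = m.timescales.step_size
        f.attrs["feedback_delay"] = m.feedback_delay
        f.attrs["proprio_dim"] = m.io_dims[0]
        f.attrs["vision_dim"] = m.io_dims[1]
        f.attrs["lesioned"] = m.lesioned
        for i, e in enumerate(m.experts):
            g = f.create_group(f"expert_{i}")
            g["recurrent_weights"] = e.recurrent_weights
            g["input_weights"] = e.input_weights
            g["output_weights"] = e.output_weights
            g["recurrent_bias"] = e.recurrent_bias
            g["output_bias"] = e.output_bias
        g = f.create_group("gating")
        for name in ("mid_recurrent", "mid_from_high", "mid_input_weights",
                     "mid_gatefeedback_weights", "mid_bias", "high_recurrent",
                     "high_from_mid", "high_bias", "gate_readout"):
            g[name] = getattr(m.gating, name)
        if training_state is not None:
            tg = f.create_group("training_state")
            tg.attrs["sigma"] = training_state.noise.sigma
            for s in range(training_state.n_sequences):
                sg = tg.create_group(f"sequence_{s}")
                sg["expert_init"] = training_state.expert_init[s]
                sg["mid_init"] = training_state.mid_init[s]
                sg["high_init"] = training_state.high_init[s]
                sg["gate_vars"] = training_state.gate_vars[s].v
                sg["values"] = training_state.sequences[s].values
                sg.attrs["proprio_dim"] = training_state.sequences[s].proprio_dim


def load_checkpoint(path: str | Path) -> tuple[ModelParams, Optional[TrainingSet]]:
    """Load a checkpoint; the round trip preserves generation bit-for-bit."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as err:
        raise IOError(f"cannot read checkpoint {path}: {err}") from None
    with f:
        version = int(f.attrs.get("format_version", -1))
        if version != CHECKPOINT_FORMAT_VERSION:
            raise IOError(f"checkpoint format version {version} not supported "
                          f"(expected {CHECKPOINT_FORMAT_VERSION})")
        experts = []
        i = 0
        while f"expert_{i}" in f:
            g = f[f"expert_{i}"]
            experts.append(ExpertParams(
                recurrent_weights=g["recurrent_weights"][()],
                input_weights=g["input_weights"][()],
                output_weights=g["output_weights"][()],
                recurrent_bias=g["recurrent_bias"][()],
                output_bias=g["output_bias"][()],
            ))
            i += 1
        g = f["gating"]
        gating = GatingParams(**{name: g[name][()] for name in (
            "mid_recurrent", "mid_from_high", "mid_input_weights",
            "mid_gatefeedback_weights", "mid_bias", "high_recurrent",
            "high_from_mid", "high_bias", "gate_readout")})
        m = ModelParams(
            experts=experts,
            gating=gating,
            timescales=TimescaleProfile(
                tau_low=float(f.attrs["tau_low"]),
                tau_mid=float(f.attrs["tau_mid"]),
                tau_high=float(f.attrs["tau_high"]),
                step_size=float(f.attrs["step_size"]),
            ),
            feedback_delay=int(f.attrs["feedback_delay"]),
            io_dims=(int(f.attrs["proprio_dim"]), int(f.attrs["vision_dim"])),
            lesioned=bool(f.attrs["lesioned"]),
        )
        m.validate()
        ts = None
        if "training_state" in f:
            tg = f["training_state"]
            seqs, e0, m0, h0, gv = [], [], [], [], []
            s = 0
            while f"sequence_{s}" in tg:
                sg = tg[f"sequence_{s}"]
                seqs.append(Trajectory(sg["values"][()], int(sg.attrs["proprio_dim"])))
                e0.append(sg["expert_init"][()])
                m0.append(sg["mid_init"][()])
                h0.append(sg["high_init"][()])
                gv.append(GateVariableSequence(sg["gate_vars"][()]))
                s += 1
            ts = TrainingSet(seqs, e0, m0, h0, gv,
                             NoiseModel(sigma=float(tg.attrs["sigma"])))
    return m, ts


# ---------------------------------------------------------------------------
# Seeding and manifests
# ---------------------------------------------------------------------------


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived by hashing the stage name
    so adding a stage never shifts another stage's stream."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(run_dir: str | Path, config: dict, master_seed: int,
                   stages: list[str], files: list[str | Path]) -> Path:
    """Write the run manifest (exactly one per run directory)."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "master_seed": master_seed,
        "stage_seeds": {s: stage_seed(master_seed, s) for s in stages},
        "config": _jsonable(config),
        "files": {str(Path(p).relative_to(run_dir)): file_sha256(p) for p in files},
    }
    out = run_dir / "manifest.json"
    with out.open("w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
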