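"""Run and cohort persistence.

A run is a CSV (columns ``time_s, ax, ay, az``; sensor frame, m/s^2) plus a
JSON sidecar carrying participant, condition, sampling rate, segment
intervals, speed and optional planted truth.  A cohort is a JSON manifest
referencing run files with roles and demographics.  Everything is plain
text and regenerable from (config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import Dataset
from .errors import DatasetError
from .runs import GRAVITY, RawRun

RUN_COLUMNS = ["time_s", "ax", "ay", "az"]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True) + "\n")


def save_run(run: RawRun, outdir: str | Path, include_truth: bool = False) -> Path:
    """Write one run as CSV + JSON sidecar; returns the CSV path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"{run.participant}_{run.condition}"
    csv_path = outdir / f"{stem}.csv"
    t = np.arange(run.n_samples) / run.fs_hz
    df = pd.DataFrame(
        dict(time_s=t, ax=run.samples[:, 0], ay=run.samples[:, 1],
             az=run.samples[:, 2]))
    df.to_csv(csv_path, index=False, float_format="%.6f")
    sidecar = dict(
        participant=run.participant,
        condition=run.condition,
        fs_hz=run.fs_hz,
        segments=[list(s) for s in run.segments],
        speed_mps=run.speed_mps,
        meta=run.meta,
    )
    if include_truth and run.truth is not None:
        truth = {k: v for k, v in run.truth.items() if k != "anatomical"}
        sidecar["truth"] = truth
    _dump_json(sidecar, outdir / f"{stem}.json")
    return csv_path


def load_run(csv_path: str | Path, units: str = "m/s2") -> RawRun:
    """Load a run; ``units='g'`` converts acceleration columns to m/s^2."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise DatasetError(f"missing run file: {csv_path}")
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise DatasetError(f"missing sidecar: {sidecar_path}")
    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:
        raise DatasetError(f"malformed CSV {csv_path}: {exc}") from exc
    if list(df.columns) != RUN_COLUMNS:
        raise DatasetError(
            f"{csv_path}: expected columns {RUN_COLUMNS}, got {list(df.columns)}")
    meta = json.loads(sidecar_path.read_text())
    samples = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    if units == "g":
        samples = samples * GRAVITY
    elif units != "m/s2":
        raise DatasetError(f"unknown units {units!r}")
    return RawRun(
        samples=samples,
        fs_hz=float(meta["fs_hz"]),
        segments=[tuple(s) for s in meta["segments"]],
        condition=meta["condition"],
        participant=meta["participant"],
        speed_mps=float(meta["speed_mps"]),
        truth=meta.get("truth"),
        meta=meta.get("meta", {}),
    )


def save_dataset(ds: Dataset, outdir: str | Path,
                 include_truth: bool = False) -> Path:
    """Write all runs and a manifest JSON; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for run in ds.runs:
        csv_path = save_run(run, outdir / "runs", include_truth=include_truth)
        entries.append(dict(
            participant=run.participant,
            condition=run.condition,
            csv=str(csv_path.relative_to(outdir)),
        ))
    manifest = dict(
        runs=entries,
        participants=ds.manifest.to_dict(orient="records"),
        provenance=ds.provenance,
    )
    path = outdir / "manifest.json"
    _dump_json(manifest, path)
    return path


def load_dataset(manifest_path: str | Path) -> Dataset:
    """Load a cohort from its manifest, validating run files and keys."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DatasetError(f"missing manifest: {manifest_path}")
    doc = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    seen = set()
    runs = []
    for entry in doc["runs"]:
        key = (entry["participant"], entry["condition"])
        if key in seen:
            raise DatasetError(f"duplicate (participant, condition): {key}")
        seen.add(key)
        runs.append(load_run(base / entry["csv"]))
    manifest = pd.DataFrame(doc["participants"])
    return Dataset(runs=runs, manifest=manifest,
                   provenance=doc.get("provenance", {}))


def save_selection(result, path: str | Path) -> None:
    """Serialize a SelectionResult to JSON."""
    _dump_json(
        dict(
            per_iteration_orders=result.per_iteration_orders,
            retention_frequency=result.retention_frequency.to_dict(),
            retained=result.retained,
            mean_rank={k: v for k, v in result.mean_rank.items()
                       if not np.isnan(v)},
            n_iterations=result.n_iterations,
            threshold=result.threshold,
        ),
        Path(path),
    )


def save_evaluation(result, path: str | Path) -> None:
    """Serialize an EvalResult to JSON (fold assignments included)."""
    _dump_json(
        dict(
            cv_accuracies=result.cv_accuracies,
            test_accuracies=result.test_accuracies,
            cv_mean=result.cv_mean, cv_sd=result.cv_sd,
            test_mean=result.test_mean, test_sd=result.test_sd,
            n_iterations=result.n_iterations,
            per_participant_counts=result.per_participant_counts.to_dict(),
            fold_assignments=result.fold_assignments,
        ),
        Path(path),
    )
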