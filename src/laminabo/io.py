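"""Session and results I/O.

A session directory holds one JSON manifest per penetration, spikes and
trials as CSV tables, unit metadata as CSV, the LFP as HDF5, and (for
synthetic sessions) a ``ground_truth.json``.  Stage results serialize to
JSON with a schema version; undefined numbers (NaN) are stored as explicit
nulls and survive a round trip.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Optional

import h5py
import numpy as np
import pandas as pd

from .datamodel import (
    LFPBlock,
    Session,
    UnitMeta,
    ValidationError,
    manifest_from_dict,
    manifest_to_dict,
)

SCHEMA_VERSION = 1


def _jsonify(obj: Any) -> Any:
    """Recursively convert to JSON-serializable values; NaN/inf -> None."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"__type__": type(obj).__name__,
                **{k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not math.isfinite(v) else v
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _dejsonify(obj: Any) -> Any:
    """Inverse of :func:`_jsonify` for plain containers (nulls -> NaN)."""
    if obj is None:
        return float("nan")
    if isinstance(obj, dict):
        return {k: _dejsonify(v) for k, v in obj.items() if k != "__type__"}
    if isinstance(obj, list):
        return [_dejsonify(v) for v in obj]
    return obj


def save_results(results: Any, path: Path | str) -> Path:
    """Serialize a stage result (dataclass / dict / array) to JSON."""
    path = Path(path)
    payload = {"schema_version": SCHEMA_VERSION, "results": _jsonify(results)}
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=1))
    except OSError as e:
        raise OSError(f"cannot write results to {path}: {e}") from e
    return path


def load_results(path: Path | str, raw: bool = False) -> Any:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"results file not found: {path}")
    payload = json.loads(path.read_text())
    res = payload["results"]
    return res if raw else _dejsonify(res)


def save_session(session: Session, directory: Path | str,
                 ground_truth: Optional[Any] = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = manifest_to_dict(session.manifest)
    manifest["files"] = {
        "spikes": "spikes.csv", "trials": "trials.csv", "units": "units.csv",
        "lfp": "lfp.h5" if session.lfp is not None else None,
        "ground_truth": "ground_truth.json" if ground_truth is not None else None,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    session.spikes.to_csv(directory / "spikes.csv", index=False)
    session.trials.to_csv(directory / "trials.csv", index=False)
    units = pd.DataFrame.from_records([
        dict(unit_id=u.unit_id, isolation=u.isolation, peak_contact=u.peak_contact,
             **{f"amp{k}": a for k, a in enumerate(u.contact_amplitudes)})
        for u in session.units])
    units.to_csv(directory / "units.csv", index=False)
    if session.lfp is not None:
        with h5py.File(directory / "lfp.h5", "w") as f:
            f.create_dataset("t_ms", data=session.lfp.t_ms)
            f.create_dataset("data", data=session.lfp.data)
            f.attrs["sampling_rate_hz"] = session.lfp.sampling_rate_hz
            f.attrs["n_trials"] = session.lfp.n_trials
    if ground_truth is not None:
        save_results(ground_truth, directory / "ground_truth.json")
    return directory / "manifest.json"


def load_session(manifest_path: Path | str) -> Session:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    d = json.loads(manifest_path.read_text())
    files = d.pop("files", {})
    manifest = manifest_from_dict(d)
    base = manifest_path.parent

    def _req(name: str) -> Path:
        rel = files.get(name)
        if rel is None:
            raise ValidationError(f"manifest lists no {name!r} file")
        p = base / rel
        if not p.exists():
            raise FileNotFoundError(f"referenced {name} file not found: {p}")
        return p

    spikes = pd.read_csv(_req("spikes"),
                         dtype={"unit_id": str, "trial_id": np.int64, "t_ms": float})
    if spikes.empty:
        spikes = pd.DataFrame({"unit_id": pd.Series(dtype=str),
                               "trial_id": pd.Series(dtype=np.int64),
                               "t_ms": pd.Series(dtype=float)})
    trials = pd.read_csv(_req("trials"))
    units_df = pd.read_csv(_req("units"), dtype={"unit_id": str})
    units = [UnitMeta(unit_id=r.unit_id, isolation=r.isolation,
                      peak_contact=int(r.peak_contact),
                      contact_amplitudes=tuple(getattr(r, f"amp{k}") for k in range(5)))
             for r in units_df.itertuples()]
    lfp = None
    if files.get("lfp"):
        with h5py.File(base / files["lfp"], "r") as f:
            lfp = LFPBlock(sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
                           t_ms=f["t_ms"][:], data=f["data"][:],
                           n_trials=int(f.attrs["n_trials"]))
    return Session(manifest=manifest, spikes=spikes, trials=trials,
                   units=units, lfp=lfp)
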