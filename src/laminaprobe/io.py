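"""Readers/writers, configuration and run manifests.

Conventions: times are stored in milliseconds (floats) in tables; sample
indices live only in trace files; trial tables are CSV, traces HDF5 (CSV
fallback), results JSON.  Every pipeline run writes a manifest recording
the config snapshot, the root seed, component seeds and output digests, so
a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import SchemaError
from .simulate.motoneuron import EmgTrace

__all__ = [
    "TRIAL_COLUMNS",
    "SCHEMA_VERSION",
    "read_trial_table",
    "write_trial_table",
    "write_traces",
    "read_traces",
    "write_trace_csv",
    "read_trace_csv",
    "load_config",
    "RunManifest",
]

SCHEMA_VERSION = 1

#: Documented trial-table schema (task-session tables).
TRIAL_COLUMNS = [
    "trial_id",
    "epoch",
    "delay_condition",
    "delay_ms",
    "cue_difficulty",
    "cue_direction",
    "response",
    "correct",
    "coherence_pct",
    "emg_id",
    "stimulus_sample",
]


def write_trial_table(trials: pd.DataFrame, path) -> Path:
    """Write a trial table as CSV (schema-checked)."""
    _check_schema(trials)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)
    return path


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial table CSV, validating the documented schema."""
    df = pd.read_csv(path)
    _check_schema(df)
    return df


def _check_schema(df: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing column(s): {', '.join(missing)}")


def write_traces(traces: dict[str, EmgTrace], path) -> Path:
    """Write an EMG/trace archive to HDF5 (one dataset per trace)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for key, tr in traces.items():
            ds = f.create_dataset(key, data=tr.samples)
            ds.attrs["sampling_rate_hz"] = tr.sampling_rate_hz
            ds.attrs["units"] = "uV"
            ds.attrs["stimulus_sample"] = tr.stimulus_sample
            if tr.tms_sample is not None:
                ds.attrs["tms_sample"] = tr.tms_sample
            if tr.fixation_offset_sample is not None:
                ds.attrs["fixation_offset_sample"] = tr.fixation_offset_sample
    return path


def read_traces(path) -> dict[str, EmgTrace]:
    """Read a trace archive written by :func:`write_traces`."""
    out: dict[str, EmgTrace] = {}
    with h5py.File(path, "r") as f:
        for key in f:
            ds = f[key]
            out[key] = EmgTrace(
                samples=ds[()],
                sampling_rate_hz=float(ds.attrs["sampling_rate_hz"]),
                stimulus_sample=int(ds.attrs["stimulus_sample"]),
                tms_sample=(
                    int(ds.attrs["tms_sample"]) if "tms_sample" in ds.attrs else None
                ),
                fixation_offset_sample=(
                    int(ds.attrs["fixation_offset_sample"])
                    if "fixation_offset_sample" in ds.attrs
                    else None
                ),
            )
    return out


def write_trace_csv(trace: EmgTrace, path) -> Path:
    """CSV fallback for a single trace (sample index + µV columns)."""
    path = Path(path)
    df = pd.DataFrame({"sample": np.arange(len(trace.samples)), "uV": trace.samples})
    df.attrs = {}
    header = (
        f"# sampling_rate_hz={trace.sampling_rate_hz}"
        f" stimulus_sample={trace.stimulus_sample}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


def read_trace_csv(path) -> EmgTrace:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise SchemaError("trace CSV missing metadata header")
        meta = dict(kv.split("=") for kv in header[1:].split())
        df = pd.read_csv(fh)
    return EmgTrace(
        samples=df["uV"].to_numpy(),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        stimulus_sample=int(meta["stimulus_sample"]),
    )


def load_config(path) -> dict:
    """Load a YAML run configuration; checks the schema version."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    version = cfg.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported config schema_version {version}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    root_seed: int
    config: dict
    component_seeds: dict[str, int] = field(default_factory=dict)
    software_version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def record_output(self, path) -> None:
        p = Path(path)
        self.outputs[p.name] = _sha256(p)

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)
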