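"""Plain-text I/O: trace TSVs with JSON sidecars, DE tables, fit records."""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import VelocityTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_de_table",
    "read_de_table",
    "write_json_record",
    "read_json_record",
]

DE_COLUMNS = ["transcript_id", "log2fc", "padj"]


def write_trace(path: str | Path, trace: VelocityTrace, extra_meta: dict | None = None) -> Path:
    """Write a trace as two-column TSV (time_s, value) plus a ``.json`` sidecar."""
    path = Path(path)
    t = trace.times
    frame = pd.DataFrame({"time_s": t, "velocity_m_per_s": trace.samples})
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    meta = {
        "dt_s": trace.dt,
        "units": {"time": "s", "value": "m/s"},
        "state_label": trace.state_label,
        "oscillation_label": trace.oscillation_label,
        "seed": trace.seed,
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2, default=_jsonable))
    return path


def read_trace(path: str | Path) -> VelocityTrace:
    """Read a trace TSV and its JSON sidecar back into a :class:`VelocityTrace`."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        meta = {}
    times = frame.iloc[:, 0].to_numpy(dtype=float)
    values = frame.iloc[:, 1].to_numpy(dtype=float)
    dt = meta.get("dt_s")
    if dt is None:
        steps = np.diff(times)
        if steps.size == 0 or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError(f"{path}: non-uniform sampling and no dt in sidecar")
        dt = float(steps[0])
    return VelocityTrace(
        samples=values,
        dt=float(dt),
        state_label=meta.get("state_label", "passive"),
        oscillation_label=meta.get("oscillation_label", "n/a"),
        seed=meta.get("seed"),
    )


def write_de_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    missing = set(DE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    table[DE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.8g")
    return path


def read_de_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    return table


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    raise TypeError(f"cannot serialize {type(obj)!r}")


def write_json_record(path: str | Path, record) -> Path:
    """Serialize a result dataclass (or dict) to JSON, tolerating numpy scalars."""
    path = Path(path)
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        record = dataclasses.asdict(record)
    path.write_text(json.dumps(record, indent=2, default=_jsonable))
    return path


def read_json_record(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
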