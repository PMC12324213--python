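"""Trace and report I/O.

Traces are delimited text, one file per sweep, with ``# key=value`` metadata
header lines followed by a CSV header and the three data columns
(time_s, extension_nm, force_pN).  Reports are JSON and always embed the
config hash and seed for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fec import AnalyzedTrace, ForceExtensionTrace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "read_trace_dir",
    "write_traces",
    "transitions_table",
    "write_json_report",
]

_META_KEYS = ("molecule_id", "cycle_index", "direction", "sample_rate_hz")


def write_trace_csv(trace: ForceExtensionTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# molecule_id={trace.molecule_id}\n")
        fh.write(f"# cycle_index={trace.cycle_index}\n")
        fh.write(f"# direction={trace.direction}\n")
        fh.write(f"# sample_rate_hz={trace.sample_rate!r}\n")
        fh.write("time_s,extension_nm,force_pN\n")
        for t, x, f in zip(trace.time, trace.extension, trace.force):
            fh.write(f"{float(t)!r},{float(x)!r},{float(f)!r}\n")


def read_trace_csv(path: str | Path) -> ForceExtensionTrace:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise ValueError(f"{path}: missing metadata keys {missing}")
    return ForceExtensionTrace(
        molecule_id=meta["molecule_id"],
        cycle_index=int(meta["cycle_index"]),
        direction=meta["direction"],
        time=df["time_s"].to_numpy(),
        extension=df["extension_nm"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        sample_rate=float(meta["sample_rate_hz"]),
    )


def write_traces(
    traces: Sequence[ForceExtensionTrace],
    outdir: str | Path,
    labels: Sequence[Mapping[str, Any]] | None = None,
    provenance: Mapping[str, Any] | None = None,
) -> list[Path]:
    """Write one CSV per sweep plus an optional ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tr in traces:
        name = f"{tr.molecule_id}_c{tr.cycle_index:02d}_{tr.direction}.csv"
        p = outdir / name
        write_trace_csv(tr, p)
        paths.append(p)
    if labels is not None:
        sidecar = {"labels": list(labels)}
        if provenance:
            sidecar.update(provenance)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=1, default=_jsonable)
    return paths


def read_trace_dir(indir: str | Path) -> list[ForceExtensionTrace]:
    indir = Path(indir)
    files = sorted(indir.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no trace CSV files in {indir}")
    return [read_trace_csv(p) for p in files]


def transitions_table(analyzed: Iterable[AnalyzedTrace]) -> pd.DataFrame:
    """Long-format table of all detected transitions."""
    rows = []
    for a in analyzed:
        tr = a.trace
        for t in a.transitions:
            rows.append({
                "molecule": tr.molecule_id,
                "cycle": tr.cycle_index,
                "direction": t.direction,
                "index": t.index,
                "force_before_pN": t.force_before,
                "jump_nm": t.jump_nm,
                "dlc_nm": t.dlc_nm,
            })
    return pd.DataFrame(
        rows,
        columns=["molecule", "cycle", "direction", "index",
                 "force_before_pN", "jump_nm", "dlc_nm"],
    )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json_report(report: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(report), fh, indent=1, default=_jsonable)
        fh.write("\n")
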