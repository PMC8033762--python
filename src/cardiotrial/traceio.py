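"""Readers/writers for traces, results and configs.

Trace CSV uses columns ``t_s, vm_mV, cai_nM`` with a JSON metadata sidecar
(``<name>.meta.json``); HDF5 stores the same arrays plus metadata as
attributes, for long runs.  Both round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import Trace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_trace_hdf5",
    "write_trace_hdf5",
    "results_to_frame",
    "write_results",
]


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"t_s": trace.t, "vm_mV": trace.vm, "cai_nM": trace.cai}
    ).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"dt": trace.dt, **trace.metadata},
                                  indent=1, default=str))


def read_trace_csv(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    dt = meta.pop("dt", None)
    if dt is None:
        dt = float(np.median(np.diff(df["t_s"]))) if len(df) > 1 else 1e-3
    return Trace(
        t=df["t_s"].to_numpy(),
        vm=df["vm_mV"].to_numpy(),
        cai=df["cai_nM"].to_numpy(),
        dt=float(dt),
        metadata=meta,
    )


def write_trace_hdf5(trace: Trace, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("t_s", data=trace.t)
        f.create_dataset("vm_mV", data=trace.vm)
        f.create_dataset("cai_nM", data=trace.cai)
        f.attrs["dt"] = trace.dt
        f.attrs["metadata"] = json.dumps(trace.metadata, default=str)


def read_trace_hdf5(path: str | Path) -> Trace:
    with h5py.File(path, "r") as f:
        return Trace(
            t=f["t_s"][...],
            vm=f["vm_mV"][...],
            cai=f["cai_nM"][...],
            dt=float(f.attrs["dt"]),
            metadata=json.loads(f.attrs.get("metadata", "{}")),
        )


def results_to_frame(results) -> pd.DataFrame:
    """Tidy frame from a list of TrialResult."""
    return pd.DataFrame([r.as_record() for r in results])


def write_results(results, path: str | Path) -> None:
    """Trial results as CSV or JSON, by extension."""
    path = Path(path)
    df = results_to_frame(results)
    if path.suffix.lower() == ".json":
        path.write_text(df.to_json(orient="records", indent=1))
    else:
        df.to_csv(path, index=False)
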