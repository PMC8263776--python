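"""CSV/TIFF plumbing shared by the CLI and pipelines.

Traces travel as long-format CSV (spot_id, frame, time_s, intensity); step
count tables as two-column CSV (k, count); images as grayscale TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .steps import StepCountTable
from .traces import BleachTrace

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_step_table_csv",
    "read_step_table_csv",
]


def write_traces_csv(traces, path) -> None:
    frames = []
    for trace in traces:
        frames.append(
            pd.DataFrame(
                {
                    "spot_id": trace.spot_id,
                    "frame": np.arange(len(trace)),
                    "time_s": trace.times,
                    "intensity": trace.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path, frame_interval: float | None = None) -> list[BleachTrace]:
    df = pd.read_csv(path)
    required = {"spot_id", "frame", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"trace CSV {path} must have columns {sorted(required)}")
    traces = []
    for spot_id, grp in df.groupby("spot_id", sort=True):
        grp = grp.sort_values("frame")
        if frame_interval is None:
            t = grp.get("time_s")
            dt = float(t.iloc[1] - t.iloc[0]) if t is not None and len(grp) > 1 else 1.0
        else:
            dt = frame_interval
        traces.append(
            BleachTrace(values=grp["intensity"].to_numpy(), frame_interval=dt, spot_id=spot_id)
        )
    return traces


def write_step_table_csv(table: StepCountTable, path) -> None:
    ks = sorted(range(1, table.k_max + 1))
    pd.DataFrame({"k": ks, "count": [table.counts.get(k, 0) for k in ks]}).to_csv(path, index=False)


def read_step_table_csv(path) -> StepCountTable:
    df = pd.read_csv(path)
    if not {"k", "count"} <= set(df.columns):
        raise ValueError(f"step table CSV {path} must have columns ['k', 'count']")
    counts = {int(k): int(c) for k, c in zip(df["k"], df["count"]) if c > 0}
    return StepCountTable.from_counts(counts, k_max=int(df["k"].max()))
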