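"""Readers and writers: tidy trace CSVs, rhythm-result CSVs, space-time
matrices, multi-page TIFF stacks and YAML/JSON configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GeneratorConfig, ImageStack, SectionProfile
from .traces import CellTrace
from .wave_model import SpaceTimeMatrix

__all__ = [
    "load_traces",
    "save_traces",
    "save_results",
    "load_results",
    "load_stack",
    "save_stack",
    "save_spacetime",
    "load_spacetime",
    "config_from_dict",
    "config_hash",
]

TRACE_COLUMNS = ["cell_id", "section", "x_mm", "y_mm", "z_mm", "time_h", "value"]


def save_traces(traces: list[CellTrace], path) -> None:
    """Write traces as tidy long CSV (one row per cell per time point)."""
    frames = [
        pd.DataFrame(
            {
                "cell_id": c.cell_id,
                "section": c.section,
                "x_mm": c.position[0],
                "y_mm": c.position[1],
                "z_mm": c.position[2],
                "time_h": c.times,
                "value": c.values,
            }
        )
        for c in traces
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=TRACE_COLUMNS
    )
    df.to_csv(path, index=False)


def load_traces(path) -> list[CellTrace]:
    """Read a tidy trace CSV back into :class:`CellTrace` objects.

    Malformed rows (missing columns, duplicated ``(cell_id, time_h)`` pairs,
    non-increasing times within a cell) raise ``ValueError`` naming the
    offending cell/column.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        return []
    dup = df.duplicated(subset=["cell_id", "time_h"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicated (cell_id, time_h) = "
            f"({row['cell_id']!r}, {row['time_h']}) at row {int(df.index[dup][0]) + 2}"
        )
    bad = df[TRACE_COLUMNS[2:]].apply(lambda s: ~np.isfinite(s))
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        raise ValueError(f"{path}: non-finite value in column {col!r}")
    traces = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy(float)
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError(f"{path}: non-monotone times for cell {cid!r}")
        traces.append(
            CellTrace(
                cell_id=str(cid),
                position=(
                    float(grp["x_mm"].iloc[0]),
                    float(grp["y_mm"].iloc[0]),
                    float(grp["z_mm"].iloc[0]),
                ),
                section=str(grp["section"].iloc[0]),
                times=times,
                values=grp["value"].to_numpy(float),
            )
        )
    return traces


def save_results(results, path) -> None:
    """Write rhythm results as CSV, one row per cell."""
    rows = []
    for r in results:
        row = {
            "cell_id": r.cell_id,
            "section": r.section,
            "x_mm": r.position[0],
            "y_mm": r.position[1],
            "z_mm": r.position[2],
            "rhythmic": r.rhythmic,
            "consensus_period_h": r.consensus_period,
            "amplitude": np.nan if r.amplitude is None else r.amplitude,
            "n_peaks": len(r.peak_times),
            "peak_times_h": ";".join(f"{t:.4f}" for t in r.peak_times),
        }
        for name, p in r.period_estimates.items():
            row[f"period_{name}_h"] = p
            row[f"gof_{name}"] = r.gof.get(name, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_stack(stack: ImageStack, path) -> None:
    """Write an image stack as multi-page TIFF (float32, lossless)."""
    import tifffile

    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        metadata={
            "frame_interval_h": stack.frame_interval,
            "pixel_size_mm": stack.pixel_size,
        },
    )


def load_stack(path, frame_interval: float = 1.5, pixel_size: float = 0.05) -> ImageStack:
    """Read a multi-page TIFF; metadata overrides the interval/pixel defaults."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray().astype(float)
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(
        frames,
        float(meta.get("frame_interval_h", frame_interval)),
        float(meta.get("pixel_size_mm", pixel_size)),
    )


def save_spacetime(stm: SpaceTimeMatrix, path) -> None:
    df = pd.DataFrame(
        stm.values,
        index=pd.Index(stm.rows, name="row"),
        columns=[f"{t:.4f}" for t in stm.times],
    )
    df.to_csv(path)


def load_spacetime(path) -> SpaceTimeMatrix:
    df = pd.read_csv(path, index_col=0)
    return SpaceTimeMatrix(
        rows=df.index.to_numpy(int),
        times=np.array([float(c) for c in df.columns]),
        values=df.to_numpy(float),
    )


def config_from_dict(d: dict) -> GeneratorConfig:
    """Build a GeneratorConfig from a plain (YAML/JSON) mapping."""
    d = dict(d)
    if "sections" in d:
        d["sections"] = [
            s if isinstance(s, SectionProfile) else SectionProfile(
                **{**s, "y_range": tuple(s["y_range"])}
            )
            for s in d["sections"]
        ]
    return GeneratorConfig(**d)


def config_hash(config) -> str:
    """Stable short hash of a (dataclass or dict) configuration."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
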