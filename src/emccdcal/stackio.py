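"""Readers and writers for frame stacks and calibration results.

Stacks travel as multi-page TIFF (16-bit unsigned, the standard microscopy
export format) with a JSON sidecar holding acquisition labels and, for
simulated data, the ground-truth camera parameters.  Results are written as
a versioned JSON summary plus CSV maps for per-pixel estimates.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .noise_model import CameraParams
from .results import CalibrationResult
from .simulator import FrameStack, SeriesDataset

__all__ = ["read_stack", "write_stack", "read_series", "write_series", "write_result"]

SCHEMA_VERSION = 1


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: FrameStack, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.counts.astype(np.uint16))
    meta = {
        "schema_version": SCHEMA_VERSION,
        "gain_label": stack.gain_label,
        "illum_label": stack.illum_label,
        "n_clipped": stack.n_clipped,
        "truth": dataclasses.asdict(stack.truth) if stack.truth is not None else None,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_stack(path) -> FrameStack:
    """Read a multi-page TIFF stack (8/16-bit unsigned) plus its optional
    JSON sidecar; missing sidecars default the labels to "unknown"."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3 or data.shape[0] < 1:
        raise ValueError(f"{path}: expected a multi-page stack, got shape {data.shape}")
    if data.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"{path}: expected 8/16-bit unsigned counts, got {data.dtype}")
    meta = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    truth = CameraParams(**meta["truth"]) if meta.get("truth") else None
    return FrameStack(
        counts=data.astype(np.uint16),
        gain_label=meta.get("gain_label", "unknown"),
        illum_label=meta.get("illum_label", "unknown"),
        truth=truth,
        n_clipped=int(meta.get("n_clipped", 0)),
    )


def write_series(series: SeriesDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = {"schema_version": SCHEMA_VERSION, "series_axis": series.series_axis,
             "stacks": [], "darks": {}}
    for i, stk in enumerate(series.stacks):
        name = f"stack_{i:02d}_{stk.gain_label}_{stk.illum_label}.tif"
        write_stack(stk, outdir / name)
        index["stacks"].append(name)
    for lbl, dk in series.dark_stacks.items():
        name = f"dark_{lbl}.tif"
        write_stack(dk, outdir / name)
        index["darks"][lbl] = name
    (outdir / "series.json").write_text(json.dumps(index, indent=2))


def read_series(outdir) -> SeriesDataset:
    outdir = Path(outdir)
    index = json.loads((outdir / "series.json").read_text())
    stacks = [read_stack(outdir / n) for n in index["stacks"]]
    darks = {lbl: read_stack(outdir / n) for lbl, n in index["darks"].items()}
    return SeriesDataset(stacks, index["series_axis"], darks)


def write_result(result, path, config: dict | None = None) -> None:
    """Write a CalibrationResult (JSON + per-pixel CSV maps), a consistency
    report dict, or any jsonable mapping."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(result, CalibrationResult):
        payload = result.to_jsonable()
        payload["schema_version"] = SCHEMA_VERSION
        if config:
            payload["config"] = config
        arrays = {
            k: np.asarray(v)
            for k, v in result.estimates.items()
            if isinstance(v, np.ndarray) and np.asarray(v).ndim == 2
        }
        if arrays:
            rows = []
            H, W = next(iter(arrays.values())).shape
            for r in range(H):
                for c in range(W):
                    row = {"row": r, "col": c}
                    row.update({k: float(v[r, c]) for k, v in arrays.items()})
                    rows.append(row)
            pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)
            payload["per_pixel_csv"] = path.with_suffix(".csv").name
        path.write_text(json.dumps(payload, indent=2))
        return
    if config:
        result = {"config": config, **result}
    result = {"schema_version": SCHEMA_VERSION, **result}
    path.write_text(json.dumps(result, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if dataclasses.is_dataclass(x):
        return dataclasses.asdict(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
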