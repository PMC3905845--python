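"""TIFF / CSV / JSON input-output with explicit physical calibration."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from halodyn.stack import ImageStack
from halodyn.frap import FrapTrace
from halodyn.segquant import CellRecord, FocusRecord, PopulationSummary

__all__ = [
    "read_stack",
    "write_stack",
    "read_traces_csv",
    "write_traces_csv",
    "write_cell_records",
    "write_focus_records",
    "write_population_summary",
    "write_json",
]


def read_stack(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as a (t, y, x) stack.

    Physical calibration is mandatory and never assumed from file
    metadata; page order is taken as time order. RGB/multichannel TIFFs
    are rejected.
    """
    path = Path(path)
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("missing calibration: pixel_size_um must be given and positive")
    try:
        data = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"grayscale required: got array of shape {data.shape}")
    # heuristics: trailing axis of 3/4 on a 3-D array is a color axis
    if data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:-1]):
        raise ValueError("grayscale required: TIFF appears to be RGB(A)")
    return ImageStack(
        data=data,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        meta={"source": str(path)},
    )


def write_stack(path: str | Path, stack: ImageStack | np.ndarray, dtype=None) -> Path:
    """Write a stack as a multi-page TIFF (uint16 by default for counts)."""
    path = Path(path)
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if dtype is None:
        dtype = np.uint16 if np.issubdtype(data.dtype, np.integer) else np.float32
    tifffile.imwrite(
        path, np.ascontiguousarray(data.astype(dtype)), photometric="minisblack"
    )
    return path


def read_traces_csv(
    path: str | Path,
    n_prebleach: int = 50,
    bleach_area_um2: float | None = None,
) -> FrapTrace:
    """Read a trace CSV with columns time_s, roi, background."""
    df = pd.read_csv(path)
    required = {"time_s", "roi", "background"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    return FrapTrace(
        t=df["time_s"].to_numpy(float),
        i_raw=df["roi"].to_numpy(float),
        i_b=df["background"].to_numpy(float),
        n_prebleach=n_prebleach,
        bleach_area_um2=bleach_area_um2,
    )


def write_traces_csv(path: str | Path, trace: FrapTrace) -> Path:
    path = Path(path)
    cols = {"time_s": trace.t, "roi": trace.i_raw, "background": trace.i_b}
    if trace.i_norm is not None:
        cols["normalized"] = trace.i_norm
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def write_cell_records(path: str | Path, cells: list[CellRecord]) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "surface_um2": c.surface_um2,
                "total_intensity": c.total_intensity,
                "n_foci": c.n_foci,
                "foci_total_intensity": c.foci_total_intensity,
            }
            for c in cells
        ]
    ).to_csv(path, index=False)
    return path


def write_focus_records(path: str | Path, foci: list[FocusRecord]) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "cell_id": f.cell_id,
                "x_um": f.centroid_um[0],
                "y_um": f.centroid_um[1],
                "diameter_um": f.diameter_um,
                "intensity": f.intensity,
                "quality": f.quality,
            }
            for f in foci
        ]
    ).to_csv(path, index=False)
    return path


def write_population_summary(path: str | Path, summary: PopulationSummary) -> Path:
    return write_json(path, summary.to_dict())


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    path.write_text(json.dumps(payload, indent=2, default=default) + "\n")
    return path
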