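"""Reading image stacks and writing tabular results."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import AnalysisConfig, FrameImage

#: Columns of the per-blob table, in output order.
BLOB_COLUMNS = [
    "frame", "blob_id", "lineage_id", "area_px", "area_um2", "axial_ratio",
    "mean_intensity", "centroid_x", "centroid_y", "dist_to_edge_um",
]

_TABLE_PRECISION = 6


def infer_full_scale(data: np.ndarray) -> float:
    """Full-scale value (2^bit_depth - 1) for an integer image.

    The camera bit depth is taken as the smallest of 8/12/16 bits that can
    hold the observed maximum, so 12-bit data stored in uint16 containers
    normalizes correctly.
    """
    if np.issubdtype(data.dtype, np.floating):
        return 1.0
    vmax = int(data.max(initial=0))
    for bits in (8, 12, 16):
        if vmax <= 2**bits - 1:
            return float(2**bits - 1)
    return float(2**32 - 1)


def normalize_frames(data: np.ndarray, full_scale: float | None = None) -> np.ndarray:
    """Map raw camera counts to dimensionless [0, 1] intensities.

    Floating-point input already in [0, 1] is passed through unchanged, so
    normalization is idempotent.
    """
    data = np.asarray(data)
    if full_scale is None:
        full_scale = infer_full_scale(data)
    out = data.astype(np.float64) / full_scale
    if out.min(initial=0.0) < 0.0 or out.max(initial=0.0) > 1.0:
        raise ValueError("normalized intensities fall outside [0, 1]")
    return out


def load_stack(
    path: str | Path,
    config: AnalysisConfig | None = None,
    full_scale: float | None = None,
) -> list[FrameImage]:
    """Load a single- or multi-page grayscale TIFF stack as FrameImage list.

    Parameters
    ----------
    path : str or Path
        TIFF file; pages are frames in acquisition order.
    config : AnalysisConfig, optional
        Supplies pixel size and frame interval calibration.
    full_scale : float, optional
        Override the inferred camera full-scale value.
    """
    config = config or AnalysisConfig()
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D grayscale stack, got shape {data.shape}")
    if data.shape[0] == 0:
        raise ValueError("stack contains zero frames")
    norm = normalize_frames(data, full_scale=full_scale)
    return [
        FrameImage(
            pixels=norm[i],
            frame_index=i,
            pixel_size_um=config.pixel_size_um,
            frame_interval_min=config.frame_interval_min,
        )
        for i in range(norm.shape[0])
    ]


def frames_from_array(
    data: np.ndarray, config: AnalysisConfig | None = None
) -> list[FrameImage]:
    """Wrap an already-normalized (T, H, W) array as FrameImage objects."""
    config = config or AnalysisConfig()
    return [
        FrameImage(
            pixels=data[i],
            frame_index=i,
            pixel_size_um=config.pixel_size_um,
            frame_interval_min=config.frame_interval_min,
        )
        for i in range(data.shape[0])
    ]


def blob_table(blobs: Sequence) -> pd.DataFrame:
    """Tabulate AdhesionBlob objects, one row per blob per frame."""
    rows = []
    for b in blobs:
        rows.append({
            "frame": b.frame_index,
            "blob_id": b.blob_id,
            "lineage_id": b.lineage_id if b.lineage_id is not None else -1,
            "area_px": b.area_px,
            "area_um2": b.area_um2,
            "axial_ratio": b.axial_ratio,
            "mean_intensity": b.mean_intensity,
            "centroid_x": b.centroid[0],
            "centroid_y": b.centroid[1],
            "dist_to_edge_um": b.dist_to_edge_um if b.dist_to_edge_um is not None else np.nan,
        })
    return pd.DataFrame(rows, columns=BLOB_COLUMNS)


def write_blob_table(blobs: Sequence, path: str | Path) -> None:
    """Write the blob table as CSV (values rounded to 6 decimals)."""
    df = blob_table(blobs)
    df.to_csv(path, index=False, float_format=f"%.{_TABLE_PRECISION}f")


def read_blob_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_run_metadata(path: str | Path, config: AnalysisConfig, extra: dict | None = None) -> None:
    """Echo the configuration (and any stage metadata) as JSON."""
    payload = {"config": config.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
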