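"""File formats: multi-page TIFF stacks, CSV tracks/traces, TSV DE tables,
YAML configs.

All writers emit plain, column-stable files so runs are diffable:

* mask movies — multi-page uint8 TIFF (0/255) plus a track CSV
  (frame, time_s, x_um, y_um, state);
* imaging stacks — one multi-page TIFF per channel plus a stage CSV
  (frame, time_s, x_um, y_um);
* DE tables — TSV with gene_id, log2fc, q_value.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "write_mask_movie",
    "read_mask_movie",
    "write_track_csv",
    "read_track_csv",
    "write_stack",
    "read_stack_channel",
    "write_stage_csv",
    "read_stage_csv",
    "write_de_table",
    "read_de_table",
    "load_config",
    "save_config",
]


def write_mask_movie(path, movie, pad_to: int | None = None) -> Path:
    """Write silhouette crops as a multi-page uint8 TIFF (0/255).

    Crops are padded to a common square size so the pages stack.
    """
    path = Path(path)
    size = pad_to or max(max(m.shape) for m in movie.masks)
    pages = np.zeros((movie.n_frames, size, size), np.uint8)
    for i, m in enumerate(movie.masks):
        pages[i, : m.shape[0], : m.shape[1]] = m.astype(np.uint8) * 255
    tifffile.imwrite(path, pages)
    return path


def read_mask_movie(path) -> list[np.ndarray]:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    return [p > 0 for p in pages]


def write_track_csv(path, movie) -> Path:
    """Track CSV (frame, time_s, x_um, y_um, state) for a synthetic movie."""
    path = Path(path)
    pd.DataFrame(
        {
            "frame": np.arange(movie.n_frames),
            "time_s": movie.times,
            "x_um": movie.centroids[:, 0],
            "y_um": movie.centroids[:, 1],
            "state": movie.truth,
        }
    ).to_csv(path, index=False)
    return path


def read_track_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "time_s", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns {sorted(missing)}")
    return df


def write_stack(directory, stack, stem: str = "stack") -> dict[str, Path]:
    """Write a two-channel stack as <stem>_donor.tif / <stem>_acceptor.tif
    plus the stage log CSV; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for channel in ("donor", "acceptor"):
        p = directory / f"{stem}_{channel}.tif"
        tifffile.imwrite(p, getattr(stack, channel).astype(np.float32))
        paths[channel] = p
    paths["stage"] = write_stage_csv(
        directory / f"{stem}_stage.csv", stack.stage_log, stack.fps
    )
    return paths


def read_stack_channel(path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr[None] if arr.ndim == 2 else arr


def write_stage_csv(path, stage_xy: np.ndarray, fps: float) -> Path:
    path = Path(path)
    n = len(stage_xy)
    pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) / fps,
            "x_um": stage_xy[:, 0],
            "y_um": stage_xy[:, 1],
        }
    ).to_csv(path, index=False)
    return path


def read_stage_csv(path):
    from wormstate.trajectory import StageLog

    df = pd.read_csv(path)
    return StageLog(xy=df[["x_um", "y_um"]].to_numpy(), times=df["time_s"].to_numpy())


def write_de_table(path, df: pd.DataFrame) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_de_table(path) -> pd.DataFrame:
    from wormstate.deg_intersection import validate_de_table

    df = pd.read_csv(path, sep="\t")
    validate_de_table(df)
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(path, config: dict) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path
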