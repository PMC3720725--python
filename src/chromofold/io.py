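"""File conventions: TIFF stacks + JSON sidecars, bleach-curve CSVs.

Image stacks are written as one multi-page TIFF per channel per cell plus a
JSON sidecar carrying voxel spacing, seed and ground truth; the nucleus
support is stored as an extra uint8 TIFF. Bleach curves are CSVs with
columns frame, time_s, spot_mean, background_mean (t = 0 at the last
pre-bleach frame).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kinetics import BleachSeries
from .morphology import ImageStack3D
from .synthetic import GroundTruth


def write_stack(
    directory: str | Path,
    cell_id: str,
    stack: ImageStack3D,
    truth: GroundTruth | None = None,
    seed: int | None = None,
) -> Path:
    """Write one cell's stack (per-channel TIFFs + JSON sidecar); returns sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in stack.channel_names:
        tifffile.imwrite(
            directory / f"{cell_id}_{name}.tif",
            stack.channel(name).astype(np.float32),
        )
    if stack.nucleus_mask is not None:
        tifffile.imwrite(
            directory / f"{cell_id}_nucleus_mask.tif",
            stack.nucleus_mask.astype(np.uint8),
        )
    sidecar: dict = {
        "cell_id": cell_id,
        "voxel_spacing_um": list(stack.voxel_spacing),
        "channel_names": list(stack.channel_names),
        "seed": seed,
    }
    if truth is not None:
        sidecar["ground_truth"] = {
            "true_volume_um3": truth.true_volume,
            "true_surface_area_um2": truth.true_surface_area,
            "true_surface_factor": truth.true_surface_factor,
            "channel_enrichments": truth.channel_enrichments,
        }
    path = directory / f"{cell_id}.json"
    path.write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(sidecar_path: str | Path) -> tuple[ImageStack3D, dict]:
    """Read a stack written by :func:`write_stack`; returns (stack, sidecar)."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    directory = sidecar_path.parent
    cell_id = meta["cell_id"]
    channels = [
        tifffile.imread(directory / f"{cell_id}_{name}.tif").astype(float)
        for name in meta["channel_names"]
    ]
    mask_path = directory / f"{cell_id}_nucleus_mask.tif"
    nucleus = tifffile.imread(mask_path).astype(bool) if mask_path.exists() else None
    stack = ImageStack3D(
        voxels=np.stack(channels),
        voxel_spacing=tuple(meta["voxel_spacing_um"]),
        channel_names=meta["channel_names"],
        nucleus_mask=nucleus,
    )
    return stack, meta


def write_bleach_csv(series: BleachSeries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series.to_frame().to_csv(path, index=False)
    return path


def read_bleach_csv(path: str | Path, mode: str = "FLIP") -> BleachSeries:
    """Read a curve CSV; pre-bleach frames are those with time_s ≤ 0."""
    df = pd.read_csv(path)
    required = {"time_s", "spot_mean", "background_mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curve CSV missing columns: {sorted(missing)}")
    n_pre = int((df["time_s"].to_numpy() <= 0).sum())
    return BleachSeries(
        times=df["time_s"].to_numpy(),
        spot=df["spot_mean"].to_numpy(),
        background=df["background_mean"].to_numpy(),
        n_prebleach=max(n_pre, 1),
        mode=mode,
    )
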