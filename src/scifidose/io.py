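"""Readers and writers: TIFF images with JSON sidecars, CSV profiles and stacks."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phantom import DetectorImage
from .preprocess import HalfProfile, ProjectedProfile
from .reconstruct import DiskGrid, DiskStack

__all__ = [
    "write_image",
    "read_image",
    "write_profile_csv",
    "read_profile_csv",
    "write_half_profile_csv",
    "write_disk_stack_csv",
    "read_disk_stack_csv",
    "write_report_json",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(path, image: DetectorImage, dtype: str = "float32") -> None:
    """Write a single-channel TIFF plus a JSON sidecar with the pixel pitch."""
    path = Path(path)
    if dtype == "float32":
        data = image.pixels.astype(np.float32)
    elif dtype == "uint16":
        data = np.clip(np.rint(image.pixels), 0, np.iinfo(np.uint16).max).astype(
            np.uint16
        )
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")
    tifffile.imwrite(path, data)
    sidecar = {
        "pixel_pitch_mm": image.pixel_pitch,
        "x0_mm": image.x0,
        "orientation": image.orientation,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_image(path, pixel_pitch: float | None = None) -> DetectorImage:
    """Read a single-channel TIFF/PNG; pixel pitch from the sidecar or argument."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        pixels = tifffile.imread(path)
    else:
        from imageio.v3 import imread  # PNG fallback; TIFF is the native format

        pixels = imread(path)
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel image, got shape {pixels.shape}; "
            "convert to grayscale before loading"
        )
    sidecar = _sidecar_path(path)
    x0 = 0.0
    orientation = "y-fiber-axis"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_pitch = meta.get("pixel_pitch_mm", pixel_pitch)
        x0 = meta.get("x0_mm", 0.0)
        orientation = meta.get("orientation", orientation)
    if pixel_pitch is None:
        raise ValueError(
            f"{path.name}: no pixel pitch available; provide a {sidecar.name} "
            "sidecar or pass pixel_pitch explicitly"
        )
    return DetectorImage(pixels.astype(float), float(pixel_pitch), x0, orientation)


def write_profile_csv(path, profile: ProjectedProfile) -> None:
    pd.DataFrame({"position_mm": profile.x, "value": profile.p}).to_csv(
        path, index=False
    )


def read_profile_csv(path) -> ProjectedProfile:
    df = pd.read_csv(path)
    if not {"position_mm", "value"} <= set(df.columns):
        raise ValueError(f"{path}: profile CSV needs columns position_mm, value")
    return ProjectedProfile(df["position_mm"].to_numpy(), df["value"].to_numpy())


def write_half_profile_csv(path, half: HalfProfile) -> None:
    pd.DataFrame({"position_mm": half.x, "value": half.S}).to_csv(path, index=False)


def write_disk_stack_csv(path, stack: DiskStack) -> None:
    pd.DataFrame({"R_mm": stack.grid.R, "beta": stack.beta}).to_csv(path, index=False)


def read_disk_stack_csv(path) -> DiskStack:
    df = pd.read_csv(path)
    return DiskStack(
        df["beta"].to_numpy(), DiskGrid(df["R_mm"].to_numpy()), n_iter=0
    )


def write_report_json(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
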