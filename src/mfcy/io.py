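"""Reading and writing rasters, frame sequences, manifests and metrics.

Conventions:

* frames — 8-bit grayscale PNG sequences (zero-padded numeric stems define
  frame order) or multi-page TIFF; intensities mapped to [0, 1] on read;
* masks — 8-bit PNG with values exactly {0, 255}, mapped to {0, 1} on read
  (anything else is a load error naming the file);
* probability maps — 32-bit float TIFF; values outside [0, 1] are clipped
  on read and counted via a logged warning;
* manifests — CSV with columns image_id, video_id, case_id, frame_index,
  is_target; image_id must be unique.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import List

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .mask_core import Frame, VideoSequence, as_binary_mask

__all__ = [
    "read_mask",
    "write_mask",
    "read_probability_map",
    "write_probability_map",
    "read_frame_sequence",
    "write_frame_sequence",
    "Manifest",
    "read_manifest",
    "write_manifest",
    "sorted_raster_paths",
]

logger = logging.getLogger("mfcy.io")

_MANIFEST_COLUMNS = ["image_id", "video_id", "case_id", "frame_index", "is_target"]


def sorted_raster_paths(directory: Path, suffixes=(".png", ".tif", ".tiff")) -> List[Path]:
    """Files in ``directory`` in frame order (numeric stems sort numerically)."""
    paths = [p for p in Path(directory).iterdir() if p.suffix.lower() in suffixes]

    def key(p: Path):
        m = re.search(r"(\d+)$", p.stem)
        return (0, int(m.group(1)), p.name) if m else (1, 0, p.name)

    return sorted(paths, key=key)


def read_mask(path: Path) -> np.ndarray:
    """Load a {0, 255} PNG annotation as a {0, 1} mask."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # tolerate grayscale saved with redundant channels
        if not (arr == arr[..., :1]).all():
            raise ValueError(f"{path}: mask must be single-channel grayscale")
        arr = arr[..., 0]
    bad = ~np.isin(arr, (0, 255))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: mask value {int(arr[r, c])} at (row={r}, col={c}) "
            "is not 0 or 255"
        )
    return (arr > 0).astype(np.uint8)


def write_mask(path: Path, mask: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (as_binary_mask(mask) * 255).astype(np.uint8))


def read_probability_map(path: Path) -> np.ndarray:
    """Load a float TIFF probability map, clipping stray values into [0, 1]."""
    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{path}: probability map must be 2D, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: probability map contains non-finite values")
    n_out = int(np.count_nonzero((arr < 0.0) | (arr > 1.0)))
    if n_out:
        logger.warning("%s: clipped %d values into [0, 1]", path, n_out)
        arr = np.clip(arr, 0.0, 1.0)
    return arr


def write_probability_map(path: Path, values: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))


def _to_unit(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr / 255.0
    if arr.dtype == np.uint16:
        return arr / 65535.0
    return np.asarray(arr, dtype=float)


def read_frame_sequence(
    source: Path, video_id: str = "", case_id: str = ""
) -> VideoSequence:
    """Load a video from a PNG directory or a multi-page TIFF file."""
    source = Path(source)
    if source.is_dir():
        paths = sorted_raster_paths(source, suffixes=(".png",))
        if not paths:
            raise ValueError(f"{source}: no PNG frames found")
        rasters = [_to_unit(np.asarray(iio.imread(p))) for p in paths]
        vid = video_id or source.name
    else:
        stack = np.asarray(tifffile.imread(source))
        if stack.ndim == 2:
            stack = stack[None]
        rasters = [_to_unit(page) for page in stack]
        vid = video_id or source.stem
    frames = [Frame(pixels=np.clip(r, 0.0, 1.0), frame_index=i) for i, r in enumerate(rasters)]
    return VideoSequence(frames=frames, video_id=vid, case_id=case_id or vid)


def write_frame_sequence(directory: Path, video: VideoSequence) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for frame in video.frames:
        arr = np.round(frame.pixels * 255).astype(np.uint8)
        iio.imwrite(directory / f"{frame.frame_index:05d}.png", arr)


@dataclass
class Manifest:
    """Table tying image ids to their video/case and frame position."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _MANIFEST_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        if self.rows["image_id"].duplicated().any():
            dup = self.rows["image_id"][self.rows["image_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate image_id {dup!r} in manifest")

    def items(self) -> List[tuple[str, str, str]]:
        return list(
            zip(self.rows["image_id"], self.rows["case_id"], self.rows["video_id"])
        )


def read_manifest(path: Path) -> Manifest:
    return Manifest(rows=pd.read_csv(path, dtype={"image_id": str, "video_id": str, "case_id": str}))


def write_manifest(path: Path, manifest: Manifest) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.rows.to_csv(path, index=False)
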