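"""Image, mask, table and ground-truth I/O with explicit pixel calibration.

Array convention used throughout the package: rows index depth (z, increasing
downward from the scan head), columns index lateral position (x, one A-scan
per column). Coordinates are 0-based and regions of interest are half-open.
Physical position is exactly ``index * pitch`` in micrometres.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "BScan",
    "Volume",
    "Roi",
    "CalibrationError",
    "read_bscan",
    "write_bscan",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_table",
    "write_table",
    "read_truth",
    "write_truth",
    "load_config",
]

#: ITU-R BT.601 luma weights used to collapse RGB input to grayscale.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class CalibrationError(ValueError):
    """Raised for non-positive or missing pixel-pitch calibration."""


@dataclasses.dataclass
class BScan:
    """One 2D grayscale OCT cross-section with pixel-pitch calibration.

    Parameters
    ----------
    pixels : ndarray, shape (depth, lateral)
        Non-negative intensities; row 0 is the shallowest depth.
    axial_pitch : float
        Micrometres per pixel along depth (z).
    lateral_pitch : float
        Micrometres per pixel along the lateral axis (x).
    bit_depth : int, optional
        Sample depth of the source file (8 or 16), if read from disk.
    id : str
        Free-form label.
    """

    pixels: np.ndarray
    axial_pitch: float
    lateral_pitch: float
    bit_depth: int | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError(
                f"B-scan must be 2D with >=2 rows and columns, got shape {self.pixels.shape}"
            )
        if not (self.axial_pitch > 0 and self.lateral_pitch > 0):
            raise CalibrationError(
                f"pixel pitches must be positive, got axial={self.axial_pitch}, "
                f"lateral={self.lateral_pitch}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("B-scan intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("B-scan intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_depth(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.pixels.shape[1]

    def depth_um(self, row: int | np.ndarray) -> float | np.ndarray:
        """Physical depth of a row index (0-based, exactly index * pitch)."""
        return np.asarray(row) * self.axial_pitch

    def lateral_um(self, col: int | np.ndarray) -> float | np.ndarray:
        return np.asarray(col) * self.lateral_pitch


@dataclasses.dataclass
class Volume:
    """Ordered stack of identically calibrated B-scans (a C-scan)."""

    bscans: list[BScan]
    slice_pitch: float

    def __post_init__(self) -> None:
        if len(self.bscans) < 1:
            raise ValueError("volume needs at least one B-scan")
        if self.slice_pitch <= 0:
            raise CalibrationError(f"slice_pitch must be positive, got {self.slice_pitch}")
        first = self.bscans[0]
        for b in self.bscans[1:]:
            if b.shape != first.shape:
                raise ValueError(
                    f"all B-scans must share one shape; got {b.shape} vs {first.shape}"
                )
            if (b.axial_pitch, b.lateral_pitch) != (first.axial_pitch, first.lateral_pitch):
                raise CalibrationError("all B-scans must share one calibration")

    @property
    def n_slices(self) -> int:
        return len(self.bscans)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.bscans),) + self.bscans[0].shape

    def as_array(self) -> np.ndarray:
        """Stack to a (slices, depth, lateral) array."""
        return np.stack([b.pixels for b in self.bscans])


@dataclasses.dataclass(frozen=True)
class Roi:
    """Half-open rectangular region: columns [x_start, x_end), rows [z_start, z_end)."""

    x_start: int
    x_end: int
    z_start: int
    z_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_start < self.x_end and 0 <= self.z_start < self.z_end):
            raise ValueError(f"ROI bounds must satisfy 0 <= start < end, got {self}")

    def validate_for(self, shape: tuple[int, int]) -> None:
        height, width = shape
        if self.x_end > width or self.z_end > height:
            raise ValueError(f"ROI {self} exceeds image shape {shape}")

    @property
    def width(self) -> int:
        return self.x_end - self.x_start

    @property
    def depth(self) -> int:
        return self.z_end - self.z_start

    def slices(self) -> tuple[slice, slice]:
        return slice(self.z_start, self.z_end), slice(self.x_start, self.x_end)


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse RGB(A) to grayscale by luma weights; pass single-channel through."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        luma = rgb @ np.asarray(LUMA_WEIGHTS)
        if np.issubdtype(arr.dtype, np.integer):
            return np.rint(luma).astype(arr.dtype)
        return luma
    raise ValueError(f"unsupported image layout with shape {arr.shape}")


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def read_bscan(
    path: str | Path,
    axial_pitch: float,
    lateral_pitch: float,
    id: str | None = None,
) -> BScan:
    """Read an 8/16-bit PNG or TIFF B-scan and attach calibration.

    RGB input is converted to grayscale with luma weights 0.299/0.587/0.114;
    single-channel input is preserved losslessly. Row 0 is the shallowest depth.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _read_image(path)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    gray = _to_grayscale(arr)
    bit_depth = gray.dtype.itemsize * 8 if np.issubdtype(gray.dtype, np.integer) else None
    return BScan(
        pixels=gray,
        axial_pitch=axial_pitch,
        lateral_pitch=lateral_pitch,
        bit_depth=bit_depth,
        id=id if id is not None else path.stem,
    )


def write_bscan(bscan: BScan, path: str | Path) -> None:
    """Write a B-scan losslessly: integer dtypes as-is, floats as float32 TIFF."""
    path = Path(path)
    arr = bscan.pixels
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError("float B-scans can only be written to TIFF")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_volume(
    path_or_dir: str | Path,
    axial_pitch: float,
    lateral_pitch: float,
    slice_pitch: float,
) -> Volume:
    """Read a C-scan from a multi-page TIFF or a directory of images.

    For a directory, lexicographic filename order defines slice order; all
    slices must share one shape.
    """
    path = Path(path_or_dir)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise ValueError(f"no PNG/TIFF images in directory {path}")
        arrays = [_to_grayscale(_read_image(f)) for f in files]
        ids = [f.stem for f in files]
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        arrays = [_to_grayscale(a) for a in stack]
        ids = [f"{path.stem}[{i}]" for i in range(len(arrays))]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"B-scan shape mismatch across slices: {sorted(shapes)}")
    bscans = [
        BScan(a, axial_pitch=axial_pitch, lateral_pitch=lateral_pitch, id=i)
        for a, i in zip(arrays, ids)
    ]
    return Volume(bscans=bscans, slice_pitch=slice_pitch)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (float slices as float32)."""
    arr = volume.as_array()
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as {0, 255} PNG/TIFF, or a small-integer label image as-is."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        out = np.where(mask, 255, 0).astype(np.uint8)
    elif np.issubdtype(mask.dtype, np.integer):
        vmax = int(mask.max(initial=0))
        if vmax <= 255:
            out = mask.astype(np.uint8)
        elif vmax <= 65535:
            out = mask.astype(np.uint16)
        else:
            raise ValueError(f"label image exceeds 16-bit range (max {vmax})")
    else:
        raise ValueError(f"mask must be boolean or integer, got dtype {mask.dtype}")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_mask(path: str | Path) -> np.ndarray:
    arr = _read_image(Path(path))
    return _to_grayscale(arr)


def write_table(table: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write rectangular records to CSV (UTF-8, header row, no index column)."""
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(list(table))
    df.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_truth(obj: Any, path: str | Path) -> None:
    """Serialize ground-truth / report structures to JSON (numpy-aware)."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(obj, fh, cls=_NumpyEncoder, indent=1)


def read_truth(path: str | Path) -> Any:
    with open(Path(path), encoding="utf-8") as fh:
        return json.load(fh)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    out = yaml.safe_load(text)
    if not isinstance(out, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return out
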