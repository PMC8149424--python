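"""Intensity-based layer segmentation of OCT B-scans.

Because OCT intensity tracks refractive-index contrast and falls off with
depth, the internal enamel layers separate naturally in intensity. The
pipeline: 5x5 median filtering, multilevel Otsu thresholding, quantization of
every pixel into an intensity class, colorization with a fixed palette, then
— independently per class — LoG filtering of the class-masked intensities,
Sobel edge detection with a per-class threshold, connected-component tracing
and morphological closing. The closed per-class structures are composited
over the grayscale source as the final overlay. A global Otsu pass on the
median-filtered image marks background so that the lowest class outside the
foreground reads as air, not tissue.

Also here: en-face slice extraction at a fixed physical depth below the
per-column detected surface, the plane on which enamel is quantified.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from . import connectivity as conn
from .io_formats import BScan, Volume

__all__ = [
    "SegmentationParams",
    "ChannelStructures",
    "LayerSegmentation",
    "median5",
    "multi_otsu",
    "quantize_colorize",
    "per_channel_structures",
    "compose_overlay",
    "segment",
    "extract_enface",
    "DEFAULT_PALETTE",
]

#: lowest -> highest intensity class (blue, green, red, magenta)
DEFAULT_PALETTE = ((0, 0, 255), (0, 255, 0), (255, 0, 0), (255, 0, 255))


@dataclasses.dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the intensity-based layer-segmentation pipeline."""

    median_size: int = 5
    n_thresholds: int = 3
    channel_sobel_thresholds: tuple[float, ...] | float = 0.1
    log_size: int = 5
    log_sigma: float = 0.5
    connectivity: int = 8
    min_component_px: int = 20
    se_erode_radius: int = 1
    se_dilate_radius: int = 1
    se_close_radius: int = 1
    class_palette: tuple[tuple[int, int, int], ...] = DEFAULT_PALETTE
    overlay_alpha: float = 0.7

    def __post_init__(self) -> None:
        if self.n_thresholds < 1:
            raise ValueError("n_thresholds must be >= 1")
        if len(self.class_palette) != self.n_thresholds + 1:
            raise ValueError(
                f"palette must list {self.n_thresholds + 1} colors, "
                f"got {len(self.class_palette)}"
            )

    def sobel_threshold_for(self, class_index: int) -> float:
        t = self.channel_sobel_thresholds
        if np.isscalar(t):
            return float(t)
        return float(t[class_index])


@dataclasses.dataclass
class ChannelStructures:
    """Per-class (per color channel) structural outputs."""

    class_index: int
    edge_mask: np.ndarray
    pre_close_mask: np.ndarray
    closed_mask: np.ndarray
    component_table: pd.DataFrame


@dataclasses.dataclass
class LayerSegmentation:
    """Full output of the layer-segmentation pipeline on one B-scan."""

    class_map: np.ndarray
    otsu_thresholds: np.ndarray
    foreground_mask: np.ndarray
    foreground_threshold: float
    quantized_rgb: np.ndarray
    channels: list[ChannelStructures]
    composite: np.ndarray


def median5(image: np.ndarray | BScan, size: int = 5) -> np.ndarray:
    """Median filter with a size x size neighborhood (symmetric padding)."""
    pixels = image.pixels if isinstance(image, BScan) else np.asarray(image, dtype=float)
    if min(pixels.shape) < size:
        raise ValueError(f"image shape {pixels.shape} smaller than kernel {size}")
    return ndimage.median_filter(pixels, size=size, mode="reflect")


def multi_otsu(image: np.ndarray, n_thresholds: int = 3, nbins: int = 256) -> np.ndarray:
    """Multilevel Otsu thresholds maximizing between-class histogram variance.

    Thresholds are reported as the *upper edge* of each threshold bin, so a
    pixel belongs to class i exactly when ``t_{i-1} < value <= t_i``. (The
    histogram search assigns the threshold bin itself to the lower class;
    reporting bin centers instead would misclassify values in that bin.)
    """
    image = np.asarray(image)
    n_distinct = np.unique(image).size
    if n_distinct < n_thresholds + 1:
        raise ValueError(
            f"multilevel Otsu with {n_thresholds} thresholds needs at least "
            f"{n_thresholds + 1} distinct values; image has {n_distinct}"
        )
    centers = threshold_multiotsu(image, classes=n_thresholds + 1, nbins=nbins)
    half_bin = (image.max() - image.min()) / (2.0 * nbins)
    return np.asarray(centers, dtype=float) + half_bin


def quantize_colorize(
    image: np.ndarray,
    thresholds: np.ndarray,
    palette: tuple[tuple[int, int, int], ...] = DEFAULT_PALETTE,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin every pixel by the thresholds and paint classes with the palette.

    Class i collects pixels in (t_{i-1}, t_i] with t_0 = -inf, t_last = +inf;
    so ``class = number of thresholds strictly below the pixel``.
    """
    image = np.asarray(image)
    thresholds = np.asarray(thresholds, dtype=float)
    if len(palette) != thresholds.size + 1:
        raise ValueError(
            f"palette has {len(palette)} colors for {thresholds.size + 1} classes"
        )
    class_map = np.searchsorted(thresholds, image, side="left").astype(np.int16)
    rgb = np.asarray(palette, dtype=np.uint8)[class_map]
    return class_map, rgb


def per_channel_structures(
    image: np.ndarray | BScan,
    class_map: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    classes: list[int] | None = None,
) -> list[ChannelStructures]:
    """Run the structural pipeline independently inside each intensity class.

    For each class the class-masked grayscale intensities (zeros elsewhere)
    are LoG-filtered and binarized, components are traced and opened, Sobel
    edges extracted with that class's threshold, and the mask closed —
    exactly the connectivity-module operations, restricted to one class.
    Class 0 (the sub-threshold/background class) is skipped unless requested.
    """
    pixels = image.pixels if isinstance(image, BScan) else np.asarray(image, dtype=float)
    class_map = np.asarray(class_map)
    if classes is None:
        classes = [c for c in range(int(class_map.max()) + 1) if c > 0]
    out = []
    for c in classes:
        mask = class_map == c
        if not mask.any():
            out.append(
                ChannelStructures(
                    class_index=c,
                    edge_mask=np.zeros_like(mask),
                    pre_close_mask=np.zeros_like(mask),
                    closed_mask=np.zeros_like(mask),
                    component_table=pd.DataFrame(
                        columns=["label", "px", "row_start", "row_end", "col_start", "col_end"]
                    ),
                )
            )
            continue
        masked = np.where(mask, pixels, 0.0)
        filtered = conn.log_filter(masked, params.log_size, params.log_sigma)
        binary, _ = conn.binarize(filtered)
        labels, table = conn.trace_components(
            binary, params.connectivity, params.min_component_px
        )
        opened = conn.open_then_visualize(
            labels, params.se_erode_radius, params.se_dilate_radius
        )
        edge_mask, *_ = conn.sobel_overlay(masked, opened, params.sobel_threshold_for(c))
        closed, _, _ = conn.close_and_account(masked, opened, params.se_close_radius)
        out.append(
            ChannelStructures(
                class_index=c,
                edge_mask=edge_mask,
                pre_close_mask=opened,
                closed_mask=closed,
                component_table=table,
            )
        )
    return out


def compose_overlay(
    bscan: BScan | np.ndarray,
    channels: list[ChannelStructures],
    palette: tuple[tuple[int, int, int], ...] = DEFAULT_PALETTE,
    alpha: float = 0.7,
) -> np.ndarray:
    """Composite the closed per-class structures over the grayscale source.

    Classes are drawn lowest first so a higher class wins where masks overlap;
    the source stays visible where no class is drawn (and through 1 - alpha).
    """
    pixels = bscan.pixels if isinstance(bscan, BScan) else np.asarray(bscan, dtype=float)
    base = conn._to_rgb(pixels).astype(float)
    out = base.copy()
    for ch in sorted(channels, key=lambda c: c.class_index):
        color = np.asarray(palette[ch.class_index], dtype=float)
        m = ch.closed_mask
        out[m] = (1 - alpha) * base[m] + alpha * color
    return out.astype(np.uint8)


def segment(
    bscan: BScan | np.ndarray, params: SegmentationParams = SegmentationParams()
) -> LayerSegmentation:
    """Run the full layer-segmentation pipeline on one B-scan."""
    pixels = bscan.pixels if isinstance(bscan, BScan) else np.asarray(bscan, dtype=float)
    smoothed = median5(pixels, params.median_size)
    thresholds = multi_otsu(smoothed, params.n_thresholds)
    class_map, rgb = quantize_colorize(smoothed, thresholds, params.class_palette)
    # global Otsu pass: mark air/background so class 0 outside it reads as tissue
    fg_threshold = float(threshold_otsu(smoothed))
    foreground = smoothed > fg_threshold
    channels = per_channel_structures(pixels, class_map, params)
    composite = compose_overlay(pixels, channels, params.class_palette, params.overlay_alpha)
    return LayerSegmentation(
        class_map=class_map,
        otsu_thresholds=thresholds,
        foreground_mask=foreground,
        foreground_threshold=fg_threshold,
        quantized_rgb=rgb,
        channels=channels,
        composite=composite,
    )


def extract_enface(
    volume: Volume,
    depth_um: float,
    surface_rows: np.ndarray,
    fill_value: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the volume on a surface-following plane ``depth_um`` deep.

    ``surface_rows`` has shape (n_slices, n_columns) with the per-column
    detected surface row of every B-scan (sentinel < 0 where no surface was
    found). Output pixel (slice, column) is the intensity at row
    ``surface_row + round(depth_um / axial_pitch)``. Columns with no surface,
    or whose target row falls below the acquisition, are set to ``fill_value``
    and flagged; if more than half of all columns are out of range the depth
    is considered beyond acquisition and an error is raised.

    Returns (enface_image, valid_mask).
    """
    if depth_um < 0:
        raise ValueError("depth_um must be >= 0")
    arr = volume.as_array()
    n_slices, n_rows, n_cols = arr.shape
    surface_rows = np.asarray(surface_rows)
    if surface_rows.shape != (n_slices, n_cols):
        raise ValueError(
            f"surface_rows shape {surface_rows.shape} != (slices, columns) "
            f"{(n_slices, n_cols)}"
        )
    offset = int(round(depth_um / volume.bscans[0].axial_pitch))
    target = surface_rows + offset
    valid = (surface_rows >= 0) & (target < n_rows)
    if valid.sum() < 0.5 * valid.size:
        raise ValueError(
            f"depth {depth_um} um is beyond acquisition for "
            f"{valid.size - valid.sum()} of {valid.size} columns"
        )
    out = np.full((n_slices, n_cols), fill_value, dtype=float)
    sl, col = np.nonzero(valid)
    out[sl, col] = arr[sl, target[sl, col], col]
    return out, valid
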