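"""Structural-connectivity analysis of enamel in OCT B-scans.

Pipeline: rotationally symmetric Laplacian-of-Gaussian (LoG) filtering of the
grayscale B-scan, Otsu binarization of the rescaled filter magnitude,
connected-component tracing (8-connectivity), morphological opening (erosion
then dilation) to discard unconnected specks, Sobel edge overlays for
visualization, and morphological closing to recover the enamel in continuity.
The total enamel is accounted as the sum of source intensities (and the pixel
count) over the closed mask. Closing-induced growth just above the locally
detected surface marks candidate abrasion sites: a dent worn into the surface
is a concavity the closing fills from its intact shoulders, so filled pixels
appear above the dent floor where an intact tooth never has any.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import sobel, threshold_otsu

from .io_formats import BScan

__all__ = [
    "ConnectivityParams",
    "ConnectivityResult",
    "AbrasionSite",
    "log_kernel",
    "otsu_threshold",
    "log_filter",
    "binarize",
    "trace_components",
    "open_then_visualize",
    "sobel_overlay",
    "close_and_account",
    "detect_abrasion",
    "run_pipeline",
]

EDGE_COLOR = (255, 0, 0)  # overlay edge color (red)


def _square(radius: int) -> np.ndarray:
    return np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)


_SE3 = np.ones((3, 3), dtype=bool)


def _erode_square(mask: np.ndarray, radius: int) -> np.ndarray:
    # radius-r square SE == r iterations of the 3x3 SE (Minkowski decomposition)
    return ndimage.binary_erosion(mask, structure=_SE3, iterations=radius)


def _dilate_square(mask: np.ndarray, radius: int) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=_SE3, iterations=radius)


@dataclasses.dataclass(frozen=True)
class ConnectivityParams:
    """Tunable parameters of the structural-connectivity pipeline.

    All values are explicit so runs are reproducible from a config file.
    ``se_close_radius`` is deliberately larger than the opening radius: the
    closing must bridge speckle voids and surface dents on the scale of a
    visible abrasion, while the opening only needs to kill isolated specks.
    """

    log_size: int = 5
    log_sigma: float = 0.5
    connectivity: int = 8
    se_erode_radius: int = 1
    se_dilate_radius: int = 1
    se_close_radius: int = 20
    sobel_threshold: float = 0.1
    min_component_px: int = 20
    surface_band_px: int = 15
    gap_tolerance_px: int = 5
    min_protrusion_px: int = 3
    min_site_px: int = 35

    def __post_init__(self) -> None:
        if self.log_size < 3 or self.log_size % 2 == 0:
            raise ValueError("log_size must be odd and >= 3")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not (0 < self.sobel_threshold <= 1):
            raise ValueError("sobel_threshold must lie in (0, 1]")
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be positive")


@dataclasses.dataclass(frozen=True)
class AbrasionSite:
    """Lateral run of closing-growth columns near the surface."""

    x_start: int
    x_end: int  # half-open
    area_px: int


@dataclasses.dataclass
class ConnectivityResult:
    """All intermediate and final artifacts of the connectivity pipeline."""

    binary_mask: np.ndarray
    binarize_threshold: float
    component_labels: np.ndarray
    component_table: pd.DataFrame
    opened_mask: np.ndarray
    edge_mask: np.ndarray
    closed_mask: np.ndarray
    overlay_gray: np.ndarray
    overlay_binary: np.ndarray
    overlay_final: np.ndarray
    total_enamel_intensity: float
    total_enamel_px: int
    abrasion_sites: list[AbrasionSite]


def log_kernel(size: int = 5, sigma: float = 0.5) -> np.ndarray:
    """Rotationally symmetric Laplacian-of-Gaussian kernel, normalized to sum 0.

    Same construction as the classic image-processing ``log`` special filter:
    sample the analytic LoG on a centered grid, then subtract the mean so the
    response to a constant image is exactly zero.
    """
    if size < 3 or size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 3")
    half = size // 2
    y, x = np.mgrid[-half: half + 1, -half: half + 1].astype(float)
    s2 = sigma * sigma
    r2 = x * x + y * y
    g = np.exp(-r2 / (2 * s2))
    g /= g.sum()
    k = g * (r2 - 2 * s2) / (s2 * s2)
    return k - k.mean()


def log_filter(
    image: np.ndarray | BScan, size: int = 5, sigma: float = 0.5
) -> np.ndarray:
    """Convolve with the LoG kernel (symmetric border padding); output is signed."""
    pixels = image.pixels if isinstance(image, BScan) else np.asarray(image, dtype=float)
    if min(pixels.shape) < size:
        raise ValueError(f"kernel size {size} exceeds image shape {pixels.shape}")
    kernel = log_kernel(size, sigma)
    # correlation with a symmetric kernel == convolution
    return ndimage.correlate(pixels.astype(float), kernel, mode="reflect")


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Global Otsu threshold reported as the threshold bin's *upper edge*.

    The histogram search assigns the threshold bin itself to the lower class;
    the upper-edge convention makes ``value > threshold`` reproduce exactly
    that partition (a bin-center threshold would misassign values inside the
    threshold bin).
    """
    values = np.asarray(values, dtype=float)
    center = float(threshold_otsu(values, nbins=nbins))
    return center + (values.max() - values.min()) / (2.0 * nbins)


def binarize(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Global-Otsu binarization of the rescaled magnitude of an image.

    The absolute value is min-max rescaled to [0, 1] before thresholding so
    signed filter output and raw intensities are handled uniformly. A constant
    image yields an empty foreground with a warning.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    mag = np.abs(image)
    lo, hi = mag.min(), mag.max()
    if hi == lo:
        warnings.warn("constant image: empty foreground", stacklevel=2)
        return np.zeros(image.shape, dtype=bool), float("nan")
    scaled = (mag - lo) / (hi - lo)
    t = otsu_threshold(scaled)
    return scaled > t, t


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def trace_components(
    mask: np.ndarray, connectivity: int = 8, min_component_px: int = 20
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label connected components, drop small ones, order labels by size.

    Returns the relabeled image (labels 1..K by decreasing pixel count) and a
    table with one row per kept component: label, px, bbox (row/col, half-open)
    and the component's summed mask value.
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0:
        return labels, pd.DataFrame(
            columns=["label", "px", "row_start", "row_end", "col_start", "col_end"]
        )
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.where(sizes >= min_component_px)[0] + 1
    order = keep[np.argsort(sizes[keep - 1], kind="stable")[::-1]]
    relabel = np.zeros(n + 1, dtype=labels.dtype)
    relabel[order] = np.arange(1, len(order) + 1)
    out = relabel[labels]
    slices = ndimage.find_objects(labels)
    rows = []
    for new, old in enumerate(order, start=1):
        sl = slices[old - 1]
        rows.append(
            {
                "label": new,
                "px": int(sizes[old - 1]),
                "row_start": sl[0].start,
                "row_end": sl[0].stop,
                "col_start": sl[1].start,
                "col_end": sl[1].stop,
            }
        )
    return out, pd.DataFrame(rows)


def open_then_visualize(
    labels_or_mask: np.ndarray,
    se_erode_radius: int = 1,
    se_dilate_radius: int = 1,
) -> np.ndarray:
    """Erode then dilate the foreground (an opening when the SEs match)."""
    mask = np.asarray(labels_or_mask) > 0
    return _dilate_square(_erode_square(mask, se_erode_radius), se_dilate_radius)


def _to_rgb(gray: np.ndarray) -> np.ndarray:
    g = np.asarray(gray, dtype=float)
    lo, hi = g.min(), g.max()
    scaled = np.zeros_like(g) if hi == lo else (g - lo) / (hi - lo)
    u8 = (scaled * 255).astype(np.uint8)
    return np.stack([u8] * 3, axis=-1)


def _paint(rgb: np.ndarray, mask: np.ndarray, color: tuple[int, int, int]) -> np.ndarray:
    out = rgb.copy()
    out[mask] = color
    return out


def sobel_overlay(
    bscan: BScan | np.ndarray,
    mask: np.ndarray,
    sobel_threshold: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sobel edge mask plus the three overlay renderings.

    Edge pixels are those whose Sobel gradient magnitude reaches
    ``sobel_threshold`` times the image's maximum gradient. Overlays: edges on
    the grayscale source, edges on the binary mask, and edges on the processed
    (masked) image — all RGB with edges painted in a fixed color.
    """
    pixels = bscan.pixels if isinstance(bscan, BScan) else np.asarray(bscan, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != pixels.shape:
        raise ValueError("image and mask shapes differ")
    grad = sobel(pixels.astype(float))
    gmax = grad.max()
    edge_mask = np.zeros(pixels.shape, dtype=bool) if gmax == 0 else grad >= sobel_threshold * gmax
    overlay_gray = _paint(_to_rgb(pixels), edge_mask, EDGE_COLOR)
    overlay_binary = _paint(_to_rgb(mask.astype(float)), edge_mask, EDGE_COLOR)
    overlay_final = _paint(_to_rgb(np.where(mask, pixels, 0.0)), edge_mask, EDGE_COLOR)
    return edge_mask, overlay_gray, overlay_binary, overlay_final


def close_and_account(
    bscan: BScan | np.ndarray,
    opened_mask: np.ndarray,
    se_close_radius: int = 20,
) -> tuple[np.ndarray, float, int]:
    """Morphologically close the mask and account the enamel under it.

    Returns the closed mask, the sum of source intensities over it (the total
    enamel in continuity), and its pixel count.
    """
    pixels = bscan.pixels if isinstance(bscan, BScan) else np.asarray(bscan, dtype=float)
    mask = np.asarray(opened_mask).astype(bool)
    # pad so closing is extensive at the image border too
    r = se_close_radius
    padded = np.pad(mask, r, mode="constant")
    closed = _erode_square(_dilate_square(padded, r), r)[r:-r, r:-r]
    closed |= mask
    total_intensity = float(pixels[closed].sum())
    return closed, total_intensity, int(closed.sum())


def detect_abrasion(
    closed_mask: np.ndarray,
    pre_close_mask: np.ndarray,
    surface_row_per_column: np.ndarray,
    surface_band_px: int = 15,
    gap_tolerance_px: int = 5,
    min_site_px: int = 35,
    min_protrusion_px: int = 3,
) -> list[AbrasionSite]:
    """Abrasion sites = closing growth confined to a band below the surface.

    An abraded dent lowers the locally detected surface, and the closing
    bridges the dent from its intact shoulders, so the fill lands in the rows
    *above* the local surface — rows where nothing is ever detected on an
    intact tooth. Protrusion pixels are therefore ``closed_mask &
    ~pre_close_mask`` restricted to rows ``[surface_row - surface_band_px,
    surface_row)`` per column. A column counts as protruding only when it
    holds at least ``min_protrusion_px`` such pixels (the closing always nips
    slightly into the ragged speckled surface). Contiguous lateral runs of
    protruding columns (gaps up to ``gap_tolerance_px`` bridged) become
    sites, sorted by area descending.
    """
    closed = np.asarray(closed_mask).astype(bool)
    pre = np.asarray(pre_close_mask).astype(bool)
    surface = np.asarray(surface_row_per_column)
    rows, cols = closed.shape
    z = np.arange(rows)[:, None]
    valid = surface[None, :] >= 0
    band = valid & (z >= surface[None, :] - surface_band_px) & (z < surface[None, :])
    protrusion = closed & ~pre & band
    col_area = protrusion.sum(axis=0)
    col_area[col_area < min_protrusion_px] = 0
    sites: list[AbrasionSite] = []
    run_start: int | None = None
    last = -1
    for c in range(cols):
        if col_area[c] > 0:
            if run_start is not None and c - last > gap_tolerance_px + 1:
                area = int(col_area[run_start: last + 1].sum())
                if area >= min_site_px:
                    sites.append(AbrasionSite(run_start, last + 1, area))
                run_start = None
            if run_start is None:
                run_start = c
            last = c
    if run_start is not None:
        area = int(col_area[run_start: last + 1].sum())
        if area >= min_site_px:
            sites.append(AbrasionSite(run_start, last + 1, area))
    sites.sort(key=lambda s: (-s.area_px, s.x_start))
    return sites


def run_pipeline(
    bscan: BScan | np.ndarray,
    params: ConnectivityParams = ConnectivityParams(),
    surface_row_per_column: np.ndarray | None = None,
) -> ConnectivityResult:
    """Run the full structural-connectivity pipeline on one B-scan.

    When per-column surface rows (from depth-profile surface detection) are
    supplied, closing growth near the surface is reported as abrasion sites;
    otherwise the site list is empty.
    """
    pixels = bscan.pixels if isinstance(bscan, BScan) else np.asarray(bscan, dtype=float)
    filtered = log_filter(pixels, params.log_size, params.log_sigma)
    binary, threshold = binarize(filtered)
    labels, table = trace_components(binary, params.connectivity, params.min_component_px)
    opened = open_then_visualize(labels, params.se_erode_radius, params.se_dilate_radius)
    edge_mask, overlay_gray, overlay_binary, overlay_final = sobel_overlay(
        pixels, opened, params.sobel_threshold
    )
    closed, total_intensity, total_px = close_and_account(
        pixels, opened, params.se_close_radius
    )
    sites: list[AbrasionSite] = []
    if surface_row_per_column is not None:
        sites = detect_abrasion(
            closed,
            opened,
            surface_row_per_column,
            params.surface_band_px,
            params.gap_tolerance_px,
            min_site_px=params.min_site_px,
            min_protrusion_px=params.min_protrusion_px,
        )
    return ConnectivityResult(
        binary_mask=binary,
        binarize_threshold=threshold,
        component_labels=labels,
        component_table=table,
        opened_mask=opened,
        edge_mask=edge_mask,
        closed_mask=closed,
        overlay_gray=overlay_gray,
        overlay_binary=overlay_binary,
        overlay_final=overlay_final,
        total_enamel_intensity=total_intensity,
        total_enamel_px=total_px,
        abrasion_sites=sites,
    )
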