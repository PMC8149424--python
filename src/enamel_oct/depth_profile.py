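"""Windowed depth-intensity profile analysis of OCT B-scans.

Within a rectangular region of interest, A-scans are grouped into lateral
windows (default 10 A-scans per window). In each window every A-scan's
intensity peaks are detected, each A-scan is shifted up so its first peak —
the specular tooth surface — sits at flattened index 0, the flattened A-scans
are averaged, and the average is max-normalized. On the normalized profile the
surface appears at index 0 and the dentinoenamel junction (DEJ) as the
strongest remaining peak; their separation times the axial pixel pitch is the
enamel thickness.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import find_peaks

from .io_formats import BScan, Roi

__all__ = [
    "PeakParams",
    "DepthProfile",
    "ThicknessResult",
    "detect_ascan_peaks",
    "first_peak",
    "detect_surface",
    "flatten_window",
    "average_profile",
    "measure_enamel_thickness",
    "analyze_roi",
]

NO_PEAK = -1  # shift-vector sentinel for A-scans with no detected peak


@dataclasses.dataclass(frozen=True)
class PeakParams:
    """Peak-detection thresholds for A-scans and averaged profiles.

    min_height is a fraction of the A-scan maximum (or an absolute level when
    ``height_is_absolute``); min_separation is the minimum peak spacing in
    pixels; the first (surface) peak must additionally clear
    ``median + noise_floor_k * MAD`` of the A-scan.
    """

    min_height: float = 0.2
    min_separation: int = 5
    noise_floor_k: float = 3.0
    height_is_absolute: bool = False

    def __post_init__(self) -> None:
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")
        if not self.height_is_absolute and not (0 < self.min_height <= 1):
            raise ValueError("fractional min_height must lie in (0, 1]")


@dataclasses.dataclass
class DepthProfile:
    """Flattened, averaged, max-normalized intensity-vs-depth curve."""

    values: np.ndarray
    window_size: int
    n_ascans_used: int
    peak_indices: np.ndarray
    axial_pitch: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak_indices must be strictly increasing")


@dataclasses.dataclass
class ThicknessResult:
    """Enamel thickness read off one window's averaged profile."""

    thickness_um: float | None
    surface_index: int | None
    dej_index: int | None
    dej_found: bool
    profile: DepthProfile


def detect_ascan_peaks(ascan: np.ndarray, params: PeakParams = PeakParams()) -> np.ndarray:
    """Local maxima of one A-scan satisfying height and separation thresholds.

    Returned sorted shallow-to-deep. Endpoints count as peaks when they
    strictly exceed their single neighbour (the flattened surface sits at
    index 0, so index-0 peaks must be detectable). An all-constant A-scan has
    no peaks.
    """
    ascan = np.asarray(ascan, dtype=float)
    if ascan.ndim != 1 or ascan.size < 3:
        raise ValueError("A-scan must be 1D with length >= 3")
    vmax = ascan.max()
    if vmax <= 0 or np.ptp(ascan) == 0:
        return np.empty(0, dtype=int)
    height = params.min_height if params.height_is_absolute else params.min_height * vmax
    # pad with -inf so endpoint maxima are admitted under the same rules
    padded = np.concatenate(([-np.inf], ascan, [-np.inf]))
    idx, _ = find_peaks(padded, height=height, distance=params.min_separation)
    return np.asarray(idx, dtype=int) - 1


def first_peak(ascan: np.ndarray, params: PeakParams = PeakParams()) -> int:
    """Shallowest detected peak clearing the robust noise floor, or NO_PEAK.

    The noise floor is ``median + noise_floor_k * MAD`` of the whole A-scan;
    this is what anchors surface flattening.
    """
    ascan = np.asarray(ascan, dtype=float)
    peaks = detect_ascan_peaks(ascan, params)
    if peaks.size == 0:
        return NO_PEAK
    med = np.median(ascan)
    mad = np.median(np.abs(ascan - med))
    floor = med + params.noise_floor_k * mad
    for p in peaks:
        if ascan[p] > floor:
            return int(p)
    return NO_PEAK


def detect_surface(bscan: BScan, params: PeakParams = PeakParams()) -> np.ndarray:
    """Per-column surface row (first peak of each A-scan); NO_PEAK where absent."""
    return np.asarray(
        [first_peak(bscan.pixels[:, c], params) for c in range(bscan.n_ascans)],
        dtype=int,
    )


def flatten_window(
    bscan: BScan,
    roi: Roi,
    window_size: int = 10,
    params: PeakParams = PeakParams(),
    x_offset: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Surface-flatten one lateral window of A-scans inside an ROI.

    Each A-scan (column) is shifted up so its first peak lands at flattened
    index 0; samples above the peak are discarded and the tail is zero-padded.
    A-scans with no detectable peak keep the sentinel shift ``NO_PEAK`` and
    are excluded from averaging downstream.

    Returns
    -------
    flattened : ndarray, shape (roi.depth, n_window_cols)
    shifts : ndarray of per-column shifts (NO_PEAK where no peak was found)
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    roi.validate_for(bscan.shape)
    if roi.width < window_size:
        raise ValueError(f"ROI width {roi.width} smaller than window_size {window_size}")
    zsl, xsl = roi.slices()
    x0 = roi.x_start + x_offset
    x1 = min(x0 + window_size, roi.x_end)
    sub = bscan.pixels[zsl, x0:x1].astype(float)
    depth, ncols = sub.shape
    flattened = np.zeros_like(sub)
    shifts = np.full(ncols, NO_PEAK, dtype=int)
    for c in range(ncols):
        p = first_peak(sub[:, c], params)
        if p == NO_PEAK:
            continue
        shifts[c] = p
        flattened[: depth - p, c] = sub[p:, c]
    return flattened, shifts


def average_profile(
    flattened: np.ndarray,
    shifts: np.ndarray,
    params: PeakParams = PeakParams(),
    axial_pitch: float = 5.0,
) -> DepthProfile:
    """Average the used (peak-bearing) flattened A-scans and max-normalize.

    Peaks are re-detected on the averaged curve with the same parameters.
    Raises when no A-scan in the window carried a detectable peak.
    """
    shifts = np.asarray(shifts)
    used = shifts != NO_PEAK
    n_used = int(used.sum())
    if n_used == 0:
        raise ValueError("no A-scan in this window has a detectable peak (no signal)")
    mean = flattened[:, used].mean(axis=1)
    vmax = mean.max()
    values = mean / vmax if vmax > 0 else mean
    peaks = detect_ascan_peaks(values, params)
    return DepthProfile(
        values=values,
        window_size=flattened.shape[1],
        n_ascans_used=n_used,
        peak_indices=peaks,
        axial_pitch=axial_pitch,
    )


def measure_enamel_thickness(
    profile: DepthProfile, params: PeakParams = PeakParams()
) -> ThicknessResult:
    """Read enamel thickness off an averaged profile.

    The surface is the flattened index-0 peak; the DEJ is the
    highest-amplitude remaining peak deeper than ``min_separation`` (ties
    broken toward the shallower index). Thickness is the DEJ index times the
    axial pitch. When fewer than two usable peaks exist the DEJ is recorded
    as missing rather than raising, so batch runs can skip thin layers.
    """
    peaks = profile.peak_indices
    surface = 0 if (peaks.size and peaks[0] == 0) else None
    candidates = peaks[peaks >= params.min_separation]
    if surface is None or candidates.size == 0:
        return ThicknessResult(
            thickness_um=None,
            surface_index=surface,
            dej_index=None,
            dej_found=False,
            profile=profile,
        )
    heights = profile.values[candidates]
    # argmax returns the first (shallowest) index among exact ties
    dej = int(candidates[np.argmax(heights)])
    return ThicknessResult(
        thickness_um=float(dej * profile.axial_pitch),
        surface_index=0,
        dej_index=dej,
        dej_found=True,
        profile=profile,
    )


def analyze_roi(
    bscan: BScan,
    roi: Roi,
    window_size: int = 10,
    params: PeakParams = PeakParams(),
) -> list[ThicknessResult]:
    """Tile the ROI into lateral windows and measure each one.

    Windows tile left to right; a trailing partial window is kept when it is
    at least half full.
    """
    roi.validate_for(bscan.shape)
    results = []
    x = 0
    while x < roi.width:
        ncols = min(window_size, roi.width - x)
        if ncols < max(1, window_size // 2) and x > 0:
            break
        flattened, shifts = flatten_window(
            bscan, roi, window_size=min(window_size, roi.width), params=params, x_offset=x
        )
        if ncols < window_size:
            flattened = flattened[:, :ncols]
            shifts = shifts[:ncols]
        try:
            profile = average_profile(
                flattened, shifts, params=params, axial_pitch=bscan.axial_pitch
            )
        except ValueError:
            x += window_size
            continue
        results.append(measure_enamel_thickness(profile, params=params))
        x += window_size
    return results
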