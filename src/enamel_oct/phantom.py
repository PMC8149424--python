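"""Synthetic layered-tooth OCT phantoms with pixel-level ground truth.

The phantom emulates the appearance of a premolar imaged occlusally with a
swept-source OCT system: a bright specular air/enamel surface line, an enamel
band carrying multiplicative speckle, exponential depth attenuation and
lateral Hunter-Schreger-like banding, a secondary reflectivity peak at the
dentinoenamel junction (DEJ), and dimmer dentin below. Optional defects model
what orthodontic treatment does to the surface: abrasion notches (material
removed, surface locally lowered), highly reflective adhesive-remnant patches
that shadow everything beneath them, and thin dark micro-crack lines.

Intensity model for a column with surface row ``s`` and enamel thickness
``T`` (pixels), before noise::

    I(z) = R_surface          at z = s           (1-px specular line)
         = R_enamel * hs(x) * exp(-mu (z - s))   for s < z < s + T
         = R_dej    * exp(-mu T)                 at z = s + T
         = R_dentin * exp(-mu (z - s))           for z > s + T

``hs(x) = 1 + A sin(2 pi x / P)`` is the Hunter-Schreger modulation. The
clean image is blurred axially with a small Gaussian (the axial point-spread
function), then multiplied by unit-mean gamma speckle with shape ``k``
(coefficient of variation ``1/sqrt(k)``) and floored with additive Gaussian
noise, clipped at zero. Class labels: 0 background, 1 enamel, 2 DEJ,
3 dentin, 4 adhesive remnant.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io_formats import BScan, Volume

__all__ = [
    "SurfaceModel",
    "AbrasionNotch",
    "AdhesivePatch",
    "CrackLine",
    "PhantomSpec",
    "GroundTruth",
    "StageDelta",
    "generate_bscan",
    "generate_treatment_series",
    "generate_cohort",
    "generate_volume",
    "generate_enface_image",
    "generate_enface_truth",
    "CLASS_BACKGROUND",
    "CLASS_ENAMEL",
    "CLASS_DEJ",
    "CLASS_DENTIN",
    "CLASS_REMNANT",
]

CLASS_BACKGROUND = 0
CLASS_ENAMEL = 1
CLASS_DEJ = 2
CLASS_DENTIN = 3
CLASS_REMNANT = 4


@dataclasses.dataclass(frozen=True)
class SurfaceModel:
    """Per-column surface row: flat, tilted, or sinusoidal."""

    kind: Literal["flat", "tilted", "sine"] = "flat"
    base_row: float = 150.0
    slope: float = 0.0        # rows per column (tilted)
    amplitude: float = 0.0    # rows (sine)
    period: float = 500.0     # columns (sine)

    def rows(self, n_cols: int) -> np.ndarray:
        x = np.arange(n_cols)
        if self.kind == "flat":
            r = np.full(n_cols, self.base_row)
        elif self.kind == "tilted":
            r = self.base_row + self.slope * x
        elif self.kind == "sine":
            r = self.base_row + self.amplitude * np.sin(2 * np.pi * x / self.period)
        else:
            raise ValueError(f"unknown surface kind {self.kind!r}")
        return np.rint(r).astype(int)


@dataclasses.dataclass(frozen=True)
class AbrasionNotch:
    """Surface abrasion: material removed over a lateral extent."""

    x_center: int
    width: int
    depth_px: int


@dataclasses.dataclass(frozen=True)
class AdhesivePatch:
    """Highly reflective adhesive remnant sitting on the surface, shadowing below."""

    x_start: int
    x_end: int
    extra_reflectivity: float = 2.0
    shadow_factor: float = 0.5
    thickness_px: int = 5


@dataclasses.dataclass(frozen=True)
class CrackLine:
    """Thin dark micro-crack running down from the surface."""

    x: int
    tilt: float = 0.0          # columns per row of depth
    darkening_factor: float = 0.3
    length_px: int = 150


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic tooth B-scan.

    Reflectivities are relative linear-intensity levels. The specular surface
    is much brighter than any internal layer so that, after axial blurring,
    every noise-free A-scan attains its maximum exactly at the surface row.
    Defaults describe a ~1 mm enamel cap at 5 um/px axial sampling.
    """

    shape: tuple[int, int] = (1407, 2000)
    surface: SurfaceModel = SurfaceModel()
    enamel_thickness_px: float = 200.0
    thickness_taper_px: float = 0.0     # parabolic lateral thinning toward edges
    hs_band_waveform: Literal["sine", "square"] = "square"
    surface_reflectivity: float = 5.0
    enamel_reflectivity: float = 0.5
    dej_reflectivity: float = 5.0
    dentin_reflectivity: float = 0.25
    attenuation: float = 0.0025          # 1/px exponential fall-off coefficient
    hs_band_period: float = 120.0       # columns
    hs_band_amplitude: float = 0.15
    speckle_k: float | None = 16.0      # gamma shape; None disables speckle
    speckle_grain: tuple[int, int] = (2, 4)  # (axial, lateral) px per speckle cell
    noise_floor_sigma: float = 0.01
    axial_psf_sigma: float = 1.5        # px; 0 disables blur
    notches: tuple[AbrasionNotch, ...] = ()
    patches: tuple[AdhesivePatch, ...] = ()
    cracks: tuple[CrackLine, ...] = ()
    axial_pitch: float = 5.0            # um/px
    lateral_pitch: float = 2.5          # um/px
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 4 or cols < 2:
            raise ValueError(f"phantom shape too small: {self.shape}")
        surf = self.surface.rows(cols)
        if surf.min() < 0:
            raise ValueError("surface rises above the image top")
        if np.any(surf + self.enamel_thickness_px >= rows - 1):
            raise ValueError("surface_depth + enamel_thickness must stay inside the image")
        for name in ("enamel_thickness_px", "attenuation", "hs_band_amplitude",
                     "noise_floor_sigma", "axial_psf_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.speckle_k is not None and self.speckle_k <= 0:
            raise ValueError("speckle_k must be positive or None")
        if self.thickness_taper_px >= self.enamel_thickness_px:
            raise ValueError("thickness_taper_px must be smaller than the base thickness")
        for n in self.notches:
            if n.depth_px < 0 or n.width < 1:
                raise ValueError(f"invalid notch {n}")
            if n.depth_px >= self.enamel_thickness_px - self.thickness_taper_px:
                raise ValueError(f"notch {n} deeper than the enamel")

    def thickness_profile(self) -> np.ndarray:
        """Per-column enamel thickness in pixels (base minus lateral taper)."""
        cols = self.shape[1]
        u = (2 * np.arange(cols) - (cols - 1)) / max(cols - 1, 1)
        return self.enamel_thickness_px - self.thickness_taper_px * u * u

    def hs_modulation(self, x: np.ndarray) -> np.ndarray:
        """Hunter-Schreger lateral intensity modulation at columns ``x``."""
        phase = np.sin(2 * np.pi * np.asarray(x) / self.hs_band_period)
        if self.hs_band_waveform == "square":
            phase = np.sign(phase) + (phase == 0)
        return 1.0 + self.hs_band_amplitude * phase


@dataclasses.dataclass
class GroundTruth:
    """Pixel-level truth accompanying one phantom B-scan."""

    surface_row: np.ndarray      # (cols,) int
    dej_row: np.ndarray          # (cols,) int
    enamel_mask: np.ndarray      # bool image, strictly between surface and DEJ
    class_map: np.ndarray        # int image with CLASS_* labels
    defect_mask: np.ndarray      # bool image: notch-excavated + remnant + crack px
    defects: list = dataclasses.field(default_factory=list)

    @property
    def enamel_thickness_px(self) -> np.ndarray:
        """Per-column enamel thickness (DEJ row minus surface row)."""
        return self.dej_row - self.surface_row

    def to_dict(self) -> dict:
        return {
            "surface_row": self.surface_row.tolist(),
            "dej_row": self.dej_row.tolist(),
            "enamel_mask": self.enamel_mask.astype(np.uint8).tolist(),
            "class_map": self.class_map.tolist(),
            "defect_mask": self.defect_mask.astype(np.uint8).tolist(),
            "defects": [dataclasses.asdict(d) for d in self.defects],
        }


def _clean_image_and_truth(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    rows, cols = spec.shape
    surface = spec.surface.rows(cols).copy()
    thickness = spec.thickness_profile()

    defects: list = list(spec.notches) + list(spec.patches) + list(spec.cracks)

    # Abrasion: lower the surface, remove that much enamel (DEJ stays put).
    for notch in spec.notches:
        lo = max(0, notch.x_center - notch.width // 2)
        hi = min(cols, lo + notch.width)
        surface[lo:hi] += notch.depth_px
        thickness[lo:hi] -= notch.depth_px
    dej = surface + np.rint(thickness).astype(int)

    z = np.arange(rows)[:, None]
    x = np.arange(cols)[None, :]
    depth_below_surface = z - surface[None, :]

    hs = spec.hs_modulation(x)
    atten = np.exp(-spec.attenuation * np.maximum(depth_below_surface, 0))

    img = np.zeros((rows, cols))
    in_enamel = (z > surface[None, :]) & (z < dej[None, :])
    in_dentin = z > dej[None, :]
    img[in_enamel] = (spec.enamel_reflectivity * hs * atten)[in_enamel]
    img[in_dentin] = (spec.dentin_reflectivity * atten)[in_dentin]
    img[dej, np.arange(cols)] = spec.dej_reflectivity * np.exp(
        -spec.attenuation * thickness
    )
    img[surface, np.arange(cols)] = spec.surface_reflectivity

    class_map = np.full((rows, cols), CLASS_BACKGROUND, dtype=np.int16)
    class_map[in_enamel] = CLASS_ENAMEL
    class_map[in_dentin] = CLASS_DENTIN
    class_map[dej, np.arange(cols)] = CLASS_DEJ
    class_map[surface, np.arange(cols)] = CLASS_ENAMEL

    defect_mask = np.zeros((rows, cols), dtype=bool)
    for notch in spec.notches:
        lo = max(0, notch.x_center - notch.width // 2)
        hi = min(cols, lo + notch.width)
        orig = spec.surface.rows(cols)
        for c in range(lo, hi):
            defect_mask[orig[c]: surface[c], c] = True

    # Adhesive remnant: bright band on top of the surface, shadow below it.
    shadow = np.ones(cols)
    for patch in spec.patches:
        lo, hi = max(0, patch.x_start), min(cols, patch.x_end)
        for c in range(lo, hi):
            top = max(0, surface[c] - patch.thickness_px)
            img[top: surface[c] + 1, c] += patch.extra_reflectivity
            class_map[top: surface[c], c] = CLASS_REMNANT
            defect_mask[top: surface[c] + 1, c] = True
            img[surface[c] + 1:, c] *= patch.shadow_factor
        shadow[lo:hi] *= patch.shadow_factor

    for crack in spec.cracks:
        for dz in range(crack.length_px):
            c = int(round(crack.x + crack.tilt * dz))
            if 0 <= c < cols:
                r = surface[c] + 1 + dz
                if r < rows:
                    img[r, c] *= crack.darkening_factor
                    defect_mask[r, c] = True

    truth = GroundTruth(
        surface_row=surface,
        dej_row=dej,
        enamel_mask=in_enamel,
        class_map=class_map,
        defect_mask=defect_mask,
        defects=defects,
    )
    return img, truth


def _speckle_field(
    rng: np.random.Generator, shape: tuple[int, int], k: float, grain: tuple[int, int]
) -> np.ndarray:
    """Unit-mean gamma speckle with one draw per grain, nearest-upsampled.

    Nearest upsampling keeps the exact gamma marginal (CV = 1/sqrt(k)) while
    giving speckle its characteristic blob size (~one resolution cell).
    """
    gz, gx = grain
    coarse = rng.gamma(
        shape=k, scale=1.0 / k, size=(-(-shape[0] // gz), -(-shape[1] // gx))
    )
    return np.repeat(np.repeat(coarse, gz, axis=0), gx, axis=1)[: shape[0], : shape[1]]


def generate_bscan(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[BScan, GroundTruth]:
    """Render one phantom B-scan and its ground truth.

    Deterministic for a fixed ``spec.seed`` (or a caller-supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    img, truth = _clean_image_and_truth(spec)
    if spec.axial_psf_sigma > 0:
        img = gaussian_filter1d(img, spec.axial_psf_sigma, axis=0, mode="constant")
    if spec.speckle_k is not None and np.isfinite(spec.speckle_k):
        img = img * _speckle_field(rng, img.shape, spec.speckle_k, spec.speckle_grain)
    if spec.noise_floor_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_floor_sigma, size=img.shape)
    img = np.clip(img, 0.0, None)
    bscan = BScan(
        pixels=img,
        axial_pitch=spec.axial_pitch,
        lateral_pitch=spec.lateral_pitch,
        id=f"phantom-seed{spec.seed}",
    )
    return bscan, truth


@dataclasses.dataclass(frozen=True)
class StageDelta:
    """What one treatment stage does to the phantom, relative to baseline.

    ``thickness_reduction_px`` models cumulative enamel wear; ``notches`` add
    stage-specific abrasion sites; ``bonding_layer`` adds a thin bright
    adhesive band covering the whole surface (the pumice/etch/bonding stage).
    """

    thickness_reduction_px: float = 0.0
    notches: tuple[AbrasionNotch, ...] = ()
    patches: tuple[AdhesivePatch, ...] = ()
    bonding_layer: AdhesivePatch | None = None

    def __post_init__(self) -> None:
        if self.thickness_reduction_px < 0:
            raise ValueError("stage thickness reductions must be non-negative")


#: Treatment-stage labels, baseline through second debonding.
STAGE_LABELS = (
    "Baseline (Control)",
    "After Pumice, Etch, & Bonding Agent",
    "After First Debonding",
    "After Second Debonding",
)


def generate_treatment_series(
    base_spec: PhantomSpec,
    stage_deltas: list[StageDelta],
    seed: int | None = None,
) -> list[tuple[BScan, GroundTruth]]:
    """Render one phantom per treatment stage with progressive enamel loss.

    Each delta is applied to the *baseline* spec: stage i has enamel thickness
    ``base - delta_i``. Reductions are taken from the top (the surface drops),
    so truth DEJ depth is unchanged while truth thickness shrinks.
    """
    out = []
    for i, delta in enumerate(stage_deltas):
        new_thickness = base_spec.enamel_thickness_px - delta.thickness_reduction_px
        if new_thickness <= 0:
            raise ValueError(
                f"stage {i} delta {delta.thickness_reduction_px} exceeds base "
                f"thickness {base_spec.enamel_thickness_px}"
            )
        surface = dataclasses.replace(
            base_spec.surface,
            base_row=base_spec.surface.base_row + delta.thickness_reduction_px,
        )
        patches = base_spec.patches + delta.patches
        if delta.bonding_layer is not None:
            patches = patches + (delta.bonding_layer,)
        spec = dataclasses.replace(
            base_spec,
            surface=surface,
            enamel_thickness_px=new_thickness,
            notches=base_spec.notches + delta.notches,
            patches=patches,
            seed=base_spec.seed if seed is None else seed + i,
        )
        out.append(generate_bscan(spec))
    return out


def generate_cohort(
    base_spec: PhantomSpec,
    stage_deltas: list[StageDelta],
    n_subjects: int = 30,
    subject_thickness_sd_px: float = 0.0,
    seed: int = 0,
) -> tuple[list[list[tuple[BScan, GroundTruth]]], np.ndarray]:
    """Simulate a cohort: per-subject baseline jitter, shared stage deltas.

    Returns the per-subject stage series plus the (subjects x stages) matrix
    of truth mean enamel thickness in pixels. Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    cohort: list[list[tuple[BScan, GroundTruth]]] = []
    truth = np.empty((n_subjects, len(stage_deltas)))
    for s in range(n_subjects):
        jitter = rng.normal(0.0, subject_thickness_sd_px) if subject_thickness_sd_px else 0.0
        base = dataclasses.replace(
            base_spec,
            enamel_thickness_px=max(base_spec.enamel_thickness_px + jitter, 1.0),
        )
        series = generate_treatment_series(
            base, stage_deltas, seed=int(rng.integers(0, 2**31 - 1))
        )
        cohort.append(series)
        truth[s] = [gt.enamel_thickness_px.mean() for _, gt in series]
    return cohort, truth


def generate_volume(
    spec: PhantomSpec,
    n_slices: int = 500,
    slice_pitch: float = 10.0,
    seed: int | None = None,
) -> tuple[Volume, list[GroundTruth]]:
    """Render a C-scan as independent speckle realizations of one spec."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    bscans, truths = [], []
    for _ in range(n_slices):
        b, t = generate_bscan(spec, rng=rng)
        bscans.append(b)
        truths.append(t)
    return Volume(bscans=bscans, slice_pitch=slice_pitch), truths


def generate_enface_image(
    spec: PhantomSpec,
    depth_um: float = 500.0,
    n_slices: int = 64,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the en-face plane ``depth_um`` below the surface directly.

    Equivalent to rendering a C-scan and sampling it on the surface-following
    plane, but without materializing the volume: each output pixel
    (slice, column) sees enamel where the local enamel thickness exceeds the
    sampling depth, the DEJ line where it crosses it, and dentin below, all
    under the usual attenuation, Hunter-Schreger modulation, adhesive
    shadowing, speckle and noise floor. Slices are independent speckle
    realizations.

    Returns (image, per-column truth class labels).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if depth_um < 0:
        raise ValueError("depth_um must be >= 0")
    d = depth_um / spec.axial_pitch
    cols = spec.shape[1]
    x = np.arange(cols)
    thickness = spec.thickness_profile()
    atten = np.exp(-spec.attenuation * d)
    # columns where the plane glances the DEJ line render at enamel level:
    # axial PSF mixing at glancing incidence dilutes the junction specularity
    row = np.where(
        d < thickness + 1,
        spec.enamel_reflectivity * spec.hs_modulation(x),
        spec.dentin_reflectivity,
    ) * atten
    classes = np.where(
        d < thickness, CLASS_ENAMEL, np.where(d < thickness + 1, CLASS_DEJ, CLASS_DENTIN)
    ).astype(np.int16)
    img = np.tile(row, (n_slices, 1))
    for patch in spec.patches:
        lo, hi = max(0, patch.x_start), min(cols, patch.x_end)
        img[:, lo:hi] *= patch.shadow_factor
    if spec.speckle_k is not None and np.isfinite(spec.speckle_k):
        img = img * _speckle_field(
            rng, img.shape, spec.speckle_k, (1, spec.speckle_grain[1])
        )
    if spec.noise_floor_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_floor_sigma, size=img.shape)
    return np.clip(img, 0.0, None), classes


def generate_enface_truth(
    volume_truth: list[GroundTruth], depth_um: float, axial_pitch: float
) -> np.ndarray:
    """Truth class labels on the en-face plane ``depth_um`` below the surface.

    Output pixel (slice, column) is the class at row
    ``surface_row + round(depth_um / axial_pitch)`` of that slice.
    """
    if depth_um < 0:
        raise ValueError("depth_um must be >= 0")
    offset = int(round(depth_um / axial_pitch))
    n_cols = volume_truth[0].class_map.shape[1]
    out = np.empty((len(volume_truth), n_cols), dtype=np.int16)
    for i, gt in enumerate(volume_truth):
        rows = gt.surface_row + offset
        if rows.max() >= gt.class_map.shape[0]:
            raise ValueError(
                f"depth {depth_um} um ({offset} px) falls below the image for slice {i}"
            )
        out[i] = gt.class_map[rows, np.arange(n_cols)]
    return out
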