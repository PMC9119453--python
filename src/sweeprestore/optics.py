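"""Widefield acquisition simulator for 3D fluorescent spheroid samples.

Models the two acquisition paradigms of a motorized widefield system imaging
spheroids in a microwell:

* **z-stack** — the camera pauses every ``z_step`` (default 25 um, within the
  25.3 um depth of field), takes ``frames_per_plane`` consecutive 50 ms
  exposures and averages them to tame shot noise.
* **z-sweep** — the camera moves continuously (default 1.25 mm/s) while a
  series of 50 ms exposures is acquired and summed into one image whose
  intensity is integrated over z; a 1.5 mm sweep therefore takes 1.2 s
  against ~101 s for the corresponding stack.

The optical model is deliberately simple: each spheroid is a uniform-emission
sphere whose projected column density is blurred by an isotropic Gaussian PSF
with width growing linearly in defocus, plus a flat background; the camera
applies Poisson shot noise, a linear gain, and 12-bit saturation.  Both
outputs are normalized by effective exposure time so the paired images share
one intensity scale (ADU/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Spheroid", "Phantom", "PhantomParams", "AcquisitionSpec", "ZStack",
    "SweepImage", "ImagePair", "generate_phantom", "render_plane",
    "render_zstack", "render_zsweep", "sweep_duration", "exposure_normalize",
    "phantom_label_mask",
]

LAYOUT_KINDS = ("single", "single_plane_multi", "embedded")


@dataclass(frozen=True)
class Spheroid:
    center: Tuple[float, float, float]  # (x, y, z) um
    radius: float                       # um
    emission_rate: float                # expected photons / um^3 / s at the detector

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.emission_rate < 0:
            raise ValueError("emission_rate must be >= 0")


@dataclass(frozen=True)
class Phantom:
    """Parametric 3D scene: spheroid positions/radii/brightness in a volume."""

    volume_size: Tuple[float, float, float]  # (x, y, z) extents, um
    spheroids: Tuple[Spheroid, ...]
    background_rate: float                   # photons / pixel / s
    layout_kind: str

    def __post_init__(self):
        if self.layout_kind not in LAYOUT_KINDS:
            raise ValueError(f"unknown layout_kind {self.layout_kind!r}")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.layout_kind == "single" and len(self.spheroids) != 1:
            raise ValueError("layout 'single' requires exactly one spheroid")
        if self.layout_kind == "single_plane_multi" and self.spheroids:
            zs = np.array([s.center[2] for s in self.spheroids])
            rmax = max(s.radius for s in self.spheroids)
            if zs.max() - zs.min() > 2 * rmax:
                raise ValueError("single_plane_multi centers must share one z "
                                 "within +/- one radius")


@dataclass(frozen=True)
class PhantomParams:
    """Sampling ranges for phantom generation."""

    n_spheroids: int = 20
    radius_range: Tuple[float, float] = (30.0, 80.0)
    emission_range: Tuple[float, float] = (2.0, 8.0)
    background_rate: float = 100.0
    volume_size: Tuple[float, float, float] = (1024.0, 1024.0, 750.0)
    plane_z: Optional[float] = None  # common z for single_plane_multi (default: mid-volume)

    def __post_init__(self):
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must be positive and ordered")
        if self.n_spheroids < 1:
            raise ValueError("n_spheroids must be >= 1")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Optical, camera and motion parameters shared by both paradigms."""

    z_range: float = 750.0            # um swept / stacked
    z_step: float = 25.0              # um between stack planes
    frame_exposure: float = 0.050     # s per stack frame
    frames_per_plane: int = 3         # consecutive frames averaged per plane
    sweep_speed: float = 1250.0       # um/s continuous axial speed
    sweep_frame_exposure: float = 0.050  # s per summed sweep frame
    bit_depth: int = 12               # ADU saturation at 2**bit_depth - 1
    pixel_size: float = 1.39          # um/pixel (4X objective scale)
    psf_sigma_focus: float = 2.0      # um, in-focus Gaussian blur width
    psf_defocus_slope: float = 0.05   # um of sigma per um of defocus
    depth_of_field: float = 25.3      # um
    adu_per_photon: float = 1.0       # camera gain
    sweep_substeps: int = 10          # motion sub-steps integrated per sweep frame

    def __post_init__(self):
        if self.z_step <= 0 or self.z_range < self.z_step:
            raise ValueError("need z_step > 0 and z_range >= z_step")
        if self.frame_exposure <= 0 or self.sweep_frame_exposure <= 0:
            raise ValueError("exposures must be > 0")
        if self.sweep_speed <= 0:
            raise ValueError("sweep_speed must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.sweep_substeps < 1:
            raise ValueError("sweep_substeps must be >= 1")

    @property
    def adu_max(self) -> float:
        return float(2**self.bit_depth - 1)

    def image_shape(self, phantom: Phantom) -> Tuple[int, int]:
        vx, vy, _ = phantom.volume_size
        return int(round(vy / self.pixel_size)), int(round(vx / self.pixel_size))


@dataclass
class ZStack:
    frames: np.ndarray                 # (h, w, n_planes) ADU
    plane_z: List[float]               # um
    effective_exposure_per_plane: float  # s


@dataclass
class SweepImage:
    pixels: np.ndarray    # (h, w) summed ADU
    n_exposures: int
    sweep_frame_exposure: float

    @property
    def effective_exposure(self) -> float:
        return self.n_exposures * self.sweep_frame_exposure


@dataclass
class ImagePair:
    """Exposure-normalized (S, P) pair — the supervised training unit."""

    S: np.ndarray   # z-sweep, ADU/s
    P: np.ndarray   # z-projection, ADU/s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.S.shape != self.P.shape:
            raise ValueError("S and P must share dimensions")


# -- phantom generation -------------------------------------------------------

def generate_phantom(layout_kind: str, params: PhantomParams, seed: int) -> Phantom:
    """Sample a phantom for one of the three assay layouts.

    ``single``: one spheroid centered in the volume.  ``single_plane_multi``:
    spheroids scattered laterally but sharing one optical plane (growth on a
    flat matrix bed).  ``embedded``: spheroids suspended throughout the z
    extent of the matrix column.
    """
    if layout_kind not in LAYOUT_KINDS:
        raise ValueError(f"unknown layout_kind {layout_kind!r}")
    rng = np.random.default_rng(seed)
    vx, vy, vz = params.volume_size
    rlo, rhi = params.radius_range
    elo, ehi = params.emission_range

    def sample_r():
        return float(rng.uniform(rlo, rhi))

    def sample_e():
        return float(rng.uniform(elo, ehi))

    spheroids: List[Spheroid] = []
    if layout_kind == "single":
        r = sample_r()
        spheroids.append(Spheroid((vx / 2, vy / 2, vz / 2), r, sample_e()))
    elif layout_kind == "single_plane_multi":
        z0 = params.plane_z if params.plane_z is not None else vz / 2
        for _ in range(params.n_spheroids):
            r = sample_r()
            x = float(rng.uniform(r, vx - r))
            y = float(rng.uniform(r, vy - r))
            spheroids.append(Spheroid((x, y, z0), r, sample_e()))
    else:  # embedded
        for _ in range(params.n_spheroids):
            r = sample_r()
            x = float(rng.uniform(r, vx - r))
            y = float(rng.uniform(r, vy - r))
            z = float(rng.uniform(min(r, vz / 2), max(vz - r, vz / 2)))
            spheroids.append(Spheroid((x, y, z), r, sample_e()))
    return Phantom((vx, vy, vz), tuple(spheroids), params.background_rate, layout_kind)


# -- forward optical model ----------------------------------------------------

def _projected_emission(phantom: Phantom, spec: AcquisitionSpec) -> List[np.ndarray]:
    """Per-spheroid projected column-density images (photons / pixel / s).

    The column through a uniform sphere at lateral distance d has chord length
    2*sqrt(r^2 - d^2); multiplied by emission rate (per um^3) and pixel area
    this gives the in-focus photon rate per pixel.
    """
    h, w = spec.image_shape(phantom)
    ys = (np.arange(h) + 0.5) * spec.pixel_size
    xs = (np.arange(w) + 0.5) * spec.pixel_size
    area = spec.pixel_size**2
    images = []
    for s in phantom.spheroids:
        cx, cy, _ = s.center
        d2 = (ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2
        chord = 2.0 * np.sqrt(np.maximum(s.radius**2 - d2, 0.0))
        images.append(s.emission_rate * chord * area)
    return images


def _expected_plane(phantom: Phantom, z: float, spec: AcquisitionSpec,
                    projections: Optional[List[np.ndarray]] = None) -> np.ndarray:
    """Expected photon rate per pixel (photons/s) with the focal plane at z."""
    h, w = spec.image_shape(phantom)
    rate = np.full((h, w), float(phantom.background_rate))
    if projections is None:
        projections = _projected_emission(phantom, spec)
    for s, proj in zip(phantom.spheroids, projections):
        sigma_um = spec.psf_sigma_focus + spec.psf_defocus_slope * abs(z - s.center[2])
        rate += gaussian_filter(proj, sigma=sigma_um / spec.pixel_size, mode="constant")
    return rate


def _to_adu(photons: np.ndarray, spec: AcquisitionSpec,
            rng: Optional[np.random.Generator], saturate: bool) -> np.ndarray:
    counts = rng.poisson(photons).astype(float) if rng is not None else photons
    adu = counts * spec.adu_per_photon
    return np.clip(adu, 0.0, spec.adu_max) if saturate else adu


def render_plane(phantom: Phantom, z: float, spec: AcquisitionSpec,
                 exposure: float, rng: Optional[np.random.Generator] = None,
                 saturate: bool = True,
                 _projections: Optional[List[np.ndarray]] = None) -> np.ndarray:
    """One camera frame (ADU) with the focal plane at height z."""
    if exposure < 0:
        raise ValueError("exposure must be >= 0")
    if not 0 <= z <= phantom.volume_size[2]:
        raise ValueError("z outside the sample volume")
    photons = exposure * _expected_plane(phantom, z, spec, _projections)
    return _to_adu(photons, spec, rng, saturate)


def render_zstack(phantom: Phantom, spec: AcquisitionSpec,
                  seed: Optional[int] = None, saturate: bool = True) -> ZStack:
    """Plane-by-plane acquisition: frames_per_plane noisy frames averaged per z.

    Each frame is saturated individually before averaging, as the camera
    digitizes each exposure.  The averaged plane keeps the single-frame
    intensity scale, so its effective exposure is one frame_exposure.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    n_planes = int(math.floor(spec.z_range / spec.z_step)) + 1
    zs = [i * spec.z_step for i in range(n_planes)]
    projections = _projected_emission(phantom, spec)
    h, w = spec.image_shape(phantom)
    frames = np.empty((h, w, n_planes))
    for i, z in enumerate(zs):
        acc = np.zeros((h, w))
        for _ in range(spec.frames_per_plane):
            acc += render_plane(phantom, z, spec, spec.frame_exposure, rng,
                                saturate=saturate, _projections=projections)
        frames[:, :, i] = acc / spec.frames_per_plane
    return ZStack(frames, zs, spec.frame_exposure)


def render_zsweep(phantom: Phantom, spec: AcquisitionSpec,
                  seed: Optional[int] = None, saturate: bool = True,
                  substeps: Optional[int] = None) -> SweepImage:
    """Continuous-motion acquisition: consecutive exposures summed.

    Motion within each frame is integrated with ``substeps`` midpoint
    sub-renders (default 10, ~6.25 um per sub-step — below the 25.3 um depth
    of field).  Poisson noise and saturation apply per frame, before summing.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    substeps = substeps or spec.sweep_substeps
    dz_frame = spec.sweep_speed * spec.sweep_frame_exposure
    n_exposures = max(1, int(math.ceil(spec.z_range / dz_frame)))
    projections = _projected_emission(phantom, spec)
    h, w = spec.image_shape(phantom)
    zmax = phantom.volume_size[2]
    total = np.zeros((h, w))
    for k in range(n_exposures):
        photons = np.zeros((h, w))
        for m in range(substeps):
            z = (k + (m + 0.5) / substeps) * dz_frame
            z = min(z, zmax)  # camera overshoot past the volume top is clamped
            photons += (spec.sweep_frame_exposure / substeps) * \
                _expected_plane(phantom, z, spec, projections)
        total += _to_adu(photons, spec, rng, saturate)
    return SweepImage(total, n_exposures, spec.sweep_frame_exposure)


def sweep_duration(z_range: float, spec: AcquisitionSpec) -> float:
    """Time to sweep z_range at the spec's speed (1.5 mm at 1.25 mm/s -> 1.2 s)."""
    if spec.sweep_speed <= 0:
        raise ValueError("sweep_speed must be > 0")
    return z_range / spec.sweep_speed


def exposure_normalize(image: np.ndarray, effective_exposure: float) -> np.ndarray:
    """ADU -> ADU/s; makes stack and sweep images share one intensity scale."""
    if effective_exposure <= 0:
        raise ValueError("effective_exposure must be > 0")
    return np.asarray(image, dtype=float) / effective_exposure


def phantom_label_mask(phantom: Phantom, spec: AcquisitionSpec) -> np.ndarray:
    """Ground-truth labeled mask of projected spheroid discs (0 = background).

    Later spheroids overwrite earlier ones where discs overlap; labels follow
    the phantom's spheroid order (1-based).
    """
    h, w = spec.image_shape(phantom)
    ys = (np.arange(h) + 0.5) * spec.pixel_size
    xs = (np.arange(w) + 0.5) * spec.pixel_size
    mask = np.zeros((h, w), dtype=np.int32)
    for i, s in enumerate(phantom.spheroids, start=1):
        cx, cy, _ = s.center
        d2 = (ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2
        mask[d2 <= s.radius**2] = i
    return mask
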