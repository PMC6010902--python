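"""Multi-distance in-line hologram simulation and inversion.

Cone-beam acquisition is mapped to an equivalent parallel-beam problem via
the Fresnel scaling theorem: magnification ``M = (D1 + D2)/D1``, effective
pixel ``detector_pixel / M`` and effective propagation distance
``D_eff = D1 * D2 / (D1 + D2)``.  Phase retrieval uses the weak-object
(pure phase) contrast-transfer-function inversion over all distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from numpy.fft import fft2, fftfreq, ifft2
from scipy import ndimage
from skimage.transform import iradon

from .volume import Volume3D

__all__ = [
    "HC_EV_NM",
    "GeometryError",
    "AcquisitionGeometry",
    "HologramSet",
    "GeometryDerived",
    "magnification",
    "photons_per_pixel_scan",
    "fresnel_propagate",
    "simulate_hologram_series",
    "normalize_and_align",
    "ctf_phase_retrieval",
    "fbp_reconstruct",
]

#: h*c in eV*nm — wavelength [nm] = HC_EV_NM / energy [eV]
HC_EV_NM = 1239.841984

#: focus-to-detector distance [mm] self-consistent with the scan-parameter
#: table: detector_pixel * D1 / l is constant across rows (3 um * 80.533 mm
#: / 200 nm).  The instrument description only gives "approximately 1.2 m".
DEFAULT_FOCUS_DETECTOR_MM = 3.0e3 * 80.533 / 200.0  # = 1207.995 mm


class GeometryError(ValueError):
    """Inconsistent acquisition geometry."""


@dataclass
class AcquisitionGeometry:
    """One scan-parameter row: energy, detector, distances and photon budget."""

    photon_energy_kev: float = 17.0
    detector_pixel_um: float = 3.0  # effective (post-binning) detector pixel
    focus_detector_mm: float = DEFAULT_FOCUS_DETECTOR_MM
    focus_sample_mm: tuple[float, ...] = (10.066, 10.499, 12.226, 15.812)
    n_projections: int = 1800
    exposure_s: float = 0.25
    photons_per_pixel_projection: float | None = 500.0  # None = noiseless

    def __post_init__(self) -> None:
        if self.photon_energy_kev <= 0:
            raise GeometryError("photon energy must be positive")
        if self.detector_pixel_um <= 0 or self.focus_detector_mm <= 0:
            raise GeometryError("detector pixel and focus-detector distance must be positive")
        self.focus_sample_mm = tuple(float(d) for d in self.focus_sample_mm)
        if not self.focus_sample_mm:
            raise GeometryError("at least one focus-sample distance is required")
        for d in self.focus_sample_mm:
            if not 0 < d < self.focus_detector_mm:
                raise GeometryError(
                    f"focus-sample distance {d} mm outside (0, {self.focus_detector_mm})")
        if self.n_projections < 1:
            raise GeometryError("n_projections must be >= 1")

    @property
    def wavelength_nm(self) -> float:
        return HC_EV_NM / (self.photon_energy_kev * 1e3)

    @property
    def n_distances(self) -> int:
        return len(self.focus_sample_mm)

    def derived(self, index: int = 0) -> "GeometryDerived":
        return magnification(self.focus_sample_mm[index], self.focus_detector_mm,
                             self.detector_pixel_um)


class GeometryDerived(NamedTuple):
    m: float  # geometric magnification
    effective_pixel_nm: float  # detector pixel / M
    d_eff_mm: float  # Fresnel-scaled propagation distance


def magnification(d1_mm: float, focus_detector_mm: float,
                  detector_pixel_um: float = 3.0) -> GeometryDerived:
    """Geometric magnification ``M = (D1 + D2)/D1`` and its derived scales.

    ``d1_mm`` is the focus-to-sample distance, ``focus_detector_mm`` the full
    focus-to-detector distance ``D1 + D2``.  Returns the magnification, the
    effective pixel (``detector_pixel / M``) in nm, and the Fresnel-scaled
    effective propagation distance ``D1 * D2 / (D1 + D2)`` in mm.
    """
    if not 0 < d1_mm <= focus_detector_mm:
        raise GeometryError(
            f"require 0 < D1 <= total distance, got D1={d1_mm}, total={focus_detector_mm}")
    m = focus_detector_mm / d1_mm
    pixel_nm = detector_pixel_um * 1e3 / m
    d2 = focus_detector_mm - d1_mm
    d_eff = d1_mm * d2 / focus_detector_mm
    return GeometryDerived(m, pixel_nm, d_eff)


def photons_per_pixel_scan(n_projections: int, photons_per_pixel_projection: float,
                           n_distances: int) -> float:
    """Total photons per pixel accumulated over a full tomographic scan."""
    if n_projections < 1 or photons_per_pixel_projection < 1 or n_distances < 1:
        raise ValueError("all photon-budget inputs must be >= 1")
    return float(n_projections) * float(photons_per_pixel_projection) * float(n_distances)


def photons_per_pixel_scan_megaphotons(n_projections: int,
                                       photons_per_pixel_projection: float,
                                       n_distances: int) -> float:
    """Same budget in units of 10^6, rounded to one decimal (table convention)."""
    total = photons_per_pixel_scan(n_projections, photons_per_pixel_projection, n_distances)
    return round(total / 1e6, 1)


# ---------------------------------------------------------------------------
# Fresnel propagation

def _chirp(shape: tuple[int, int], wavelength_nm: float, distance_nm: float,
           pixel_nm: float) -> np.ndarray:
    fy = fftfreq(shape[0], d=pixel_nm)
    fx = fftfreq(shape[1], d=pixel_nm)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    return np.pi * wavelength_nm * distance_nm * f2  # chi(f)


def fresnel_propagate(phase_map: np.ndarray, amplitude_map: np.ndarray | float,
                      wavelength_nm: float, distance_eff_mm: float,
                      pixel_nm: float) -> np.ndarray:
    """Paraxial free-space propagation of ``A * exp(i*phi)``; returns |wave|^2.

    Periodic boundary handling (FFT); total intensity is conserved to
    numerical precision (Parseval).  Warns when the quadratic propagator
    phase is undersampled at the band edge (Nyquist criterion
    ``D > N * pixel^2 / lambda``).
    """
    phase = np.asarray(phase_map, dtype=np.float64)
    if phase.ndim != 2:
        raise ValueError("phase_map must be 2D")
    amp = np.broadcast_to(np.asarray(amplitude_map, dtype=np.float64), phase.shape)
    if distance_eff_mm < 0:
        raise ValueError("distance_eff_mm must be >= 0")
    if not np.all(np.isfinite(phase)) or not np.all(np.isfinite(amp)):
        raise ValueError("phase/amplitude maps must be finite")
    d_nm = distance_eff_mm * 1e6
    if d_nm == 0:
        return amp**2
    n_min = min(phase.shape)
    if d_nm > n_min * pixel_nm**2 / wavelength_nm:
        warnings.warn(
            "Fresnel propagator undersampled: distance exceeds the "
            f"critical sampling distance N*pixel^2/lambda for grid {phase.shape}",
            stacklevel=2)
    wave = amp * np.exp(1j * phase)
    chi = _chirp(phase.shape, wavelength_nm, d_nm, pixel_nm)
    out = ifft2(fft2(wave) * np.exp(-1j * chi))
    return np.abs(out) ** 2


# ---------------------------------------------------------------------------
# hologram series

@dataclass
class HologramSet:
    """Per-distance noisy holograms with flat fields and geometry side-car."""

    holograms: list[np.ndarray]
    flats: list[np.ndarray]
    magnifications: list[float]
    effective_pixels_nm: list[float]
    d_eff_mm: list[float]
    photons_per_pixel_projection: float | None = None

    def __post_init__(self) -> None:
        n = len(self.holograms)
        if not (len(self.flats) == len(self.magnifications)
                == len(self.effective_pixels_nm) == len(self.d_eff_mm) == n):
            raise ValueError("all per-distance lists must have equal length")
        for img in self.holograms:
            if np.any(np.asarray(img) < 0):
                raise ValueError("hologram intensities must be >= 0")

    @property
    def n_distances(self) -> int:
        return len(self.holograms)


def _resample_to_pixel(img: np.ndarray, pixel_in_nm: float, pixel_out_nm: float,
                       out_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Resample so sample ``j`` sits at physical ``j * pixel_out`` (origin-aligned)."""
    ratio = pixel_out_nm / pixel_in_nm
    if abs(ratio - 1.0) < 1e-12 and out_shape in (None, img.shape):
        return img
    if out_shape is None:
        out_shape = tuple(int(np.floor(s / ratio)) for s in img.shape)
    coords = np.meshgrid(*(np.arange(s) * ratio for s in out_shape), indexing="ij")
    return ndimage.map_coordinates(img, coords, order=1, mode="nearest")


def simulate_hologram_series(phase_projection: np.ndarray,
                             geometry: AcquisitionGeometry,
                             rng_seed: int = 0) -> HologramSet:
    """Simulate one multi-distance hologram series of a pure-phase projection.

    ``phase_projection`` is the phase map (radians) sampled at the effective
    pixel of the *first* distance.  For every other distance the projection
    is resampled to that distance's coarser effective pixel, propagated over
    its Fresnel-scaled distance, scaled to the photon budget and Poisson
    sampled.  ``photons_per_pixel_projection=None`` disables noise.
    """
    phase = np.asarray(phase_projection, dtype=np.float64)
    if phase.ndim != 2:
        raise GeometryError("phase projection must be 2D")
    if not np.all(np.isfinite(phase)):
        raise ValueError("phase projection must be finite")
    rng = np.random.default_rng(rng_seed)
    lam = geometry.wavelength_nm
    photons = geometry.photons_per_pixel_projection

    holograms, flats, mags, pixels, deffs = [], [], [], [], []
    ref = geometry.derived(0)
    for i in range(geometry.n_distances):
        der = geometry.derived(i)
        ph = _resample_to_pixel(phase, ref.effective_pixel_nm, der.effective_pixel_nm)
        intensity = fresnel_propagate(ph, 1.0, lam, der.d_eff_mm, der.effective_pixel_nm)
        if photons is None or not np.isfinite(photons):
            holograms.append(intensity)
            flats.append(np.ones_like(intensity))
        else:
            holograms.append(rng.poisson(intensity * photons).astype(np.float64))
            flats.append(rng.poisson(
                np.full_like(intensity, float(photons))).astype(np.float64))
        mags.append(der.m)
        pixels.append(der.effective_pixel_nm)
        deffs.append(der.d_eff_mm)
    return HologramSet(holograms, flats, mags, pixels, deffs, photons)


class NormalizationError(ValueError):
    pass


def normalize_and_align(h: HologramSet) -> np.ndarray:
    """Flat-normalize, rescale to the finest pixel and register each distance.

    Returns a stack ``(n_distances, ny, nx)`` at the effective pixel of the
    first (finest) distance, translation-registered to the first hologram.
    """
    from .metrics import _register_translation  # local: avoid import cycle

    finest = min(h.effective_pixels_nm)
    normed = []
    for holo, flat, pix in zip(h.holograms, h.flats, h.effective_pixels_nm):
        flat = np.asarray(flat, dtype=np.float64)
        if np.any(flat <= 0):
            raise NormalizationError("flat field contains non-positive pixels")
        img = np.asarray(holo, dtype=np.float64) / flat
        normed.append((img, pix))

    target = normed[0][0].shape
    stack = [normed[0][0]]
    for img, pix in normed[1:]:
        out = _resample_to_pixel(img, pix, finest, out_shape=target)
        shift, _ = _register_translation(stack[0], out, subpixel=False)
        if np.any(shift):  # offset is moving-relative-to-fixed: undo it
            out = np.roll(out, tuple(-int(s) for s in shift), axis=(0, 1))
        stack.append(out)
    return np.stack(stack, axis=0)


# ---------------------------------------------------------------------------
# CTF phase retrieval

def ctf_phase_retrieval(aligned_stack: np.ndarray, wavelength_nm: float,
                        distances_eff_mm: Sequence[float], pixel_nm: float,
                        regularization: float | None = None) -> np.ndarray:
    """Least-squares weak-object CTF inversion over all distances.

    ``phi_hat = sum_d sin(chi_d) I_hat_d / (2 sum_d sin^2(chi_d) + eps)``
    with ``chi_d = pi * lambda * D_d * f^2`` and ``I_hat_d`` the Fourier
    transform of the flat-normalized contrast ``I_d - 1``.  ``eps`` defaults
    to ``1e-3`` of the peak denominator and also guards the zero frequency.
    Returns the phase map in radians.
    """
    stack = np.atleast_3d(np.asarray(aligned_stack, dtype=np.float64))
    if stack.ndim != 3:
        raise ValueError("aligned_stack must be (n_distances, ny, nx)")
    distances = np.asarray(distances_eff_mm, dtype=np.float64)
    if len(distances) != stack.shape[0]:
        raise ValueError("one effective distance per stack entry required")

    shape = stack.shape[1:]
    num = np.zeros(shape, dtype=np.complex128)
    den = np.zeros(shape, dtype=np.float64)
    for img, d_mm in zip(stack, distances):
        chi = _chirp(shape, wavelength_nm, d_mm * 1e6, pixel_nm)
        s = np.sin(chi)
        num += s * fft2(img - 1.0)
        den += 2.0 * s**2
    eps = regularization
    if eps is None:
        peak = den.max()
        eps = 1e-3 * peak if peak > 0 else 1e-3
    if eps <= 0 and np.any(den < 1e-12):
        raise ZeroDivisionError(
            "CTF denominator vanishes at some frequency and regularization is 0")
    return np.real(ifft2(num / (den + eps)))


# ---------------------------------------------------------------------------
# tomographic reconstruction

def fbp_reconstruct(sinograms: np.ndarray, angles_deg: Sequence[float],
                    spacing_nm: float = 1.0) -> Volume3D:
    """Ramp-filtered back projection, slice by slice.

    ``sinograms`` has shape ``(n_slices, n_angles, n_detector)``; angles are
    equally spaced over 180 degrees.  Delegates the inverse Radon transform
    to scikit-image.
    """
    sino = np.asarray(sinograms, dtype=np.float64)
    if sino.ndim == 2:
        sino = sino[None]
    if sino.ndim != 3:
        raise ValueError("sinograms must be (n_slices, n_angles, n_detector)")
    angles = np.asarray(angles_deg, dtype=np.float64)
    if angles.size < 2:
        raise ValueError("at least two projection angles are required")
    if sino.shape[1] != angles.size:
        raise ValueError("angle count must match the sinogram's second axis")
    slices = [
        iradon(s.T, theta=angles, filter_name="ramp", circle=True,
               output_size=sino.shape[2])
        for s in sino
    ]
    return Volume3D(np.stack(slices, axis=0), spacing=spacing_nm)
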