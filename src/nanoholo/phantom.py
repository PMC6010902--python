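"""Synthetic brain-tissue phantoms and degradation models.

Everything any downstream stage consumes is generated here: grayscale
volumes of neuropil with embedded ellipsoidal somata (nucleus, nuclear
envelope, nucleolus compartments), paired ground-truth label volumes,
blurred/noisy/binned degradations, step-edge targets for resolution
estimation, and a synthetic H&E-style RGB image for color-transfer tests.

Gray values are dimensionless electron-density-like units in ``[0, 1]``.
Default compartment ordering: nucleus < neuropil < soma cytoplasm <
nuclear envelope < nucleolus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .volume import Volume3D

__all__ = [
    "CellSpec",
    "PhantomSpec",
    "EdgePhantom",
    "PlacementError",
    "random_cells",
    "COMPARTMENT_CODES",
    "LABEL_STRIDE",
    "generate_tissue_phantom",
    "generate_edge_phantom",
    "bin_volume",
    "synthesize_hne_image",
    "rgb_to_gray",
    "cell_id_volume",
    "soma_mask",
    "nucleus_mask",
    "nucleolus_mask",
    "envelope_mask",
]

# Exclusive compartment codes inside one cell's label block.  Masks below
# re-derive the *inclusive* nesting (nucleolus within nucleus within soma).
COMPARTMENT_CODES = {"cytoplasm": 1, "nucleus": 2, "envelope": 3, "nucleolus": 4}
#: labels are ``cell_index * LABEL_STRIDE + compartment_code`` (background 0)
LABEL_STRIDE = 10

CELL_CLASSES = ("pyramidal", "purkinje", "granule", "stellate")

# default gray levels (nucleus < neuropil < cytoplasm < envelope < nucleolus)
DEFAULT_NEUROPIL = 0.25
DEFAULT_DENSITIES = {"soma": 0.68, "nucleus": 0.10, "envelope": 0.88, "nucleolus": 0.98}


class PlacementError(RuntimeError):
    """Raised when a cell cannot be placed inside the volume."""


@dataclass
class CellSpec:
    """Geometry and gray levels of one ellipsoidal soma with nested compartments."""

    center: tuple[float, float, float] | None = None  # (z, y, x) voxels; None = auto
    radii: tuple[float, float, float] = (20.0, 20.0, 20.0)  # semi-axes, voxels
    orientation: np.ndarray | None = None  # 3x3 rotation matrix, None = identity
    soma_density: float = DEFAULT_DENSITIES["soma"]
    nucleus_density: float = DEFAULT_DENSITIES["nucleus"]
    envelope_density: float = DEFAULT_DENSITIES["envelope"]
    nucleolus_density: float = DEFAULT_DENSITIES["nucleolus"]
    envelope_thickness: float = 1.5  # voxels
    nucleolus_radius: float = 4.0  # voxels
    nucleus_fraction: float = 0.5  # nucleus semi-axes as a fraction of ``radii``
    cell_class: str = "pyramidal"

    def __post_init__(self) -> None:
        self.radii = tuple(float(r) for r in self.radii)
        if len(self.radii) != 3 or any(r <= 0 for r in self.radii):
            raise ValueError(f"radii must be three positive values, got {self.radii}")
        if self.envelope_thickness < 1.0:
            raise ValueError("envelope_thickness must be >= 1 voxel")
        if not 0 < self.nucleus_fraction < 1:
            raise ValueError("nucleus_fraction must lie in (0, 1)")
        if self.nucleolus_radius >= self.nucleus_fraction * min(self.radii):
            raise ValueError("nucleolus must fit inside the nucleus")
        for name in ("soma_density", "nucleus_density", "envelope_density", "nucleolus_density"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"cell_class must be one of {CELL_CLASSES}")
        if self.orientation is not None:
            R = np.asarray(self.orientation, dtype=float)
            if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
                raise ValueError("orientation must be a 3x3 rotation matrix")
            self.orientation = R

    @property
    def rotation(self) -> np.ndarray:
        return np.eye(3) if self.orientation is None else self.orientation


def random_cells(n: int, rng: np.random.Generator,
                 radius_range: tuple[float, float] = (15.0, 25.0),
                 **cell_kwargs) -> list["CellSpec"]:
    """``n`` auto-placed cells with per-axis radii drawn from ``radius_range``."""
    return [CellSpec(center=None, radii=tuple(rng.uniform(*radius_range, 3)),
                     **cell_kwargs)
            for _ in range(n)]


@dataclass
class PhantomSpec:
    """Full recipe for one reproducible tissue phantom."""

    shape: tuple[int, int, int] = (128, 128, 128)  # (z, y, x)
    spacing: float = 100.0  # nm per voxel
    neuropil_density: float = DEFAULT_NEUROPIL
    neuropil_texture_sigma: float = 2.0  # correlation length, voxels
    neuropil_texture_amplitude: float = 0.0  # std of the low-pass field, gray units
    cells: list[CellSpec] = field(default_factory=list)
    psf_sigma: float = 0.0  # voxels
    noise_sigma: float = 0.0  # gray units
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.psf_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("psf_sigma and noise_sigma must be >= 0")
        if self.neuropil_texture_amplitude < 0 or self.neuropil_texture_sigma < 0:
            raise ValueError("texture parameters must be >= 0")


def _ellipsoid_distance(shape: Sequence[int], center: np.ndarray, radii: np.ndarray,
                        rotation: np.ndarray, box: tuple[slice, slice, slice]) -> np.ndarray:
    """Normalized ellipsoidal coordinate ``||R^T (p - c) / radii||`` on a sub-box."""
    grids = np.meshgrid(*(np.arange(s.start, s.stop, dtype=float) for s in box),
                        indexing="ij")
    rel = np.stack([g - c for g, c in zip(grids, center)], axis=-1)
    local = rel @ rotation  # rotate world -> ellipsoid axes
    return np.sqrt(np.sum((local / radii) ** 2, axis=-1))


def _cell_bounding_box(cell: CellSpec, shape: Sequence[int]) -> tuple[slice, slice, slice]:
    rmax = max(cell.radii) + 2.0
    c = np.asarray(cell.center, dtype=float)
    lo = np.maximum(np.floor(c - rmax).astype(int), 0)
    hi = np.minimum(np.ceil(c + rmax).astype(int) + 1, np.asarray(shape))
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))  # type: ignore[return-value]


def _render_cell(intensity: np.ndarray, labels: np.ndarray, cell: CellSpec,
                 cell_index: int) -> None:
    box = _cell_bounding_box(cell, intensity.shape)
    center = np.asarray(cell.center, dtype=float)
    radii = np.asarray(cell.radii, dtype=float)
    rot = cell.rotation

    u_soma = _ellipsoid_distance(intensity.shape, center, radii, rot, box)
    nuc_radii = radii * cell.nucleus_fraction
    u_nuc = _ellipsoid_distance(intensity.shape, center, nuc_radii, rot, box)
    inner_radii = np.maximum(nuc_radii - cell.envelope_thickness, 0.5)
    u_inner = _ellipsoid_distance(intensity.shape, center, inner_radii, rot, box)
    u_cn = _ellipsoid_distance(intensity.shape, center,
                               np.full(3, cell.nucleolus_radius), rot, box)

    in_soma = u_soma <= 1.0
    in_nuc = in_soma & (u_nuc <= 1.0)
    in_env = in_nuc & (u_inner > 1.0)  # outer rim of the nucleus
    in_cn = in_nuc & (u_cn <= 1.0)

    sub_i = intensity[box]
    sub_l = labels[box]
    sub_i[in_soma] = cell.soma_density
    sub_i[in_nuc] = cell.nucleus_density
    sub_i[in_env] = cell.envelope_density
    sub_i[in_cn] = cell.nucleolus_density

    base = cell_index * LABEL_STRIDE
    sub_l[in_soma] = base + COMPARTMENT_CODES["cytoplasm"]
    sub_l[in_nuc] = base + COMPARTMENT_CODES["nucleus"]
    sub_l[in_env] = base + COMPARTMENT_CODES["envelope"]
    sub_l[in_cn] = base + COMPARTMENT_CODES["nucleolus"]


def _auto_place(cells: list[CellSpec], shape: tuple[int, int, int],
                rng: np.random.Generator, max_tries: int = 2000) -> list[CellSpec]:
    """Fill in missing centers by rejection sampling without cell overlap."""
    placed: list[CellSpec] = []
    occupied: list[tuple[np.ndarray, float]] = []
    for cell in cells:
        if cell.center is not None:
            placed.append(cell)
            occupied.append((np.asarray(cell.center, float), max(cell.radii)))
    for cell in cells:
        if cell.center is not None:
            continue
        rmax = max(cell.radii)
        lo = rmax + 2.0
        his = [s - rmax - 2.0 for s in shape]
        if any(h <= lo for h in his):
            raise PlacementError(f"cell with radii {cell.radii} cannot fit in {shape}")
        for _ in range(max_tries):
            cand = np.array([rng.uniform(lo, h) for h in his])
            if all(np.linalg.norm(cand - c) > rmax + r + 2.0 for c, r in occupied):
                break
        else:
            raise PlacementError("auto-placement exhausted; too many/large cells")
        new = CellSpec(**{**cell.__dict__, "center": tuple(cand)})
        placed.append(new)
        occupied.append((cand, rmax))
    return placed


def generate_tissue_phantom(spec: PhantomSpec) -> tuple[Volume3D, Volume3D]:
    """Render a tissue phantom and its ground-truth labels.

    Returns ``(intensity, labels)``.  The intensity volume is neuropil
    background plus per-cell compartments, degraded by a Gaussian PSF and
    additive Gaussian noise.  Labels encode the undegraded geometry:
    background 0, cell ``i`` compartment ``c`` as ``i * LABEL_STRIDE + c``.
    Identical ``rng_seed`` gives a bit-identical phantom.
    """
    rng = np.random.default_rng(spec.rng_seed)
    intensity = np.full(spec.shape, spec.neuropil_density, dtype=np.float32)
    labels = np.zeros(spec.shape, dtype=np.uint16)

    if spec.neuropil_texture_amplitude > 0:
        tex = rng.standard_normal(spec.shape).astype(np.float32)
        if spec.neuropil_texture_sigma > 0:
            tex = ndimage.gaussian_filter(tex, spec.neuropil_texture_sigma)
        std = tex.std()
        if std > 0:
            intensity += (spec.neuropil_texture_amplitude / std) * tex

    cells = _auto_place(list(spec.cells), spec.shape, rng)
    for i, cell in enumerate(cells, start=1):
        box = _cell_bounding_box(cell, spec.shape)
        for ax, s in enumerate(box):
            if s.start < 0 or s.stop > spec.shape[ax]:
                raise PlacementError(f"cell {i} extends outside the volume")
        _render_cell(intensity, labels, cell, i)

    if spec.psf_sigma > 0:
        intensity = ndimage.gaussian_filter(intensity, spec.psf_sigma)
    if spec.noise_sigma > 0:
        intensity = intensity + rng.normal(
            0.0, spec.noise_sigma, size=spec.shape).astype(np.float32)

    vol = Volume3D(intensity.astype(np.float32), spacing=spec.spacing)
    lab = Volume3D(labels, spacing=spec.spacing)
    return vol, lab


# ---------------------------------------------------------------------------
# label-mask helpers (inclusive nesting: nucleolus < nucleus < soma)

def _compartment(labels: np.ndarray, codes: set[int], cell_id: int | None) -> np.ndarray:
    lab = np.asarray(labels)
    comp = lab % LABEL_STRIDE
    mask = np.isin(comp, list(codes)) & (lab > 0)
    if cell_id is not None:
        mask &= (lab - comp) // LABEL_STRIDE == cell_id
    return mask


def cell_id_volume(labels: np.ndarray) -> np.ndarray:
    """Collapse compartment-coded labels to one integer id per cell."""
    lab = np.asarray(labels)
    return (lab // LABEL_STRIDE).astype(lab.dtype)  # codes 1..4 < LABEL_STRIDE


def soma_mask(labels: np.ndarray, cell_id: int | None = None) -> np.ndarray:
    """All voxels of the soma, including every nested compartment."""
    return _compartment(labels, {1, 2, 3, 4}, cell_id)


def nucleus_mask(labels: np.ndarray, cell_id: int | None = None) -> np.ndarray:
    return _compartment(labels, {2, 3, 4}, cell_id)


def envelope_mask(labels: np.ndarray, cell_id: int | None = None) -> np.ndarray:
    return _compartment(labels, {3}, cell_id)


def nucleolus_mask(labels: np.ndarray, cell_id: int | None = None) -> np.ndarray:
    return _compartment(labels, {4}, cell_id)


# ---------------------------------------------------------------------------

class EdgePhantom(NamedTuple):
    volume: Volume3D
    edge_axis: int  # axis perpendicular to the edge plane
    edge_index: float  # plane position along that axis, voxels


def generate_edge_phantom(shape: Sequence[int], blur_sigma: float,
                          contrast: float, noise_sigma: float = 0.0,
                          spacing: float = 100.0, base: float = 0.3,
                          rng_seed: int = 0) -> EdgePhantom:
    """Half-volume step edge for edge-spread resolution estimation.

    The step runs perpendicular to the last (x) axis at ``x = shape[2] / 2``;
    the high side sits at ``base + contrast``.  Blur is an isotropic Gaussian
    PSF of ``blur_sigma`` voxels, noise is additive Gaussian.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"shape must be three positive ints, got {shape}")
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    edge = shape[2] / 2.0
    x = np.arange(shape[2])
    profile = np.where(x >= edge, base + contrast, base).astype(np.float64)
    vol = np.broadcast_to(profile, shape).copy()
    if blur_sigma > 0:
        # blur only the profile: separable PSF leaves a 1D edge 1D
        blurred = ndimage.gaussian_filter1d(profile, blur_sigma)
        vol = np.broadcast_to(blurred, shape).copy()
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        vol = vol + rng.normal(0.0, noise_sigma, size=shape)
    return EdgePhantom(Volume3D(vol.astype(np.float32), spacing=spacing), 2, edge)


def bin_volume(v: Volume3D, factor: int) -> Volume3D:
    """Block-mean downsample by an integer factor; spacing scales up by it.

    Dimensions not divisible by ``factor`` are truncated (with a warning).
    Mean intensity over the retained region is conserved to machine
    precision.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"bin factor must be >= 1, got {factor}")
    if factor == 1:
        return v.copy()
    vox = v.voxels
    new_shape = tuple(s // factor for s in vox.shape)
    if any(s == 0 for s in new_shape):
        raise ValueError(f"volume {vox.shape} too small for factor {factor}")
    trimmed = tuple(s * factor for s in new_shape)
    if trimmed != vox.shape:
        warnings.warn(
            f"bin_volume: truncating {vox.shape} to {trimmed} (factor {factor})",
            stacklevel=2)
        vox = vox[: trimmed[0], : trimmed[1], : trimmed[2]]
    out = (
        vox.astype(np.float64)
        .reshape(new_shape[0], factor, new_shape[1], factor, new_shape[2], factor)
        .mean(axis=(1, 3, 5))
    )
    return Volume3D(out.astype(np.float64), spacing=v.spacing * factor, origin=v.origin)


# ---------------------------------------------------------------------------
# synthetic H&E image

#: luminance weights (ITU-R BT.601), the fixed grayscale transform
_LUMA = np.array([0.299, 0.587, 0.114])

_EOSIN_PINK = np.array([235.0, 145.0, 190.0])
_HEMATOXYLIN_PURPLE = np.array([90.0, 45.0, 150.0])
_LUMEN_WHITE = np.array([250.0, 248.0, 250.0])


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Fixed luminance transform used throughout (BT.601 weights)."""
    return np.tensordot(np.asarray(rgb, dtype=np.float64), _LUMA, axes=([-1], [0]))


def synthesize_hne_image(seed: int, shape: tuple[int, int] = (256, 256),
                         n_nuclei: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic H&E-stained-section lookalike plus its grayscale transform.

    Pink eosin background with purple hematoxylin nuclei and a few white
    lumen patches; returns ``(rgb uint8 HxWx3, gray float64 HxW)`` where
    gray is the BT.601 luminance of the RGB image.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]

    # smooth eosin intensity modulation
    mod = ndimage.gaussian_filter(rng.standard_normal(shape), 8.0)
    mod = (mod - mod.min()) / max(np.ptp(mod), 1e-12)  # [0,1]
    rgb = _EOSIN_PINK[None, None, :] * (0.85 + 0.15 * mod)[..., None]

    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(4, 10), rng.uniform(4, 10)
        d = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        strength = np.clip(1.2 - d, 0, 1)[..., None]
        rgb = rgb * (1 - strength) + _HEMATOXYLIN_PURPLE[None, None, :] * strength

    for _ in range(4):  # white lumen patches widen the luminance range
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(8, 16)
        d = ((yy - cy) ** 2 + (xx - cx) ** 2) / r**2
        strength = np.clip(1.1 - d, 0, 1)[..., None]
        rgb = rgb * (1 - strength) + _LUMEN_WHITE[None, None, :] * strength

    rgb8 = np.clip(rgb, 0, 255).astype(np.uint8)
    return rgb8, rgb_to_gray(rgb8)
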