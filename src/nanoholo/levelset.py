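"""Second segmentation stage: sparse-field active-contour refinement.

Entry points: :func:`sfm_evolve` (one evolution on a 2D slice or 3D
volume), :func:`segment_automated` (detection mask -> slice-wise 2D
evolution -> 3D evolution -> size cleanup), :func:`segment_semiautomated`
(user seeds on one slice propagated outward slice by slice), and
:func:`region_growing` for high-contrast subcellular structures.

The evolution combines a two-phase region data force (separation of the
inside/outside mean intensities) with a ``zeta``-weighted mean-curvature
smoothing term; ``zeta`` is the relative weight of curve smoothness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import detection
from ._sparse_field import _evolve, _region_grow
from .volume import Volume3D

__all__ = [
    "SfmParams",
    "SegmentationResult",
    "sfm_evolve",
    "segment_automated",
    "segment_semiautomated",
    "region_growing",
]


@dataclass(frozen=True)
class SfmParams:
    """Iteration counts and smoothness weights of the two-stage evolution."""

    n_iterations_2d: int = 900
    zeta_2d: float = 0.01
    n_iterations_3d: int = 60
    zeta_3d: float = 1.0
    min_final_voxels: int = 300

    def __post_init__(self) -> None:
        if self.n_iterations_2d < 0 or self.n_iterations_3d < 0:
            raise ValueError("iteration counts must be >= 0")
        if self.zeta_2d < 0 or self.zeta_3d < 0:
            raise ValueError("zeta must be >= 0")
        if self.min_final_voxels < 0:
            raise ValueError("min_final_voxels must be >= 0")


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _object_table(labels: np.ndarray, spacing_nm: float) -> pd.DataFrame:
    """Per-object stats: size, centroid, border contact, ellipsoid axes."""
    rows = []
    n = int(labels.max())
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        if coords.size == 0:
            continue
        size = len(coords)
        centroid = coords.mean(axis=0)
        touches = bool(
            np.any(coords == 0)
            or np.any(coords == np.asarray(labels.shape) - 1))
        a = b = c = float("nan")
        if size >= 4:
            cov = np.cov(coords.T.astype(np.float64))
            evals = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
            # solid-ellipsoid relation: covariance eigenvalue = semi_axis^2 / 5
            axes = np.sqrt(np.maximum(5.0 * evals, 0.0))
            a, b, c = (float(x) for x in axes)
        eq_d_um = 2.0 * (3.0 * size / (4.0 * np.pi)) ** (1.0 / 3.0) * spacing_nm / 1e3
        rows.append({"label": lab, "voxels": size,
                     "centroid_z": centroid[0], "centroid_y": centroid[1],
                     "centroid_x": centroid[2], "touches_border": touches,
                     "a_vox": a, "b_vox": b, "c_vox": c,
                     "equivalent_diameter_um": eq_d_um})
    return pd.DataFrame(rows, columns=["label", "voxels", "centroid_z", "centroid_y",
                                       "centroid_x", "touches_border", "a_vox",
                                       "b_vox", "c_vox", "equivalent_diameter_um"])


@dataclass
class SegmentationResult:
    """Integer label volume plus a recomputable per-object statistics table."""

    labels: Volume3D
    objects: pd.DataFrame

    @classmethod
    def from_labels(cls, labels: Volume3D) -> "SegmentationResult":
        lab = np.asarray(labels.voxels)
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        return cls(labels, _object_table(lab, labels.spacing))

    @property
    def n_objects(self) -> int:
        return len(self.objects)


def _as_array(image) -> np.ndarray:
    if isinstance(image, Volume3D):
        return np.asarray(image.voxels)
    return np.asarray(image)


def sfm_evolve(image, init_mask, n_iterations: int, zeta: float,
               return_touched: bool = False,
               fixed_means: tuple[float, float] | None = None):
    """Sparse-field evolution of ``init_mask`` on a 2D or 3D image.

    Returns the converged interior mask (bool, same shape); with
    ``return_touched`` also a mask of every voxel whose level-set value was
    written during the run (band-locality diagnostics).
    ``n_iterations == 0`` returns the initialization unchanged.

    By default the two-phase means adapt to the evolving partition; passing
    ``fixed_means=(c_in, c_out)`` freezes them, which makes the contour
    collapse on regions that do not resemble the seeded object (used by the
    slice-propagating semi-automated mode).
    """
    img = _as_array(image).astype(np.float32)
    mask = _as_array(init_mask).astype(bool)
    if img.shape != mask.shape:
        raise ValueError(f"image {img.shape} and init mask {mask.shape} differ")
    if img.ndim not in (2, 3):
        raise ValueError("image must be 2D or 3D")
    if n_iterations == 0:
        out = mask.copy()
        return (out, np.zeros_like(mask)) if return_touched else out
    if not mask.any():
        raise ValueError("initialization mask is empty")
    if zeta < 0:
        raise ValueError("zeta must be >= 0")

    two_d = img.ndim == 2
    if two_d:
        img3 = img[None]
        mask3 = mask[None]
    else:
        img3, mask3 = img, mask
    padded = np.pad(img3, 1, mode="edge").astype(np.float32)
    inside = np.pad(mask3, 1, mode="constant").astype(np.uint8)
    valid = np.zeros_like(inside)
    valid[1:-1, 1:-1, 1:-1] = 1
    nz, ny, nx = padded.shape
    phi = np.empty(padded.size, dtype=np.float32)
    touched = np.zeros(padded.size, dtype=np.uint8)

    use_fixed = fixed_means is not None
    c_in_f, c_out_f = (float(fixed_means[0]), float(fixed_means[1])) if use_fixed else (0.0, 0.0)
    _evolve(padded.ravel(), inside.reshape(-1), valid.ravel(), phi,
            ny * nx, nx, 1, not two_d, int(n_iterations), float(zeta), touched,
            use_fixed, c_in_f, c_out_f)

    out = inside.reshape(nz, ny, nx)[1:-1, 1:-1, 1:-1].astype(bool)
    tout = touched.reshape(nz, ny, nx)[1:-1, 1:-1, 1:-1].astype(bool)
    if two_d:
        out, tout = out[0], tout[0]
    if not out.any():
        warnings.warn("level-set contour vanished; returning an empty mask",
                      stacklevel=2)
    return (out, tout) if return_touched else out


def _remove_small(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    if min_voxels <= 0 or not mask.any():
        return mask
    labeled, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n + 1))
    keep = np.concatenate([[False], sizes >= min_voxels])
    return keep[labeled]


def _finalize(v: Volume3D, mask: np.ndarray, sp: SfmParams) -> SegmentationResult:
    mask = _remove_small(mask, sp.min_final_voxels)
    labeled, _ = ndimage.label(mask, structure=_CONN26)
    labels = Volume3D(labeled.astype(np.uint16), spacing=v.spacing, origin=v.origin)
    return SegmentationResult.from_labels(labels)


def _slicewise_then_3d(v: Volume3D, init3d: np.ndarray, sp: SfmParams,
                       slice_axis: int = 0) -> np.ndarray:
    img = np.moveaxis(np.asarray(v.voxels), slice_axis, 0)
    init = np.moveaxis(init3d, slice_axis, 0)
    out2d = np.zeros_like(init, dtype=bool)
    for z in range(img.shape[0]):
        if init[z].any():
            out2d[z] = sfm_evolve(img[z], init[z], sp.n_iterations_2d, sp.zeta_2d)
    if out2d.any() and sp.n_iterations_3d > 0:
        out3d = sfm_evolve(img, out2d, sp.n_iterations_3d, sp.zeta_3d)
    else:
        out3d = out2d
    return np.moveaxis(out3d, 0, slice_axis)


def segment_automated(v: Volume3D, fp: detection.FrangiParams, sp: SfmParams,
                      slice_axis: int = 0) -> SegmentationResult:
    """Fully automated two-step segmentation.

    Multi-scale Hessian detection produces the initialization mask, which is
    refined slice by slice in 2D, then once in 3D; components below
    ``sp.min_final_voxels`` are removed and the survivors labelled.
    Deterministic: identical inputs give an identical label volume.
    """
    response = detection.frangi_response(v, fp)
    mask, _ = detection.make_initialization_mask(response, fp)
    init = np.asarray(mask.voxels, dtype=bool)
    if not init.any():
        return _finalize(v, init, sp)
    final = _slicewise_then_3d(v, init, sp, slice_axis)
    return _finalize(v, final, sp)


def segment_semiautomated(v: Volume3D, seed_slice_index: int,
                          seed_masks_on_slice: np.ndarray, sp: SfmParams,
                          slice_axis: int = 0) -> SegmentationResult:
    """Seeded segmentation: one annotated slice propagated through the volume.

    The seed mask is evolved in 2D on its slice; the converged mask then
    initializes the adjacent slice, marching outward in both directions
    until the evolved mask turns empty.  The stacked result feeds the same
    3D step and cleanup as the automated pipeline.
    """
    img = np.moveaxis(np.asarray(v.voxels), slice_axis, 0)
    nz = img.shape[0]
    if not 0 <= seed_slice_index < nz:
        raise IndexError(f"seed slice {seed_slice_index} outside [0, {nz})")
    seeds = np.asarray(seed_masks_on_slice).astype(bool)
    if seeds.shape != img.shape[1:]:
        raise ValueError("seed mask shape must match the slice shape")
    if not seeds.any():
        raise ValueError("seed mask is empty")

    out = np.zeros(img.shape, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-contour warnings end propagation
        seed_result = sfm_evolve(
            img[seed_slice_index], seeds, sp.n_iterations_2d, sp.zeta_2d)
        out[seed_slice_index] = seed_result
        # freeze the object/background means at the annotated slice so the
        # contour collapses (and propagation stops) past the object's extent
        ref = img[seed_slice_index]
        means = (float(ref[seed_result].mean()) if seed_result.any() else 0.0,
                 float(ref[~seed_result].mean()) if not seed_result.all() else 0.0)
        for direction in (1, -1):
            z = seed_slice_index + direction
            prev = out[seed_slice_index]
            while 0 <= z < nz and prev.any():
                cur = sfm_evolve(img[z], prev, sp.n_iterations_2d, sp.zeta_2d,
                                 fixed_means=means)
                out[z] = cur
                prev = cur
                z += direction
        if out.any() and sp.n_iterations_3d > 0:
            out = sfm_evolve(img, out, sp.n_iterations_3d, sp.zeta_3d)
    final = np.moveaxis(out, 0, slice_axis)
    return _finalize(v, final, sp)


def region_growing(v: Volume3D, seeds, tolerance: float) -> SegmentationResult:
    """Seeded flood fill: voxels join while within ``tolerance`` of the
    running region mean (6-connectivity).  One label per seed, in seed
    order; a seed falling in an already-grown region is skipped.
    """
    vox = np.asarray(v.voxels, dtype=np.float32)
    seeds = [tuple(int(c) for c in s) for s in seeds]
    if not seeds:
        raise ValueError("at least one seed is required")
    for s in seeds:
        if len(s) != 3 or any(not 0 <= c < d for c, d in zip(s, vox.shape)):
            raise IndexError(f"seed {s} outside volume {vox.shape}")
        if not np.isfinite(vox[s]):
            raise ValueError(f"seed {s} sits on a non-finite voxel")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")

    padded = np.pad(vox, 1, mode="edge")
    labels = np.zeros(padded.shape, dtype=np.int32)
    labels[0, :, :] = labels[-1, :, :] = -1
    labels[:, 0, :] = labels[:, -1, :] = -1
    labels[:, :, 0] = labels[:, :, -1] = -1
    nz, ny, nx = padded.shape
    flat_seeds = np.array(
        [(s[0] + 1) * ny * nx + (s[1] + 1) * nx + (s[2] + 1) for s in seeds],
        dtype=np.int64)
    _region_grow(padded.ravel(), labels.reshape(-1), flat_seeds,
                 np.float32(tolerance), ny * nx, nx, 1)
    out = labels[1:-1, 1:-1, 1:-1]
    out[out < 0] = 0
    vol = Volume3D(out.astype(np.uint16), spacing=v.spacing, origin=v.origin)
    return SegmentationResult.from_labels(vol)
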