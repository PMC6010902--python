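"""First segmentation stage: multi-scale 3D Hessian structure detection.

A scale-normalized Hessian is evaluated at a set of scales mapped from a
target radius range, its eigenvalues feed the classic three-ratio
vesselness response (plate/line ratio, blob ratio, structureness), and the
maximal response over scales is binarized and filtered by object size and
border contact to produce the level-set initialization mask.

Eigenvalues of the symmetric 3x3 Hessian are computed with a vectorized
closed-form (trigonometric Cardano) solver — orders of magnitude faster
than per-voxel LAPACK calls on full volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage

from .volume import Volume3D

__all__ = [
    "FrangiParams",
    "hessian_eigenvalues",
    "frangi_response",
    "make_initialization_mask",
]

#: structureness cutoff quoted for ~8-bit-scaled gray data
GAMMA_8BIT = 60.0


@dataclass(frozen=True)
class FrangiParams:
    """Parameters of the multi-scale vesselness detector and mask filters.

    ``gamma`` is in the gray units of the volume the filter runs on; the
    reference value of 60 corresponds to 8-bit-scaled data (use
    :meth:`for_gray_range` to rescale it for other dynamic ranges).
    """

    alpha: float = 0.5  # plate/line discrimination
    beta: float = 0.1  # blob discrimination
    gamma: float = GAMMA_8BIT  # structureness cutoff, gray units
    radius_min: float = 15.0  # voxels
    radius_max: float = 25.0
    radius_step: float = 2.0
    binarize_threshold: float = 0.01  # on the [0,1] response
    min_object_voxels: int = 20_000
    exclude_border: bool = True
    scale_ratio: float = 0.8  # sigma = scale_ratio * radius
    bright_structures: bool = True  # detect bright-on-dark polarity

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("alpha, beta and gamma must be > 0")
        if not 0 < self.radius_min <= self.radius_max:
            raise ValueError("require 0 < radius_min <= radius_max")
        if self.radius_step <= 0:
            raise ValueError("radius_step must be > 0")
        if not 0 < self.binarize_threshold <= 1:
            raise ValueError("binarize_threshold must lie in (0, 1]")
        if self.min_object_voxels < 0:
            raise ValueError("min_object_voxels must be >= 0")
        if self.scale_ratio <= 0:
            raise ValueError("scale_ratio must be > 0")

    @property
    def radii(self) -> np.ndarray:
        return np.arange(self.radius_min, self.radius_max + 1e-9, self.radius_step)

    @property
    def sigmas(self) -> np.ndarray:
        return self.scale_ratio * self.radii

    @classmethod
    def for_gray_range(cls, gray_range: float, **overrides) -> "FrangiParams":
        """Defaults with ``gamma`` rescaled from the 8-bit reference value."""
        if gray_range <= 0:
            raise ValueError("gray_range must be > 0")
        return cls(gamma=GAMMA_8BIT * gray_range / 255.0, **overrides)


def _symmetric_eigvals_3x3(h: dict[str, np.ndarray]) -> np.ndarray:
    """Eigenvalues of a field of symmetric 3x3 matrices (ascending by value).

    Trigonometric (Cardano) closed form, vectorized over all voxels.
    Returns an array of shape ``(3,) + field_shape``.
    """
    a, b, c = h["zz"], h["yy"], h["xx"]
    d, e, f = h["zy"], h["zx"], h["yx"]  # off-diagonals
    q = (a + b + c) / 3.0
    p2 = (a - q) ** 2 + (b - q) ** 2 + (c - q) ** 2 + 2.0 * (d**2 + e**2 + f**2)
    p = np.sqrt(np.maximum(p2 / 6.0, 0.0))
    safe_p = np.where(p > 0, p, 1.0)
    b11, b22, b33 = (a - q) / safe_p, (b - q) / safe_p, (c - q) / safe_p
    detb = (b11 * (b22 * b33 - f * f / safe_p**2)
            - (d / safe_p) * ((d / safe_p) * b33 - (f / safe_p) * (e / safe_p))
            + (e / safe_p) * ((d / safe_p) * (f / safe_p) - b22 * (e / safe_p)))
    r = np.clip(detb / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    eig1 = q + 2.0 * p * np.cos(phi)  # largest
    eig3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)  # smallest
    eig2 = 3.0 * q - eig1 - eig3
    out = np.stack([eig3, eig2, eig1])
    return np.where(p[None] > 0, out, np.broadcast_to(q, out.shape))


def _hessian_components(vox: np.ndarray, sigma: float) -> dict[str, np.ndarray]:
    # demean: truncated derivative kernels leak a small DC term, which would
    # break the additive-offset invariance of the Hessian
    vox = vox - np.float32(vox.mean())

    def g(orders):
        return ndimage.gaussian_filter(vox, sigma, order=orders,
                                       mode="nearest", truncate=3.0)

    # scale normalization: multiply by sigma^2
    s2 = sigma * sigma
    return {
        "zz": s2 * g((2, 0, 0)), "yy": s2 * g((0, 2, 0)), "xx": s2 * g((0, 0, 2)),
        "zy": s2 * g((1, 1, 0)), "zx": s2 * g((1, 0, 1)), "yx": s2 * g((0, 1, 1)),
    }


def hessian_eigenvalues(v: Volume3D, scale_sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale-normalized Hessian eigenvalues at scale ``sigma``.

    Returns three volumes ``(l1, l2, l3)`` sorted by increasing magnitude,
    ``|l1| <= |l2| <= |l3|`` at every voxel.
    """
    if scale_sigma <= 0:
        raise ValueError("scale_sigma must be > 0")
    support = 2 * int(np.ceil(3.0 * scale_sigma)) + 1
    if min(v.shape) < support:
        raise ValueError(
            f"volume {v.shape} smaller than the kernel support {support} at sigma={scale_sigma}")
    vox = np.asarray(v.voxels, dtype=np.float32)
    eigs = _symmetric_eigvals_3x3(_hessian_components(vox, scale_sigma))
    order = np.argsort(np.abs(eigs), axis=0)
    eigs = np.take_along_axis(eigs, order, axis=0)
    return eigs[0], eigs[1], eigs[2]


@njit(cache=True, fastmath=True)
def _vesselness_accumulate(hzz, hyy, hxx, hzy, hzx, hyx, best,
                           two_a2, two_b2, two_g2, bright):
    """Fused per-voxel eigenvalues (Cardano) + three-ratio response, max into
    ``best``.  Same math as the vectorized path, without the temporaries."""
    n = best.size
    tiny = 1e-10
    for i in range(n):
        a = hzz[i]
        b = hyy[i]
        c = hxx[i]
        d = hzy[i]
        e = hzx[i]
        f = hyx[i]
        q = (a + b + c) / 3.0
        p2 = (a - q) ** 2 + (b - q) ** 2 + (c - q) ** 2 + 2.0 * (d * d + e * e + f * f)
        p = np.sqrt(p2 / 6.0) if p2 > 0 else 0.0
        if p <= 0:
            continue  # isotropic point: all eigenvalues equal, no structure
        b11 = (a - q) / p
        b22 = (b - q) / p
        b33 = (c - q) / p
        d_, e_, f_ = d / p, e / p, f / p
        detb = (b11 * (b22 * b33 - f_ * f_)
                - d_ * (d_ * b33 - f_ * e_)
                + e_ * (d_ * f_ - b22 * e_))
        r = detb / 2.0
        if r > 1.0:
            r = 1.0
        elif r < -1.0:
            r = -1.0
        phi = np.arccos(r) / 3.0
        e1 = q + 2.0 * p * np.cos(phi)
        e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
        e2 = 3.0 * q - e1 - e3
        # sort by magnitude: l1 smallest |.|, l3 largest
        a1, a2_, a3 = abs(e1), abs(e2), abs(e3)
        l1, l2, l3 = e1, e2, e3
        if a1 > a2_:
            l1, l2 = l2, l1
            a1, a2_ = a2_, a1
        if a2_ > a3:
            l2, l3 = l3, l2
            a2_, a3 = a3, a2_
        if a1 > a2_:
            l1, l2 = l2, l1
            a1, a2_ = a2_, a1
        if bright:
            if l2 >= 0 or l3 >= 0:
                continue
        else:
            if l2 <= 0 or l3 <= 0:
                continue
        ra2 = (a2_ / (a3 + tiny)) ** 2
        rb2 = a1 * a1 / (a2_ * a3 + tiny)
        s2 = a1 * a1 + a2_ * a2_ + a3 * a3
        resp = ((1.0 - np.exp(-ra2 / two_a2))
                * np.exp(-rb2 / two_b2)
                * (1.0 - np.exp(-s2 / two_g2)))
        if resp > best[i]:
            best[i] = resp


def frangi_response(v: Volume3D, p: FrangiParams) -> Volume3D:
    """Maximal three-ratio vesselness response over the radius-mapped scales.

    ``V = (1 - exp(-Ra^2/2a^2)) * exp(-Rb^2/2b^2) * (1 - exp(-S^2/2g^2))``
    with ``Ra = |l2|/|l3|``, ``Rb = |l1|/sqrt(|l2 l3|)`` and ``S`` the
    Frobenius norm of the eigenvalues; the response is zeroed where the
    bright-structure polarity condition (``l2, l3 < 0``) fails.  Values lie
    in [0, 1].
    """
    vox = np.asarray(v.voxels, dtype=np.float32)
    best = np.zeros(vox.size, dtype=np.float32)
    two_a2 = 2.0 * p.alpha**2
    two_b2 = 2.0 * p.beta**2
    two_g2 = 2.0 * p.gamma**2
    for sigma in p.sigmas:
        h = _hessian_components(vox, float(sigma))
        _vesselness_accumulate(
            h["zz"].ravel(), h["yy"].ravel(), h["xx"].ravel(),
            h["zy"].ravel(), h["zx"].ravel(), h["yx"].ravel(),
            best, two_a2, two_b2, two_g2, p.bright_structures)
    return v.with_voxels(best.reshape(vox.shape))


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def make_initialization_mask(response: Volume3D, p: FrangiParams) -> tuple[Volume3D, pd.DataFrame]:
    """Binarize the response and filter objects by size and border contact.

    Components (26-connectivity) below ``min_object_voxels`` are dropped, as
    are components touching any of the six volume faces when
    ``exclude_border`` is set.  Returns the surviving binary mask and a
    table of *all* components with columns ``id, voxels, centroid_z/y/x,
    border_flag, kept``.
    """
    resp = np.asarray(response.voxels)
    if resp.min() < -1e-6 or resp.max() > 1 + 1e-6:
        raise ValueError("response must lie in [0, 1]")
    binary = resp >= p.binarize_threshold
    labeled, n = ndimage.label(binary, structure=_CONN26)

    rows = []
    keep = np.zeros(n + 1, dtype=bool)
    if n:
        idx = np.arange(1, n + 1)
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, idx)
        centroids = ndimage.center_of_mass(binary, labeled, idx)
        border_ids = set()
        for ax in range(3):
            for face in (0, -1):
                sl = [slice(None)] * 3
                sl[ax] = face
                border_ids.update(np.unique(labeled[tuple(sl)]))
        border_ids.discard(0)
        for i, size, com in zip(idx, sizes, centroids):
            on_border = i in border_ids
            kept = size >= p.min_object_voxels and not (p.exclude_border and on_border)
            keep[i] = kept
            rows.append({"id": int(i), "voxels": int(size),
                         "centroid_z": com[0], "centroid_y": com[1], "centroid_x": com[2],
                         "border_flag": bool(on_border), "kept": bool(kept)})
    table = pd.DataFrame(rows, columns=["id", "voxels", "centroid_z", "centroid_y",
                                        "centroid_x", "border_flag", "kept"])
    mask = keep[labeled]
    if not mask.any():
        warnings.warn("initialization mask is empty after filtering", stacklevel=2)
    return response.with_voxels(mask.astype(np.uint8)), table
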