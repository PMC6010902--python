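"""Quantitative image-quality and segmentation metrics.

Contrast-to-noise ratio from a two-Gaussian histogram fit, edge-based
normalized-MTF resolution (10% crossing, half-period convention),
object-level sensitivity ``S = TP / T``, elliptical envelope curvature
``R = a^2 / b``, normalized-cross-correlation translation registration,
running median over slices, and gray-to-RGB color transfer against a
histology reference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from numpy.fft import fftn, ifftn, rfft, rfftfreq
from scipy import ndimage, optimize

from .volume import Volume3D

__all__ = [
    "CnrFit",
    "ResolutionEstimate",
    "RegistrationResult",
    "MetricsReport",
    "FitError",
    "cnr",
    "nmtf_resolution",
    "sensitivity",
    "ellipse_curvature",
    "fit_ellipse_axes",
    "translation_register",
    "median_over_slices",
    "hne_color_transfer",
]


class FitError(RuntimeError):
    """Degenerate histogram fit."""


@dataclass
class CnrFit:
    """Two-component intensity model and the contrast-to-noise ratio.

    ``cnr = |i1 - i2| / sqrt(sigma1^2 + sigma2^2)``, recomputable from the
    stored component moments.
    """

    i1: float
    i2: float
    sigma1: float
    sigma2: float
    cnr: float
    residual: float = 0.0
    interval: tuple[float, float] | None = None

    def recompute(self) -> float:
        return abs(self.i1 - self.i2) / np.sqrt(self.sigma1**2 + self.sigma2**2)


def _two_gaussians(x, w1, mu1, s1, w2, mu2, s2):
    g1 = w1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2) / (np.sqrt(2 * np.pi) * s1)
    g2 = w2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2) / (np.sqrt(2 * np.pi) * s2)
    return g1 + g2


def _fit_two_gaussians(values: np.ndarray, bins: int = 128) -> CnrFit:
    hist, edges = np.histogram(values, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lo, hi = np.percentile(values, [25, 75])
    span = max(values.std(), 1e-12)
    p0 = (0.5, lo, span / 2, 0.5, hi, span / 2)
    bounds = ([0, -np.inf, 1e-12, 0, -np.inf, 1e-12],
              [np.inf] * 6)
    try:
        popt, _ = optimize.curve_fit(_two_gaussians, centers, hist, p0=p0,
                                     bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - optimizer failure path
        raise FitError(f"two-Gaussian fit did not converge: {exc}") from exc
    w1, mu1, s1, w2, mu2, s2 = popt
    wsum = w1 + w2
    if wsum <= 0 or min(w1, w2) / wsum < 0.01:
        raise FitError(
            f"degenerate two-Gaussian fit: component weights {w1:.3g}, {w2:.3g}")
    resid = float(np.sqrt(np.mean((_two_gaussians(centers, *popt) - hist) ** 2)))
    c = abs(mu1 - mu2) / np.sqrt(s1**2 + s2**2)
    return CnrFit(float(mu1), float(mu2), float(s1), float(s2), float(c), resid)


def cnr(v: Volume3D, roi_a=None, roi_b=None) -> CnrFit:
    """Contrast-to-noise ratio between two image components.

    With two ROI masks (or index expressions) the component moments are
    taken directly from the ROIs; without them, a two-Gaussian mixture is
    fitted to the full intensity histogram.  Invariant under affine
    intensity rescaling.
    """
    vox = np.asarray(v.voxels, dtype=np.float64)
    if (roi_a is None) != (roi_b is None):
        raise ValueError("provide both ROIs or neither")
    if roi_a is not None:
        def _extract(roi):
            if isinstance(roi, np.ndarray) and roi.dtype == bool:
                return vox[roi]
            return np.asarray(vox[roi]).ravel()

        a, b = _extract(roi_a), _extract(roi_b)
        if a.size == 0 or b.size == 0:
            raise ValueError("ROIs must be nonempty")
        i1, i2 = float(a.mean()), float(b.mean())
        s1, s2 = float(a.std()), float(b.std())
        denom = np.sqrt(s1**2 + s2**2)
        c = abs(i1 - i2) / denom if denom > 0 else (0.0 if i1 == i2 else np.inf)
        return CnrFit(i1, i2, s1, s2, float(c))
    return _fit_two_gaussians(vox.ravel())


# ---------------------------------------------------------------------------
# edge-based resolution

@dataclass
class ResolutionEstimate:
    """Upper-limit resolution from the 10% crossing of the normalized MTF.

    ``resolution_nm`` is the *half-period* of the crossing frequency — the
    smallest resolvable feature size.  (A full-period convention would
    report twice this value; the choice is stated here because the
    normalization in use at instruments varies.)
    """

    resolution_nm: float
    frequencies: np.ndarray  # cycles per nm
    nmtf: np.ndarray
    crossing_frequency: float  # cycles per nm
    median_slices: int = 1
    at_band_edge: bool = False
    interval: tuple[float, float] | None = None


def nmtf_resolution(v: Volume3D, edge_region=None, median_slices: int = 1,
                    edge_axis: int = 2) -> ResolutionEstimate:
    """Edge-spread resolution estimate.

    The edge profile is read along ``edge_axis`` inside ``edge_region`` (a
    tuple of slices; whole volume by default), optionally median-combined
    over ``median_slices`` slices along axis 0, and averaged to a 1D edge
    spread function.  Its derivative is Fourier-transformed, normalized at
    the lowest nonzero frequency, and the first 10% crossing converted to a
    feature size via the voxel spacing.  Without a crossing inside the band
    the Nyquist limit is reported with ``at_band_edge`` set.
    """
    sub = np.asarray(v.voxels, dtype=np.float64)
    if edge_region is not None:
        sub = sub[tuple(edge_region)]
    if median_slices > sub.shape[0]:
        raise ValueError("median_slices exceeds available slices")
    if median_slices > 1:
        sub = np.median(sub[:median_slices], axis=0, keepdims=True)
    sub = np.moveaxis(sub, edge_axis, -1)
    esf = sub.reshape(-1, sub.shape[-1]).mean(axis=0)
    if abs(esf[-1] - esf[0]) < 1e-9 * max(1.0, np.abs(esf).max()):
        warnings.warn("edge region shows no contrast step", stacklevel=2)
    lsf = np.diff(esf)  # forward difference: an ideal step maps to an impulse
    spectrum = np.abs(rfft(lsf))
    freqs_vox = rfftfreq(lsf.size)  # cycles per voxel
    if spectrum.size < 3 or spectrum[1] == 0:
        raise ValueError("edge profile too short for an MTF estimate")
    nmtf = spectrum / spectrum[1]  # normalize at lowest nonzero frequency
    freqs_nm = freqs_vox / v.spacing

    below = np.nonzero(nmtf[1:] < 0.1)[0]
    if below.size == 0:
        f10_vox = freqs_vox[-1]  # Nyquist
        at_edge = True
    else:
        k = below[0] + 1
        f_lo, f_hi = freqs_vox[k - 1], freqs_vox[k]
        m_lo, m_hi = nmtf[k - 1], nmtf[k]
        t = (m_lo - 0.1) / max(m_lo - m_hi, 1e-12)
        f10_vox = f_lo + t * (f_hi - f_lo)
        at_edge = False
    resolution_vox = 1.0 / (2.0 * f10_vox)  # half-period feature size
    return ResolutionEstimate(
        resolution_nm=float(resolution_vox * v.spacing),
        frequencies=freqs_nm,
        nmtf=nmtf,
        crossing_frequency=float(f10_vox / v.spacing),
        median_slices=int(median_slices),
        at_band_edge=at_edge,
    )


# ---------------------------------------------------------------------------
# object-level sensitivity

def sensitivity(result, truth: Volume3D, min_overlap: float = 0.5) -> float:
    """Fraction of detected objects matching a ground-truth object.

    A detected object counts as a true positive when its centroid voxel
    falls inside a ground-truth object and the intersection covers at least
    ``min_overlap`` of the smaller of the two objects.  Returns
    ``S = TP / T``; ``nan`` when nothing was detected (undefined).
    Permutation-invariant in both labelings.
    """
    det = np.asarray(result.labels.voxels if hasattr(result, "labels") else result)
    tru = np.asarray(truth.voxels if isinstance(truth, Volume3D) else truth)
    if det.shape != tru.shape:
        raise ValueError("detected and truth label volumes must be congruent")
    det_ids = [i for i in np.unique(det) if i != 0]
    if not det_ids:
        warnings.warn("no detected objects; sensitivity is undefined", stacklevel=2)
        return float("nan")
    truth_sizes = {i: int((tru == i).sum()) for i in np.unique(tru) if i != 0}
    tp = 0
    for i in det_ids:
        mask = det == i
        size = int(mask.sum())
        centroid = tuple(int(round(c)) for c in np.argwhere(mask).mean(axis=0))
        t_id = int(tru[centroid])
        if t_id == 0:
            continue
        inter = int(np.logical_and(mask, tru == t_id).sum())
        if inter >= min_overlap * min(size, truth_sizes[t_id]):
            tp += 1
    return tp / len(det_ids)


# ---------------------------------------------------------------------------
# elliptical curvature

def fit_ellipse_axes(mask: np.ndarray, spacing_nm: float = 1.0) -> tuple[float, float]:
    """Semi-axes ``(a, b)`` in micrometres of a filled 2D object.

    Second-moment (inertia) fit: for a solid ellipse the covariance
    eigenvalue equals ``semi_axis^2 / 4``.
    """
    coords = np.argwhere(np.asarray(mask, dtype=bool))
    if len(coords) < 4:
        raise ValueError("object too small for an ellipse fit")
    cov = np.cov(coords.T.astype(np.float64))
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    a, b = (float(2.0 * np.sqrt(max(e, 0.0))) for e in evals)
    return a * spacing_nm / 1e3, b * spacing_nm / 1e3


def ellipse_curvature(a_um: float, b_um: float) -> float:
    """Envelope curvature ``R = a^2 / b`` of an ellipse with semi-axes a >= b.

    For a circle (``a == b == r``) this is the radius ``r``.
    """
    if b_um <= 0:
        raise ValueError("minor semi-axis must be > 0")
    if a_um < b_um:
        raise ValueError(f"require a >= b, got a={a_um}, b={b_um}")
    return a_um**2 / b_um


# ---------------------------------------------------------------------------
# translation registration

class RegistrationResult(NamedTuple):
    offset: tuple[float, ...]  # displacement of `moving` relative to `fixed`
    peak_correlation: float
    low_confidence: bool


def _register_translation(fixed: np.ndarray, moving: np.ndarray,
                          subpixel: bool = True) -> tuple[np.ndarray, float]:
    """Shift maximizing the circular normalized cross-correlation."""
    f = np.asarray(fixed, dtype=np.float64)
    m = np.asarray(moving, dtype=np.float64)
    if f.shape != m.shape:
        raise ValueError("volumes must have the same shape for registration")
    f0 = f - f.mean()
    m0 = m - m.mean()
    denom = np.sqrt((f0**2).sum() * (m0**2).sum())
    if denom == 0:
        return np.zeros(f.ndim), 1.0 if np.allclose(f, m) else 0.0
    corr = np.real(ifftn(fftn(m0) * np.conj(fftn(f0)))) / denom
    peak_idx = np.unravel_index(np.argmax(corr), corr.shape)
    peak = float(corr[peak_idx])
    shift = np.array(peak_idx, dtype=np.float64)
    for ax, s in enumerate(shift):  # wrap to signed displacements
        if s > f.shape[ax] // 2:
            shift[ax] = s - f.shape[ax]
    if subpixel:
        for ax in range(f.ndim):
            idx_m = list(peak_idx)
            idx_p = list(peak_idx)
            idx_m[ax] = (peak_idx[ax] - 1) % f.shape[ax]
            idx_p[ax] = (peak_idx[ax] + 1) % f.shape[ax]
            c0 = corr[tuple(idx_m)]
            c1 = peak
            c2 = corr[tuple(idx_p)]
            denom_q = c0 - 2 * c1 + c2
            if denom_q < 0:
                corr_frac = 0.5 * (c0 - c2) / denom_q
                if abs(corr_frac) >= 1e-4:  # below FFT noise: keep integer peak
                    shift[ax] += corr_frac
    return shift, peak


def translation_register(fixed: Volume3D, moving: Volume3D,
                         min_correlation: float = 0.1) -> RegistrationResult:
    """Displacement of ``moving`` relative to ``fixed`` by cross-correlation.

    The returned ``offset`` is the translation that was applied to the
    fixed content to produce ``moving``; shifting ``moving`` by ``-offset``
    aligns it with ``fixed``.  Subvoxel precision by quadratic fit around
    the correlation peak.  A peak correlation below ``min_correlation``
    sets the low-confidence flag.
    """
    f = np.asarray(fixed.voxels if isinstance(fixed, Volume3D) else fixed)
    m = np.asarray(moving.voxels if isinstance(moving, Volume3D) else moving)
    shift, peak = _register_translation(f, m, subpixel=True)
    low = peak < min_correlation
    if low:
        warnings.warn(
            f"registration peak correlation {peak:.3f} below {min_correlation}",
            stacklevel=2)
    return RegistrationResult(tuple(float(s) for s in shift), peak, low)


# ---------------------------------------------------------------------------

def median_over_slices(v: Volume3D, n: int) -> Volume3D:
    """Per-pixel running median over a window of ``n`` slices (axis 0)."""
    if n < 1:
        raise ValueError("window must be >= 1")
    if n > v.shape[0]:
        raise ValueError(f"window {n} exceeds slice count {v.shape[0]}")
    if n == 1:
        return v.copy()
    if n % 2 == 0:
        warnings.warn("even median window; the filter is not symmetric", stacklevel=2)
    out = ndimage.median_filter(np.asarray(v.voxels), size=(n, 1, 1), mode="nearest")
    return v.with_voxels(out)


# ---------------------------------------------------------------------------
# histology color transfer

def hne_color_transfer(gray: np.ndarray, histology_rgb: np.ndarray,
                       histology_gray: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Colorize a grayscale slice from a pixel-aligned histology RGB/gray pair.

    Histology pixels are binned on their gray value and the RGB mean per
    bin defines a gray-to-RGB lookup (the inverse of the RGB-to-gray
    transform); empty bins are interpolated, values outside the histology
    gray range are clamped with a warning.  Returns a uint8 RGB image.
    """
    rgb = np.asarray(histology_rgb, dtype=np.float64)
    hgray = np.asarray(histology_gray, dtype=np.float64)
    if rgb.shape[:-1] != hgray.shape or rgb.shape[-1] != 3:
        raise ValueError("histology RGB and gray images must be pixel-aligned")
    g = np.asarray(gray, dtype=np.float64)

    lo, hi = hgray.min(), hgray.max()
    if hi <= lo:
        return np.broadcast_to(
            rgb.reshape(-1, 3).mean(axis=0).round().astype(np.uint8),
            g.shape + (3,)).copy()
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(hgray.ravel(), edges) - 1, 0, n_bins - 1)
    lut = np.zeros((n_bins, 3))
    counts = np.bincount(which, minlength=n_bins)
    for c in range(3):
        sums = np.bincount(which, weights=rgb[..., c].ravel(), minlength=n_bins)
        filled = counts > 0
        centers = 0.5 * (edges[:-1] + edges[1:])
        lut[:, c] = np.interp(centers, centers[filled], sums[filled] / counts[filled])

    if g.min() < lo - 1e-9 or g.max() > hi + 1e-9:
        warnings.warn("input gray values outside the histology range; clamping",
                      stacklevel=2)
    pos = np.clip((g - lo) / (hi - lo) * (n_bins - 1), 0, n_bins - 1)
    idx = np.round(pos).astype(int)
    return np.clip(lut[idx], 0, 255).round().astype(np.uint8)


# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Container for every metric of one evaluation run; JSON round-trips."""

    cnr: CnrFit | None = None
    resolution: ResolutionEstimate | None = None
    sensitivity: float | None = None
    curvatures_um: list[float] = field(default_factory=list)
    diameters_um: list[float] = field(default_factory=list)
    registration_offset: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.sensitivity is not None and np.isfinite(self.sensitivity):
            if not 0.0 <= self.sensitivity <= 1.0:
                raise ValueError("sensitivity must lie in [0, 1]")

    def to_dict(self) -> dict:
        d: dict = {}
        if self.cnr is not None:
            d["cnr"] = asdict(self.cnr)
        if self.resolution is not None:
            r = asdict(self.resolution)
            r["frequencies"] = self.resolution.frequencies.tolist()
            r["nmtf"] = self.resolution.nmtf.tolist()
            d["resolution"] = r
        d["sensitivity"] = self.sensitivity
        d["curvatures_um"] = list(self.curvatures_um)
        d["diameters_um"] = list(self.diameters_um)
        d["registration_offset"] = (list(self.registration_offset)
                                    if self.registration_offset is not None else None)
        return d

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        cnr_fit = None
        if d.get("cnr") is not None:
            c = dict(d["cnr"])
            if c.get("interval") is not None:
                c["interval"] = tuple(c["interval"])
            cnr_fit = CnrFit(**c)
        res = None
        if d.get("resolution") is not None:
            r = dict(d["resolution"])
            r["frequencies"] = np.asarray(r["frequencies"])
            r["nmtf"] = np.asarray(r["nmtf"])
            if r.get("interval") is not None:
                r["interval"] = tuple(r["interval"])
            res = ResolutionEstimate(**r)
        off = d.get("registration_offset")
        return cls(cnr=cnr_fit, resolution=res, sensitivity=d.get("sensitivity"),
                   curvatures_um=list(d.get("curvatures_um", [])),
                   diameters_um=list(d.get("diameters_um", [])),
                   registration_offset=tuple(off) if off is not None else None)

    @classmethod
    def load_json(cls, path) -> "MetricsReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
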