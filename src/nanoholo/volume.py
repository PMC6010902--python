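"""The universal 3D scalar-grid carrier used by every pipeline stage.

Axis convention: 0-based voxel indices in ``(z, y, x)`` order, where ``z``
is the tomographic slice axis.  Spacing is a single scalar in nanometres
per voxel (isotropic voxels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume3D"]


@dataclass
class Volume3D:
    """Scalar voxel grid with isotropic spacing and a physical origin.

    Parameters
    ----------
    voxels:
        3D array in ``(z, y, x)`` order.  Any scalar dtype.
    spacing:
        Edge length of one voxel in nanometres.  Isotropic.
    origin:
        Physical offset of voxel ``(0, 0, 0)`` in nanometres, ``(z, y, x)``.
    """

    voxels: np.ndarray
    spacing: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(c) for c in self.origin)
        if len(self.origin) != 3:
            raise ValueError("origin must have three components")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def dtype(self) -> np.dtype:
        return self.voxels.dtype

    def copy(self) -> "Volume3D":
        return Volume3D(self.voxels.copy(), self.spacing, self.origin)

    def astype(self, dtype) -> "Volume3D":
        return Volume3D(self.voxels.astype(dtype), self.spacing, self.origin)

    def with_voxels(self, voxels: np.ndarray) -> "Volume3D":
        """New volume sharing this volume's geometry (shape may differ)."""
        return Volume3D(np.asarray(voxels), self.spacing, self.origin)

    def assert_finite(self) -> None:
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")

    def congruent_with(self, other: "Volume3D") -> bool:
        """Same shape and spacing (geometric congruence of label/intensity pairs)."""
        return self.shape == other.shape and np.isclose(self.spacing, other.spacing)
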