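"""Core geometry types: axis-aligned 3D voxel grids and millimetre displacements.

All arrays are ordered (LR, AP, SI) — patient left-right, anterior-posterior,
superior-inferior. World coordinates are millimetres; the world position of
voxel (i, j, k) is ``origin + index * spacing`` (axis-aligned grids only, no
rotation support: the matcher estimates translations exclusively).

Sign convention, stated once and used everywhere: a displacement ``d`` maps
the prostate position in the reference scan onto its position in the guide
scan (GPV = RPV + d). The couch correction is ``-d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid3D", "BinaryMask3D", "Displacement3D", "AXIS_NAMES"]

AXIS_NAMES = ("LR", "AP", "SI")


@dataclass(frozen=True)
class Displacement3D:
    """A rigid translation in mm on patient axes (LR, AP, SI)."""

    d_lr: float
    d_ap: float
    d_si: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("displacement components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.d_lr, self.d_ap, self.d_si], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Displacement3D":
        a = np.asarray(a, dtype=float)
        if a.shape != (3,):
            raise ValueError(f"expected 3 components, got shape {a.shape}")
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def norm(self) -> float:
        return float(np.linalg.norm(self.as_array()))

    def __add__(self, other: "Displacement3D") -> "Displacement3D":
        return Displacement3D.from_array(self.as_array() + other.as_array())

    def __sub__(self, other: "Displacement3D") -> "Displacement3D":
        return Displacement3D.from_array(self.as_array() - other.as_array())

    def __neg__(self) -> "Displacement3D":
        return Displacement3D(-self.d_lr, -self.d_ap, -self.d_si)


@dataclass
class VoxelGrid3D:
    """A 3D scalar volume with spacing and origin in mm on (LR, AP, SI) axes."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.values.ndim}")
        self.spacing_mm = np.broadcast_to(
            np.asarray(self.spacing_mm, dtype=float), (3,)
        ).copy()
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing must be positive on every axis")
        if self.origin_mm is None:
            self.origin_mm = np.zeros(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3).copy()
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def world_to_index(self, world_mm) -> np.ndarray:
        """Continuous voxel index of a world position."""
        return (np.asarray(world_mm, dtype=float) - self.origin_mm) / self.spacing_mm

    def index_to_world(self, index) -> np.ndarray:
        return self.origin_mm + np.asarray(index, dtype=float) * self.spacing_mm

    def same_geometry(self, other: "VoxelGrid3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )


class BinaryMask3D(VoxelGrid3D):
    """A boolean 3D mask carrying the same geometry contract as a volume."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        super().__post_init__()

    def count(self) -> int:
        return int(self.values.sum())

    def bounding_box(self) -> tuple:
        """(lo, hi) inclusive voxel index corners of the nonzero extent."""
        if not self.values.any():
            raise ValueError("mask is empty")
        idx = np.nonzero(self.values)
        lo = np.array([a.min() for a in idx])
        hi = np.array([a.max() for a in idx])
        return lo, hi
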