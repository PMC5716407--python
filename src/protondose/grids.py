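"""Dose / detector-output grids with per-voxel statistical variance."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["DoseGrid", "save_grids", "load_grids"]


@dataclass
class DoseGrid:
    """Per-voxel accumulated dose (or detector output) on a regular grid.

    ``variance`` is the statistical variance of the per-voxel total estimated
    by the batch method; ``n_batches`` records how many batches produced it.
    """

    dose: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    variance: np.ndarray | None = None
    n_histories: int = 0
    n_batches: int = 0
    _interp: RegularGridInterpolator = field(default=None, repr=False, compare=False)
    _vinterp: RegularGridInterpolator = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=np.float64)
        if self.dose.ndim != 3:
            raise ValueError("dose must be 3-D")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")
        if self.variance is None:
            self.variance = np.zeros_like(self.dose)
        self.variance = np.asarray(self.variance, dtype=np.float64)
        if self.variance.shape != self.dose.shape:
            raise ValueError("variance shape must match dose shape")
        if np.any(self.variance < 0):
            raise ValueError("variance must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.dose.shape

    def axes(self):
        return tuple(
            self.origin[i] + np.arange(self.shape[i]) * self.voxel_size[i] for i in range(3)
        )

    def same_geometry(self, other: "DoseGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )

    def value_at(self, point) -> float:
        """Trilinear interpolation; 0 outside the grid."""
        if self._interp is None:
            self._interp = RegularGridInterpolator(
                self.axes(), self.dose, bounds_error=False, fill_value=0.0
            )
        return float(self._interp(np.asarray(point, dtype=float))[0])

    def variance_at(self, point) -> float:
        if self._vinterp is None:
            self._vinterp = RegularGridInterpolator(
                self.axes(), self.variance, bounds_error=False, fill_value=0.0
            )
        return float(self._vinterp(np.asarray(point, dtype=float))[0])

    def scaled(self, k: float) -> "DoseGrid":
        return DoseGrid(
            self.dose * k,
            self.voxel_size,
            self.origin,
            variance=self.variance * k * k,
            n_histories=self.n_histories,
            n_batches=self.n_batches,
        )


def save_grids(path, **grids) -> None:
    """Persist named grids (geometry + dose + variance) to an HDF5 file."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name, g in grids.items():
            grp = fh.create_group(name)
            grp.create_dataset("dose", data=g.dose, compression="gzip")
            grp.create_dataset("variance", data=g.variance, compression="gzip")
            grp.attrs["voxel_size"] = g.voxel_size
            grp.attrs["origin"] = g.origin
            grp.attrs["n_histories"] = g.n_histories
            grp.attrs["n_batches"] = g.n_batches


def load_grids(path) -> dict[str, DoseGrid]:
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        for name, grp in fh.items():
            out[name] = DoseGrid(
                grp["dose"][...],
                tuple(grp.attrs["voxel_size"]),
                tuple(grp.attrs["origin"]),
                variance=grp["variance"][...],
                n_histories=int(grp.attrs["n_histories"]),
                n_batches=int(grp.attrs["n_batches"]),
            )
    return out
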