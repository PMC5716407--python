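"""Voxel phantoms of relative stopping power and water-equivalent path evaluation.

Coordinate convention (nowhere else restated): positions in mm, beam axis +z,
voxel indices 0-based, a voxel owns the half-open cube centred on its centre.
The default in-plane voxel pitch is 0.586 mm with 3 mm slices; the dose
calculation grid is the phantom grid downsampled 2x in-plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .materials import AIR, CORTICAL_BONE, Material, SOFT_TISSUE

__all__ = [
    "VoxelPhantom",
    "DEFAULT_VOXEL",
    "make_water_tank",
    "make_slab_phantom",
    "make_head_like",
    "wed_along_ray",
    "calc_grid_geometry",
]

DEFAULT_VOXEL = (0.586, 0.586, 3.0)


@dataclass
class VoxelPhantom:
    """3-D raster of relative stopping power.

    ``rsp`` has shape (nx, ny, nz); ``origin`` is the mm position of the
    centre of voxel (0, 0, 0).
    """

    rsp: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL
    origin: tuple[float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.rsp = np.ascontiguousarray(self.rsp, dtype=np.float64)
        if self.rsp.ndim != 3:
            raise ValueError("rsp must be a 3-D array")
        if np.any(self.rsp < 0):
            raise ValueError("rsp must be non-negative")
        vs = np.asarray(self.voxel_size, dtype=float)
        if vs.shape != (3,) or np.any(vs <= 0):
            raise ValueError("voxel_size must be three positive numbers")
        self.voxel_size = tuple(vs)
        if self.origin is None:
            # centre the grid on x = y = 0 with the first slice centred at z = vz/2
            nx, ny, _ = self.rsp.shape
            self.origin = (
                -(nx - 1) / 2.0 * vs[0],
                -(ny - 1) / 2.0 * vs[1],
                vs[2] / 2.0,
            )
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.rsp.shape

    @property
    def lower_corner(self) -> np.ndarray:
        return np.asarray(self.origin) - 0.5 * np.asarray(self.voxel_size)

    @property
    def upper_corner(self) -> np.ndarray:
        return self.lower_corner + np.asarray(self.shape) * np.asarray(self.voxel_size)

    @property
    def isocenter(self) -> np.ndarray:
        """Geometric centre of the grid (the prescription point by convention)."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.voxel_size
        )

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.lower_corner) and np.all(p < self.upper_corner))

    def voxel_index(self, point) -> tuple[int, int, int]:
        p = np.asarray(point, dtype=float)
        idx = np.floor((p - self.lower_corner) / np.asarray(self.voxel_size)).astype(int)
        return tuple(idx)

    def rsp_at(self, point) -> float:
        if not self.contains(point):
            raise ValueError(f"point {point} outside phantom")
        return float(self.rsp[self.voxel_index(point)])

    def save(self, path_prefix: str) -> None:
        """Persist as flat float64 raster ``<prefix>.raw`` + JSON sidecar ``<prefix>.json``."""
        self.rsp.astype(np.float64).tofile(f"{path_prefix}.raw")
        sidecar = {
            "shape": list(self.shape),
            "voxel_size": list(self.voxel_size),
            "origin": list(self.origin),
            "dtype": "float64",
            "order": "C",
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path_prefix: str) -> "VoxelPhantom":
        with open(f"{path_prefix}.json") as fh:
            sidecar = json.load(fh)
        arr = np.fromfile(f"{path_prefix}.raw", dtype=sidecar["dtype"]).reshape(sidecar["shape"])
        return cls(arr, tuple(sidecar["voxel_size"]), tuple(sidecar["origin"]))


def make_water_tank(shape, voxel_size=DEFAULT_VOXEL, origin=None) -> VoxelPhantom:
    """Homogeneous rsp = 1 phantom used as the reference medium."""
    if any(s <= 0 for s in shape):
        raise ValueError("shape must be positive")
    return VoxelPhantom(np.ones(tuple(shape)), voxel_size, origin)


def make_slab_phantom(base: VoxelPhantom, inserts) -> VoxelPhantom:
    """Override boxes of a phantom with insert materials.

    ``inserts`` is a list of ``(box_min_mm, box_max_mm, material_or_rsp)``;
    voxels whose centres fall inside a box (half-open, [min, max)) take the
    insert rsp, with later inserts overriding earlier ones.
    """
    rsp = base.rsp.copy()
    lo_ph, hi_ph = base.lower_corner, base.upper_corner
    centers = [
        base.origin[i] + np.arange(base.shape[i]) * base.voxel_size[i] for i in range(3)
    ]
    for box_min, box_max, mat in inserts:
        bmin = np.asarray(box_min, dtype=float)
        bmax = np.asarray(box_max, dtype=float)
        if np.any(bmin >= bmax):
            raise ValueError(f"degenerate insert box {box_min}..{box_max}")
        if np.any(bmin < lo_ph - 1e-9) or np.any(bmax > hi_ph + 1e-9):
            raise ValueError(f"insert box {box_min}..{box_max} outside phantom bounds")
        value = mat.rsp if isinstance(mat, Material) else float(mat)
        masks = [
            (centers[i] >= bmin[i]) & (centers[i] < bmax[i]) for i in range(3)
        ]
        rsp[np.ix_(*[np.where(m)[0] for m in masks])] = value
    return VoxelPhantom(rsp, base.voxel_size, base.origin)


def make_head_like(
    seed: int = 0,
    shape=(136, 136, 100),
    voxel_size=DEFAULT_VOXEL,
) -> VoxelPhantom:
    """Synthetic head-like heterogeneous phantom (deterministic for a seed).

    Soft-tissue ellipsoid in a water bath, a cortical-bone jaw arc, an air
    oral cavity and a lateral half-field bone plate; irradiated along +z all
    of these perturb the distal edge. Not a reconstruction of any real
    anatomy — an analogue built to exercise lateral heterogeneity.
    """
    rng = np.random.default_rng(seed)
    ph = make_water_tank(shape, voxel_size)
    rsp = ph.rsp
    vs = np.asarray(voxel_size)
    nx, ny, nz = shape
    xs = ph.origin[0] + np.arange(nx) * vs[0]
    ys = ph.origin[1] + np.arange(ny) * vs[1]
    zs = ph.origin[2] + np.arange(nz) * vs[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    z_extent = nz * vs[2]

    jit = lambda s: float(rng.uniform(-s, s))  # noqa: E731  small positional jitter

    # soft-tissue ellipsoid spanning most of the volume
    cx, cy, cz = jit(1.0), jit(1.0), z_extent * 0.5 + jit(2.0)
    ax, ay, az = 0.44 * nx * vs[0], 0.44 * ny * vs[1], 0.48 * z_extent
    ell = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0
    rsp[ell] = SOFT_TISSUE.rsp

    # cortical-bone jaw arc: half annulus in-plane over a band of slices
    R = np.hypot(X - cx, Y - cy)
    r_in, r_out = 22.0 + jit(0.5), 29.0 + jit(0.5)
    z0, z1 = 0.28 * z_extent + jit(2.0), 0.40 * z_extent + jit(2.0)
    arc = (R >= r_in) & (R <= r_out) & (Y - cy < 0) & (Z >= z0) & (Z <= z1)
    rsp[arc] = CORTICAL_BONE.rsp

    # air oral cavity box
    acx, acy = jit(2.0), -8.0 + jit(2.0)
    acz = 0.34 * z_extent + jit(2.0)
    cav = (
        (np.abs(X - acx) <= 9.0)
        & (np.abs(Y - acy) <= 9.0)
        & (np.abs(Z - acz) <= 8.0)
    )
    rsp[cav] = AIR.rsp

    # lateral half-field bone plate: covers x > edge over a thin z slab
    edge = jit(1.5)
    pz0 = 0.52 * z_extent + jit(2.0)
    plate = (X >= edge) & (Z >= pz0) & (Z <= pz0 + 6.0)
    rsp[plate] = CORTICAL_BONE.rsp

    return VoxelPhantom(rsp, voxel_size, ph.origin)


def wed_along_ray(phantom: VoxelPhantom, entry, direction, step: float = 0.5):
    """Cumulative water-equivalent depth along a straight ray.

    Samples rsp at segment midpoints every ``step`` mm from ``entry`` until
    the ray leaves the phantom; returns ``(geometric_depths, wed)`` arrays of
    cumulative values at segment ends.
    """
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    if step <= 0:
        raise ValueError("step must be > 0")
    p = np.asarray(entry, dtype=float)
    if not phantom.contains(p):
        raise ValueError(f"entry point {entry} outside phantom")

    lo, hi = phantom.lower_corner, phantom.upper_corner
    # max traversal: diagonal of the bounding box
    n_max = int(np.ceil(np.linalg.norm(hi - lo) / step)) + 2
    ks = np.arange(n_max)
    mids = p[None, :] + (ks[:, None] + 0.5) * step * d[None, :]
    inside = np.all((mids >= lo) & (mids < hi), axis=1)
    if not inside[0]:
        return np.array([]), np.array([])
    n = int(np.argmin(inside)) if not inside.all() else n_max
    mids = mids[:n]
    idx = np.floor((mids - lo) / np.asarray(phantom.voxel_size)).astype(int)
    rsp = phantom.rsp[idx[:, 0], idx[:, 1], idx[:, 2]]
    geo = (ks[:n] + 1) * step
    return geo, np.cumsum(rsp * step)


def calc_grid_geometry(phantom: VoxelPhantom, factor: int = 2):
    """Dose-grid geometry: phantom grid downsampled ``factor``x in-plane.

    Returns ``(shape, voxel_size, origin)`` with origin at the centre of the
    first (merged) dose voxel.
    """
    nx, ny, nz = phantom.shape
    vs = np.asarray(phantom.voxel_size)
    gshape = (nx // factor, ny // factor, nz)
    gvs = (vs[0] * factor, vs[1] * factor, vs[2])
    lo = phantom.lower_corner
    gorigin = (lo[0] + gvs[0] / 2.0, lo[1] + gvs[1] / 2.0, lo[2] + gvs[2] / 2.0)
    return gshape, gvs, gorigin
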