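"""Simplified Monte Carlo proton transport on voxel phantoms.

Each history carries (position, direction, residual range in water). Energy
loss per step comes from the water-equivalent model (rsp x geometric step)
and the deposit is read off the measured/synthetic broad-beam depth curve at
the depth corresponding to the proton's residual range. Multiple Coulomb
scattering is sampled per step as two normal projection angles with the
Highland width. Every trajectory is scored twice — against the depth-dose
curve (PPIC grid) and the depth-output curve (MOSFET grid) — so the two grids
are exactly paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .curves import DepthCurve
from .grids import DoseGrid
from .phantoms import VoxelPhantom, calc_grid_geometry

__all__ = [
    "ProtonState",
    "BeamSpec",
    "sample_source",
    "transport_proton",
    "run_smc",
    "statistical_error",
    "highland_sigma",
    "fermi_eyges_sigma",
]

_MP = 938.27208816
_X0_WATER = 360.8  # radiation length of water, mm
_HIGHLAND_E = 14.1  # MeV
_RANGE_ALPHA = 0.022
_RANGE_P = 1.77
_E_FLOOR = 0.5  # MeV floor when evaluating pv near end of range


@dataclass
class ProtonState:
    """Position (mm), unit direction, residual range in water (mm)."""

    position: np.ndarray
    direction: np.ndarray
    residual_range: float

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.residual_range < 0:
            raise ValueError("residual_range must be >= 0")


@dataclass(frozen=True)
class BeamSpec:
    """Broad-beam description: range, modulation, upstream absorbers, source model.

    ``angular_sigma`` is the standard deviation (radians) of each projection
    slope of the initial direction at the entrance plane (the effective source
    model); ``field_radius`` is a hard aperture on the entrance fluence.
    """

    nominal_range: float
    sobp_width: float = 0.0
    range_shifter: float = 0.0
    field_radius: float = 25.0
    angular_sigma: float = 0.003
    source_to_isocenter: float = 2000.0

    def __post_init__(self):
        if self.field_radius <= 0:
            raise ValueError("field_radius must be > 0")
        if self.angular_sigma < 0:
            raise ValueError("angular_sigma must be >= 0")
        if self.nominal_range <= 0:
            raise ValueError("nominal_range must be > 0")
        if self.range_shifter < 0 or self.sobp_width < 0:
            raise ValueError("range_shifter and sobp_width must be >= 0")

    @property
    def entrance_residual_range(self) -> float:
        """Residual range at the phantom entrance: nominal minus shifter WET."""
        return self.nominal_range - self.range_shifter


def sample_source(beam: BeamSpec, n: int, rng, entrance_z: float = 0.0):
    """Sample n histories at the entrance plane.

    Positions are uniform over the circular aperture (uniform fluence);
    direction slopes are independent normals of sd ``angular_sigma`` about +z;
    initial residual range is ``nominal_range - range_shifter``.

    Returns ``(positions (n,3), directions (n,3), residual_ranges (n,))``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    r = beam.field_radius * np.sqrt(rng.random(n))
    phi = rng.random(n) * 2.0 * np.pi
    pos = np.empty((n, 3))
    pos[:, 0] = r * np.cos(phi)
    pos[:, 1] = r * np.sin(phi)
    pos[:, 2] = entrance_z
    sx = rng.normal(0.0, beam.angular_sigma, n) if beam.angular_sigma > 0 else np.zeros(n)
    sy = rng.normal(0.0, beam.angular_sigma, n) if beam.angular_sigma > 0 else np.zeros(n)
    dirs = np.stack([sx, sy, np.ones(n)], axis=1)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    res = np.full(n, beam.entrance_residual_range)
    if beam.entrance_residual_range <= 0:
        raise ValueError("range shifter thicker than the nominal range")
    return pos, dirs, res


def _pv(residual_range: float) -> float:
    e = (max(residual_range, _RANGE_ALPHA * _E_FLOOR**_RANGE_P) / _RANGE_ALPHA) ** (
        1.0 / _RANGE_P
    )
    return e * (e + 2.0 * _MP) / (e + _MP)


def highland_sigma(residual_range: float, wed_step: float) -> float:
    """Highland projection-angle sd (radians) for one water-equivalent step."""
    if wed_step <= 0:
        return 0.0
    return _HIGHLAND_E / _pv(residual_range) * np.sqrt(wed_step / _X0_WATER)


def fermi_eyges_sigma(depth_mm, initial_residual_range: float, step: float = 0.5):
    """Analytic lateral spread sqrt(A2) in water at the given depth(s).

    Independent accumulation of the same per-unit-length scattering power the
    transport samples from: A2(z) = int_0^z T(z') (z - z')^2 dz'.
    """
    zq = np.atleast_1d(np.asarray(depth_mm, dtype=float))
    zmax = float(zq.max())
    zp = np.arange(0.5 * step, zmax, step)
    t = np.array(
        [(_HIGHLAND_E / _pv(initial_residual_range - z)) ** 2 / _X0_WATER for z in zp]
    )
    out = np.array([np.sum(t[zp < z] * (z - zp[zp < z]) ** 2) * step for z in zq])
    out = np.sqrt(out)
    return float(out[0]) if np.isscalar(depth_mm) else out


def _curve_table(curve: DepthCurve, tab_step: float = 0.25):
    zmax = float(curve.depths[-1])
    grid = np.arange(0.0, zmax + tab_step, tab_step)
    return np.ascontiguousarray(curve.lookup(grid)), tab_step


@njit(cache=True)
def _transport_batch(
    pos,
    dirs,
    res,
    rsp,
    plo,
    pvs,
    dd_tab,
    do_tab,
    tab_step,
    curve_range,
    step,
    glo,
    gvs,
    gnx,
    gny,
    gnz,
    dose,
    outp,
    seed,
):  # pragma: no cover - exercised via run_smc
    np.random.seed(seed)
    nx, ny, nz = rsp.shape
    ntab = dd_tab.shape[0]
    for i in range(pos.shape[0]):
        x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
        dx, dy, dz = dirs[i, 0], dirs[i, 1], dirs[i, 2]
        r = res[i]
        while r > 0.0:
            # midpoint of the candidate step
            h = step
            mx = x + 0.5 * h * dx
            my = y + 0.5 * h * dy
            mz = z + 0.5 * h * dz
            ix = int((mx - plo[0]) / pvs[0])
            iy = int((my - plo[1]) / pvs[1])
            iz = int((mz - plo[2]) / pvs[2])
            if (
                ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz
                or mx < plo[0] or my < plo[1] or mz < plo[2]
            ):
                break
            rv = rsp[ix, iy, iz]
            dwed = rv * h
            if dwed >= r:
                # final partial step: stop exactly at range exhaustion
                if rv > 0.0:
                    h = r / rv
                dwed = r
            depth = curve_range - r + 0.5 * dwed
            # linear interpolation on the resampled curve tables
            t = depth / tab_step
            if t <= 0.0:
                dd_v = dd_tab[0]
                do_v = do_tab[0]
            elif t >= ntab - 1:
                dd_v = 0.0
                do_v = 0.0
            else:
                j = int(t)
                f = t - j
                dd_v = dd_tab[j] * (1.0 - f) + dd_tab[j + 1] * f
                do_v = do_tab[j] * (1.0 - f) + do_tab[j + 1] * f
            gx = int((mx - glo[0]) / gvs[0])
            gy = int((my - glo[1]) / gvs[1])
            gz = int((mz - glo[2]) / gvs[2])
            if 0 <= gx < gnx and 0 <= gy < gny and 0 <= gz < gnz:
                dose[gx, gy, gz] += dd_v * dwed
                outp[gx, gy, gz] += do_v * dwed
            x += h * dx
            y += h * dy
            z += h * dz
            r -= dwed
            if r <= 0.0:
                break
            # Highland multiple-scattering kick for the traversed step
            e = (max(r, 0.0064) / 0.022) ** (1.0 / 1.77)
            pv = e * (e + 2.0 * 938.27208816) / (e + 938.27208816)
            th0 = 14.1 / pv * np.sqrt(dwed / 360.8)
            tx = np.random.normal(0.0, 1.0) * th0
            ty = np.random.normal(0.0, 1.0) * th0
            # orthonormal transverse basis
            nrm = np.sqrt(dx * dx + dz * dz)
            if nrm > 1e-9:
                e1x, e1y, e1z = dz / nrm, 0.0, -dx / nrm
            else:
                e1x, e1y, e1z = 1.0, 0.0, 0.0
            e2x = dy * e1z - dz * e1y
            e2y = dz * e1x - dx * e1z
            e2z = dx * e1y - dy * e1x
            dx += tx * e1x + ty * e2x
            dy += tx * e1y + ty * e2y
            dz += tx * e1z + ty * e2z
            inv = 1.0 / np.sqrt(dx * dx + dy * dy + dz * dz)
            dx *= inv
            dy *= inv
            dz *= inv


def transport_proton(
    state: ProtonState,
    phantom: VoxelPhantom,
    dd: DepthCurve,
    do: DepthCurve,
    step: float = 1.0,
    rng=None,
):
    """Reference single-history transport; returns [(voxel index, dose, output), ...].

    Voxel indices refer to the phantom grid. With ``rng=None`` scattering is
    switched off (straight-line transport), which the tests use to compare
    deposits against direct curve evaluation.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if step > min(phantom.voxel_size):
        warnings.warn("step exceeds the smallest voxel dimension; accuracy reduced", stacklevel=2)
    curve_range = dd.full_range
    p = state.position.copy()
    d = state.direction.copy()
    r = float(state.residual_range)
    lo = phantom.lower_corner
    hi = phantom.upper_corner
    vs = np.asarray(phantom.voxel_size)
    deposits = []
    while r > 0:
        h = step
        mid = p + 0.5 * h * d
        if np.any(mid < lo) or np.any(mid >= hi):
            break
        idx = tuple(np.floor((mid - lo) / vs).astype(int))
        rv = float(phantom.rsp[idx])
        dwed = rv * h
        if dwed >= r:
            if rv > 0:
                h = r / rv
            dwed = r
        depth = curve_range - r + 0.5 * dwed
        deposits.append((idx, dd.lookup(depth) * dwed, do.lookup(depth) * dwed))
        p = p + h * d
        r -= dwed
        if r <= 0:
            break
        if rng is not None:
            th0 = highland_sigma(r, dwed)
            tx, ty = rng.normal(0.0, th0, 2) if th0 > 0 else (0.0, 0.0)
            nrm = np.hypot(d[0], d[2])
            e1 = np.array([d[2] / nrm, 0.0, -d[0] / nrm]) if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
            e2 = np.cross(d, e1)
            d = d + tx * e1 + ty * e2
            d /= np.linalg.norm(d)
    return deposits


def run_smc(
    phantom: VoxelPhantom,
    beam: BeamSpec,
    dd: DepthCurve,
    do: DepthCurve,
    n: int,
    seed: int,
    batches: int = 10,
    step: float = 1.0,
    calc_factor: int = 2,
    normalize_point=None,
    normalize_value: float = 100.0,
):
    """Run n histories, scoring PPIC and MOSFET grids from the same trajectories.

    Histories are split into ``batches`` batches; per-voxel statistical
    variance of the total comes from the spread of batch totals. Both grids
    are rescaled by one common factor so the PPIC dose at ``normalize_point``
    (default: beam axis, mid-modulation depth) equals ``normalize_value``.

    Bit-reproducible for fixed (seed, n, batches, step).
    """
    if batches < 2 or n < batches:
        raise ValueError("need n >= batches >= 2")
    if dd.kind != "dose" or do.kind != "output":
        raise ValueError("expected a dose curve and an output curve")
    if step > min(phantom.voxel_size):
        warnings.warn("step exceeds the smallest voxel dimension; accuracy reduced", stacklevel=2)

    gshape, gvs, gorigin = calc_grid_geometry(phantom, calc_factor)
    glo = np.asarray(gorigin) - 0.5 * np.asarray(gvs)
    dd_tab, tab_step = _curve_table(dd)
    do_tab, _ = _curve_table(do)
    if do_tab.shape != dd_tab.shape:
        m = min(dd_tab.shape[0], do_tab.shape[0])
        dd_tab, do_tab = dd_tab[:m], do_tab[:m]

    dose_sum = np.zeros(gshape)
    dose_sq = np.zeros(gshape)
    out_sum = np.zeros(gshape)
    out_sq = np.zeros(gshape)
    bdose = np.empty(gshape)
    bout = np.empty(gshape)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(batches)
    counts = np.full(batches, n // batches)
    counts[: n % batches] += 1
    entrance_z = float(phantom.lower_corner[2])
    plo = phantom.lower_corner

    for k in range(batches):
        src_ss, kick_ss = children[k].spawn(2)
        pos, dirs, res = sample_source(beam, int(counts[k]), np.random.default_rng(src_ss), entrance_z)
        bdose[:] = 0.0
        bout[:] = 0.0
        _transport_batch(
            pos,
            dirs,
            res,
            phantom.rsp,
            plo,
            np.asarray(phantom.voxel_size),
            dd_tab,
            do_tab,
            tab_step,
            dd.full_range,
            step,
            glo,
            np.asarray(gvs),
            gshape[0],
            gshape[1],
            gshape[2],
            bdose,
            bout,
            int(kick_ss.generate_state(1)[0]),
        )
        dose_sum += bdose
        dose_sq += bdose**2
        out_sum += bout
        out_sq += bout**2

    def _grid(total, sq):
        # variance of the total from the batch spread
        var = batches / (batches - 1.0) * np.maximum(sq - total**2 / batches, 0.0)
        return DoseGrid(total, gvs, gorigin, variance=var, n_histories=n, n_batches=batches)

    ppic = _grid(dose_sum, dose_sq)
    mosfet = _grid(out_sum, out_sq)

    if normalize_point is None:
        r_eff = beam.entrance_residual_range
        z_cal = r_eff - beam.sobp_width / 2.0 if beam.sobp_width > 0 else 0.5 * r_eff
        normalize_point = (0.0, 0.0, entrance_z + z_cal)
    ref = ppic.value_at(normalize_point)
    if ref <= 0:
        raise ValueError(f"zero dose at normalization point {normalize_point}")
    k = normalize_value / ref
    return ppic.scaled(k), mosfet.scaled(k)


def statistical_error(grid: DoseGrid, region: np.ndarray) -> float:
    """Per-voxel relative batch standard error, rms over the region, in percent."""
    if grid.n_batches < 2:
        raise ValueError("statistical error needs at least 2 batches")
    region = np.asarray(region, dtype=bool)
    if region.shape != grid.shape:
        raise ValueError("region mask shape must match the grid")
    if not region.any():
        raise ValueError("region is empty")
    d = grid.dose[region]
    if np.any(d <= 0):
        raise ValueError("region contains voxels with zero dose")
    rel = np.sqrt(grid.variance[region]) / d * 100.0
    return float(np.sqrt(np.mean(rel**2)))
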