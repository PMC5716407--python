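"""Correction factors, detector calibration, simulated readings, uncertainties.

The correction factor at a point is the ratio of the computed dose grid to
the computed detector-output grid there; multiplying the raw detector dose by
it removes the LET dependence of the response. The legacy alternative is a
correction factor tabulated purely against penetration depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .curves import DepthCurve
from .grids import DoseGrid

__all__ = [
    "OutOfFieldError",
    "CalibrationRecord",
    "CorrectionResult",
    "calibrate",
    "raw_dose",
    "cf_smc",
    "cf_pba",
    "cf_depth",
    "simulate_measurement",
    "setup_uncertainty",
    "cf_setup_halfwidth",
    "total_uncertainty",
    "correct_point",
]


class OutOfFieldError(ValueError):
    """Raised when a point lies outside the useful field of a grid."""


@dataclass(frozen=True)
class CalibrationRecord:
    """Dose calibration: factor (cGy/mV) from repeated exposures at a known dose."""

    readings: tuple
    delivered_dose: float
    factor: float


@dataclass(frozen=True)
class CorrectionResult:
    point: tuple
    cf: float
    raw_dose: float
    corrected_dose: float
    cf_uncertainty: float
    dose_uncertainty: float
    method: str


def calibrate(readings, delivered: float = 200.0) -> CalibrationRecord:
    """Calibration factor from the mean of repeated readings (default protocol:
    five exposures of 200 cGy)."""
    r = np.asarray(readings, dtype=float)
    if r.size == 0 or np.any(r <= 0):
        raise ValueError("readings must be positive")
    return CalibrationRecord(tuple(r), float(delivered), float(delivered / r.mean()))


def raw_dose(reading: float, record: CalibrationRecord) -> float:
    """Raw (uncorrected) dose: reading (mV) times the calibration factor."""
    if reading <= 0:
        raise ValueError("reading must be positive")
    return reading * record.factor


def _grid_ratio(num: DoseGrid, den: DoseGrid, point) -> float:
    if not num.same_geometry(den):
        raise ValueError("grids do not share geometry")
    d = den.value_at(point)
    if d < 0.01 * den.dose.max():
        raise OutOfFieldError(f"point {tuple(point)} is out of field (denominator too small)")
    return num.value_at(point) / d


def cf_smc(smc_ppic: DoseGrid, smc_mosfet: DoseGrid, point) -> float:
    """Monte Carlo correction factor: interpolated dose / interpolated output."""
    return _grid_ratio(smc_ppic, smc_mosfet, point)


def cf_pba(pba_ppic: DoseGrid, pba_mosfet: DoseGrid, point) -> float:
    """Pencil-beam correction factor; same ratio on the deterministic grids."""
    return _grid_ratio(pba_ppic, pba_mosfet, point)


def cf_depth(dd: DepthCurve, do: DepthCurve, depth: float) -> float:
    """Legacy correction factor as a function of penetration depth only."""
    d = do.lookup(depth)
    if d <= 0:
        raise ValueError(f"depth {depth} mm beyond the output curve")
    return dd.lookup(depth) / d


def simulate_measurement(
    output_grid: DoseGrid,
    record: CalibrationRecord,
    point,
    rng=None,
    noise_sd: float = 0.0,
) -> float:
    """Synthetic detector reading (mV) at a point.

    The output grid already embodies the detector response model, so the
    reading is the response-weighted dose divided by the calibration factor,
    optionally degraded by multiplicative Gaussian noise. With zero noise the
    correction-factor pipeline recovers the true dose up to statistical error.
    """
    v = output_grid.value_at(point)
    if v < 0.01 * output_grid.dose.max():
        raise OutOfFieldError(f"point {tuple(point)} is out of field")
    reading = v / record.factor
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        reading *= 1.0 + rng.normal(0.0, noise_sd)
    return reading


def _cavity_lattice(point, diameter: float, pitch: float):
    r = diameter / 2.0
    t = np.arange(-r, r + pitch / 2, pitch)
    X, Y, Z = np.meshgrid(t, t, t, indexing="ij")
    keep = X**2 + Y**2 + Z**2 <= r**2
    p = np.asarray(point, dtype=float)
    return np.stack([X[keep] + p[0], Y[keep] + p[1], Z[keep] + p[2]], axis=1)


def setup_uncertainty(
    grid: DoseGrid, point, cavity_diameter: float = 5.0, pitch: float = 0.25
):
    """(min, max) interpolated dose over a sphere modelling detector setup error.

    The sphere (default 5 mm diameter) is sampled on a lattice of the given
    pitch; lattice points that fall out of field are dropped with a warning.
    """
    axes = grid.axes()
    p = np.asarray(point, dtype=float)
    for i in range(3):
        if not (axes[i][0] <= p[i] <= axes[i][-1]):
            raise ValueError(f"cavity centre {tuple(point)} outside the grid")
    pts = _cavity_lattice(point, cavity_diameter, pitch)
    vals = np.array([grid.value_at(q) for q in pts])
    in_field = vals > 0.01 * grid.dose.max()
    if not in_field.all():
        warnings.warn("cavity extends out of field; extrema taken over the in-field part",
                      stacklevel=2)
    vals = vals[in_field]
    if vals.size == 0:
        raise OutOfFieldError(f"cavity at {tuple(point)} entirely out of field")
    return float(vals.min()), float(vals.max())


def cf_setup_halfwidth(
    num: DoseGrid, den: DoseGrid, point, cavity_diameter: float = 5.0, pitch: float = 0.5
) -> float:
    """Relative half-spread of the correction factor over the setup cavity."""
    pts = _cavity_lattice(point, cavity_diameter, pitch)
    cfs = []
    for q in pts:
        try:
            cfs.append(_grid_ratio(num, den, q))
        except OutOfFieldError:
            continue
    if not cfs:
        raise OutOfFieldError(f"cavity at {tuple(point)} entirely out of field")
    cfs = np.asarray(cfs)
    centre = _grid_ratio(num, den, point)
    return float(max(cfs.max() - centre, centre - cfs.min()) / centre)


def total_uncertainty(setup_halfwidth: float, statistical: float) -> float:
    """Quadrature combination of setup and statistical fractional uncertainties."""
    if setup_halfwidth < 0 or statistical < 0:
        raise ValueError("uncertainties must be >= 0")
    return float(np.sqrt(setup_halfwidth**2 + statistical**2))


def correct_point(
    point,
    reading: float,
    record: CalibrationRecord,
    ppic: DoseGrid,
    mosfet: DoseGrid,
    method: str = "smc",
    cavity_diameter: float = 5.0,
) -> CorrectionResult:
    """Full correction at one point: CF, corrected dose, and its uncertainties.

    The dose uncertainty combines the setup half-width of the dose over the
    cavity with the per-point statistical error (zero for deterministic
    grids); the CF uncertainty is the CF half-spread over the same cavity.
    """
    cf = _grid_ratio(ppic, mosfet, point)
    raw = raw_dose(reading, record)
    dmin, dmax = setup_uncertainty(ppic, point, cavity_diameter)
    centre = ppic.value_at(point)
    setup_hw = max(dmax - centre, centre - dmin) / centre
    stat = np.sqrt(ppic.variance_at(point)) / centre if ppic.n_batches >= 2 else 0.0
    return CorrectionResult(
        point=tuple(float(x) for x in point),
        cf=cf,
        raw_dose=raw,
        corrected_dose=cf * raw,
        cf_uncertainty=cf_setup_halfwidth(ppic, mosfet, point, cavity_diameter),
        dose_uncertainty=total_uncertainty(setup_hw, float(stat)),
        method=method,
    )
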