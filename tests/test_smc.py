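import numpy as np
import pytest

from protondose.curves import apply_response, IDENTITY_RESPONSE
from protondose.grids import DoseGrid
from protondose.phantoms import make_slab_phantom, make_water_tank
from protondose.materials import CORTICAL_BONE
from protondose.smc import (
    BeamSpec,
    ProtonState,
    fermi_eyges_sigma,
    highland_sigma,
    run_smc,
    sample_source,
    statistical_error,
    transport_proton,
)


@pytest.fixture(scope="module")
def tank():
    # 1 mm voxels, 120 mm deep water tank
    return make_water_tank((40, 40, 120), voxel_size=(1.0, 1.0, 1.0))


@pytest.fixture(scope="module")
def dd100():
    from protondose.curves import pristine_bragg

    return pristine_bragg(100.0).normalize()


@pytest.fixture(scope="module")
def do100(dd100):
    from protondose.curves import calibrate_response

    return apply_response(dd100, calibrate_response(dd100))


class TestSampleSource:
    def test_zero_angular_sigma_all_forward(self):
        beam = BeamSpec(nominal_range=100.0, field_radius=10.0, angular_sigma=0.0)
        _, dirs, _ = sample_source(beam, 1000, 42)
        assert np.allclose(dirs[:, :2], 0.0)
        assert np.allclose(dirs[:, 2], 1.0)

    def test_mean_slope_clt_bound(self):
        sigma = 0.004
        n = 100_000
        beam = BeamSpec(nominal_range=100.0, field_radius=10.0, angular_sigma=sigma)
        _, dirs, _ = sample_source(beam, n, 7)
        slopes = dirs[:, 0] / dirs[:, 2]
        assert abs(slopes.mean()) < 4.0 * sigma / np.sqrt(n)
        assert np.std(slopes) == pytest.approx(sigma, rel=0.05)

    def test_determinism(self):
        beam = BeamSpec(nominal_range=100.0, field_radius=10.0)
        a = sample_source(beam, 100, 3)
        b = sample_source(beam, 100, 3)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_positions_within_aperture(self):
        beam = BeamSpec(nominal_range=100.0, field_radius=7.0)
        pos, _, _ = sample_source(beam, 5000, 1)
        assert np.all(np.hypot(pos[:, 0], pos[:, 1]) <= 7.0)

    def test_residual_range_subtracts_shifter(self):
        beam = BeamSpec(nominal_range=100.0, range_shifter=7.5, field_radius=10.0)
        _, _, res = sample_source(beam, 10, 1)
        assert np.all(res == 100.0 - 7.5)

    def test_bad_n(self):
        beam = BeamSpec(nominal_range=100.0, field_radius=10.0)
        with pytest.raises(ValueError):
            sample_source(beam, 0, 1)

    def test_shifter_thicker_than_range(self):
        beam = BeamSpec(nominal_range=10.0, range_shifter=20.0, field_radius=5.0)
        with pytest.raises(ValueError):
            sample_source(beam, 10, 1)


class TestTransportProton:
    def test_water_no_scatter_reproduces_curve(self, tank, dd100, do100):
        entry = np.array([0.0, 0.0, tank.lower_corner[2] + 1e-9])
        st = ProtonState(entry, np.array([0.0, 0.0, 1.0]), 100.0)
        step = 0.5
        deps = transport_proton(st, tank, dd100, do100, step=step, rng=None)
        for k, (_, dose, _) in enumerate(deps):
            depth = (k + 0.5) * step
            assert dose == pytest.approx(dd100.lookup(depth) * step, abs=step * 0.2)

    def test_zero_residual_range_empty(self, tank, dd100, do100):
        st = ProtonState(tank.isocenter, np.array([0.0, 0.0, 1.0]), 0.0)
        assert transport_proton(st, tank, dd100, do100) == []

    def test_path_length_conserves_range_in_water(self, tank, dd100, do100, rng):
        entry = np.array([0.0, 0.0, tank.lower_corner[2] + 1e-9])
        st = ProtonState(entry, np.array([0.0, 0.0, 1.0]), 100.0)
        deps = transport_proton(st, tank, dd100, do100, step=0.5, rng=rng)
        # total water-equivalent path = number of full steps * step (+ partial)
        assert 0.5 * len(deps) == pytest.approx(100.0, abs=0.5)

    def test_bone_slab_shortens_penetration(self, dd100, do100):
        tank = make_water_tank((20, 20, 120), voxel_size=(1.0, 1.0, 1.0))
        lo = tank.lower_corner
        ph = make_slab_phantom(
            tank,
            [((lo[0], lo[1], lo[2]), (-lo[0], -lo[1], lo[2] + 30.0), CORTICAL_BONE)],
        )
        entry = np.array([0.0, 0.0, lo[2] + 1e-9])
        d = np.array([0.0, 0.0, 1.0])
        deps_w = transport_proton(ProtonState(entry, d, 100.0), tank, dd100, do100, step=0.5)
        deps_b = transport_proton(ProtonState(entry, d, 100.0), ph, dd100, do100, step=0.5)
        # 30 mm of rsp-1.6 bone costs 18 mm extra water depth
        assert len(deps_b) * 0.5 == pytest.approx(len(deps_w) * 0.5 - 18.0, abs=1.0)

    def test_warns_on_coarse_step(self, tank, dd100, do100):
        st = ProtonState(np.array([0.0, 0.0, tank.lower_corner[2] + 1e-9]),
                         np.array([0.0, 0.0, 1.0]), 50.0)
        with pytest.warns(UserWarning, match="step exceeds"):
            transport_proton(st, tank, dd100, do100, step=2.0)


@pytest.fixture(scope="module")
def water_run(tank, dd100, do100):
    beam = BeamSpec(nominal_range=100.0, field_radius=12.0, angular_sigma=0.003)
    return run_smc(tank, beam, dd100, do100, n=120_000, seed=5, batches=6, step=0.5)


class TestRunSMC:
    def test_paired_scoring_mosfet_below_ppic(self, water_run):
        ppic, mosfet = water_run
        assert np.all(mosfet.dose <= ppic.dose * (1.0 + 1e-12))

    def test_bit_reproducible(self, tank, dd100, do100, water_run):
        beam = BeamSpec(nominal_range=100.0, field_radius=12.0, angular_sigma=0.003)
        ppic2, mosfet2 = run_smc(tank, beam, dd100, do100, n=120_000, seed=5, batches=6, step=0.5)
        assert np.array_equal(water_run[0].dose, ppic2.dose)
        assert np.array_equal(water_run[1].dose, mosfet2.dose)
        assert np.array_equal(water_run[0].variance, ppic2.variance)

    def test_different_seed_differs(self, tank, dd100, do100, water_run):
        beam = BeamSpec(nominal_range=100.0, field_radius=12.0, angular_sigma=0.003)
        ppic2, _ = run_smc(tank, beam, dd100, do100, n=120_000, seed=6, batches=6, step=0.5)
        assert not np.array_equal(water_run[0].dose, ppic2.dose)

    def test_output_ratio_unity_in_plateau(self, water_run):
        ppic, mosfet = water_run
        cx, cy = ppic.shape[0] // 2, ppic.shape[1] // 2
        ratio = mosfet.dose[cx, cy, 10] / ppic.dose[cx, cy, 10]
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_error_scaling_with_histories(self, tank, dd100, do100):
        beam = BeamSpec(nominal_range=100.0, field_radius=12.0, angular_sigma=0.003)
        errs = []
        for n in (40_000, 80_000):
            ppic, _ = run_smc(tank, beam, dd100, do100, n=n, seed=9, batches=8, step=0.5)
            region = ppic.dose > 0.5 * ppic.dose.max()
            errs.append(statistical_error(ppic, region))
        ratio = errs[0] / errs[1]
        assert np.sqrt(2.0) * 0.8 < ratio < np.sqrt(2.0) * 1.2

    def test_normalization_sets_value(self, tank, dd100, do100):
        beam = BeamSpec(nominal_range=100.0, field_radius=12.0)
        pt = (0.0, 0.0, tank.lower_corner[2] + 40.0)
        ppic, _ = run_smc(tank, beam, dd100, do100, n=20_000, seed=2, batches=2,
                          step=0.5, normalize_point=pt, normalize_value=200.0)
        assert ppic.value_at(pt) == pytest.approx(200.0)

    def test_zero_dose_at_normalization_point_raises(self, tank, dd100, do100):
        beam = BeamSpec(nominal_range=100.0, field_radius=5.0)
        with pytest.raises(ValueError, match="normalization"):
            run_smc(tank, beam, dd100, do100, n=5_000, seed=2, batches=2, step=0.5,
                    normalize_point=(18.0, 18.0, tank.lower_corner[2] + 110.0))

    def test_requires_batches(self, tank, dd100, do100):
        beam = BeamSpec(nominal_range=100.0, field_radius=10.0)
        with pytest.raises(ValueError):
            run_smc(tank, beam, dd100, do100, n=100, seed=1, batches=1)


class TestStatisticalError:
    def _grid(self, dose, var, n_batches=10):
        return DoseGrid(dose, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0), variance=var,
                        n_batches=n_batches)

    def test_identical_batches_zero(self):
        g = self._grid(np.full((3, 3, 3), 5.0), np.zeros((3, 3, 3)))
        assert statistical_error(g, np.ones((3, 3, 3), bool)) == 0.0

    def test_constructed_two_percent(self):
        dose = np.full((4, 4, 4), 50.0)
        var = (0.02 * dose) ** 2
        g = self._grid(dose, var)
        assert statistical_error(g, np.ones((4, 4, 4), bool)) == pytest.approx(2.0)

    def test_too_few_batches(self):
        g = self._grid(np.ones((2, 2, 2)), np.zeros((2, 2, 2)), n_batches=1)
        with pytest.raises(ValueError):
            statistical_error(g, np.ones((2, 2, 2), bool))

    def test_empty_region(self):
        g = self._grid(np.ones((2, 2, 2)), np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            statistical_error(g, np.zeros((2, 2, 2), bool))

    def test_zero_dose_in_region(self):
        g = self._grid(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            statistical_error(g, np.ones((2, 2, 2), bool))


class TestHighland:
    def test_sigma_positive_and_grows_near_range_end(self):
        assert highland_sigma(100.0, 1.0) > 0
        assert highland_sigma(5.0, 1.0) > highland_sigma(100.0, 1.0)

    def test_fermi_eyges_monotone(self):
        s = fermi_eyges_sigma(np.array([20.0, 40.0, 60.0, 80.0]), 100.0)
        assert np.all(np.diff(s) > 0)
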