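import numpy as np
import pytest

from conepore.analysis import (
    CensoringError,
    InsufficientDataError,
    MsdCurve,
    NoAbsorptionError,
    PositionHistogram,
    UndefinedForceError,
    ensemble_msd,
    entropic_force,
    find_tmin,
    fit_exponential,
    fit_power_law,
    fpt_median,
    orientation_histogram,
    position_histogram,
    survival_curve,
)
from conftest import CONE, make_synthetic_result


class TestEnsembleMsd:
    def test_frozen_trajectory_has_zero_msd(self):
        pos = np.zeros((1, 50, 3))
        curve = ensemble_msd(make_synthetic_result(pos))
        assert np.all(curve.msd == 0.0)

    def test_ballistic_walk_is_quadratic(self):
        t = np.arange(1, 101)
        v = 0.02
        pos = np.zeros((1, 100, 3))
        pos[0, :, 0] = v * t
        curve = ensemble_msd(make_synthetic_result(pos))
        assert np.allclose(curve.msd, v**2 * t.astype(float) ** 2, rtol=1e-12)
        fit = fit_power_law(curve, t_min=100)
        assert fit.alpha == pytest.approx(2.0, abs=1e-6)

    def test_free_walk_matches_three_sigma_squared_t(self):
        rng = np.random.default_rng(0)
        n, T, sx = 1000, 300, 0.05
        steps = rng.normal(0.0, sx, size=(n, T, 3))
        pos = np.cumsum(steps, axis=1)
        curve = ensemble_msd(make_synthetic_result(pos))
        t = curve.times.astype(float)
        expected = 3 * sx**2 * t
        # var(|x|^2) = 6 sigma^4 t^2 for a 3D Gaussian displacement
        se = np.sqrt(6.0) * sx**2 * t / np.sqrt(n)
        assert np.all(np.abs(curve.msd - expected) < 3.5 * se)

    def test_absorbed_trajectories_leave_the_average(self):
        pos = np.ones((2, 10, 3))
        pos[1] *= 5.0
        fpt = np.array([-1, 6], dtype=np.int64)
        curve = ensemble_msd(make_synthetic_result(pos, fpt=fpt))
        # trajectory 1 (|x|^2 = 75) contributes only while fpt > t
        assert curve.n_alive.tolist() == [2] * 5 + [1] * 5
        assert np.allclose(curve.msd[:5], (3.0 + 75.0) / 2)
        assert np.allclose(curve.msd[5:], 3.0)

    def test_censoring_rule_is_idempotent(self):
        rng = np.random.default_rng(1)
        pos = np.cumsum(rng.normal(0, 0.05, (50, 40, 3)), axis=1)
        fpt = np.where(rng.random(50) < 0.5, rng.integers(5, 40, 50), -1).astype(np.int64)
        res = make_synthetic_result(pos, fpt=fpt)
        curve = ensemble_msd(res)
        # blanking all post-absorption samples changes nothing
        t = res.sample_times[None, :]
        gone = (fpt[:, None] >= 0) & (t >= fpt[:, None])
        pos2 = pos.copy()
        pos2[gone] = np.nan
        curve2 = ensemble_msd(make_synthetic_result(pos2, fpt=fpt))
        assert np.allclose(curve.msd, curve2.msd, equal_nan=True)


class TestTmin:
    def test_minimum_over_absorbed(self):
        res = make_synthetic_result(np.zeros((3, 5, 3)), fpt=np.array([100, 250, 90]))
        assert find_tmin(res) == 90

    def test_censored_excluded(self):
        res = make_synthetic_result(np.zeros((3, 5, 3)), fpt=np.array([2000, -1, 1500]))
        assert find_tmin(res) == 1500

    def test_no_absorption_raises(self):
        res = make_synthetic_result(np.zeros((2, 5, 3)))
        with pytest.raises(NoAbsorptionError):
            find_tmin(res)


class TestPowerLawFit:
    def test_exact_recovery(self):
        t = np.arange(1, 2001, dtype=np.int64)
        curve = MsdCurve(times=t, msd=2.0 * t.astype(float) ** 0.8, n_alive=np.full(t.size, 10))
        fit = fit_power_law(curve, t_min=2000)
        assert fit.D == pytest.approx(2.0, rel=1e-6)
        assert fit.alpha == pytest.approx(0.8, rel=1e-6)

    def test_normal_diffusion_amplitude(self):
        t = np.arange(1, 1001, dtype=np.int64)
        curve = MsdCurve(times=t, msd=0.0075 * t.astype(float), n_alive=np.full(t.size, 10))
        fit = fit_power_law(curve, t_min=1000)
        assert fit.alpha == pytest.approx(1.0, abs=1e-6)
        assert fit.D == pytest.approx(3 * 0.05**2, rel=1e-6)

    def test_window_too_sparse_raises(self):
        t = np.array([1, 500, 1000], dtype=np.int64)
        curve = MsdCurve(times=t, msd=t.astype(float), n_alive=np.full(3, 5))
        with pytest.raises(InsufficientDataError):
            fit_power_law(curve, t_min=1000)

    def test_noisy_free_diffusion_exponent(self):
        rng = np.random.default_rng(2)
        n, T, sx = 1000, 4000, 0.05
        pos = np.cumsum(rng.normal(0.0, sx, size=(n, T, 3)), axis=1)
        times = np.unique(np.round(np.logspace(0, np.log10(T), 300)).astype(np.int64))
        res = make_synthetic_result(pos[:, times - 1, :], sample_times=times)
        fit = fit_power_law(ensemble_msd(res), t_min=T)
        assert 0.97 <= fit.alpha <= 1.03


class TestFptStatistics:
    def test_median_odd(self):
        res = make_synthetic_result(np.zeros((3, 2, 3)), fpt=np.array([1, 2, 3]))
        assert fpt_median(res) == 2.0

    def test_median_even_uses_midpoint(self):
        res = make_synthetic_result(np.zeros((4, 2, 3)), fpt=np.array([1, 2, 3, 100]))
        assert fpt_median(res) == 2.5

    def test_heavy_censoring_raises(self):
        res = make_synthetic_result(np.zeros((4, 2, 3)), fpt=np.array([1, 2, -1, -1]))
        with pytest.raises(CensoringError):
            fpt_median(res)

    def test_all_censored_raises(self):
        res = make_synthetic_result(np.zeros((2, 2, 3)))
        with pytest.raises(NoAbsorptionError):
            fpt_median(res)


class TestSurvival:
    def test_boundary_values(self):
        res = make_synthetic_result(np.zeros((4, 2, 3)), fpt=np.array([10, 20, 30, 40]))
        S = survival_curve(res, np.array([0, 25, 50]))
        assert S.tolist() == [1.0, 0.5, 0.0]

    def test_censored_count_as_surviving(self):
        res = make_synthetic_result(np.zeros((2, 2, 3)), fpt=np.array([10, -1]))
        assert survival_curve(res, np.array([15]))[0] == 0.5

    def test_exact_exponential_recovery(self):
        t = np.linspace(0, 5000, 200)
        S = np.exp(-1e-3 * t)
        fit = fit_exponential(S, t, band=(0.001, 1.0))
        assert fit.A == pytest.approx(1.0, abs=1e-9)
        assert fit.lam == pytest.approx(1e-3, rel=1e-9)

    def test_prefactor_recovery_on_truncated_band(self):
        t = np.linspace(0, 8000, 400)
        S = 2.0 * np.exp(-1e-3 * t)
        usable = S <= 0.9
        fit = fit_exponential(S[usable], t[usable])
        assert fit.A == pytest.approx(2.0, rel=1e-9)

    def test_insufficient_band_points_raise(self):
        t = np.linspace(0, 10, 5)
        with pytest.raises(InsufficientDataError):
            fit_exponential(np.full(5, 0.95), t)


class TestHistograms:
    def test_axial_directors_fill_first_theta_bin(self):
        ori = np.zeros((2, 30, 3))
        ori[..., 2] = 1.0
        res = make_synthetic_result(np.zeros((2, 30, 3)), orientations=ori)
        h = orientation_histogram(res, n_bins=9)
        assert h.density[0] > 0 and np.all(h.density[1:] == 0)

    def test_perpendicular_directors_fill_last_theta_bin(self):
        ori = np.zeros((2, 30, 3))
        ori[..., 0] = 1.0
        res = make_synthetic_result(np.zeros((2, 30, 3)), orientations=ori)
        h = orientation_histogram(res, n_bins=9)
        assert h.density[-1] > 0 and np.all(h.density[:-1] == 0)

    def test_isotropic_directors_give_sine_density(self):
        rng = np.random.default_rng(3)
        u = rng.standard_normal((1, 40_000, 3))
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        res = make_synthetic_result(np.zeros((1, 40_000, 3)), orientations=u)
        h = orientation_histogram(res, n_bins=12)
        centers = 0.5 * (h.edges[:-1] + h.edges[1:])
        assert np.allclose(h.density, np.sin(centers), atol=0.03)
        # and the sine-corrected density is flat
        assert np.allclose(
            h.density_sine_corrected, 2 / np.pi, atol=0.05 * 2 / np.pi
        )

    def test_density_normalization(self):
        rng = np.random.default_rng(4)
        pos = np.zeros((2, 3000, 3))
        pos[..., 2] = rng.uniform(0, 15, size=(2, 3000))
        res = make_synthetic_result(pos)
        h = position_histogram(res, n_bins=30)
        width = h.edges[1] - h.edges[0]
        assert np.sum(h.density) * width == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(h.density, 1.0 / 15.0, atol=0.02)

    def test_stationary_trajectory_occupies_one_bin(self):
        pos = np.zeros((1, 20, 3))
        pos[..., 2] = 7.1
        h = position_histogram(make_synthetic_result(pos), n_bins=15)
        assert np.count_nonzero(h.density) == 1
        assert h.density[7] > 0  # z=7.1 falls in bin [7, 8)

    def test_rebinning_requires_divisor(self):
        from conepore.dynamics import SimulationConfig, run_ensemble
        from conepore.geometry import Spherocylinder

        cfg = SimulationConfig(
            channel=CONE, particle=Spherocylinder(0.0, 0.05), n_rep=2,
            max_steps=2000, seed=0, n_occ_z_bins=600,
        )
        res = run_ensemble(cfg)
        with pytest.raises(ValueError):
            position_histogram(res, n_bins=7)  # 7 does not divide 600


class TestEntropicForce:
    def hist(self, density, L=15.0):
        edges = np.linspace(0, L, len(density) + 1)
        return PositionHistogram(edges=edges, density=np.asarray(density, float), count=1000)

    def test_exponential_density_gives_constant_force(self):
        edges = np.linspace(0, 15, 31)
        centers = 0.5 * (edges[:-1] + edges[1:])
        f = np.exp(-centers)
        force = entropic_force(self.hist(f))
        assert np.allclose(force[1:-1], -1.0, atol=1e-9)

    def test_flat_density_gives_zero_force(self):
        force = entropic_force(self.hist(np.full(20, 1 / 15)))
        assert np.allclose(force, 0.0, atol=1e-12)

    def test_equilibrium_cross_section_profile(self):
        # occupation proportional to the local cross-section area R(z)^2
        edges = np.linspace(0, 15, 61)
        centers = 0.5 * (edges[:-1] + edges[1:])
        R = 0.5 - centers / 60.0
        force = entropic_force(self.hist(R**2))
        expected = 2.0 * (-1.0 / 60.0) / R
        assert np.allclose(force[1:-1], expected[1:-1], rtol=1e-3)
        assert np.all(force < 0)

    def test_zero_interior_bin_raises(self):
        f = np.full(10, 0.1)
        f[4] = 0.0
        with pytest.raises(UndefinedForceError):
            entropic_force(self.hist(f))
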