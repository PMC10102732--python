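"""Langevin ensembles, fluctuation theorems, Fokker-Planck diagnostics."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from bayesmech.thermo import (
    ColoredNoiseReport,
    LangevinConfig,
    WorkProtocol,
    colored_noise_check,
    dragged_trap,
    entropy_ft_estimate,
    flux_field,
    fp_equilibrium_density,
    jarzynski_estimate,
    simulate_paths,
    stiffness_switch,
    work_along_path,
)

SEED = 907


def static_trap(kappa=1.0, duration=1.0):
    return WorkProtocol(
        potential=lambda mu, lam: 0.5 * kappa * mu**2,
        grad_potential=lambda mu, lam: kappa * mu,
        schedule=lambda t: 0.0,
        t_start=0.0,
        t_end=duration,
        delta_F=0.0,
        name="static",
    )


class TestSimulatePaths:
    def test_zero_noise_reduces_to_euler(self):
        # T -> 0 limit: noiseless gradient descent in the trap
        config = LangevinConfig(temperature=1e-30)
        proto = static_trap(duration=0.5)
        ens = simulate_paths(
            config, proto, dt=0.01, n_paths=3, seed=SEED,
            mu0_sampler=lambda rng, n: np.full(n, 2.0),
        )
        mu = np.full(3, 2.0)
        for _ in range(50):
            mu = mu + (-mu) * 0.01
        np.testing.assert_allclose(ens.paths[:, -1], mu, rtol=1e-9)

    def test_ou_stationary_variance(self):
        # overdamped particle in a harmonic trap: var = I / (2 theta)
        theta = 1.0
        config = LangevinConfig(temperature=1.0)  # I = 2
        proto = static_trap(kappa=theta, duration=4.0)
        ens = simulate_paths(config, proto, dt=0.005, n_paths=4000, seed=SEED)
        var = ens.paths[:, -1].var()
        expect = config.noise_strength / (2 * theta)
        se = expect * np.sqrt(2.0 / ens.n_paths)
        assert abs(var - expect) < 4 * se + 0.01  # + O(dt) discretisation bias

    def test_seed_reproducibility(self):
        config = LangevinConfig()
        proto = dragged_trap()
        a = simulate_paths(config, proto, dt=0.01, n_paths=50, seed=SEED)
        b = simulate_paths(config, proto, dt=0.01, n_paths=50, seed=SEED)
        assert np.array_equal(a.paths, b.paths)
        assert np.array_equal(a.works, b.works)

    def test_long_time_histogram_matches_boltzmann(self):
        # KS distance between late-time samples and the equilibrium CDF
        config = LangevinConfig(temperature=1.0)
        proto = static_trap(kappa=1.0, duration=6.0)
        ens = simulate_paths(config, proto, dt=0.005, n_paths=3000, seed=SEED)
        stat = kstest(ens.paths[:, -1], "norm", args=(0.0, 1.0)).statistic
        assert stat < 0.04

    def test_noise_strength_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            LangevinConfig(noise_strength=5.0, temperature=1.0)


class TestWork:
    def test_static_protocol_zero_work(self):
        ens = simulate_paths(LangevinConfig(), static_trap(), dt=0.01, n_paths=20, seed=SEED)
        assert np.all(ens.works == 0)

    def test_single_path_matches_ensemble_bookkeeping(self):
        config = LangevinConfig()
        proto = dragged_trap()
        ens = simulate_paths(config, proto, dt=0.01, n_paths=5, seed=SEED)
        w0 = work_along_path(ens.paths[0], proto, ens.times)
        assert w0 == pytest.approx(ens.works[0], rel=1e-12)

    def test_instantaneous_quench_convention(self):
        # single step: W = V(mu0, lam_end) - V(mu0, lam_start)
        proto = WorkProtocol(
            potential=lambda mu, lam: 0.5 * lam * mu**2,
            grad_potential=lambda mu, lam: lam * mu,
            schedule=lambda t: 1.0 if t <= 0 else 3.0,
            t_start=0.0, t_end=1.0, delta_F=0.0,
        )
        w = work_along_path(np.array([2.0, 2.1]), proto, np.array([0.0, 1.0]))
        assert w == pytest.approx(0.5 * (3.0 - 1.0) * 4.0)

    def test_quasi_static_limit_approaches_delta_F(self):
        # same trap displacement, slower drag: mean work decreases to dF = 0
        config = LangevinConfig()
        fast = dragged_trap(speed=1.0, duration=1.0)
        slow = dragged_trap(speed=0.1, duration=10.0)
        wf = simulate_paths(config, fast, dt=0.002, n_paths=800, seed=SEED).works.mean()
        ws = simulate_paths(config, slow, dt=0.002, n_paths=800, seed=SEED).works.mean()
        # analytic means: v^2 (tau_d - (1 - e^{-tau_d})) = 0.368 vs 0.090
        assert ws < wf / 2
        assert ws < 0.15  # approaching the reversible value dF = 0


@pytest.fixture(scope="module")
def drag_ensemble():
    config = LangevinConfig(temperature=1.0)
    proto = dragged_trap(kappa=1.0, speed=1.0, duration=1.0)
    return simulate_paths(config, proto, dt=1e-3, n_paths=10000, seed=SEED,
                          store_paths=False), proto


class TestFluctuationTheorems:

    def test_reversible_ensemble_gives_exact_unity(self):
        est = jarzynski_estimate(np.full(100, 0.7), beta=2.0, delta_F=0.7)
        assert est.mean_exp == 1.0 and est.std_error == 0.0
        ent = entropy_ft_estimate(np.full(100, 0.7), beta=2.0, delta_F=0.7)
        assert ent.mean_exp == 1.0

    def test_jarzynski_equality_dragged_trap(self, drag_ensemble):
        ens, proto = drag_ensemble
        est = jarzynski_estimate(ens.works, beta=1.0, delta_F=proto.delta_F)
        assert abs(est.mean_exp - 1.0) < 3 * est.std_error
        assert est.jensen_gap >= 0.0  # <W> >= dF

    def test_entropy_ft_dragged_trap(self, drag_ensemble):
        ens, proto = drag_ensemble
        est = entropy_ft_estimate(ens.works, beta=1.0, delta_F=proto.delta_F)
        assert abs(est.mean_exp - 1.0) < 3 * est.std_error
        assert est.jensen_gap >= 0.0  # <dS_tot> >= 0

    def test_stiffness_switch_with_analytic_delta_F(self):
        beta = 1.0
        proto = stiffness_switch(kappa_i=1.0, kappa_f=2.0, duration=2.0, beta=beta)
        assert proto.delta_F == pytest.approx(0.5 * np.log(2.0))
        ens = simulate_paths(LangevinConfig(), proto, dt=1e-3, n_paths=8000, seed=SEED,
                             store_paths=False)
        est = jarzynski_estimate(ens.works, beta, proto.delta_F)
        assert abs(est.mean_exp - 1.0) < 3.5 * est.std_error

    def test_convergence_with_ensemble_size(self, drag_ensemble):
        ens, proto = drag_ensemble
        devs = []
        for n in (500, 5000):
            est = jarzynski_estimate(ens.works[:n], 1.0, proto.delta_F)
            devs.append(abs(est.mean_exp - 1.0) + est.std_error)
        assert devs[1] < devs[0]

    def test_overflow_guarded(self):
        # exponents far beyond the double range: the log-domain value
        # stays finite even when mean_exp itself saturates
        est = jarzynski_estimate(np.array([-800.0, -700.0, -750.0]), beta=1.0, delta_F=0.0)
        assert est.mean_exp > 0
        assert np.isfinite(est.log_mean_exp)
        assert est.log_mean_exp == pytest.approx(800.0 - np.log(3.0), abs=1.0)


@pytest.fixture(scope="module")
def report() -> ColoredNoiseReport:
    config = LangevinConfig(temperature=1.0, ou_tau=0.5)
    return colored_noise_check(config, dt=0.01, horizon=2000.0, seed=SEED, n_lags=60)


class TestColoredNoise:

    def test_zero_lag_variance(self, report):
        # kernel at zero lag: 2 k_B T gamma / tau = 4
        assert report.variance_expected == pytest.approx(4.0)
        assert report.variance_measured == pytest.approx(4.0, rel=0.1)

    def test_exponential_decay_at_tau(self, report):
        i = int(round(0.5 / 0.01))
        ratio = report.empirical[i] / report.empirical[0]
        assert ratio == pytest.approx(np.exp(-1.0), abs=0.08)

    def test_kernel_shape(self, report):
        assert report.max_rel_dev < 0.1

    def test_white_noise_limit(self):
        config = LangevinConfig(temperature=1.0, ou_tau=0.002)
        rep = colored_noise_check(config, dt=0.01, horizon=200.0, seed=SEED)
        # at lag dt >> tau the autocorrelation has decayed to ~0
        assert abs(rep.empirical[1]) < 0.05 * rep.empirical[0]

    def test_requires_tau(self):
        with pytest.raises(ValueError):
            colored_noise_check(LangevinConfig(), dt=0.01, horizon=10.0, seed=SEED)


class TestEquilibriumDensity:
    def test_harmonic_gaussian_moments(self):
        beta, kappa = 2.0, 3.0
        ax = np.linspace(-6, 6, 2001)
        dens = fp_equilibrium_density(lambda x: 0.5 * kappa * x**2, beta, (ax,))
        assert dens.total_mass == pytest.approx(1.0, abs=1e-12)
        var = np.sum(ax**2 * dens.values) * dens.cell_volume
        assert var == pytest.approx(1.0 / (beta * kappa), rel=1e-6)

    def test_constant_potential_uniform(self):
        ax = np.linspace(0, 1, 101)
        dens = fp_equilibrium_density(lambda x: np.zeros_like(x), 1.0, (ax,), mass_tol=1.0)
        assert np.ptp(dens.values) == 0

    def test_double_well_matches_quadrature(self):
        beta = 2.0
        V = lambda x: x**4 - 2 * x**2  # noqa: E731
        ax = np.linspace(-4, 4, 4001)
        dens = fp_equilibrium_density(V, beta, (ax,))
        Z_quad, _ = quad(lambda x: np.exp(-beta * (V(np.array(x)) - (-1.0))), -4, 4,
                         limit=200)
        # compare density at the well minimum against the quadrature oracle
        i = np.argmin(np.abs(ax - 1.0))
        expect = np.exp(-beta * (V(ax[i:i + 1]) - (-1.0)))[0] / Z_quad
        assert dens.values[i] == pytest.approx(expect, rel=1e-6)
        assert abs(dens.total_mass - 1.0) < 1e-10

    def test_non_confining_potential_refused(self):
        ax = np.linspace(-1, 1, 101)
        with pytest.raises(ValueError, match="boundary"):
            fp_equilibrium_density(lambda x: 0.5 * x**2, 1.0, (ax,))


class TestFluxField:
    @staticmethod
    def _equilibrium_2d(n, beta=1.0, kappa=1.0, rotation=0.0):
        ax = np.linspace(-8, 8, n)
        pot = lambda x, y: 0.5 * kappa * (x**2 + y**2)  # noqa: E731
        drift = None
        if rotation:
            def drift(x, y):
                return (-kappa * x - rotation * y, -kappa * y + rotation * x)
        return fp_equilibrium_density(pot, beta, (ax, ax), diffusion=1.0,
                                      drift_field=drift)

    def test_equilibrium_flux_vanishes_second_order(self):
        norms = []
        for n in (81, 161):
            fl = flux_field(self._equilibrium_2d(n))
            norms.append(fl.max_norm)
        assert norms[0] < 1e-2
        assert norms[0] / norms[1] > 3.0  # halving h shrinks ||j|| ~4x

    def test_rotational_drift_gives_solenoidal_flux(self):
        fl = flux_field(self._equilibrium_2d(161, rotation=1.0))
        assert fl.max_norm > 0.05  # broken detailed balance: j != 0
        divs = []
        for n in (81, 161):
            divs.append(flux_field(self._equilibrium_2d(n, rotation=1.0)).max_abs_divergence)
        assert divs[1] < divs[0]
        assert divs[1] < 0.03 * fl.max_norm  # divergence-free steady state

    def test_uniform_density_zero_drift(self):
        ax = np.linspace(0, 1, 51)
        from bayesmech.thermo import GridDensity

        p = np.ones((51, 51))
        p /= p.sum() * (ax[1] - ax[0]) ** 2
        dens = GridDensity(axes=(ax, ax), values=p, diffusion=1.0,
                           drift_field=lambda x, y: (np.zeros_like(x), np.zeros_like(y)))
        fl = flux_field(dens)
        # nonuniform last-ulp spacings leave only rounding-level residue
        assert fl.max_norm < 1e-12 and fl.max_abs_divergence < 1e-10

    def test_coarse_grid_rejected(self):
        ax = np.linspace(-1, 1, 4)
        from bayesmech.thermo import GridDensity

        with pytest.raises(ValueError, match="coarse"):
            GridDensity(axes=(ax,), values=np.ones(4), diffusion=1.0)
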