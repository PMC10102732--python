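"""Stochastic-thermodynamic foundations: Langevin paths, fluctuation
theorems and Fokker-Planck steady-state diagnostics.

Overdamped Langevin dynamics ``dmu/dt = f(mu; t) + w(t)`` with white
noise ``<w(t) w(t')> = I delta(t - t')`` (``I = 2 k_B T / (m gamma)``)
are simulated by the Euler-Maruyama scheme.  Work along driven paths
follows the Sekimoto convention (energy change under protocol-parameter
updates at fixed state), which makes the Jarzynski equality
``<exp(-beta (W - dF))> = 1`` and the integral entropy fluctuation
theorem ``<exp(-dS_tot/k_B)> = 1`` (with ``dS_tot/k_B = beta (W - dF)``
isothermally) directly testable, along with the second-law bounds
``<W> >= dF`` and ``<dS_tot> >= 0``.

The drift-diffusion (Smoluchowski-Fokker-Planck) layer provides the
equilibrium Boltzmann density ``p_eq propto exp(-beta V)`` and the
probability flux ``j = p f - D grad p``; equilibrium has ``j = 0``
everywhere (detailed balance), while non-equilibrium steady states keep
a nonzero but divergence-free flux.  Only steady-state diagnostics are
computed; transient density evolution is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "LangevinConfig",
    "WorkProtocol",
    "FTEstimate",
    "PathEnsemble",
    "GridDensity",
    "FluxField",
    "ColoredNoiseReport",
    "dragged_trap",
    "stiffness_switch",
    "simulate_paths",
    "colored_noise_check",
    "work_along_path",
    "jarzynski_estimate",
    "entropy_ft_estimate",
    "fp_equilibrium_density",
    "flux_field",
]


@dataclass
class LangevinConfig:
    """Physical parameters of the overdamped dynamics.

    ``noise_strength`` is I = 2 k_B T / (m gamma); when temperature,
    mass and friction are all given, consistency with the supplied
    noise strength is enforced (fluctuation-dissipation relation).
    ``k_B = 1`` and arbitrary units by default.
    """

    drift: Optional[Callable] = None  # (mu, t, lam) -> drift
    noise_strength: Optional[float] = None
    temperature: float = 1.0
    k_B: float = 1.0
    friction_gamma: float = 1.0
    mass: float = 1.0
    ou_tau: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("temperature", "k_B", "friction_gamma", "mass"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive, got {v!r}")
        implied = 2.0 * self.k_B * self.temperature / (self.mass * self.friction_gamma)
        if self.noise_strength is None:
            self.noise_strength = implied
        elif not np.isclose(self.noise_strength, implied, rtol=1e-9):
            raise ValueError(
                f"noise_strength {self.noise_strength} inconsistent with "
                f"2 k_B T/(m gamma) = {implied}"
            )

    @property
    def beta(self) -> float:
        return 1.0 / (self.k_B * self.temperature)


@dataclass
class WorkProtocol:
    """Driven potential V(mu, lambda) with a schedule lambda(t).

    ``delta_F`` is the Helmholtz free-energy change between the endpoint
    equilibria; the built-in protocols supply it analytically so the
    fluctuation-theorem checks are self-contained.
    """

    potential: Callable[[np.ndarray, float], np.ndarray]
    schedule: Callable[[float], float]
    t_start: float
    t_end: float
    delta_F: float
    grad_potential: Optional[Callable[[np.ndarray, float], np.ndarray]] = None
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")

    def grad(self, mu: np.ndarray, lam: float) -> np.ndarray:
        if self.grad_potential is not None:
            return self.grad_potential(mu, lam)
        h = 1e-6
        return (self.potential(mu + h, lam) - self.potential(mu - h, lam)) / (2.0 * h)

    def equilibrium_sampler(
        self, config: LangevinConfig, at_end: bool = False
    ) -> Callable[[np.random.Generator, int], np.ndarray]:
        """Rejection sampler from exp(-beta V(., lambda)) at an endpoint.

        For the built-in quadratic potentials a Gaussian draw is exact;
        general potentials fall back to rejection on a wide grid.
        """
        lam = self.schedule(self.t_end if at_end else self.t_start)
        beta = config.beta

        def sampler(rng: np.random.Generator, size: int) -> np.ndarray:
            grid = np.linspace(-20.0, 20.0, 4001)
            V = self.potential(grid, lam)
            p = np.exp(-beta * (V - V.min()))
            p /= p.sum()
            idx = rng.choice(grid.size, size=size, p=p)
            jitter = (rng.random(size) - 0.5) * (grid[1] - grid[0])
            return grid[idx] + jitter

        return sampler


def dragged_trap(kappa: float = 1.0, speed: float = 1.0, duration: float = 1.0) -> WorkProtocol:
    """Harmonic trap V = (kappa/2)(mu - v t)^2 dragged at constant speed.

    The trap minimum moves but its shape does not, so the endpoint
    equilibrium free energies coincide: delta_F = 0 exactly.
    """
    return WorkProtocol(
        potential=lambda mu, lam: 0.5 * kappa * (mu - lam) ** 2,
        grad_potential=lambda mu, lam: kappa * (mu - lam),
        schedule=lambda t: speed * t,
        t_start=0.0,
        t_end=duration,
        delta_F=0.0,
        name="dragged_trap",
    )


def stiffness_switch(
    kappa_i: float = 1.0,
    kappa_f: float = 2.0,
    duration: float = 1.0,
    beta: float = 1.0,
) -> WorkProtocol:
    """Harmonic trap whose stiffness ramps linearly from kappa_i to kappa_f.

    delta_F = (1/(2 beta)) ln(kappa_f / kappa_i) from the Gaussian
    partition functions at the endpoints.
    """
    if kappa_i <= 0 or kappa_f <= 0:
        raise ValueError("stiffnesses must be positive")
    rate = (kappa_f - kappa_i) / duration
    return WorkProtocol(
        potential=lambda mu, lam: 0.5 * lam * mu**2,
        grad_potential=lambda mu, lam: lam * mu,
        schedule=lambda t: kappa_i + rate * t,
        t_start=0.0,
        t_end=duration,
        delta_F=0.5 / beta * float(np.log(kappa_f / kappa_i)),
        name="stiffness_switch",
    )


@dataclass
class PathEnsemble:
    """Euler-Maruyama path bundle with Sekimoto work bookkeeping."""

    times: np.ndarray
    lambdas: np.ndarray
    paths: np.ndarray  # (n_paths, n_times)
    works: np.ndarray  # (n_paths,) cumulative Sekimoto work
    seed: int
    n_diverged: int = 0

    @property
    def n_paths(self) -> int:
        return self.paths.shape[0]


def simulate_paths(
    config: LangevinConfig,
    protocol: WorkProtocol,
    dt: float,
    n_paths: int,
    seed: int,
    mu0_sampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    store_paths: bool = True,
) -> PathEnsemble:
    """Driven overdamped ensemble with per-path work accumulation.

    Per-step update: ``mu += f dt + sqrt(I dt) xi`` with standard-normal
    xi; the drift defaults to the potential gradient flow
    ``f = -dV/dmu / (m gamma)``.  Work increments follow the Sekimoto
    convention ``V(mu_t, lam_{t+dt}) - V(mu_t, lam_t)``.  Initial states
    default to the initial-endpoint equilibrium (as the Jarzynski
    derivation requires).  Fixed ``seed`` gives bitwise reproducibility.
    Divergent paths are excluded, with the count reported.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_paths < 1:
        raise ValueError("need at least one path")
    rng = np.random.default_rng(seed)
    mg = config.mass * config.friction_gamma

    if config.drift is not None:
        drift = config.drift
    else:
        drift = lambda mu, t, lam: -protocol.grad(mu, lam) / mg  # noqa: E731

    n_steps = int(round((protocol.t_end - protocol.t_start) / dt))
    times = protocol.t_start + dt * np.arange(n_steps + 1)
    lambdas = np.array([protocol.schedule(t) for t in times])

    # warn when the drift stiffness makes Euler-Maruyama marginal
    probe = np.linspace(-5, 5, 11)
    try:
        dfdmu = np.max(np.abs(np.gradient(drift(probe, times[0], lambdas[0]), probe)))
        if dt * dfdmu >= 0.1:
            warnings.warn(
                f"dt * max|df/dmu| = {dt * dfdmu:.3g} >= 0.1: Euler-Maruyama may be inaccurate"
            )
    except Exception:
        pass

    if mu0_sampler is None:
        mu0_sampler = protocol.equilibrium_sampler(config, at_end=False)
    mu = np.asarray(mu0_sampler(rng, n_paths), dtype=float)
    if mu.shape != (n_paths,):
        raise ValueError("mu0_sampler must return shape (n_paths,)")

    sig = np.sqrt(config.noise_strength * dt)
    works = np.zeros(n_paths)
    paths = np.empty((n_paths, n_steps + 1)) if store_paths else None
    if store_paths:
        paths[:, 0] = mu
    for i in range(n_steps):
        # work: parameter update at fixed state
        works += protocol.potential(mu, lambdas[i + 1]) - protocol.potential(mu, lambdas[i])
        mu = mu + drift(mu, times[i], lambdas[i + 1]) * dt + sig * rng.standard_normal(n_paths)
        if store_paths:
            paths[:, i + 1] = mu

    finite = np.isfinite(mu) & np.isfinite(works)
    n_diverged = int(np.sum(~finite))
    if n_diverged:
        warnings.warn(f"{n_diverged} divergent path(s) excluded from the ensemble")
        works = works[finite]
        if store_paths:
            paths = paths[finite]
    if paths is None:
        paths = np.empty((0, n_steps + 1))
    return PathEnsemble(
        times=times, lambdas=lambdas, paths=paths, works=works,
        seed=seed, n_diverged=n_diverged,
    )


def work_along_path(path: np.ndarray, protocol: WorkProtocol, times: np.ndarray) -> float:
    """Sekimoto work of a single sampled path on an aligned time grid.

    W = sum over steps of V(mu_t, lam_{t+dt}) - V(mu_t, lam_t): the
    energy change under the protocol-parameter update at fixed state.
    A static protocol therefore yields exactly zero work.
    """
    path = np.asarray(path, dtype=float)
    times = np.asarray(times, dtype=float)
    if path.shape != times.shape:
        raise ValueError("path and time grid must be aligned")
    lam = np.array([protocol.schedule(t) for t in times])
    return _work_scan(path, lam, protocol)


def _work_scan(path: np.ndarray, lam: np.ndarray, protocol: WorkProtocol) -> float:
    w = 0.0
    for i in range(path.size - 1):
        w += float(protocol.potential(path[i], lam[i + 1]) - protocol.potential(path[i], lam[i]))
    return w


@dataclass
class FTEstimate:
    """Monte-Carlo estimate of an integral fluctuation-theorem average."""

    mean_exp: float
    std_error: float
    n_paths: int
    mean_work: float
    delta_F: float
    beta: float
    log_mean_exp: float = 0.0  # overflow-safe log of mean_exp
    entropy_changes: np.ndarray = field(repr=False, default=None)
    jensen_gap: float = 0.0  # <W> - delta_F, non-negative by the second law

    def __post_init__(self) -> None:
        if self.mean_exp <= 0:
            raise ValueError("mean_exp must be positive")


def _exp_mean(x: np.ndarray) -> tuple[float, float, float]:
    """Overflow-guarded sample mean, SE and log-mean of exp(x)."""
    m = float(np.max(x))
    vals = np.exp(x - m)
    log_mean = m + float(np.log(np.mean(vals)))
    with np.errstate(over="ignore"):
        mean = float(np.exp(m) * np.mean(vals))
        se = float(np.exp(m) * np.std(vals, ddof=1) / np.sqrt(x.size))
    return mean, se, log_mean


def jarzynski_estimate(works: np.ndarray, beta: float, delta_F: float) -> FTEstimate:
    """Sample estimate of <exp(-beta (W - dF))> with its standard error.

    Also records the Jensen/second-law gap <W> - dF (>= 0 in expectation).
    """
    works = np.asarray(works, dtype=float)
    if works.size < 2:
        raise ValueError("need at least two work samples")
    x = -beta * (works - delta_F)
    mean, se, log_mean = _exp_mean(x)
    return FTEstimate(
        mean_exp=mean,
        std_error=se,
        n_paths=works.size,
        mean_work=float(np.mean(works)),
        delta_F=delta_F,
        beta=beta,
        log_mean_exp=log_mean,
        entropy_changes=beta * (works - delta_F),
        jensen_gap=float(np.mean(works) - delta_F),
    )


def entropy_ft_estimate(works: np.ndarray, beta: float, delta_F: float) -> FTEstimate:
    """Integral entropy fluctuation theorem <exp(-dS_tot/k_B)>.

    Per-path total entropy production in units of k_B is the isothermal
    identity ``dS_tot/k_B = beta (W - dF)``; the estimator then mirrors
    the Jarzynski average.  The second-law mean <dS_tot> >= 0 is exposed
    via ``jensen_gap`` scaled by beta.
    """
    works = np.asarray(works, dtype=float)
    if works.size < 2:
        raise ValueError("need at least two work samples")
    ds = beta * (works - delta_F)
    mean, se, log_mean = _exp_mean(-ds)
    return FTEstimate(
        mean_exp=mean,
        std_error=se,
        n_paths=works.size,
        mean_work=float(np.mean(works)),
        delta_F=delta_F,
        beta=beta,
        log_mean_exp=log_mean,
        entropy_changes=ds,
        jensen_gap=float(np.mean(ds)),
    )


@dataclass
class ColoredNoiseReport:
    """Empirical vs theoretical Ornstein-Uhlenbeck autocorrelation."""

    lags: np.ndarray
    empirical: np.ndarray
    theoretical: np.ndarray
    variance_expected: float
    variance_measured: float
    max_rel_dev: float


def colored_noise_check(
    config: LangevinConfig,
    dt: float,
    horizon: float,
    seed: int,
    n_lags: int = 50,
) -> ColoredNoiseReport:
    """Generate OU noise and verify the fluctuation-dissipation kernel.

    The exponential memory kernel gamma(|t-t'|) = (gamma/tau) exp(-|t-t'|/tau)
    implies noise autocorrelation 2 k_B T (gamma/tau) exp(-lag/tau) with
    variance 2 k_B T gamma / tau at zero lag.
    """
    if config.ou_tau is None or config.ou_tau <= 0:
        raise ValueError("ou_tau must be set and positive for the colored-noise check")
    tau = config.ou_tau
    if horizon < 10.0 * tau:
        warnings.warn("horizon < 10 tau: autocorrelation estimate may be unreliable")
    var = 2.0 * config.k_B * config.temperature * config.friction_gamma / tau
    n = int(round(horizon / dt))
    rng = np.random.default_rng(seed)
    # exact OU update: zeta_{k+1} = rho zeta_k + sqrt(var (1 - rho^2)) xi
    rho = float(np.exp(-dt / tau))
    zeta = np.empty(n)
    zeta[0] = rng.normal(0.0, np.sqrt(var))
    noise = rng.standard_normal(n - 1) * np.sqrt(var * (1.0 - rho * rho))
    for i in range(1, n):
        zeta[i] = rho * zeta[i - 1] + noise[i - 1]
    z = zeta - zeta.mean()
    lags = np.arange(n_lags)
    emp = np.array([np.mean(z[: n - k] * z[k:]) for k in lags])
    theo = var * np.exp(-lags * dt / tau)
    max_rel = float(np.max(np.abs(emp - theo)) / var)
    return ColoredNoiseReport(
        lags=lags * dt,
        empirical=emp,
        theoretical=theo,
        variance_expected=var,
        variance_measured=float(np.var(z)),
        max_rel_dev=max_rel,
    )


@dataclass
class GridDensity:
    """Probability density sampled on a regular 1D or 2D lattice.

    ``axes`` holds the per-dimension coordinate vectors; ``values`` the
    non-negative density normalised so that sum(p) * cell_volume = 1.
    ``diffusion`` and ``drift_field`` parameterise the flux.
    """

    axes: tuple
    values: np.ndarray
    diffusion: float
    drift_field: Optional[Callable] = None

    def __post_init__(self) -> None:
        if len(self.axes) not in (1, 2):
            raise ValueError("only 1D and 2D grids are supported")
        for ax in self.axes:
            if len(ax) < 5:
                raise ValueError("grid too coarse: need at least 5 points per dimension")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    @property
    def cell_volume(self) -> float:
        return float(np.prod([ax[1] - ax[0] for ax in self.axes]))

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.values) * self.cell_volume)


def fp_equilibrium_density(
    potential: Callable,
    beta: float,
    axes: Sequence[np.ndarray],
    diffusion: float = 1.0,
    drift_field: Optional[Callable] = None,
    mass_tol: float = 1e-8,
) -> GridDensity:
    """Normalised Boltzmann density ``p propto exp(-beta V)`` on a grid.

    The potential must be confining on the grid: the un-normalised
    density on the boundary must be negligible, otherwise normalisation
    is refused.
    """
    axes = tuple(np.asarray(ax, dtype=float) for ax in axes)
    if len(axes) == 1:
        V = potential(axes[0])
    else:
        X, Y = np.meshgrid(axes[0], axes[1], indexing="ij")
        V = potential(X, Y)
    V = np.asarray(V, dtype=float)
    p = np.exp(-beta * (V - V.min()))
    cell = float(np.prod([ax[1] - ax[0] for ax in axes]))
    Z = float(np.sum(p) * cell)
    if not np.isfinite(Z) or Z <= 0:
        raise ValueError("potential is not normalizable on the supplied grid")
    p = p / Z
    boundary = np.concatenate([p[0].ravel(), p[-1].ravel()] + (
        [p[:, 0].ravel(), p[:, -1].ravel()] if p.ndim == 2 else []))
    if boundary.max() * cell > mass_tol:
        raise ValueError(
            "density mass on the grid boundary is not negligible; enlarge the grid"
        )
    if drift_field is None:
        # gradient drift consistent with equilibrium: f = -D beta grad V
        if len(axes) == 1:
            def drift_field(x, _V=V, _axes=axes):  # noqa: ANN001
                g = np.gradient(_V, _axes[0])
                return (-diffusion * beta * g,)
        else:
            def drift_field(x, y, _V=V, _axes=axes):  # noqa: ANN001
                gx, gy = np.gradient(_V, _axes[0], _axes[1])
                return (-diffusion * beta * gx, -diffusion * beta * gy)
    return GridDensity(axes=axes, values=p, diffusion=diffusion, drift_field=drift_field)


@dataclass
class FluxField:
    """Probability flux j = p f - D grad p and its divergence on the grid."""

    components: tuple
    divergence: np.ndarray
    max_norm: float
    max_abs_divergence: float


def flux_field(density: GridDensity) -> FluxField:
    """Central-difference flux and divergence of a grid density.

    Equilibrium pairs (Boltzmann density with gradient drift) give
    ``j -> 0`` at second order in the spacing; adding a solenoidal drift
    gives nonzero j whose divergence still vanishes (non-equilibrium
    steady state with broken detailed balance).
    """
    if abs(density.total_mass - 1.0) > 1e-6:
        raise ValueError(f"density is not normalised (mass = {density.total_mass:g})")
    if density.drift_field is None:
        raise ValueError("density carries no drift field")
    p = density.values
    D = density.diffusion
    if len(density.axes) == 1:
        (x,) = density.axes
        (fx,) = density.drift_field(x)
        jx = p * fx - D * np.gradient(p, x)
        div = np.gradient(jx, x)
        comps = (jx,)
        norm = np.abs(jx)
    else:
        x, y = density.axes
        X, Y = np.meshgrid(x, y, indexing="ij")
        fx, fy = density.drift_field(X, Y)
        gpx, gpy = np.gradient(p, x, y)
        jx = p * fx - D * gpx
        jy = p * fy - D * gpy
        div = np.gradient(jx, x, axis=0) + np.gradient(jy, y, axis=1)
        comps = (jx, jy)
        norm = np.sqrt(jx**2 + jy**2)
    # exclude the one-sided boundary stencils from the summary metrics
    inner = tuple(slice(1, -1) for _ in comps)
    return FluxField(
        components=comps,
        divergence=div,
        max_norm=float(np.max(norm[inner])),
        max_abs_divergence=float(np.max(np.abs(div[inner]))),
    )
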