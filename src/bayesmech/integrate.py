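"""Fixed-step integration of the recognition dynamics.

A classical fourth-order Runge-Kutta one-step method on a uniform grid
is the only engine for nonlinear generative models and the independent
cross-check for the exact linear propagator.  The scheme and default
step (dt = 0.01) are validated against the closed-form linear solution
rather than mandated a priori; no adaptive stepping is used so that
every run is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import GenerativeModel, StateVector, free_energy, hamiltonian
from .stimuli import Stimulus

__all__ = [
    "Trajectory",
    "DivergenceError",
    "integrate",
    "rk4_step",
    "convergence_report",
    "ConvergenceReport",
]


class DivergenceError(RuntimeError):
    """The integrated state became non-finite."""

    def __init__(self, step: int, t: float):
        super().__init__(f"state became non-finite at step {step} (t = {t:g})")
        self.step = step
        self.t = t


@dataclass
class Trajectory:
    """Sampled solution of the equations of motion on a uniform grid.

    ``states`` has shape (n, 4) with columns (mu, a, p_mu, p_a);
    ``stimulus_values``, ``free_energy_values`` and ``hamiltonian_values``
    are aligned length-n complex arrays.
    """

    times: np.ndarray
    states: np.ndarray
    stimulus_values: np.ndarray
    free_energy_values: Optional[np.ndarray] = None
    hamiltonian_values: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=complex)
        self.stimulus_values = np.asarray(self.stimulus_values, dtype=complex)
        n = self.times.size
        if self.states.shape != (n, 4):
            raise ValueError(f"states shape {self.states.shape} != ({n}, 4)")
        if self.stimulus_values.shape != (n,):
            raise ValueError("stimulus_values misaligned with time grid")
        if n > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
                raise ValueError("time grid must be strictly increasing with constant step")

    def __len__(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self) > 1 else 0.0

    def state_at(self, i: int) -> StateVector:
        return StateVector.from_array(self.states[i])

    def attach_energies(self, model: GenerativeModel) -> "Trajectory":
        """Record F(t) and H(t) along the trajectory (in place)."""
        F = np.empty(len(self), dtype=complex)
        H = np.empty(len(self), dtype=complex)
        for i in range(len(self)):
            psi = self.state_at(i)
            s = complex(self.stimulus_values[i])
            F[i] = free_energy(psi, s, model)
            H[i] = hamiltonian(psi, s, model)
        self.free_energy_values = F
        self.hamiltonian_values = H
        return self

    def to_dataframe(self):
        """Flat real-column view (t, s, Psi components, F, H)."""
        import pandas as pd

        cols = {
            "t": self.times,
            "s_re": self.stimulus_values.real,
            "s_im": self.stimulus_values.imag,
            "mu_re": self.states[:, 0].real,
            "mu_im": self.states[:, 0].imag,
            "a_re": self.states[:, 1].real,
            "a_im": self.states[:, 1].imag,
            "pmu_re": self.states[:, 2].real,
            "pmu_im": self.states[:, 2].imag,
            "pa_re": self.states[:, 3].real,
            "pa_im": self.states[:, 3].imag,
        }
        nan = np.full(len(self), np.nan)
        F = self.free_energy_values
        H = self.hamiltonian_values
        cols["F_re"] = F.real if F is not None else nan
        cols["F_im"] = F.imag if F is not None else nan
        cols["H_re"] = H.real if H is not None else nan
        cols["H_im"] = H.imag if H is not None else nan
        return pd.DataFrame(cols)


def _rhs(model: GenerativeModel):
    """Vector field on raw length-4 complex arrays (mu, a, p_mu, p_a)."""
    m = model.precisions
    g, f, pi = model.g, model.f, model.pi

    def rate(y: np.ndarray, s: complex) -> np.ndarray:
        mu, a, p_mu, p_a = y
        eps_z = s - g(mu, a)
        dg_dmu, dg_da = model.grad_g(mu, a)
        return np.array(
            [
                p_mu / m.m_w + f(mu),
                p_a / m.m_eta + pi(a),
                -p_mu * model.grad_f(mu) - m.m_z * eps_z * dg_dmu,
                -p_a * model.grad_pi(a) - m.m_z * eps_z * dg_da,
            ],
            dtype=complex,
        )

    return rate


def rk4_step(rate, y: np.ndarray, s0: complex, sh: complex, s1: complex, dt: float) -> np.ndarray:
    """One classical RK4 step with stimulus values at the stage times."""
    k1 = rate(y, s0)
    k2 = rate(y + 0.5 * dt * k1, sh)
    k3 = rate(y + 0.5 * dt * k2, sh)
    k4 = rate(y + dt * k3, s1)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate(
    model: GenerativeModel,
    psi0: StateVector,
    stimulus: Stimulus,
    t0: float = 0.0,
    dt: float = 0.01,
    n: int = 1000,
    record_energies: bool = True,
) -> Trajectory:
    """Classical RK4 trajectory of the recognition dynamics.

    The stimulus is evaluated at the stage times (t, t + dt/2, t + dt).
    F and H are recorded per sample unless ``record_energies`` is False.
    Raises :class:`DivergenceError` at the first non-finite state.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    if n < 0:
        raise ValueError("n must be non-negative")
    rate = _rhs(model)
    times = t0 + dt * np.arange(n + 1)
    svals = stimulus.sample(times)
    shalf = stimulus.sample(times[:-1] + 0.5 * dt) if n else np.empty(0, complex)

    states = np.empty((n + 1, 4), dtype=complex)
    y = psi0.to_array()
    states[0] = y
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(n):
            y = rk4_step(rate, y, svals[i], shalf[i], svals[i + 1], dt)
            if not np.all(np.isfinite(y.view(float))):
                raise DivergenceError(i + 1, float(times[i + 1]))
            states[i + 1] = y

    traj = Trajectory(times=times, states=states, stimulus_values=svals,
                      meta={"engine": "rk4", "dt": dt})
    if record_energies:
        traj.attach_energies(model)
    return traj


@dataclass
class ConvergenceReport:
    """Empirical order-of-accuracy estimate from a step-size sweep."""

    dts: list
    errors: list
    orders: list
    order_estimate: float
    reference_dt: float
    flagged: bool  # True when the estimate falls below 3.5 for the RK4 scheme
    excluded: list = field(default_factory=list)  # dts whose runs diverged


def convergence_report(
    model: GenerativeModel,
    psi0: StateVector,
    stimulus: Stimulus,
    horizon: float,
    dts: Sequence[float],
    reference: Optional[np.ndarray] = None,
) -> ConvergenceReport:
    """Richardson-style convergence order of the RK4 engine.

    Integrates over ``horizon`` at each step size and compares final
    states either with ``reference`` (exact final state, if available)
    or with the run at the finest step.  Requires at least three step
    sizes; divergent runs are excluded with a warning.
    """
    import warnings

    dts = sorted(float(d) for d in dts)
    if len(dts) < 3:
        raise ValueError("need at least three step sizes for an order estimate")
    finals: dict[float, np.ndarray] = {}
    excluded: list[float] = []
    for d in dts:
        n = int(round(horizon / d))
        if abs(n * d - horizon) > 1e-9 * max(1.0, horizon):
            raise ValueError(f"horizon {horizon} is not an integer multiple of dt {d}")
        try:
            traj = integrate(model, psi0, stimulus, 0.0, d, n, record_energies=False)
        except DivergenceError:
            warnings.warn(f"run at dt={d} diverged; excluded from order estimate")
            excluded.append(d)
            continue
        finals[d] = traj.states[-1]
    usable = [d for d in dts if d in finals]
    if reference is None:
        if len(usable) < 4:
            raise ValueError("not enough convergent runs to self-reference an order estimate")
        ref = finals[usable[0]]
        usable = usable[1:]
    else:
        ref = np.asarray(reference, dtype=complex)
    errors = [float(np.max(np.abs(finals[d] - ref))) for d in usable]
    orders = [
        float(np.log(errors[i + 1] / errors[i]) / np.log(usable[i + 1] / usable[i]))
        for i in range(len(usable) - 1)
        if errors[i] > 0 and errors[i + 1] > 0
    ]
    est = float(np.median(orders)) if orders else float("nan")
    return ConvergenceReport(
        dts=usable,
        errors=errors,
        orders=orders,
        order_estimate=est,
        reference_dt=usable[0],
        flagged=not (est >= 3.5),
        excluded=excluded,
    )
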