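"""Phase-space state, generative model, free energy and equations of motion.

The recognition dynamics of a single cortical column live in a complex
four-dimensional phase space ``Psi = (mu, a, p_mu, p_a)``: the perceptual
state ``mu``, the motor state ``a`` and their conjugate momenta, which are
the neural-mass-weighted prediction errors

    p_mu = m_w (dmu/dt - f(mu)),     p_a = m_eta (da/dt - pi(a)).

The Laplace-encoded free energy ``F`` plays the role of a Lagrangian; its
Legendre transform ``H`` generates symplectic equations of motion

    dPsi_i/dt = -J_ij dH/dPsi_j

with the canonical block matrix J.  All quadratic forms use *holomorphic*
(non-conjugated) products of the complex variables; conjugation enters only
the cognitive intensity |Psi_c|^2 defined in :mod:`bayesmech.linear`.
"""

from __future__ import annotations

import cmath
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StateVector",
    "Precisions",
    "PredictionErrors",
    "GenerativeModel",
    "ConfigurationError",
    "prediction_errors",
    "free_energy",
    "hamiltonian",
    "bm_vector_field",
    "action",
    "SYMPLECTIC_J",
]

#: Canonical symplectic block matrix of the equations of motion,
#: J = [[0, -1], [1, 0]] in 2x2 identity blocks, ordering (mu, a, p_mu, p_a).
SYMPLECTIC_J = np.array(
    [
        [0, 0, -1, 0],
        [0, 0, 0, -1],
        [1, 0, 0, 0],
        [0, 1, 0, 0],
    ],
    dtype=float,
)


class ConfigurationError(ValueError):
    """A model or parameter block is structurally invalid."""


def _require_finite(name: str, *values: complex) -> None:
    for v in values:
        if not cmath.isfinite(complex(v)):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class StateVector:
    """Complex phase-space point ``(mu, a, p_mu, p_a)``.

    The component ordering is fixed everywhere in the package:
    index 0 is the perceptual state, 1 the motor state, 2 and 3 the
    conjugate momenta (mass-weighted state and motor prediction errors).
    Units are arbitrary.
    """

    mu: complex
    a: complex
    p_mu: complex
    p_a: complex

    def __post_init__(self) -> None:
        _require_finite("StateVector component", self.mu, self.a, self.p_mu, self.p_a)

    def to_array(self) -> np.ndarray:
        return np.array([self.mu, self.a, self.p_mu, self.p_a], dtype=complex)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "StateVector":
        arr = np.asarray(arr, dtype=complex)
        if arr.shape != (4,):
            raise ValueError(f"state array must have shape (4,), got {arr.shape}")
        return cls(*[complex(x) for x in arr])

    @classmethod
    def zeros(cls) -> "StateVector":
        return cls(0j, 0j, 0j, 0j)


@dataclass(frozen=True)
class Precisions:
    """Neural masses (predictive precisions) of the three channels.

    Each mass is the inverse variance of the corresponding prediction
    channel: ``m_z = 1/sigma_z`` (sensory), ``m_w = 1/sigma_w`` (state),
    ``m_eta = 1/sigma_eta`` (motor).  Heavier mass means a more precise
    prediction.
    """

    m_z: float = 1.0
    m_w: float = 1.0
    m_eta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("m_z", "m_w", "m_eta"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ConfigurationError(f"precision {name} must be strictly positive, got {v!r}")

    @property
    def sigma_z(self) -> float:
        return 1.0 / self.m_z

    @property
    def sigma_w(self) -> float:
        return 1.0 / self.m_w

    @property
    def sigma_eta(self) -> float:
        return 1.0 / self.m_eta

    @classmethod
    def from_variances(cls, sigma_z: float, sigma_w: float, sigma_eta: float) -> "Precisions":
        return cls(m_z=1.0 / sigma_z, m_w=1.0 / sigma_w, m_eta=1.0 / sigma_eta)


@dataclass(frozen=True)
class PredictionErrors:
    """Channel-wise prediction errors ``(eps_w, eps_eta, eps_z)``.

    In phase space the state and motor errors are the momenta divided by
    their neural masses, exactly; the sensory error is ``s - g(mu, a)``.
    """

    eps_w: complex
    eps_eta: complex
    eps_z: complex


def _central_diff(fun: Callable[[complex], complex], x: complex, h: float) -> complex:
    # Holomorphic derivative: a real step suffices for analytic maps.
    return (fun(x + h) - fun(x - h)) / (2.0 * h)


@dataclass
class GenerativeModel:
    """Generative map and priors of the column, with their derivatives.

    ``g(mu, a)`` predicts the sensory signal, ``f(mu)`` is the prior
    drift of the perceptual state and ``pi(a)`` the policy prior on the
    motor state.  Analytic first-derivative maps should be supplied; if
    absent, a central finite-difference fallback (holomorphic step
    ``fd_step``) is used and its use is logged once.
    """

    g: Callable[[complex, complex], complex]
    f: Callable[[complex], complex]
    pi: Callable[[complex], complex]
    precisions: Precisions = field(default_factory=Precisions)
    dg_dmu: Optional[Callable[[complex, complex], complex]] = None
    dg_da: Optional[Callable[[complex, complex], complex]] = None
    df_dmu: Optional[Callable[[complex], complex]] = None
    dpi_da: Optional[Callable[[complex], complex]] = None
    params: dict = field(default_factory=dict)
    fd_step: float = 1e-6
    _fd_logged: bool = field(default=False, repr=False)

    def _note_fd(self) -> None:
        if not self._fd_logged:
            logger.info(
                "GenerativeModel: analytic derivative map(s) missing; "
                "using central finite differences with step %.3g",
                self.fd_step,
            )
            self._fd_logged = True

    def grad_g(self, mu: complex, a: complex) -> tuple[complex, complex]:
        if self.dg_dmu is not None and self.dg_da is not None:
            return self.dg_dmu(mu, a), self.dg_da(mu, a)
        self._note_fd()
        h = self.fd_step
        return (
            _central_diff(lambda x: self.g(x, a), mu, h),
            _central_diff(lambda x: self.g(mu, x), a, h),
        )

    def grad_f(self, mu: complex) -> complex:
        if self.df_dmu is not None:
            return self.df_dmu(mu)
        self._note_fd()
        return _central_diff(self.f, mu, self.fd_step)

    def grad_pi(self, a: complex) -> complex:
        if self.dpi_da is not None:
            return self.dpi_da(a)
        self._note_fd()
        return _central_diff(self.pi, a, self.fd_step)

    def check_derivatives(
        self, points: list[tuple[complex, complex]], tol: float = 1e-5
    ) -> float:
        """Compare declared derivative maps against finite differences.

        Returns the maximum absolute discrepancy over the sampled
        ``(mu, a)`` points and raises :class:`ConfigurationError` if it
        exceeds ``tol`` scaled by the local derivative magnitude.
        """
        worst = 0.0
        h = self.fd_step
        for mu, a in points:
            pairs = [
                (self.grad_g(mu, a)[0], _central_diff(lambda x: self.g(x, a), mu, h)),
                (self.grad_g(mu, a)[1], _central_diff(lambda x: self.g(mu, x), a, h)),
                (self.grad_f(mu), _central_diff(self.f, mu, h)),
                (self.grad_pi(a), _central_diff(self.pi, a, h)),
            ]
            for declared, fd in pairs:
                err = abs(declared - fd)
                worst = max(worst, err)
                if err > tol * (1.0 + abs(fd)):
                    raise ConfigurationError(
                        f"declared derivative {declared!r} disagrees with finite "
                        f"difference {fd!r} at (mu={mu!r}, a={a!r})"
                    )
        return worst


def prediction_errors(psi: StateVector, s: complex, model: GenerativeModel) -> PredictionErrors:
    """Prediction errors of the three channels at a phase-space point.

    The state and motor errors are recovered exactly from the momenta,
    ``eps_w = p_mu/m_w`` and ``eps_eta = p_a/m_eta``; the sensory error is
    the residual ``s - g(mu, a)``.
    """
    _require_finite("stimulus", s)
    m = model.precisions
    return PredictionErrors(
        eps_w=psi.p_mu / m.m_w,
        eps_eta=psi.p_a / m.m_eta,
        eps_z=s - model.g(psi.mu, psi.a),
    )


def free_energy(psi: StateVector, s: complex, model: GenerativeModel) -> complex:
    """Laplace-encoded free energy in phase-space form.

    F = p_mu^2/(2 m_w) + p_a^2/(2 m_eta) + (m_z/2)(s - g)^2, with
    holomorphic squares.  This equals the configuration-space quadratic
    form evaluated at dmu/dt = f + p_mu/m_w, da/dt = pi + p_a/m_eta.
    The additive constant (1/2)ln(sigma_z sigma_w sigma_eta) is omitted.
    """
    _require_finite("stimulus", s)
    m = model.precisions
    eps_z = s - model.g(psi.mu, psi.a)
    return (
        psi.p_mu**2 / (2.0 * m.m_w)
        + psi.p_a**2 / (2.0 * m.m_eta)
        + 0.5 * m.m_z * eps_z**2
    )


def hamiltonian(psi: StateVector, s: complex, model: GenerativeModel) -> complex:
    """Legendre transform of the free-energy Lagrangian.

    H = p_mu^2/(2 m_w) + p_a^2/(2 m_eta) + p_mu f(mu) + p_a pi(a)
        - (m_z/2)(s - g)^2.

    It satisfies H + F = p_mu dmu/dt + p_a da/dt and is conserved along
    trajectories under a constant stimulus.
    """
    _require_finite("stimulus", s)
    m = model.precisions
    eps_z = s - model.g(psi.mu, psi.a)
    return (
        psi.p_mu**2 / (2.0 * m.m_w)
        + psi.p_a**2 / (2.0 * m.m_eta)
        + psi.p_mu * model.f(psi.mu)
        + psi.p_a * model.pi(psi.a)
        - 0.5 * m.m_z * eps_z**2
    )


def bm_vector_field(psi: StateVector, s: complex, model: GenerativeModel) -> StateVector:
    """Right-hand side of the symplectic equations of motion.

    Returns the rates ``(dmu/dt, da/dt, dp_mu/dt, dp_a/dt)``:

        dmu/dt  = p_mu/m_w + f(mu)
        da/dt   = p_a/m_eta + pi(a)
        dp_mu/dt = -p_mu df/dmu - m_z (s - g) dg/dmu
        dp_a/dt  = -p_a dpi/da - m_z (s - g) dg/da

    equivalent to ``-J grad H`` with the fixed block matrix J.
    """
    _require_finite("stimulus", s)
    m = model.precisions
    eps_z = s - model.g(psi.mu, psi.a)
    dg_dmu, dg_da = model.grad_g(psi.mu, psi.a)
    return StateVector(
        mu=psi.p_mu / m.m_w + model.f(psi.mu),
        a=psi.p_a / m.m_eta + model.pi(psi.a),
        p_mu=-psi.p_mu * model.grad_f(psi.mu) - m.m_z * eps_z * dg_dmu,
        p_a=-psi.p_a * model.grad_pi(psi.a) - m.m_z * eps_z * dg_da,
    )


def action(trajectory, model: GenerativeModel) -> complex:
    """Time integral of the free energy along a trajectory (trapezoid rule).

    The trajectory must carry aligned state and stimulus samples on a
    uniform grid; the accumulated value is the informational action over
    the temporal horizon.
    """
    times = np.asarray(trajectory.times, dtype=float)
    if times.size == 0:
        return 0j
    if times.size > 1:
        steps = np.diff(times)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("action requires a uniform time grid")
    fvals = getattr(trajectory, "free_energy_values", None)
    if fvals is None:
        fvals = [
            free_energy(StateVector.from_array(state), s, model)
            for state, s in zip(trajectory.states, trajectory.stimulus_values)
        ]
    fvals = np.asarray(fvals, dtype=complex)
    if times.size == 1:
        return 0j
    return complex(np.trapezoid(fvals, times))
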