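"""Exact treatment of the linear generative model.

With linear maps ``g = tg0 + tg1 mu + tg2 a``, ``f = tf0 + tf1 mu`` and
``pi = tp0 + tp2 a`` the equations of motion collapse to a driven linear
system ``dPsi/dt + R Psi = I(t)`` with a traceless 4x4 complex relaxation
matrix R.  This module builds R and the source vector, solves for the
attractor centre ``Psi_c = R^{-1} I(s)``, propagates trajectories by
matrix exponentials (exactly for piecewise-linear-in-time stimuli),
performs the eigen/modal analysis and evaluates the cognitive intensity
``|Psi_c|^2 = Psi_c . conj(Psi_c)``.

All products of complex parameters are holomorphic (non-conjugated);
conjugation enters only the cognitive intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.linalg

from .core import ConfigurationError, GenerativeModel, Precisions, StateVector
from .integrate import Trajectory
from .stimuli import Stimulus

__all__ = [
    "LinearParams",
    "RelaxationSystem",
    "AttractorAnalysis",
    "DegenerateAttractorError",
    "DecompositionError",
    "InstabilityError",
    "build_relaxation_matrix",
    "attractor_centre",
    "propagate",
    "eigen_spectrum",
    "modal_expansion",
    "cognitive_intensity",
    "det_closed_form",
]


class DegenerateAttractorError(ValueError):
    """The relaxation matrix is (numerically) singular."""


class DecompositionError(RuntimeError):
    """The eigenbasis is too ill-conditioned for a modal expansion."""


class InstabilityError(RuntimeError):
    """The matrix-exponential propagator overflowed."""


@dataclass(frozen=True)
class LinearParams:
    """Parameters of the linear generative model.

    ``theta_g0/g1/g2`` are the sensory intercept, perceptual gain and
    motor gain; ``theta_f0/f1`` the state-prior intercept and rate;
    ``theta_pi0/pi2`` the policy intercept and rate (the linear policy
    coefficient is conventionally indexed 2, not 1).  All may be complex.
    """

    theta_g0: complex = 0j
    theta_g1: complex = 0j
    theta_g2: complex = 0j
    theta_f0: complex = 0j
    theta_f1: complex = 0j
    theta_pi0: complex = 0j
    theta_pi2: complex = 0j
    precisions: Precisions = field(default_factory=Precisions)

    def __post_init__(self) -> None:
        for name in ("theta_g0", "theta_g1", "theta_g2", "theta_f0",
                     "theta_f1", "theta_pi0", "theta_pi2"):
            v = complex(getattr(self, name))
            if not (np.isfinite(v.real) and np.isfinite(v.imag)):
                raise ConfigurationError(f"{name} must be finite, got {v!r}")

    def to_generative_model(self) -> GenerativeModel:
        """The equivalent :class:`GenerativeModel` with analytic derivatives."""
        tg0, tg1, tg2 = self.theta_g0, self.theta_g1, self.theta_g2
        tf0, tf1 = self.theta_f0, self.theta_f1
        tp0, tp2 = self.theta_pi0, self.theta_pi2
        return GenerativeModel(
            g=lambda mu, a: tg0 + tg1 * mu + tg2 * a,
            f=lambda mu: tf0 + tf1 * mu,
            pi=lambda a: tp0 + tp2 * a,
            dg_dmu=lambda mu, a: tg1,
            dg_da=lambda mu, a: tg2,
            df_dmu=lambda mu: tf1,
            dpi_da=lambda a: tp2,
            precisions=self.precisions,
            params={"kind": "linear"},
        )


@dataclass
class RelaxationSystem:
    """The matrix R and stimulus-dependent source vector of the linear system."""

    R: np.ndarray
    params: LinearParams

    def source(self, s: complex) -> np.ndarray:
        """Source vector I(s); the stimulus enters only rows 3-4."""
        p = self.params
        m_z = p.precisions.m_z
        return np.array(
            [
                p.theta_f0,
                p.theta_pi0,
                -m_z * p.theta_g1 * s + m_z * p.theta_g0 * p.theta_g1,
                -m_z * p.theta_g2 * s + m_z * p.theta_g0 * p.theta_g2,
            ],
            dtype=complex,
        )

    def source_of_time(self, stimulus: Stimulus) -> Callable[[float], np.ndarray]:
        return lambda t: self.source(stimulus(t))

    @property
    def trace(self) -> complex:
        return complex(np.trace(self.R))

    @property
    def det(self) -> complex:
        return complex(np.linalg.det(self.R))


def build_relaxation_matrix(params: LinearParams) -> RelaxationSystem:
    """Assemble the 4x4 relaxation matrix, row/column order (mu, a, p_mu, p_a).

    R is traceless by construction (the diagonal rates cancel pairwise),
    which forces the eigenvalue sum rule ``sum(lambda) = 0``.
    """
    p = params
    m = p.precisions
    tg1, tg2 = p.theta_g1, p.theta_g2
    R = np.array(
        [
            [-p.theta_f1, 0.0, -1.0 / m.m_w, 0.0],
            [0.0, -p.theta_pi2, 0.0, -1.0 / m.m_eta],
            [-m.m_z * tg1 * tg1, -m.m_z * tg1 * tg2, p.theta_f1, 0.0],
            [-m.m_z * tg1 * tg2, -m.m_z * tg2 * tg2, 0.0, p.theta_pi2],
        ],
        dtype=complex,
    )
    return RelaxationSystem(R=R, params=params)


def det_closed_form(params: LinearParams) -> complex:
    """Closed-form determinant of R.

    det R = tf1^2 tp2^2 + (m_z/m_w) tg1^2 tp2^2 + (m_z/m_eta) tf1^2 tg2^2
    (holomorphic squares).
    """
    p = params
    m = p.precisions
    tf1, tp2, tg1, tg2 = p.theta_f1, p.theta_pi2, p.theta_g1, p.theta_g2
    return (
        tf1 * tf1 * tp2 * tp2
        + (m.m_z / m.m_w) * tg1 * tg1 * tp2 * tp2
        + (m.m_z / m.m_eta) * tf1 * tf1 * tg2 * tg2
    )


def attractor_centre(
    params: LinearParams, s: complex = 0j, det_tol: float = 1e-12
) -> StateVector:
    """Fixed point ``Psi_c = R^{-1} I(s)`` of the linear dynamics.

    Raises :class:`DegenerateAttractorError` when R is numerically
    singular (|det R| below ``det_tol`` relative to ||R||^4).
    """
    sys = build_relaxation_matrix(params)
    scale = max(np.linalg.norm(sys.R), 1.0) ** 4
    det = sys.det
    if abs(det) <= det_tol * scale:
        raise DegenerateAttractorError(
            f"relaxation matrix is singular (det(R) = {det!r}); no unique attractor centre"
        )
    psi_c = np.linalg.solve(sys.R, sys.source(s))
    return StateVector.from_array(psi_c)


def cognitive_intensity(centre) -> float:
    """Conjugate-squared norm ``sum_i |Psi_c,i|^2`` of a centre (real, >= 0)."""
    arr = centre.to_array() if isinstance(centre, StateVector) else np.asarray(centre, complex)
    return float(np.sum(arr * np.conj(arr)).real)


@dataclass
class AttractorAnalysis:
    """Eigen-structure of R and the attractor it implies.

    ``eigenvalues`` are ``lambda_alpha = i omega_alpha``; ``eigenvectors``
    holds ``phi_alpha`` as columns; ``coefficients`` are the modal
    expansion weights when computed.  ``max_real_part`` is the
    stationarity diagnostic: eigenvalues with |Re| below a small multiple
    of ||R|| are centre-like (oscillatory, non-decaying modes).
    """

    centre: StateVector
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    intensity: float
    coefficients: Optional[np.ndarray] = None
    trace: complex = 0j
    det: complex = 0j
    det_closed: complex = 0j
    max_real_part: float = 0.0
    centre_like: Optional[np.ndarray] = None
    stimulus_value: complex = 0j

    def omegas(self) -> np.ndarray:
        """Angular frequencies, from lambda = i omega (omega = -i lambda)."""
        return -1j * self.eigenvalues


def _sorted_eig(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, V = np.linalg.eig(R)
    order = np.lexsort((lam.real, lam.imag))
    return lam[order], V[:, order]


def eigen_spectrum(
    params: LinearParams,
    s: complex = 0j,
    centre_tol: float = 1e-6,
) -> AttractorAnalysis:
    """Eigenvalues/vectors of R with the sum-rule and determinant checks.

    Eigenvalues with ``|Re lambda| < centre_tol * ||R||`` are classified
    centre-like; the classification is diagnostic only (whether the
    printed parameter sets give exactly pure-imaginary spectra is not
    asserted).
    """
    sys = build_relaxation_matrix(params)
    lam, V = _sorted_eig(sys.R)
    residual = np.max(np.abs(sys.R @ V - V * lam))
    norm = np.linalg.norm(sys.R)
    if not np.all(np.isfinite(lam.view(float))) or residual > 1e-8 * max(norm, 1.0):
        raise RuntimeError(f"eigen-decomposition residual too large: {residual:g}")
    centre = attractor_centre(params, s)
    return AttractorAnalysis(
        centre=centre,
        eigenvalues=lam,
        eigenvectors=V,
        intensity=cognitive_intensity(centre),
        trace=sys.trace,
        det=sys.det,
        det_closed=det_closed_form(params),
        max_real_part=float(np.max(np.abs(lam.real))),
        centre_like=np.abs(lam.real) < centre_tol * max(norm, 1.0),
        stimulus_value=complex(s),
    )


def modal_expansion(
    params: LinearParams,
    psi0: StateVector,
    s_inf: complex,
    cond_bound: float = 1e8,
) -> AttractorAnalysis:
    """Expansion of the constant-stimulus solution over eigenmodes.

    Solves ``Phi c = Psi(0) - Psi_bar_c`` so that the trajectory is
    ``Psi(t) = Psi_bar_c + sum_alpha c_alpha exp(-lambda_alpha t) phi_alpha``
    with ``Psi_bar_c = R^{-1} I(s_inf)``.  Raises
    :class:`DecompositionError` when the eigenvector matrix condition
    number exceeds ``cond_bound`` (fall back to :func:`propagate`).
    """
    analysis = eigen_spectrum(params, s=s_inf)
    V = analysis.eigenvectors
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > cond_bound:
        raise DecompositionError(
            f"eigenbasis condition number {cond:g} exceeds bound {cond_bound:g}"
        )
    c = np.linalg.solve(V, psi0.to_array() - analysis.centre.to_array())
    analysis.coefficients = c
    return analysis


def _linear_energies(
    params: LinearParams, states: np.ndarray, svals: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised F(t), H(t) along a linear-model trajectory."""
    p = params
    m = p.precisions
    mu, a, pmu, pa = states[:, 0], states[:, 1], states[:, 2], states[:, 3]
    eps_z = svals - (p.theta_g0 + p.theta_g1 * mu + p.theta_g2 * a)
    kinetic = pmu**2 / (2.0 * m.m_w) + pa**2 / (2.0 * m.m_eta)
    F = kinetic + 0.5 * m.m_z * eps_z**2
    H = (
        kinetic
        + pmu * (p.theta_f0 + p.theta_f1 * mu)
        + pa * (p.theta_pi0 + p.theta_pi2 * a)
        - 0.5 * m.m_z * eps_z**2
    )
    return F, H


def _phi_matrices(R: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-step propagator E = exp(-R dt) and the source-quadrature blocks.

    Uses the augmented-exponential (Van Loan) construction, valid for
    singular R:  G1 = int_0^dt exp(-R (dt-u)) du,
                 G2 = int_0^dt exp(-R (dt-u)) u du.
    """
    A = -R
    n = R.shape[0]
    M = np.zeros((3 * n, 3 * n), dtype=complex)
    M[:n, :n] = A
    M[:n, n : 2 * n] = np.eye(n)
    M[n : 2 * n, 2 * n :] = np.eye(n)
    EM = scipy.linalg.expm(M * dt)
    E = EM[:n, :n]
    G1 = EM[:n, n : 2 * n]
    G2 = EM[:n, 2 * n :]
    return E, G1, G2


def propagate(
    params: LinearParams,
    psi0: StateVector,
    stimulus: Stimulus,
    t0: float = 0.0,
    dt: float = 0.01,
    n: int = 1000,
    record_energies: bool = True,
) -> Trajectory:
    """Matrix-exponential solution of ``dPsi/dt + R Psi = I(t)``.

    For null/constant stimuli the closed form
    ``Psi(t) = Psi_c + exp(-R t)(Psi(0) - Psi_c)`` is evaluated through
    the eigendecomposition (stepping is used as a fallback if R is
    singular or defective).  For time-varying stimuli the source is
    treated as piecewise linear on each step and convolved exactly with
    the one-step matrix exponential, which preserves the closed-form
    constant-stimulus limits.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    sys = build_relaxation_matrix(params)
    times = t0 + dt * np.arange(n + 1)
    svals = stimulus.sample(times)

    states: Optional[np.ndarray] = None
    if stimulus.is_static:
        s = stimulus.static_value()
        try:
            centre = attractor_centre(params, s).to_array()
            lam, V = _sorted_eig(sys.R)
            cond = np.linalg.cond(V)
            if np.isfinite(cond) and cond < 1e10:
                coeff = np.linalg.solve(V, psi0.to_array() - centre)
                # Psi(t) = Psi_c + V diag(exp(-lam (t - t0))) coeff
                phases = np.exp(-np.outer(times - t0, lam))  # (n+1, 4)
                states = centre[None, :] + (phases * coeff[None, :]) @ V.T
                if not np.all(np.isfinite(states.view(float))):
                    raise InstabilityError(
                        "closed-form propagation overflowed; "
                        f"max growth rate Re(-lambda) = {np.max(-lam.real):g}"
                    )
        except DegenerateAttractorError:
            states = None

    if states is None:
        E, G1, G2 = _phi_matrices(sys.R, dt)
        if not np.all(np.isfinite(E.view(float))):
            lam = np.linalg.eigvals(sys.R)
            raise InstabilityError(
                "one-step matrix exponential is non-finite; "
                f"max growth rate Re(-lambda) = {np.max(-lam.real):g}"
            )
        sources = np.array([sys.source(s) for s in svals])
        states = np.empty((n + 1, 4), dtype=complex)
        y = psi0.to_array()
        states[0] = y
        for i in range(n):
            b = (sources[i + 1] - sources[i]) / dt
            y = E @ y + G1 @ sources[i] + G2 @ b
            states[i + 1] = y
        if not np.all(np.isfinite(states.view(float))):
            lam = np.linalg.eigvals(sys.R)
            raise InstabilityError(
                f"propagated state overflowed; max growth rate Re(-lambda) = {np.max(-lam.real):g}"
            )

    traj = Trajectory(times=times, states=states, stimulus_values=svals,
                      meta={"engine": "expm", "dt": dt})
    if record_energies:
        F, H = _linear_energies(params, traj.states, traj.stimulus_values)
        traj.free_energy_values = F
        traj.hamiltonian_values = H
    return traj
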