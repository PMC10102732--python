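# Methods

## Model

The package simulates recognition dynamics of a single cortical column as a
Hamiltonian system on a complex four-dimensional phase space
Ψ = (μ, a, p_μ, p_a).  The Laplace-encoded free energy

F(μ, a; s) = (m_z/2)(s − g(μ, a))² + (m_w/2)(μ̇ − f(μ))² + (m_η/2)(ȧ − π(a))²

is treated as a Lagrangian; the momenta p_μ = m_w(μ̇ − f), p_a = m_η(ȧ − π)
are the mass-weighted prediction errors, and the Legendre transform gives

H = p_μ²/2m_w + p_a²/2m_η + p_μ f(μ) + p_a π(a) − (m_z/2)(s − g)².

The equations of motion are Ψ̇ᵢ = −J_ij ∂H/∂Ψⱼ with the canonical symplectic
block matrix J.  The identity H + F = p_μ μ̇ + p_a ȧ holds pointwise and is
enforced by a property test; under a constant stimulus H is a conserved
quantity, which is the main integration diagnostic.

**Complex-arithmetic convention.**  All parameters and state components may
be complex, and every quadratic form in F, H and every product inside the
relaxation matrix is holomorphic (no conjugation).  Conjugation appears in
exactly one place: the cognitive intensity |Ψ_c|² = Σᵢ Ψ_c,i conj(Ψ_c,i).
This convention is what reproduces the reference centre (−10, 10, −20) and
the closed-form determinant; a sesquilinear convention does not.

**Constant term.**  The additive constant (1/2)ln(σ_z σ_w σ_η) is omitted
from F.  It shifts F and H by a state-independent amount and does not affect
the dynamics.

**Scalar state space.**  μ and a are complex scalars (one column, eight real
phase-space dimensions).  Vector-valued or multi-column extensions, and any
learning of the generative parameters θ, are out of scope.

## Linear model

With g = θ_g⁽⁰⁾ + θ_g⁽¹⁾μ + θ_g⁽²⁾a, f = θ_f⁽⁰⁾ + θ_f⁽¹⁾μ,
π = θ_π⁽⁰⁾ + θ_π⁽²⁾a the dynamics are Ψ̇ + RΨ = I(s(t)).  R is traceless by
construction (its diagonal is (−θ_f⁽¹⁾, −θ_π⁽²⁾, θ_f⁽¹⁾, θ_π⁽²⁾)), so the
eigenvalue sum rule Σλ_α = 0 holds for every parameter draw; the determinant
has the closed form

det R = θ_f⁽¹⁾²θ_π⁽²⁾² + (m_z/m_w)θ_g⁽¹⁾²θ_π⁽²⁾² + (m_z/m_η)θ_f⁽¹⁾²θ_g⁽²⁾²

(holomorphic squares), checked to 1e−10 against the numerical determinant.
The stimulus enters only rows 3–4 of the source vector.

**Propagation.**  For null/constant stimuli the closed form
Ψ(t) = Ψ_c + e^{−Rt}(Ψ(0) − Ψ_c) is evaluated through the eigendecomposition
(vectorised over the whole time grid).  For time-varying stimuli the source
is treated as piecewise linear on each step and convolved exactly with the
one-step matrix exponential: the blocks E = e^{−R dt},
G₁ = ∫₀^dt e^{−R(dt−u)}du and G₂ = ∫₀^dt e^{−R(dt−u)}u du are read off a
single augmented (Van Loan) matrix exponential, which remains valid for
singular R.  This stepping rule is exact for constant and linear-in-time
sources, so the constant-stimulus closed forms are preserved identically;
for the sigmoid stimulus its deviation from the generic integrator is at
the 1e−5 level at dt = 0.01.  The dense matrix exponential is delegated to
`scipy.linalg.expm`; its accuracy is certified against the ODE integrator
rather than mandated.

**Stationarity classification.**  Eigenvalues with |Re λ| < 1e−6·‖R‖ are
labelled centre-like.  The classification is diagnostic only; whether the
reference spectrum is exactly pure imaginary is reported, not asserted (its
characteristic polynomial is λ⁴ + 5λ² + 2, which does place all four roots
on the imaginary axis).

## Time integration

A fixed-step classical fourth-order Runge–Kutta scheme (stimulus evaluated
at stage times) is the only engine for nonlinear generative models and the
cross-check for the linear closed forms.  Default dt = 0.01 with horizons up
to t = 500, matching the largest snapshot time of the bifurcation
experiment.  No adaptive stepping: bit-reproducibility of experiment scripts
takes precedence.  Derivative maps for user models default to central finite
differences (holomorphic step, default 1e−6) with the fallback logged.

Accuracy, measured against the exact propagator for the reference model:
empirical convergence order 4.0; Hamiltonian drift over t ∈ [0, 500] at
dt = 0.01 about 3e−4 on |H(0)| ≈ 4e3 (relative 8e−8), shrinking faster than
fourth order in dt.  One caveat is intrinsic to any explicit fourth-order
one-step method: the per-step phase error (ω dt)⁵/120 of the fastest mode
(ω ≈ 2.136) accumulates linearly, so the sup-norm gap to the exact solution
over 50 000 steps is ≈ 2e−6 per unit modal amplitude — about 1.6e−4 for the
experiment-scale orbits (amplitude ~10²).  Phase error moves states along
the orbit without leaving it, which is why energy conservation is orders of
magnitude better than the sup-norm gap.  Conclusions that depend on
pointwise trajectory agreement at the 1e−6 level therefore use the exact
propagator, not the RK4 engine.

## Stimuli

Null, constant, logistic onset s(t) = s_∞/(1 + e^{−k(t−t_m)}) and sampled
series (linear interpolation, constant extrapolation at the ends).  The
experiments use s_∞ = 100, k = 0.2, t_m = 250.  Stimuli are complex-capable
but the experiments pass real values.  Representable-range convention: for
k(t − t_m) < −700 the sigmoid returns exactly 0 (the unguarded expression
would overflow).

## Experiments

* **Spontaneous dynamics** — the particular solution
  Ψ_sp(t) = Ψ_c − R⁻¹e^{−Rt}I_sp starts at the origin; the run reports the
  centre (real projection (−10, 10, −20)) and spectrum.
* **Static stimulus** — trajectory under s = 100 from a spontaneous state,
  plus the intensity sweep |Ψ_c(s)|² for neural masses (1,1,1) vs (10,1,10).
  The sweep range is a config knob (default s ∈ [0, 200]); the ordering
  "heavier masses → weaker intensity" is asserted, not a numeric target.
* **Sigmoid stimulus** — the motor-inference readout is Im[p_a](t).  Note
  the two attractor centres share Im[p_a] = −10, so the transition is most
  visible in Im[μ] (−10 → −110).
* **Bifurcation** — snapshot windows ending at t ∈ {5, 100, 260, 500}.  The
  published initial state gives only (Re μ, Re a, Re p_μ) = (−16.9, 21.1,
  −13.3) of an 8-real-dimensional state "from the spontaneous attractor";
  the completion convention simulates the spontaneous orbit and picks the
  sample minimising Euclidean distance to that triple in those three
  coordinates (achieved distance ≈ 0.008, logged).  Each snapshot window
  covers the trailing half of the inter-snapshot interval; window means are
  compared with the two centres at 5% of the centre shift (‖Ψ̄_c(100) −
  Ψ_c(0)‖ ≈ 158.1), a tolerance chosen to sit well above the residual
  oscillation of a window mean (~0.7) and well below the shift itself.  The
  empirical relaxation time (first time the running mean enters and stays
  within that ball) is ≈ 270.
* **Initial states** for the static/sigmoid runs are drawn from the
  spontaneous orbit (the end-of-horizon sample, a fixed deterministic
  convention); figure outputs are numeric CSV/JSON, not rendered images.

## Stochastic thermodynamics

Euler–Maruyama integration of overdamped Langevin dynamics
dμ/dt = f + w, ⟨w(t)w(t′)⟩ = Iδ(t−t′), I = 2k_BT/(mγ) (k_B = 1, arbitrary
units; the fluctuation–dissipation consistency of a user-supplied noise
strength is enforced).  Work uses the Sekimoto parameter-update convention
W = Σ [V(μ_t, λ_{t+dt}) − V(μ_t, λ_t)], the standard choice in the
fluctuation-theorem literature; alternative conventions are out of scope.
Built-in protocols ship with analytic free-energy changes: the dragged
harmonic trap (ΔF = 0) and the stiffness switch (ΔF = (1/2β)ln(κ_f/κ_i)).
Initial states are drawn from the initial-endpoint equilibrium, as the
Jarzynski derivation requires.  Estimator means of e^{−β(W−ΔF)} are
accumulated in log domain (a `log_mean_exp` field stays finite even when
the linear-scale mean saturates).  The reference ensemble is 10⁴ paths at
dt = 1e−3, β = 1, drag speed 1 over unit time: ⟨W⟩ ≈ 0.37 analytically, and
both integral fluctuation theorems hold within Monte-Carlo error (the two
averages coincide path-by-path because ΔS_tot/k_B ≡ β(W − ΔF) under the
isothermal identity).

The Fokker–Planck layer computes only steady-state diagnostics (the
transient p(μ, t) evolution is not solved): the Boltzmann density
p_eq ∝ e^{−βV} on a regular 1D/2D grid (cell-sum normalisation; refused if
boundary mass is non-negligible) and the flux j = pf − D∇p with
central-difference gradients.  Equilibrium pairs give max‖j‖ → 0 at second
order in the spacing; adding a solenoidal (rotational) drift to a Gaussian
steady state gives j ≠ 0 with ∇·j → 0, the broken-detailed-balance
signature.  Boundary stencils (one-sided differences) are excluded from the
summary maxima.

## What the synthetic conditions do and do not show

All inputs are generated in-package from printed parameter values; there is
no external data.  The deterministic experiments therefore validate the
mechanics (exact propagation, conservation laws, attractor geometry) rather
than any fit to recordings; the Langevin ensembles validate estimator
correctness on potentials with known ΔF, not the thermodynamics of real
neural tissue.  Arbitrary units throughout; no unit system is enforced.

## Known limitations

* Gauge-field constructions for the non-equilibrium steady-state flux
  (vector potentials, Biot–Savart-type reconstructions) are not implemented;
  nothing quantitative exercises them.
* The RK4 engine is not symplectic; long-horizon pointwise accuracy at the
  1e−6 level requires the exact linear propagator (see above).
* Master-equation (jump-process) simulation, underdamped Langevin dynamics
  and transient Fokker–Planck solutions are out of scope.
* Learning/updating the generative parameters θ is explicitly out of scope.
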