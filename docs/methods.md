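# Methods

## Model

The package analyses two-species reaction–diffusion systems on a unit
interval,

    u_t = (D_u / L²) u_xx + f(u, v),
    v_t = (D_v / L²) v_xx + g(u, v),

where the domain scale `L` multiplies the physical length, so growing or
shrinking the domain is equivalent to moving `L`, and `L` is used
throughout as the bifurcation parameter.  The kinetics are arbitrary
closed-form expressions, at least three times differentiable at the
homogeneous steady state `(u_s, v_s)`, held as sympy expressions so every
partial derivative up to third order is exact.  Two boundary conditions
are treated, each with its natural domain so only cosine modes appear:

* **Dirichlet** (in this package's specific sense): both concentrations
  pinned to the homogeneous steady state at the walls, domain
  `[-1/2, 1/2]`, even solutions expanded in `cos((2n+1)πx)`;
* **Neumann**: zero flux, domain `[0, 1]`, expansions in `cos(nπx)`.

The analysis is local to one steady state (the root reached from the
user's initial guess); multiple steady states are not enumerated.
Positivity of the state is enforced by default because the variables
model concentrations, with an explicit opt-out for mathematically
motivated kinetics.

## Linear Turing analysis

Standard: Routh–Hurwitz stability of the diffusion-free system
(`f_u + g_v < 0`, `det J > 0`), the dispersion quadratic
`det(λI + (k²/L²)D − J) = 0`, the window `k_-² < k² < k_+²` of unstable
squared wavenumbers, and the critical scale

    L_c² = 2 D_u D_v π² / (h + sqrt(h² − 4 D_u D_v det J)),   h = D_u g_v + f_u D_v,

at which the first admissible mode `k = π` (shared by both boundary
conditions) touches neutrality.  The kernel and adjoint-kernel vectors of
`A = J − (π²/L_c²) D` are extracted by SVD and normalized with
v-component 1; their u-components are the ratios Λ and η used in the
projections.

The `(L, D_v)` patterning region of the first mode is mapped two ways:
a generic sign-scan of the leading dispersion root with 1-D root
bracketing of the neutral curve per `D_v` column (absolute tolerance
1e-8 in `L`, far below any printed precision), and closed-form extremes:
the vertical asymptote `L_min = π sqrt(D_u / f_u)` and the minimum
admissible `D_v` obtained by bounded scalar minimization of the explicit
boundary function `D_v(L)`.

## Weakly nonlinear expansion

A multiple-scales ansatz about onset, `L = L_c + εL₁ + ε²L₂`,
`u = u_s + εU₁ + ε²U₂ + ε³U₃`, slow times `t₁ = εt`, `t₂ = ε²t`, with
critical mode `U₁ = a Φ cos(πx)`.  Orders of ε give a cascade of linear
problems with the singular operator `𝓛 = (1/L_c²)D∂ₓₓ + J`; each level is
solvable only if its forcing is orthogonal to the adjoint kernel
(Fredholm alternative), and enforcing that yields the amplitude ODE.

The boundary conditions decide where the first solvability condition
bites.  Under Dirichlet conditions `cos²(πx)` is resonant — its odd-cosine
expansion has the coefficient `8/(3π)` along the critical mode — so a
quadratic term survives at second order and the bifurcation is generic
**transcritical**:

    da/dt₁ = p1 L₁ a + p2 a².

Under Neumann conditions `cos²(πx) = (1 + cos 2πx)/2` is orthogonal to
`cos(πx)`, second order is silent (`L₁ = 0`), and third order produces the
canonical **pitchfork** `da/dt₂ = lin·L₂ a − cub·a³`.

All second-order fields are obtained numerically: each non-critical
Fourier mode is a regular 2×2 solve, and the critical mode a gauge-fixed
singular solve.  The third-order secular projection collects the slow
drift of U₁ and U₂, the `L₂` and `L₁²` corrections of the diffusion
prefactor, the `U₁·U₂` cross terms (an infinite mode sum under Dirichlet,
exactly two modes under Neumann) and the direct `U₁³` term, giving the
third-order transcritical equation

    (1/ε) da/dt = (p1(L₁+εL₂) − p3 ε L₁²) a + (p2 − p4 ε L₁) a² − ε p5 a³.

Coefficients are reported ε-stripped, displayed at 2 decimal places.

### Conventions that fix the numbers

* **Sign.** The kernel vector is negated when that makes `p2 > 0`, so the
  branch with `a > 0` is the subcritical one.  `p1`, `p3`, `p5` and the
  pitchfork pair are invariant under this flip.
* **Gauge.** The critical-mode coefficient of `U₂` is defined only up to a
  kernel-direction multiple α.  The package zeroes the **v-component** of
  that coefficient (`gauge="v0"`), so the critical mode of `U₂` carries a
  u-component only; α itself is 0 in that frame.  `p3` and `p5` are
  gauge-invariant, `p4` is not — the v0 frame is the one in which the
  reported `p4` is meaningful.  The alternative gauges (`u0`,
  kernel-orthogonal) are kept available and tested for invariance of
  `p3`/`p5`.
* **Truncation.** The Dirichlet second-order field retains
  `truncation_N = 128` odd cosine modes by default; the per-mode
  coefficients decay like mode⁻⁵ (the forcing series decays cubically and
  the mode matrices gain another factor mode⁻²), and every cubic assembly
  is recomputed at `2N` and required to agree to 1e-6 relative.

For the built-in activator-depletion fixture (`f = 1 − 2u + u²v`,
`g = 3 − u²v`, `D_u = 1/1000`, `D_v = 1/10`) these conventions give
`p1 = 13.93`, `p2 = 15.19`, `p3 = 237.69`, `p4 = 268.02`, `p5 = 35.13`
and the Neumann pair `lin = 13.93`, `cub = 222.81`, each recomputed (not
stored) by the test suite and the acceptance script.  Three independent
cross-checks pin these routes: `p1` and `lin` equal the finite-differenced
derivative of the leading dispersion root at `L_c`; converged PDE
amplitudes match the transcritical steady state `-p1 L₁ / p2` with a
defect that shrinks quadratically towards onset; and converged Neumann
patterns match `±sqrt(lin (L−L_c) / cub)` built from the computed cubic
coefficient.

## PDE simulation

Method of lines, second-order central differences on a uniform grid
(default 256 nodes).  Dirichlet runs keep only interior unknowns with the
pinned wall values entering the stencil as constant sources, so the pin is
bit-exact at every step; Neumann runs use ghost-node reflection.  Time
stepping is fully implicit BDF (scipy `solve_ivp`) with the analytic
sparse Jacobian, relative tolerance 1e-8, absolute 1e-10; these are tight
enough that the quantitative checks are integrator-independent, and long
growing-domain runs may relax them.  Initial data follow the study
conventions: pointwise `|steady + U(−σ, σ)|` noise (σ = 0.01 default,
seeded, boundary nodes pinned or copied from their neighbour), or the
signed parabolas `u₀ = u_s ± (1/2 − x)(x + 1/2)` whose sign selects the
sub- or supercritical branch near onset; the v-component of the parabola
perturbations is left at `v_s` (only the u-perturbation is prescribed by
the construction, and the branch selection depends only on the sign of
the projection onto the critical mode).  Uniform slow growth is modelled
by `L(t) = L₀(1 + t/100)` entering through the diffusion prefactor only;
the dilution term of a genuinely growing domain is neglected, which is
accurate in the slow-growth limit.  The critical-mode amplitude is read
off a trace by the adjoint projection
`a = 2⟨ψ·(U − U_s), cos πx⟩ / (ψ·Φ)`, which is exact on synthetic
kernel-direction fields and insensitive to the other cosine modes.

## Pseudo-arclength continuation

Steady states of the same discretization are continued in `L` with a
secant/tangent predictor and a bordered Newton corrector under the
arclength constraint `w⟨τ_y, Δy⟩/n + τ_L ΔL = 0`.  The `1/n` state
scaling makes diagrams resolution-independent; the extra weight
`w = 0.04` keeps arclength from being swallowed by the state when the
large-amplitude branch climbs from `u ≈ 2` to `u ≈ 50`.  Steps adapt
between 1e-7 and 0.05 on corrector iteration count.  Every accepted point
carries the five rightmost eigenvalues of the dense linearization;
stability changes without a fold are refined by bisection (1e-4 in `L`),
folds by a three-point parabola in arclength.  Branch switching at a
simple bifurcation seeds the corrector at `y ± δ·φ` with φ the critical
eigenvector, enlarging δ if the corrector falls back.  The in-branch
Newton targets residual 1e-8 in the max norm: the `1/h²` stencil times
machine epsilon puts the attainable floor near 3e-10 on fine grids at
small `L`, so demanding 1e-10 there only burns iterations.  Default
resolution for quantitative corridor locations is 200 interior nodes; the
fixture's fold and bifurcation locations move by under 1% between 128 and
256 nodes.

## What the fixture does and does not show

The built-in kinetics are a mathematically motivated Turing benchmark,
not a calibrated model of any organism: passing tests demonstrate the
correctness of the analysis chain (linear landmarks, amplitude-equation
coefficients, bifurcation topology, branch corridors), not biological
realism.  Real morphogen systems add stochasticity, curved and genuinely
growing geometries, dilution, and parameter heterogeneity, all outside
scope here.  Known limitations: one spatial dimension and exactly two
species; no Hopf/wave instabilities (the dispersion roots are tracked
only through their real parts); no deflation, so disconnected branches
are found only via switching from known ones; fifth-order expansions are
not derived; Robin (mixed) boundary conditions are not swept.
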