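"""Weakly nonlinear amplitude equations at the first Turing bifurcation.

The solution is expanded in a small parameter eps about the critical
domain scale, L = L_c + eps*L1 + eps^2*L2, with slow times t1 = eps*t and
t2 = eps^2*t, and U = eps*U1 + eps^2*U2 + eps^3*U3.  The critical mode is
U1 = a * Phi * cos(pi x) with Phi the kernel vector of the critical-mode
matrix.  Applying the Fredholm solvability condition (forcing orthogonal
to the adjoint kernel) order by order yields an amplitude ODE whose
structure depends on the boundary conditions:

* Dirichlet (concentrations pinned to the steady state, domain
  [-1/2, 1/2], odd-cosine basis): cos^2(pi x) is resonant, so a quadratic
  term survives at second order and the bifurcation is transcritical,

      da/dt1 = p1 L1 a + p2 a^2,

  with third-order corrections

      (1/eps) da/dt = (p1 (L1 + eps L2) - p3 eps L1^2) a
                      + (p2 - p4 eps L1) a^2 - eps p5 a^3.

* Neumann (zero flux, domain [0, 1]): cos^2(pi x) = (1 + cos(2 pi x))/2 is
  orthogonal to the critical mode, second order is silent (L1 = 0) and the
  first nontrivial balance at third order is the canonical pitchfork

      da/dt2 = lin * L2 * a - cub * a^3.

All coefficients are reported eps-stripped, as pure numbers.

Sign convention: the kernel vector is normalized with v-component 1 and
its overall sign is flipped when that makes p2 positive, so the
transcritical branch with a > 0 is the subcritical one.  Gauge convention:
the second-order field's critical-mode coefficient has a free component
along the kernel; the package zeroes its v-component (gauge ``"v0"``), so
the critical mode of U2 carries a u-component only.  The gauge-invariant
coefficients p1, p2, p3, p5 and the Neumann pair do not depend on this
choice; the mixed coefficient p4 does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linear import LinearAnalysisResult, linear_analysis
from .systems import DerivativeTable, ReactionDiffusionSystem

__all__ = [
    "MultiscaleConfig",
    "SecondOrderField",
    "TranscriticalCoefficients",
    "PitchforkCoefficients",
    "DegenerateBifurcationError",
    "cos_squared_fourier_coefficient",
    "quadratic_form_projection",
    "oriented_vectors",
    "dirichlet_quadratic_coefficients",
    "solve_second_order",
    "dirichlet_cubic_coefficients",
    "neumann_cubic_coefficients",
    "amplitude_steady_states",
    "predicted_branch",
]


class DegenerateBifurcationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MultiscaleConfig:
    """Numerical settings of the multiple-scales expansion.

    ``truncation_N`` is the number of odd cosine modes retained when the
    Dirichlet second-order field is expanded; the cubic coefficients are
    checked to be stable under doubling it (relative ``convergence_tol``).
    Coefficients are always reported eps-free.
    """

    truncation_N: int = 128
    convergence_tol: float = 1e-6
    gauge: str = "v0"

    def __post_init__(self):
        if self.truncation_N < 8:
            raise ValueError("truncation_N must be at least 8")
        if self.gauge not in ("v0", "u0", "kernel"):
            raise ValueError("gauge must be 'v0', 'u0' or 'kernel'")


@dataclass(frozen=True)
class TranscriticalCoefficients:
    """Coefficients of the Dirichlet (transcritical) amplitude equation."""

    p1: float
    p2: float
    p3: float = np.nan
    p4: float = np.nan
    p5: float = np.nan

    @property
    def slope_m(self) -> float:
        """Slope of the supercritical branch: steady a = -m * L1, m = p1/p2."""
        return self.p1 / self.p2


@dataclass(frozen=True)
class PitchforkCoefficients:
    """Coefficients of the Neumann (pitchfork) amplitude equation.

    ``lin`` multiplies a*L2 and ``cub`` multiplies a^3 (with a minus sign
    in the equation); both are positive in the supercritical case.
    """

    lin: float
    cub: float


@dataclass(frozen=True)
class SecondOrderField:
    """Second-order field U2 of the expansion.

    Dirichlet: U2 = a*L1*crit_linear*cos(pi x)
                   + a^2 * sum_m quad[m] * cos((2m+1) pi x).
    Neumann (L1 = 0): U2 = a^2 * (quad[0] + quad[1]*cos(2 pi x)); the
    wavenumber of mode index m is found in ``wavenumbers[m]``.

    The free kernel-direction component of the critical-mode coefficient
    (``alpha`` in the expansion) is fixed by the gauge; the stored value of
    the gauge constraint residual is zero by construction.
    """

    bc: str
    wavenumbers: np.ndarray
    quad: np.ndarray  # (n_modes, 2) coefficients of a^2
    crit_linear: np.ndarray | None = None  # Dirichlet: coefficient of a*L1
    gauge: str = "v0"

    def max_mode_residual(
        self,
        system: ReactionDiffusionSystem,
        derivs: DerivativeTable,
        lin: LinearAnalysisResult,
    ) -> float:
        """Largest per-mode residual of the second-order balance."""
        Phi, Psi = oriented_vectors(system, derivs, lin)
        L_c = lin.L_c
        D = system.diffusion_matrix
        J = derivs.jacobian
        Q = derivs.quadratic_form(Phi, Phi)
        res = 0.0
        if self.bc == "dirichlet":
            p1, p2 = dirichlet_quadratic_coefficients(system, derivs, lin)
            r_lin = p1 * Phi - 2 * np.pi**2 / L_c**3 * (D @ Phi)
            A0 = J - (np.pi / L_c) ** 2 * D
            res = max(res, float(np.max(np.abs(A0 @ self.crit_linear - r_lin))))
            for m, k in enumerate(self.wavenumbers):
                Am = J - (k / L_c) ** 2 * D
                g = cos_squared_fourier_coefficient(m)
                r = (p2 * Phi if m == 0 else 0.0) - 0.5 * g * Q
                res = max(res, float(np.max(np.abs(Am @ self.quad[m] - r))))
        else:
            for m, k in enumerate(self.wavenumbers):
                Am = J - (k / L_c) ** 2 * D
                res = max(res, float(np.max(np.abs(Am @ self.quad[m] + 0.25 * Q))))
        return res


def cos_squared_fourier_coefficient(n: int) -> float:
    """Odd-cosine Fourier coefficient of cos^2(pi x) on [-1/2, 1/2].

    cos^2(pi x) = sum_n 8 (-1)^(n+1) / (pi (2n+3)(2n+1)(2n-1)) cos((2n+1) pi x);
    the n = 0 coefficient is 8/(3 pi).
    """
    if n < 0 or int(n) != n:
        raise ValueError("mode index n must be a nonnegative integer")
    n = int(n)
    return 8.0 * (-1) ** (n + 1) / (np.pi * (2 * n + 3) * (2 * n + 1) * (2 * n - 1))


def quadratic_form_projection(
    derivs: DerivativeTable, kernel_vector: np.ndarray
) -> np.ndarray:
    """Coefficient pair of a^2 cos^2(pi x) in the second-order forcing.

    Returns (f-part, g-part) = 1/2 F''[Phi, Phi] with Phi the kernel
    vector, i.e. 1/2 (f_uu Phi_u^2 + 2 f_uv Phi_u Phi_v + f_vv Phi_v^2)
    and the g analogue.
    """
    return 0.5 * derivs.quadratic_form(kernel_vector, kernel_vector)


def _raw_p1_p2(system, derivs, L_c, Phi, Psi):
    S = float(Psi @ Phi)
    if abs(S) < 1e-10 * (np.linalg.norm(Phi) * np.linalg.norm(Psi)):
        raise DegenerateBifurcationError(
            "adjoint and kernel vectors are orthogonal (eta*Lambda + 1 ~ 0); "
            "the normalization degenerates"
        )
    D = system.diffusion_matrix
    p1 = 2 * np.pi**2 * float(Psi @ (D @ Phi)) / (L_c**3 * S)
    g0 = cos_squared_fourier_coefficient(0)
    p2 = g0 * float(Psi @ derivs.quadratic_form(Phi, Phi)) / (2 * S)
    return p1, p2


def oriented_vectors(
    system: ReactionDiffusionSystem,
    derivs: DerivativeTable,
    lin: LinearAnalysisResult,
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel and adjoint vectors with the sign convention applied.

    The kernel vector (v-component normalized to 1) is negated when that
    makes the transcritical quadratic coefficient p2 positive; the adjoint
    vector is returned unchanged.
    """
    Phi = np.asarray(lin.kernel_vector, dtype=float)
    Psi = np.asarray(lin.adjoint_vector, dtype=float)
    _, p2 = _raw_p1_p2(system, derivs, lin.L_c, Phi, Psi)
    if p2 < 0:
        Phi = -Phi
    return Phi, Psi


def dirichlet_quadratic_coefficients(
    system: ReactionDiffusionSystem,
    derivs: DerivativeTable,
    lin: LinearAnalysisResult,
) -> tuple[float, float]:
    """(p1, p2) of the transcritical equation da/dt1 = p1 L1 a + p2 a^2.

    p1 = 2 pi^2 (eta Lambda D_u + D_v) / (L_c^3 (eta Lambda + 1)) and p2 is
    the projected quadratic form scaled by the resonant cos^2 coefficient
    8/(3 pi), both under the positive-p2 sign convention.
    """
    Phi, Psi = oriented_vectors(system, derivs, lin)
    return _raw_p1_p2(system, derivs, lin.L_c, Phi, Psi)


def _solve_critical(A0, Phi, r, gauge):
    """Particular solution of the singular system A0 x = r, gauge-fixed."""
    if gauge == "kernel":
        x, *_ = np.linalg.lstsq(np.vstack([A0, Phi]), np.append(r, 0.0), rcond=None)
        return x
    col = 0 if gauge == "v0" else 1
    c, *_ = np.linalg.lstsq(A0[:, [col]], r, rcond=None)
    x = np.zeros(2)
    x[col] = c[0]
    return x


def solve_second_order(
    system: ReactionDiffusionSystem,
    derivs: DerivativeTable,
    lin: LinearAnalysisResult,
    bc: str,
    truncation_N: int = 128,
    *,
    gauge: str = "v0",
) -> SecondOrderField:
    """Solve the second-order balance for U2 under either boundary condition.

    Dirichlet: the forcing cos^2(pi x) is expanded over odd cosine modes
    (2m+1) pi, m = 0..truncation_N; each non-critical mode gives a regular
    2x2 solve and the critical mode a gauge-fixed singular solve (the
    solvability condition has already removed its resonant part).
    Neumann: exactly two modes, the constant and cos(2 pi x).
    """
    Phi, Psi = oriented_vectors(system, derivs, lin)
    L_c = lin.L_c
    J = derivs.jacobian
    D = system.diffusion_matrix
    Q = derivs.quadratic_form(Phi, Phi)

    if bc == "neumann":
        A2 = J - (2 * np.pi / L_c) ** 2 * D
        for M, label in ((J, "constant"), (A2, "cos(2 pi x)")):
            if abs(np.linalg.det(M)) < 1e-12:
                raise RuntimeError(
                    f"resonance: the {label} mode matrix is singular, violating "
                    "the single-unstable-wavelength assumption"
                )
        w0 = np.linalg.solve(J, -0.25 * Q)
        w2 = np.linalg.solve(A2, -0.25 * Q)
        return SecondOrderField(
            bc="neumann",
            wavenumbers=np.array([0.0, 2 * np.pi]),
            quad=np.vstack([w0, w2]),
            gauge=gauge,
        )

    if bc != "dirichlet":
        raise ValueError("bc must be 'dirichlet' or 'neumann'")

    p1, p2 = _raw_p1_p2(system, derivs, L_c, Phi, Psi)
    A0 = J - (np.pi / L_c) ** 2 * D
    d1 = _solve_critical(A0, Phi, p1 * Phi - 2 * np.pi**2 / L_c**3 * (D @ Phi), gauge)
    e0 = _solve_critical(
        A0, Phi, p2 * Phi - 0.5 * cos_squared_fourier_coefficient(0) * Q, gauge
    )
    ks = np.array([(2 * m + 1) * np.pi for m in range(truncation_N + 1)])
    quad = np.empty((truncation_N + 1, 2))
    quad[0] = e0
    for m in range(1, truncation_N + 1):
        Am = J - (ks[m] / L_c) ** 2 * D
        if abs(np.linalg.det(Am)) < 1e-12:
            raise RuntimeError(
                f"resonance at mode {2 * m + 1}: a second wavelength sits on the "
                "neutral curve"
            )
        quad[m] = np.linalg.solve(Am, -0.5 * cos_squared_fourier_coefficient(m) * Q)
    return SecondOrderField(
        bc="dirichlet", wavenumbers=ks, quad=quad, crit_linear=d1, gauge=gauge
    )


def _dirichlet_p345(system, derivs, lin, Phi, Psi, field2):
    """Assemble p3, p4, p5 from the third-order secular projection."""
    L_c = lin.L_c
    D = system.diffusion_matrix
    S = float(Psi @ Phi)
    p1, p2 = _raw_p1_p2(system, derivs, L_c, Phi, Psi)
    d1 = field2.crit_linear
    e0 = field2.quad[0]
    pi2 = np.pi**2
    p3 = (2 / S) * (
        0.5 * p1 * (Psi @ d1)
        - pi2 / L_c**3 * (Psi @ (D @ d1))
        + 1.5 * pi2 / L_c**4 * (Psi @ (D @ Phi))
    )
    g0 = cos_squared_fourier_coefficient(0)
    p4 = (2 / S) * (
        0.5 * p2 * (Psi @ d1)
        + p1 * (Psi @ e0)
        - pi2 / L_c**3 * (Psi @ (D @ e0))
        - 0.5 * g0 * (Psi @ derivs.quadratic_form(Phi, d1))
    )
    cross = sum(
        0.5
        * cos_squared_fourier_coefficient(m)
        * (Psi @ derivs.quadratic_form(Phi, field2.quad[m]))
        for m in range(field2.quad.shape[0])
    )
    p5 = (2 / S) * (
        p2 * (Psi @ e0) - cross - (Psi @ derivs.cubic_form(Phi, Phi, Phi)) / 16
    )
    return float(p3), float(p4), float(p5)


def dirichlet_cubic_coefficients(
    system: ReactionDiffusionSystem,
    derivs: DerivativeTable,
    lin: LinearAnalysisResult,
    truncation_N: int = 128,
    *,
    gauge: str = "v0",
    convergence_tol: float = 1e-6,
) -> TranscriticalCoefficients:
    """All five coefficients of the third-order transcritical equation.

    The third-order secular terms (slow drift of U1 and U2, the L2 and
    L1^2 corrections to the diffusion prefactor, the U1-U2 cross term and
    the U1^3 term) are projected onto the adjoint kernel under the
    [-1/2, 1/2] inner product.  Convergence in the Fourier truncation is
    verified by recomputing at 2 * truncation_N.
    """
    Phi, Psi = oriented_vectors(system, derivs, lin)
    p1, p2 = _raw_p1_p2(system, derivs, lin.L_c, Phi, Psi)

    def assemble(N):
        f2 = solve_second_order(
            system, derivs, lin, "dirichlet", truncation_N=N, gauge=gauge
        )
        return _dirichlet_p345(system, derivs, lin, Phi, Psi, f2)

    coarse = assemble(truncation_N)
    fine = assemble(2 * truncation_N)
    for name, c, f in zip(("p3", "p4", "p5"), coarse, fine):
        scale = max(abs(f), 1e-12)
        if abs(c - f) / scale > convergence_tol:
            raise RuntimeError(
                f"Fourier truncation not converged for {name}: "
                f"{c!r} at N={truncation_N} vs {f!r} at N={2 * truncation_N}"
            )
    p3, p4, p5 = fine
    return TranscriticalCoefficients(p1=p1, p2=p2, p3=p3, p4=p4, p5=p5)


def neumann_cubic_coefficients(
    system: ReactionDiffusionSystem,
    derivs: DerivativeTable,
    lin: LinearAnalysisResult,
) -> PitchforkCoefficients:
    """Coefficients of the Neumann pitchfork da/dt2 = lin L2 a - cub a^3.

    With L1 = 0 the second-order field has only the constant and
    cos(2 pi x) modes; the third-order secular projection onto the adjoint
    kernel under the [0, 1] inner product collects the L2 diffusion
    correction (giving ``lin``, identical to the Dirichlet p1) and the
    cubic interactions: the U1 cross terms with both second-order modes
    plus the direct U1^3 term.
    """
    Phi, Psi = oriented_vectors(system, derivs, lin)
    S = float(Psi @ Phi)
    field2 = solve_second_order(system, derivs, lin, "neumann")
    w0, w2 = field2.quad
    p1, _ = _raw_p1_p2(system, derivs, lin.L_c, Phi, Psi)
    cub = -(2 / S) * (
        0.5 * (Psi @ derivs.quadratic_form(Phi, w0))
        + 0.25 * (Psi @ derivs.quadratic_form(Phi, w2))
        + (Psi @ derivs.cubic_form(Phi, Phi, Phi)) / 16
    )
    return PitchforkCoefficients(lin=float(p1), cub=float(cub))


def amplitude_steady_states(
    coeffs: TranscriticalCoefficients | PitchforkCoefficients,
    L_offset: float,
) -> list[tuple[float, bool]]:
    """Steady amplitudes and their stability at a given slow offset.

    Transcritical (``L_offset`` = L1): a = 0 and a = -p1 L1 / p2, which
    exchange stability at L1 = 0.  Pitchfork (``L_offset`` = L2): a = 0 and
    a = +/- sqrt(lin L2 / cub) when the radicand is nonnegative.
    """
    if isinstance(coeffs, TranscriticalCoefficients):
        if coeffs.p2 == 0:
            raise DegenerateBifurcationError(
                "p2 = 0: the bifurcation is not transcritical at this order"
            )
        rate0 = coeffs.p1 * L_offset
        states = [(0.0, rate0 < 0)]
        a_star = -coeffs.p1 * L_offset / coeffs.p2
        if a_star != 0.0:
            states.append((a_star, -rate0 < 0))
        return states
    if coeffs.cub == 0:
        raise DegenerateBifurcationError("cubic coefficient vanishes (degenerate)")
    states = [(0.0, coeffs.lin * L_offset < 0)]
    rad = coeffs.lin * L_offset / coeffs.cub
    if rad > 0:
        root = float(np.sqrt(rad))
        nontrivial_stable = coeffs.lin * L_offset > 0
        states += [(root, nontrivial_stable), (-root, nontrivial_stable)]
    return states


def predicted_branch(
    coeffs: TranscriticalCoefficients,
    steady_state,
    kernel_vector: np.ndarray,
    L_values: np.ndarray,
    L_c: float,
    order: int = 2,
) -> pd.DataFrame:
    """Analytic transcritical branch curves for overlay on continuation data.

    For each L the nontrivial steady amplitudes of the amplitude equation
    (eps folded into a, so L1 = L - L_c) are converted to the center-line
    extremum u_s + Phi_u * a.  ``order=2`` uses the quadratic equation
    (a single straight branch of slope -p1/p2); ``order=3`` the cubic one,
    which can be multivalued in a beyond its range of validity.
    """
    rows = []
    Phi_u = float(kernel_vector[0])
    for L in np.asarray(L_values, dtype=float):
        l1 = L - L_c
        if order == 2:
            amps = [-coeffs.p1 * l1 / coeffs.p2]
        elif order == 3:
            # roots of p5 a^2 - (p2 - p4 l1) a - (p1 l1 - p3 l1^2) = 0
            disc = (coeffs.p2 - coeffs.p4 * l1) ** 2 + 4 * coeffs.p5 * (
                coeffs.p1 * l1 - coeffs.p3 * l1**2
            )
            if disc < 0:
                amps = []
            else:
                rt = np.sqrt(disc)
                amps = [
                    ((coeffs.p2 - coeffs.p4 * l1) + s * rt) / (2 * coeffs.p5)
                    for s in (+1, -1)
                ]
        else:
            raise ValueError("order must be 2 or 3")
        for branch, a in enumerate(amps):
            rows.append(
                {
                    "L": L,
                    "order": order,
                    "branch": branch,
                    "a": a,
                    "u_extremum": steady_state.u + Phi_u * a,
                }
            )
    return pd.DataFrame(rows)
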