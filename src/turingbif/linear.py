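"""Linearized Turing analysis.

Perturbing the homogeneous steady state with a Fourier mode cos(kx) e^{lt}
turns the linearization into a 2x2 eigenvalue problem per wavenumber:

    det( l*I + (k^2/L^2) D - J ) = 0.

The standard chain follows: Routh-Hurwitz stability of the diffusion-free
system, the dispersion relation l(k; L), the window (k_-^2, k_+^2) of
unstable squared wavenumbers, the critical domain scale L_c at which the
first admissible mode k = pi touches instability, and the kernel / adjoint
kernel vectors of the critical-mode matrix used by the amplitude equations.

Admissible wavenumbers are k = n*pi under zero-flux (Neumann) conditions
and k = (2n+1)*pi for the even subspace under steady-state-pinned
(Dirichlet) conditions; the first unstable mode k = pi is common to both,
so L_c does not depend on the boundary conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .systems import DerivativeTable, ReactionDiffusionSystem

__all__ = [
    "DispersionResult",
    "LinearAnalysisResult",
    "TuringConditionError",
    "ode_stability",
    "dispersion_eigenvalues",
    "instability_window",
    "critical_length",
    "kernel_vectors",
    "linear_analysis",
    "patterning_region",
    "region_extremes",
]


class TuringConditionError(RuntimeError):
    """A necessary condition for diffusion-driven instability fails.

    The ``condition`` attribute names the failed inequality.
    """

    def __init__(self, condition: str, message: str):
        super().__init__(message)
        self.condition = condition


@dataclass(frozen=True)
class DispersionResult:
    """Both growth rates of the mode cos(kx) at domain scale L."""

    k: float
    lambda_pair: tuple[complex, complex]
    max_real: float


@dataclass(frozen=True)
class LinearAnalysisResult:
    """Summary of the linear Turing analysis at the critical point.

    ``Lambda`` and ``eta`` are the u-components of the kernel and adjoint
    kernel vectors of the critical-mode matrix J - (pi^2/L_c^2) D, both
    normalized so the v-component is 1.  ``kernel_vector`` may additionally
    carry the overall sign flip chosen by the amplitude layer so that the
    quadratic coefficient of the transcritical equation is positive; the
    flip leaves the ratio fields untouched.
    """

    ode_stable: bool
    trace_condition: bool
    determinant_condition: bool
    diffusion_driven: bool
    k_minus_sq: float
    k_plus_sq: float
    L_c: float
    Lambda: float
    eta: float
    kernel_vector: np.ndarray
    adjoint_vector: np.ndarray

    @property
    def k_minus(self) -> float:
        return float(np.sqrt(self.k_minus_sq))

    @property
    def k_plus(self) -> float:
        return float(np.sqrt(self.k_plus_sq))


def ode_stability(derivs: DerivativeTable) -> tuple[bool, bool, bool]:
    """Routh-Hurwitz flags for the diffusion-free steady state.

    Returns (trace_condition, determinant_condition, stable): the state is
    stable iff f_u + g_v < 0 and f_u g_v - g_u f_v > 0.
    """
    trace_ok = derivs.f_u + derivs.g_v < 0
    det_ok = derivs.f_u * derivs.g_v - derivs.g_u * derivs.f_v > 0
    return trace_ok, det_ok, trace_ok and det_ok


def dispersion_eigenvalues(
    system: ReactionDiffusionSystem,
    derivs: DerivativeTable,
    k: float,
    L: float | None = None,
) -> DispersionResult:
    """Growth rates of the cos(kx) perturbation at domain scale L.

    The two roots of the quadratic in l; at k = 0 this reduces to the
    diffusion-free characteristic polynomial.
    """
    if k < 0:
        raise ValueError("wavenumber k must be nonnegative")
    L = system.L if L is None else L
    if L <= 0:
        raise ValueError("domain scale L must be positive")
    q = (k / L) ** 2
    tr = derivs.f_u + derivs.g_v - q * (system.D_u + system.D_v)
    det = (q * system.D_u - derivs.f_u) * (q * system.D_v - derivs.g_v) \
        - derivs.g_u * derivs.f_v
    disc = complex(tr * tr - 4 * det) ** 0.5
    lam = ((tr + disc) / 2, (tr - disc) / 2)
    return DispersionResult(k=k, lambda_pair=lam, max_real=max(l.real for l in lam))


def _window_pieces(system: ReactionDiffusionSystem, derivs: DerivativeTable):
    h = system.D_u * derivs.g_v + derivs.f_u * system.D_v
    det = derivs.f_u * derivs.g_v - derivs.g_u * derivs.f_v
    disc = h * h - 4 * system.D_u * system.D_v * det
    return h, det, disc


def instability_window(
    system: ReactionDiffusionSystem,
    derivs: DerivativeTable,
    L: float | None = None,
) -> tuple[float, float]:
    """Endpoints (k_-^2, k_+^2) of the band of unstable squared wavenumbers.

    Every k^2 strictly inside the window makes the constant term of the
    dispersion quadratic negative, hence one growth rate positive.  Both
    endpoints scale with L^2.
    """
    L = system.L if L is None else L
    h, det, disc = _window_pieces(system, derivs)
    if h <= 0 or disc <= 0:
        raise TuringConditionError(
            "diffusion_driven",
            "no diffusion-driven instability: D_u g_v + f_u D_v must exceed "
            "2 sqrt(D_u D_v (f_u g_v - g_u f_v))",
        )
    root = np.sqrt(disc)
    denom = 2 * system.D_u * system.D_v
    return L * L * (h - root) / denom, L * L * (h + root) / denom


def critical_length(
    system: ReactionDiffusionSystem, derivs: DerivativeTable
) -> float:
    """Critical domain scale L_c at which the first mode k = pi destabilizes.

    Defined by k_+^2(L_c) = pi^2, i.e.

        L_c^2 = 2 D_u D_v pi^2 / (h + sqrt(h^2 - 4 D_u D_v det J)),
        h = D_u g_v + f_u D_v.
    """
    trace_ok, det_ok, stable = ode_stability(derivs)
    if not trace_ok:
        raise TuringConditionError("trace", "f_u + g_v must be negative")
    if not det_ok:
        raise TuringConditionError("determinant", "det J must be positive")
    h, det, disc = _window_pieces(system, derivs)
    if h <= 0 or disc <= 0:
        raise TuringConditionError(
            "diffusion_driven",
            "no diffusion-driven instability for these diffusivities",
        )
    Lc2 = 2 * system.D_u * system.D_v * np.pi**2 / (h + np.sqrt(disc))
    return float(np.sqrt(Lc2))


def kernel_vectors(
    system: ReactionDiffusionSystem,
    derivs: DerivativeTable,
    L_c: float | None = None,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Kernel and adjoint-kernel data of the critical-mode matrix.

    Returns (Lambda, eta, kernel_vector, adjoint_vector) where the matrix
    A = J - (pi^2/L_c^2) D is singular by construction, A @ kernel = 0 and
    A.T @ adjoint = 0, and both vectors are normalized with v-component 1.
    """
    if L_c is None:
        L_c = critical_length(system, derivs)
    A = derivs.jacobian - (np.pi / L_c) ** 2 * system.diffusion_matrix
    # null space by smallest singular vector; robust even if the top-left
    # entry happens to be tiny
    _, s, Vt = np.linalg.svd(A)
    if s[-1] > 1e-6 * max(s[0], 1.0):
        raise RuntimeError(
            f"critical-mode matrix is not numerically singular "
            f"(smallest singular value {s[-1]:.3e})"
        )
    kern = Vt[-1]
    _, s2, Vt2 = np.linalg.svd(A.T)
    adj = Vt2[-1]
    if abs(kern[1]) < 1e-12 or abs(adj[1]) < 1e-12:
        raise RuntimeError("kernel vector has vanishing v-component; cannot normalize")
    kern = kern / kern[1]
    adj = adj / adj[1]
    return float(kern[0]), float(adj[0]), kern, adj


def linear_analysis(
    system: ReactionDiffusionSystem, derivs: DerivativeTable
) -> LinearAnalysisResult:
    """Run the full linear chain and bundle the results."""
    trace_ok, det_ok, stable = ode_stability(derivs)
    L_c = critical_length(system, derivs)
    km2, kp2 = instability_window(system, derivs, L_c)
    Lam, eta, kern, adj = kernel_vectors(system, derivs, L_c)
    return LinearAnalysisResult(
        ode_stable=stable,
        trace_condition=trace_ok,
        determinant_condition=det_ok,
        diffusion_driven=True,
        k_minus_sq=float(km2),
        k_plus_sq=float(kp2),
        L_c=L_c,
        Lambda=Lam,
        eta=eta,
        kernel_vector=kern,
        adjoint_vector=adj,
    )


def _first_mode_max_real(system, derivs, L, D_v=None):
    sys_ = system if D_v is None else system.with_(D_v=D_v)
    return dispersion_eigenvalues(sys_, derivs, np.pi, L).max_real


def patterning_region(
    system: ReactionDiffusionSystem,
    derivs: DerivativeTable,
    D_v_grid: np.ndarray,
    L_grid: np.ndarray,
    *,
    bracket_tol: float = 1e-8,
):
    """Map the (L, D_v) region where the first mode k = pi grows.

    Returns ``(mask, boundary)``: a boolean mask of max Re l(pi; L, D_v) > 0
    over the grid (rows follow ``L_grid``, columns ``D_v_grid``) and, per
    D_v column, the smallest L on the neutral curve located by 1-D root
    bracketing (NaN where the column never destabilizes).
    """
    D_v_grid = np.asarray(D_v_grid, dtype=float)
    L_grid = np.asarray(L_grid, dtype=float)
    mask = np.empty((L_grid.size, D_v_grid.size), dtype=bool)
    boundary = np.full(D_v_grid.size, np.nan)
    for j, dv in enumerate(D_v_grid):
        vals = np.array(
            [_first_mode_max_real(system, derivs, L, dv) for L in L_grid]
        )
        mask[:, j] = vals > 0
        pos = np.flatnonzero(vals > 0)
        if pos.size == 0 or pos[0] == 0:
            continue
        lo, hi = L_grid[pos[0] - 1], L_grid[pos[0]]
        boundary[j] = optimize.brentq(
            lambda L: _first_mode_max_real(system, derivs, L, dv),
            lo,
            hi,
            xtol=bracket_tol,
        )
    return mask, boundary


def region_extremes(
    system: ReactionDiffusionSystem, derivs: DerivativeTable
) -> dict[str, float]:
    """Closed-form extremes of the first-mode patterning region.

    Keeping D_u fixed, the neutral curve of the mode k = pi solves

        (pi^2 D_u / L^2 - f_u)(pi^2 D_v / L^2 - g_v) = g_u f_v,

    which gives D_v as an explicit function of L.  The region has a
    vertical asymptote at L_min = pi sqrt(D_u / f_u) (the infimum of
    admissible L as D_v grows) and an interior minimum D_v_min attained at
    L_at_D_v_min, located here by scalar minimization of the explicit
    boundary function.
    """
    if derivs.f_u <= 0:
        raise TuringConditionError(
            "activator", "f_u must be positive for a finite L asymptote"
        )
    L_min = float(np.pi * np.sqrt(system.D_u / derivs.f_u))

    def boundary_D_v(L):
        a = np.pi**2 * system.D_u / L**2 - derivs.f_u  # negative for L > L_min
        return (derivs.g_u * derivs.f_v / a + derivs.g_v) * L**2 / np.pi**2

    res = optimize.minimize_scalar(
        boundary_D_v,
        bounds=(L_min * 1.0001, L_min * 10),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return {
        "L_min": L_min,
        "D_v_min": float(res.fun),
        "L_at_D_v_min": float(res.x),
    }
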