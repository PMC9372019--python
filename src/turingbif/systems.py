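"""Two-species reaction-diffusion systems and their local Taylor data.

A system is

    u_t = (D_u / L^2) u_xx + f(u, v)
    v_t = (D_v / L^2) v_xx + g(u, v)

on a unit interval, where the domain scale ``L`` multiplies the physical
length so that it can serve as a bifurcation parameter.  Kinetics are held
as sympy expressions, which gives exact partial derivatives up to the third
order needed by the weakly nonlinear machinery; a central finite-difference
fallback is provided for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import sympy as sp
from scipy import optimize

__all__ = [
    "ReactionDiffusionSystem",
    "SteadyState",
    "DerivativeTable",
    "schnakenberg",
    "classic_schnakenberg",
    "make_system",
    "find_steady_state",
    "derivative_table",
    "SteadyStateError",
]

_U, _V = sp.symbols("u v", real=True)


class SteadyStateError(RuntimeError):
    """Raised when no acceptable homogeneous steady state is found."""


@dataclass(frozen=True)
class ReactionDiffusionSystem:
    """A two-species reaction-diffusion system on a scaled unit interval.

    Parameters
    ----------
    f_expr, g_expr
        Kinetics as sympy expressions in the symbols ``u`` and ``v`` (any
        named parameters already substituted by :func:`make_system`).
    D_u, D_v
        Positive diffusivities.
    L
        Positive domain scale; the diffusion term carries a 1/L^2 factor.
    name
        Optional label used in reports.
    """

    f_expr: sp.Expr
    g_expr: sp.Expr
    D_u: float
    D_v: float
    L: float = 1.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if not (self.D_u > 0 and self.D_v > 0):
            raise ValueError("diffusivities must be positive")
        if not self.L > 0:
            raise ValueError("domain scale L must be positive")

    @property
    def f(self) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
        return _lambdify(self.f_expr)

    @property
    def g(self) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
        return _lambdify(self.g_expr)

    @property
    def diffusion_matrix(self) -> np.ndarray:
        return np.diag([self.D_u, self.D_v])

    def reaction(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate (f, g) elementwise."""
        return self.f(u, v), self.g(u, v)

    def with_(self, **changes) -> "ReactionDiffusionSystem":
        """Return a copy with selected fields replaced (e.g. ``L`` or ``D_v``)."""
        data = {
            "f_expr": self.f_expr,
            "g_expr": self.g_expr,
            "D_u": self.D_u,
            "D_v": self.D_v,
            "L": self.L,
            "name": self.name,
        }
        data.update(changes)
        return ReactionDiffusionSystem(**data)


_LAMBDIFY_CACHE: dict[sp.Expr, Callable] = {}


def _lambdify(expr: sp.Expr) -> Callable:
    fn = _LAMBDIFY_CACHE.get(expr)
    if fn is None:
        fn = sp.lambdify((_U, _V), expr, modules="numpy")
        _LAMBDIFY_CACHE[expr] = fn
    return fn


@dataclass(frozen=True)
class SteadyState:
    """A nonnegative homogeneous steady state (u_s, v_s)."""

    u: float
    v: float

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v])


# the 18 partial derivatives needed for a third-order Taylor expansion
_ORDERS = [
    ("f_u", "f", (1, 0)), ("f_v", "f", (0, 1)),
    ("g_u", "g", (1, 0)), ("g_v", "g", (0, 1)),
    ("f_uu", "f", (2, 0)), ("f_uv", "f", (1, 1)), ("f_vv", "f", (0, 2)),
    ("g_uu", "g", (2, 0)), ("g_uv", "g", (1, 1)), ("g_vv", "g", (0, 2)),
    ("f_uuu", "f", (3, 0)), ("f_uuv", "f", (2, 1)),
    ("f_uvv", "f", (1, 2)), ("f_vvv", "f", (0, 3)),
    ("g_uuu", "g", (3, 0)), ("g_uuv", "g", (2, 1)),
    ("g_uvv", "g", (1, 2)), ("g_vvv", "g", (0, 3)),
]


@dataclass(frozen=True)
class DerivativeTable:
    """All kinetic partials up to third order, evaluated at the steady state.

    Mixed partials are stored once per multi-index; symmetry is therefore
    automatic.  The table is the only kinetic information the linear and
    weakly nonlinear layers ever see.
    """

    f_u: float
    f_v: float
    g_u: float
    g_v: float
    f_uu: float
    f_uv: float
    f_vv: float
    g_uu: float
    g_uv: float
    g_vv: float
    f_uuu: float
    f_uuv: float
    f_uvv: float
    f_vvv: float
    g_uuu: float
    g_uuv: float
    g_uvv: float
    g_vvv: float
    steady_state: SteadyState = field(default=SteadyState(np.nan, np.nan))

    @property
    def jacobian(self) -> np.ndarray:
        return np.array([[self.f_u, self.f_v], [self.g_u, self.g_v]])

    def quadratic_form(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Bilinear second-derivative form F''[a, b] (a 2-vector)."""
        cu = a[0] * b[0]
        cm = a[0] * b[1] + a[1] * b[0]
        cv = a[1] * b[1]
        return np.array(
            [
                self.f_uu * cu + self.f_uv * cm + self.f_vv * cv,
                self.g_uu * cu + self.g_uv * cm + self.g_vv * cv,
            ]
        )

    def cubic_form(self, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Trilinear third-derivative form F'''[a, b, c] (a 2-vector)."""
        s_uuu = a[0] * b[0] * c[0]
        s_uuv = a[0] * b[0] * c[1] + a[0] * b[1] * c[0] + a[1] * b[0] * c[0]
        s_uvv = a[0] * b[1] * c[1] + a[1] * b[0] * c[1] + a[1] * b[1] * c[0]
        s_vvv = a[1] * b[1] * c[1]
        return np.array(
            [
                self.f_uuu * s_uuu + self.f_uuv * s_uuv
                + self.f_uvv * s_uvv + self.f_vvv * s_vvv,
                self.g_uuu * s_uuu + self.g_uuv * s_uuv
                + self.g_uvv * s_uvv + self.g_vvv * s_vvv,
            ]
        )


def schnakenberg(D_u: float = 1e-3, D_v: float = 0.1, L: float = 1.0) -> ReactionDiffusionSystem:
    """The canonical activator-depletion fixture.

    Kinetics f = 1 - 2u + u^2 v, g = 3 - u^2 v, whose homogeneous steady
    state is (2, 3/4).  The two populations pattern out of phase ("cross"
    kinetics): peaks of u sit on troughs of v.
    """
    return ReactionDiffusionSystem(
        f_expr=1 - 2 * _U + _U**2 * _V,
        g_expr=3 - _U**2 * _V,
        D_u=D_u,
        D_v=D_v,
        L=L,
        name="schnakenberg",
    )


def classic_schnakenberg(
    a: float, b: float, D_u: float = 1e-3, D_v: float = 0.1, L: float = 1.0
) -> ReactionDiffusionSystem:
    """Schnakenberg kinetics with free production rates.

    f = a - u + u^2 v, g = b - u^2 v; steady state (a + b, b / (a + b)^2).
    """
    return ReactionDiffusionSystem(
        f_expr=a - _U + _U**2 * _V,
        g_expr=b - _U**2 * _V,
        D_u=D_u,
        D_v=D_v,
        L=L,
        name="classic_schnakenberg",
    )


_BUILTINS = {"schnakenberg": schnakenberg}


def make_system(
    kinetics: str,
    parameters: Mapping[str, float] | None = None,
    *,
    D_u: float = 1e-3,
    D_v: float = 0.1,
    L: float = 1.0,
    g_expr: str | None = None,
) -> ReactionDiffusionSystem:
    """Build a system from a named built-in or from expression strings.

    ``kinetics`` is either a built-in name ("schnakenberg") or the f
    expression string; in the latter case ``g_expr`` must be given.
    Named parameters are substituted as floats.
    """
    if kinetics in _BUILTINS:
        return _BUILTINS[kinetics](D_u=D_u, D_v=D_v, L=L)
    if g_expr is None:
        raise ValueError(f"unknown built-in kinetics {kinetics!r} and no g_expr given")
    subs = {sp.Symbol(k): float(v) for k, v in (parameters or {}).items()}
    local = {"u": _U, "v": _V}
    f = sp.sympify(kinetics, locals=local).subs(subs)
    g = sp.sympify(g_expr, locals=local).subs(subs)
    extra = (f.free_symbols | g.free_symbols) - {_U, _V}
    if extra:
        raise ValueError(f"unbound parameters in kinetics: {sorted(map(str, extra))}")
    return ReactionDiffusionSystem(f_expr=f, g_expr=g, D_u=D_u, D_v=D_v, L=L)


def find_steady_state(
    system: ReactionDiffusionSystem,
    initial_guess: tuple[float, float] = (1.0, 1.0),
    *,
    tol: float = 1e-13,
    require_positive: bool = True,
) -> SteadyState:
    """Find the homogeneous steady state reached from ``initial_guess``.

    Local analysis is anchored at a single state, so only the root reached
    from the supplied guess is returned; no global enumeration is attempted.
    Roots with negative components are rejected by default (the populations
    are concentrations), which can be relaxed with ``require_positive=False``.
    """
    guess = np.asarray(initial_guess, dtype=float)
    if require_positive and np.any(guess <= 0):
        raise ValueError("initial guess must have positive entries")
    f, g = system.f, system.g

    def residual(x):
        return [f(x[0], x[1]), g(x[0], x[1])]

    sol = optimize.root(residual, guess, method="hybr", tol=1e-14)
    res = np.max(np.abs(residual(sol.x)))
    if not sol.success or res > 1e-9:
        raise SteadyStateError(
            f"no steady state from guess {tuple(guess)}: residual {res:.3e}"
        )
    # Newton polish to push the residual to machine precision
    x = sol.x
    jac = _fd_jacobian(f, g, x)
    for _ in range(5):
        r = np.array(residual(x))
        if np.max(np.abs(r)) <= tol:
            break
        x = x - np.linalg.solve(jac, r)
        jac = _fd_jacobian(f, g, x)
    if require_positive and np.any(x < -1e-12):
        raise SteadyStateError(
            f"root {tuple(x)} violates positivity; pass require_positive=False "
            "to accept it"
        )
    return SteadyState(float(x[0]), float(x[1]))


def _fd_jacobian(f, g, x):
    h = 1e-7 * max(1.0, float(np.max(np.abs(x))))
    J = np.empty((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = h
        J[0, j] = (f(*(x + e)) - f(*(x - e))) / (2 * h)
        J[1, j] = (g(*(x + e)) - g(*(x - e))) / (2 * h)
    return J


def derivative_table(
    system: ReactionDiffusionSystem,
    steady_state: SteadyState,
    *,
    method: str = "symbolic",
) -> DerivativeTable:
    """Evaluate all 18 kinetic partials at the steady state.

    ``method='symbolic'`` differentiates the sympy expressions exactly;
    ``method='fd'`` uses central finite differences with an order-dependent
    relative step (cbrt(eps) scaling for first order, wider for higher
    orders) and exists mainly as an independent cross-check.
    """
    u0, v0 = steady_state.u, steady_state.v
    exprs = {"f": system.f_expr, "g": system.g_expr}
    values: dict[str, float] = {}
    if method == "symbolic":
        for name, which, (du, dv) in _ORDERS:
            d = sp.diff(exprs[which], _U, du, _V, dv)
            val = complex(d.subs({_U: u0, _V: v0}))
            if abs(val.imag) > 1e-12:
                raise ValueError(f"derivative {name} is not real at the steady state")
            values[name] = float(val.real)
    elif method == "fd":
        funcs = {"f": system.f, "g": system.g}
        for name, which, (du, dv) in _ORDERS:
            values[name] = _fd_partial(funcs[which], u0, v0, du, dv)
    else:
        raise ValueError("method must be 'symbolic' or 'fd'")
    bad = [k for k, v in values.items() if not math.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite derivatives at steady state: {bad}")
    return DerivativeTable(steady_state=steady_state, **values)


def _fd_partial(func, u0, v0, du, dv):
    """Central finite difference of order (du, dv), total order <= 3."""
    order = du + dv
    eps = np.finfo(float).eps
    # step balances truncation against round-off; higher orders need wider steps
    h = eps ** (1.0 / (order + 2)) * max(1.0, abs(u0), abs(v0))
    # 1-D central-difference stencils on offsets -order..order
    stencils = {
        1: {-1: -0.5, 1: 0.5},
        2: {-1: 1.0, 0: -2.0, 1: 1.0},
        3: {-2: -0.5, -1: 1.0, 1: -1.0, 2: 0.5},
    }

    def axis_apply(fn, var_order, along_u):
        if var_order == 0:
            return fn(0.0)
        st = stencils[var_order]
        return sum(w * fn(k * h) for k, w in st.items()) / h**var_order

    def g_of_dv_offset(dv_off):
        def f_of_du_offset(du_off):
            return func(u0 + du_off, v0 + dv_off)

        return axis_apply(f_of_du_offset, du, True) if du else func(u0, v0 + dv_off)

    if dv == 0:
        return axis_apply(lambda o: func(u0 + o, v0), du, True)
    return axis_apply(g_of_dv_offset, dv, False)
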