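"""Pseudo-arclength continuation of discretized steady states in L.

Steady states of the discretized system solve R(y; L) = 0 with y the
packed (u, v) unknowns from :mod:`turingbif.simulate`.  Branches are
parametrized by arclength so folds in L are traversed: a secant/tangent
predictor steps along the branch and a bordered Newton corrector solves
R = 0 together with the arclength constraint

    (1/n) <tau_y, y - y_pred> + tau_L (L - L_pred) = 0,

the 1/n state weight making diagrams resolution independent.  Every
accepted point carries the few rightmost eigenvalues of the linearization
so stability changes (bifurcations) and folds can be detected and refined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .simulate import Operator

__all__ = [
    "BranchPoint",
    "Branch",
    "CorrectorError",
    "corrector",
    "continue_branch",
    "detect_events",
    "switch_branch",
    "branch_diagram",
    "homogeneous_branch",
]

_N_EIGS = 5


class CorrectorError(RuntimeError):
    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history or []


@dataclass
class BranchPoint:
    """One converged steady state along a branch."""

    L: float
    y: np.ndarray
    s: float
    leading_eigenvalues: np.ndarray
    stable: bool
    max_u: float
    min_u: float

    @property
    def leading_real(self) -> float:
        return float(self.leading_eigenvalues[0].real)


@dataclass
class Branch:
    """Arclength-ordered branch points plus detected events."""

    points: list[BranchPoint] = field(default_factory=list)
    events: list[tuple[str, float]] = field(default_factory=list)
    truncated_reason: str | None = None

    @property
    def L(self) -> np.ndarray:
        return np.array([p.L for p in self.points])

    @property
    def max_u(self) -> np.ndarray:
        return np.array([p.max_u for p in self.points])

    @property
    def min_u(self) -> np.ndarray:
        return np.array([p.min_u for p in self.points])

    @property
    def stable(self) -> np.ndarray:
        return np.array([p.stable for p in self.points])


def _eigs_and_stability(op: Operator, y: np.ndarray, L: float):
    J = op.jacobian(y, L).toarray()
    lam = sla.eigvals(J)
    order = np.argsort(-lam.real)
    lead = lam[order[:_N_EIGS]]
    return lead, bool(lead[0].real < 0)


def _point(op: Operator, y: np.ndarray, L: float, s: float = np.nan,
           *, with_eigs: bool = True) -> BranchPoint:
    if with_eigs:
        lead, stable = _eigs_and_stability(op, y, L)
    else:
        lead, stable = np.array([], dtype=complex), False
    u_full, _ = op.unpack_full(y)
    return BranchPoint(
        L=float(L),
        y=y,
        s=s,
        leading_eigenvalues=lead,
        stable=stable,
        max_u=float(u_full.max()),
        min_u=float(u_full.min()),
    )


def corrector(
    op: Operator,
    L: float,
    guess: np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 30,
    stall_tol: float = 1e-8,
) -> BranchPoint:
    """Damped Newton solve of the steady problem at fixed L.

    Converges to ``tol`` in the max norm; stagnation below ``stall_tol``
    (round-off limited on fine grids, where the diffusion stencil scales
    like 1/h^2) is accepted as converged.
    """
    y = np.array(guess, dtype=float)
    history = []
    r = op.rhs(y, L)
    rn = np.max(np.abs(r))
    history.append(rn)
    for _ in range(max_iter):
        if rn <= tol:
            return _point(op, y, L)
        J = op.jacobian(y, L)
        step = np.linalg.solve(J.toarray(), -r)
        lam = 1.0
        for _ in range(10):
            y_try = y + lam * step
            r_try = op.rhs(y_try, L)
            rn_try = np.max(np.abs(r_try))
            if rn_try < rn or rn_try <= tol:
                break
            lam *= 0.5
        else:
            if rn <= stall_tol:
                return _point(op, y, L)
            raise CorrectorError(
                f"Newton stalled at residual {rn:.3e} (L={L})", history
            )
        y, r, rn = y_try, r_try, rn_try
        history.append(rn)
    if rn <= tol:
        return _point(op, y, L)
    raise CorrectorError(f"Newton did not converge: residual {rn:.3e}", history)


def _dR_dL(op: Operator, y: np.ndarray, L: float) -> np.ndarray:
    # the only L dependence is the 1/L^2 diffusion prefactor
    h = 1e-7 * max(L, 1e-3)
    return (op.rhs(y, L + h) - op.rhs(y, L - h)) / (2 * h)


def _tangent_from_jacobian(op, y, L, orient, w):
    J = op.jacobian(y, L).toarray()
    try:
        dy = np.linalg.solve(J, -_dR_dL(op, y, L))
    except np.linalg.LinAlgError:
        dy = np.linalg.lstsq(J, -_dR_dL(op, y, L), rcond=None)[0]
    n = y.size
    norm = np.sqrt(w * (dy @ dy) / n + 1.0)
    tau_y, tau_L = dy / norm, 1.0 / norm
    if orient < 0:
        tau_y, tau_L = -tau_y, -tau_L
    return tau_y, tau_L


def continue_branch(
    op: Operator,
    start: BranchPoint,
    direction: int,
    L_window: tuple[float, float],
    *,
    ds0: float = 1e-3,
    ds_min: float = 1e-7,
    ds_max: float = 0.05,
    max_steps: int = 2000,
    corrector_tol: float = 1e-8,
    stop_after_stability_change: bool = False,
    compute_eigs: bool = True,
    state_weight: float = 0.04,
) -> Branch:
    """Trace a branch through the L window, traversing folds.

    ``direction`` orients the initial tangent by the sign of dL/ds.  The
    branch is truncated with a recorded reason if the corrector fails at
    the minimum step; setting ``stop_after_stability_change`` ends the
    trace as soon as the stability flag flips (used when only the first
    bifurcation along the branch is of interest).
    """
    n = start.y.size
    Lmin, Lmax = L_window
    branch = Branch()
    start.s = 0.0
    branch.points.append(start)
    w = state_weight
    tau_y, tau_L = _tangent_from_jacobian(op, start.y, start.L, direction, w)
    ds = ds0
    y_prev, L_prev, s_prev = start.y, start.L, 0.0
    for _ in range(max_steps):
        accepted = False
        while ds >= ds_min:
            y_pred = y_prev + ds * tau_y
            L_pred = L_prev + ds * tau_L
            try:
                y_new, L_new, iters = _bordered_newton(
                    op, y_pred, L_pred, tau_y, tau_L, corrector_tol, w
                )
                accepted = True
                break
            except CorrectorError:
                ds *= 0.5
        if not accepted:
            branch.truncated_reason = "corrector failed at minimum step"
            break
        s_new = s_prev + ds
        pt = _point(op, y_new, L_new, s_new, with_eigs=compute_eigs)
        branch.points.append(pt)
        # secant tangent update
        dy = (y_new - y_prev) / ds
        dL = (L_new - L_prev) / ds
        norm = np.sqrt(w * (dy @ dy) / n + dL * dL)
        tau_y, tau_L = dy / norm, dL / norm
        y_prev, L_prev, s_prev = y_new, L_new, s_new
        if iters <= 4:
            ds = min(ds * 1.5, ds_max)
        elif iters >= 6:
            ds = max(ds * 0.5, ds_min)
        if not (Lmin <= L_new <= Lmax):
            break
        if (
            stop_after_stability_change
            and len(branch.points) >= 2
            and branch.points[-1].stable != branch.points[-2].stable
        ):
            break
    branch.events = detect_events(branch, op)
    return branch


def _bordered_newton(op, y, L, tau_y, tau_L, tol, w, max_iter=12):
    n = y.size
    for it in range(max_iter):
        r = op.rhs(y, L)
        # the affine arclength constraint is zero at the predictor and each
        # Newton step preserves it, so only R enters the residual check
        rn = np.max(np.abs(r))
        if rn <= tol:
            return y, L, it
        J = op.jacobian(y, L).toarray()
        RL = _dR_dL(op, y, L)
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = J
        A[:n, n] = RL
        A[n, :n] = w * tau_y / n
        A[n, n] = tau_L
        rhs = np.empty(n + 1)
        rhs[:n] = -r
        rhs[n] = 0.0
        try:
            step = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise CorrectorError(f"bordered system singular: {exc}")
        y = y + step[:n]
        L = L + step[n]
        if not np.isfinite(L) or L <= 0:
            raise CorrectorError("corrector left the admissible L range")
    if np.max(np.abs(op.rhs(y, L))) <= 1e-8:
        return y, L, max_iter
    raise CorrectorError("bordered Newton did not converge")


def detect_events(branch: Branch, op: Operator | None = None,
                  *, refine_tol: float = 1e-4) -> list[tuple[str, float]]:
    """Locate folds and bifurcations along a computed branch.

    A fold is a sign change of dL/ds (located by a three-point parabola in
    arclength); a bifurcation is a stability-flag change without a fold in
    the same interval, refined by bisection on the leading eigenvalue's
    real part when the operator is supplied.
    """
    pts = branch.points
    events: list[tuple[str, float]] = []
    if len(pts) < 3:
        return events
    Ls = branch.L
    dL = np.diff(Ls)
    for i in range(1, len(dL)):
        if dL[i - 1] * dL[i] < 0:
            L3 = Ls[i - 1: i + 2]
            s3 = np.array([pts[i - 1].s, pts[i].s, pts[i + 1].s])
            coef = np.polyfit(s3 - s3[1], L3, 2)
            s_ext = -coef[1] / (2 * coef[0]) if coef[0] != 0 else 0.0
            events.append(("fold", float(np.polyval(coef, s_ext))))
    if any(p.leading_eigenvalues.size == 0 for p in pts):
        return sorted(events, key=lambda e: e[1])  # no eigen-data: folds only
    for i in range(len(pts) - 1):
        if pts[i].stable != pts[i + 1].stable:
            lo, hi = pts[i], pts[i + 1]
            near_fold = any(
                abs(e_loc - 0.5 * (lo.L + hi.L)) <= abs(hi.L - lo.L)
                for kind, e_loc in events
                if kind == "fold"
            )
            if near_fold:
                continue
            L_star = _refine_bifurcation(op, lo, hi, refine_tol) if op else 0.5 * (
                lo.L + hi.L
            )
            events.append(("bifurcation", float(L_star)))
    return sorted(events, key=lambda e: e[1])


def _refine_bifurcation(op, lo: BranchPoint, hi: BranchPoint, tol: float) -> float:
    a, b = lo, hi
    fa = a.leading_real
    for _ in range(60):
        if abs(b.L - a.L) <= tol:
            break
        Lm = 0.5 * (a.L + b.L)
        w = (Lm - a.L) / (b.L - a.L)
        guess = (1 - w) * a.y + w * b.y
        try:
            mid = corrector(op, Lm, guess)
        except CorrectorError:
            break
        if mid.leading_real * fa <= 0:
            b = mid
        else:
            a, fa = mid, mid.leading_real
    return 0.5 * (a.L + b.L)


def switch_branch(
    op: Operator,
    point: BranchPoint,
    sign: int,
    L_target: float,
    *,
    delta: float = 1e-2,
    max_retries: int = 4,
) -> BranchPoint:
    """Step off a simple bifurcation onto the crossing branch.

    Seeds the corrector at ``point.y + sign * delta * phi`` (phi the
    critical eigenvector, max-normalized) at the slightly offset
    ``L_target``; if the corrector falls back onto the original branch the
    perturbation is enlarged and retried.
    """
    J = op.jacobian(point.y, point.L).toarray()
    lam, vecs = sla.eig(J)
    crit = np.argmin(np.abs(lam.real) + np.abs(lam.imag))
    phi = vecs[:, crit].real
    phi = phi / np.max(np.abs(phi))
    base = corrector(op, L_target, point.y)  # on-branch reference at L_target
    d = delta
    for _ in range(max_retries):
        try:
            cand = corrector(op, L_target, base.y + sign * d * phi)
        except CorrectorError:
            d *= 3.0
            continue
        dist = np.max(np.abs(cand.y - base.y))
        if dist > 0.2 * d:
            return cand
        d *= 3.0
    raise CorrectorError(
        "branch switching kept falling back onto the original branch"
    )


def branch_diagram(branches: dict[str, Branch] | list[Branch]) -> pd.DataFrame:
    """Long-format table (branch, s, L, max_u, min_u, stable) for plotting."""
    if isinstance(branches, list):
        branches = {str(i): b for i, b in enumerate(branches)}
    rows = []
    for name, br in branches.items():
        for p in br.points:
            rows.append(
                {
                    "branch": name,
                    "s": p.s,
                    "L": p.L,
                    "max_u": p.max_u,
                    "min_u": p.min_u,
                    "stable": p.stable,
                }
            )
    return pd.DataFrame(rows)


def homogeneous_branch(op: Operator, L_values: np.ndarray) -> Branch:
    """The trivial branch: the homogeneous steady state at each L.

    Exact to machine precision at every L; only its stability varies.
    """
    branch = Branch()
    y = op.homogeneous_state()
    s = 0.0
    prev_L = None
    for L in np.asarray(L_values, dtype=float):
        if prev_L is not None:
            s += abs(L - prev_L)
        branch.points.append(_point(op, y.copy(), L, s))
        prev_L = L
    branch.events = detect_events(branch, op)
    return branch
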