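"""High-level analysis chains built from the lower-level modules.

These functions wire the standard pipeline together — steady state,
linear Turing analysis, amplitude equations, branch seeding and
continuation — in the order a study of a given kinetics would run them.
"""

from __future__ import annotations

import numpy as np

from . import amplitude as amp
from . import continuation as cont
from . import linear
from . import simulate as sim
from . import systems

__all__ = [
    "full_analysis",
    "seed_branch_point",
    "trace_transcritical_branch",
    "trace_pitchfork_branch",
    "supercritical_stability_loss",
]


def full_analysis(
    system: systems.ReactionDiffusionSystem,
    initial_guess=(1.0, 1.0),
    truncation_N: int = 128,
):
    """Steady state, linear analysis and both amplitude equations.

    Returns a dict with the steady state, derivative table, linear
    results, transcritical (Dirichlet) and pitchfork (Neumann)
    coefficients, plus the oriented kernel/adjoint pair.
    """
    steady = systems.find_steady_state(system, initial_guess)
    derivs = systems.derivative_table(system, steady)
    lin = linear.linear_analysis(system, derivs)
    trans = amp.dirichlet_cubic_coefficients(
        system, derivs, lin, truncation_N=truncation_N
    )
    pitch = amp.neumann_cubic_coefficients(system, derivs, lin)
    Phi, Psi = amp.oriented_vectors(system, derivs, lin)
    return {
        "steady": steady,
        "derivs": derivs,
        "linear": lin,
        "transcritical": trans,
        "pitchfork": pitch,
        "Phi": Phi,
        "Psi": Psi,
    }


def report_dict(analysis) -> dict:
    """JSON-ready summary of a :func:`full_analysis` result."""
    lin = analysis["linear"]
    tc = analysis["transcritical"]
    pf = analysis["pitchfork"]
    return {
        "steady_state": {"u": analysis["steady"].u, "v": analysis["steady"].v},
        "L_c": lin.L_c,
        "k_minus": lin.k_minus,
        "k_plus": lin.k_plus,
        "Lambda": lin.Lambda,
        "eta": lin.eta,
        "dirichlet": {
            "p1": tc.p1,
            "p2": tc.p2,
            "p3": tc.p3,
            "p4": tc.p4,
            "p5": tc.p5,
            "m": tc.slope_m,
        },
        "neumann": {"lin": pf.lin, "cub": pf.cub},
    }


def seed_branch_point(
    op: sim.Operator,
    analysis,
    branch: str,
    dL: float,
) -> cont.BranchPoint:
    """Converge a starting point on a bifurcating branch near onset.

    ``branch`` selects the predicted small-amplitude state: Dirichlet
    "supercritical" (a < 0, pattern dipping below the steady state, exists
    for L > L_c) or "subcritical" (a > 0, above it, L < L_c); Neumann
    "pitchfork+" / "pitchfork-" for the two mirror states at L > L_c.
    ``dL`` is the signed offset from L_c at which to seed.
    """
    lin = analysis["linear"]
    Phi = analysis["Phi"]
    steady = analysis["steady"]
    L = lin.L_c + dL
    x = op.x_full
    mode = np.cos(np.pi * x)
    if branch in ("supercritical", "subcritical"):
        tc = analysis["transcritical"]
        a = -tc.p1 * dL / tc.p2
        expected_sign = -1.0 if branch == "supercritical" else 1.0
        if a * expected_sign < 0:
            raise ValueError(
                f"offset dL={dL} puts the {branch} branch on the wrong side of L_c"
            )
    elif branch in ("pitchfork+", "pitchfork-"):
        pf = analysis["pitchfork"]
        rad = pf.lin * dL / pf.cub
        if rad <= 0:
            raise ValueError("pitchfork branches require dL > 0 (supercritical)")
        a = np.sqrt(rad) * (1.0 if branch.endswith("+") else -1.0)
    else:
        raise ValueError(f"unknown branch {branch!r}")
    u0 = steady.u + Phi[0] * a * mode
    v0 = steady.v + Phi[1] * a * mode
    guess = op.pack(u0, v0)
    pt = cont.corrector(op, L, guess)
    spread = pt.max_u - pt.min_u
    if spread < 0.1 * abs(Phi[0] * a):
        raise cont.CorrectorError(
            "seed collapsed onto the homogeneous branch; increase |dL|"
        )
    return pt


def trace_transcritical_branch(
    system,
    analysis,
    branch: str,
    n_interior: int = 200,
    *,
    dL_seed: float | None = None,
    L_window=(0.03, 1.0),
    **cont_kwargs,
):
    """Continue the Dirichlet sub- or supercritical branch from onset."""
    op = sim.build_operator(
        system, sim.DIRICHLET, n_interior + 2, analysis["steady"]
    )
    if dL_seed is None:
        dL_seed = 0.004 if branch == "supercritical" else -0.004
    start = seed_branch_point(op, analysis, branch, dL_seed)
    direction = 1 if branch == "supercritical" else -1
    return op, cont.continue_branch(
        op, start, direction, L_window, **cont_kwargs
    )


def trace_pitchfork_branch(
    system,
    analysis,
    sign: str = "+",
    n_interior: int = 200,
    *,
    dL_seed: float = 0.004,
    L_window=(0.03, 1.0),
    **cont_kwargs,
):
    """Continue one sign of the Neumann pitchfork from onset."""
    op = sim.build_operator(system, sim.NEUMANN, n_interior, analysis["steady"])
    start = seed_branch_point(op, analysis, f"pitchfork{sign}", dL_seed)
    return op, cont.continue_branch(op, start, 1, L_window, **cont_kwargs)


def supercritical_stability_loss(
    system,
    analysis=None,
    n_interior: int = 200,
    *,
    L_max: float = 0.45,
    refine_tol: float = 1e-4,
    **cont_kwargs,
) -> float:
    """First L above L_c where the small-amplitude Dirichlet branch destabilizes.

    Switches onto the supercritical branch at the transcritical point,
    continues upward in L monitoring the rightmost eigenvalue, and refines
    the first crossing by bisection along the branch.
    """
    if analysis is None:
        analysis = full_analysis(system)
    op, branch = trace_transcritical_branch(
        system,
        analysis,
        "supercritical",
        n_interior,
        L_window=(analysis["linear"].L_c, L_max),
        stop_after_stability_change=True,
        **cont_kwargs,
    )
    bifs = [loc for kind, loc in branch.events if kind == "bifurcation"]
    if not bifs:
        raise RuntimeError(
            "no stability change found on the supercritical branch up to "
            f"L={L_max} (truncated: {branch.truncated_reason})"
        )
    return min(bifs)
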