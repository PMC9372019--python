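"""Weakly nonlinear machinery: projections, second-order fields, coefficients."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from turingbif import amplitude as amp
from turingbif import linear, systems

U, V = sp.symbols("u v", real=True)


def _quadrature_coefficient(n):
    """Independent oracle: 2 * integral of cos^2(pi x) cos((2n+1) pi x)."""
    val, _ = integrate.quad(
        lambda x: np.cos(np.pi * x) ** 2 * np.cos((2 * n + 1) * np.pi * x),
        -0.5,
        0.5,
        epsabs=1e-13,
    )
    return 2 * val


def test_cos_squared_coefficient_leading_values():
    assert amp.cos_squared_fourier_coefficient(0) == pytest.approx(8 / (3 * np.pi))
    assert amp.cos_squared_fourier_coefficient(1) == pytest.approx(
        _quadrature_coefficient(1)
    )
    with pytest.raises(ValueError):
        amp.cos_squared_fourier_coefficient(-1)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(n=st.integers(0, 40))
def test_cos_squared_coefficient_matches_quadrature(n):
    assert amp.cos_squared_fourier_coefficient(n) == pytest.approx(
        _quadrature_coefficient(n), rel=1e-9, abs=1e-12
    )


def test_cos_squared_partial_sums_converge():
    x = np.linspace(-0.5, 0.5, 401)
    target = np.cos(np.pi * x) ** 2
    errs = []
    for N in (2, 8, 32):
        approx = sum(
            amp.cos_squared_fourier_coefficient(n) * np.cos((2 * n + 1) * np.pi * x)
            for n in range(N)
        )
        errs.append(np.sqrt(np.trapezoid((approx - target) ** 2, x)))
    assert errs[0] < 0.02  # two terms already give an excellent approximation
    assert errs[0] > errs[1] > errs[2]


def test_quadratic_projection_vanishes_for_linear_kinetics():
    system = systems.ReactionDiffusionSystem(1 - U + V, 1 - V, 1e-3, 0.1)
    ss = systems.find_steady_state(system, (1.0, 1.0))
    table = systems.derivative_table(system, ss)
    assert np.allclose(amp.quadratic_form_projection(table, np.array([2.0, 1.0])), 0)


def test_quadratic_projection_relabeling(schnak, steady, derivs):
    """Swapping the species labels transposes the projection pair."""
    swapped = systems.ReactionDiffusionSystem(
        schnak.g_expr.subs({U: V, V: U}, simultaneous=True),
        schnak.f_expr.subs({U: V, V: U}, simultaneous=True),
        schnak.D_v,
        schnak.D_u,
    )
    ss_sw = systems.find_steady_state(swapped, (steady.v, steady.u))
    table_sw = systems.derivative_table(swapped, ss_sw)
    vec = np.array([-3.1, 1.7])
    direct = amp.quadratic_form_projection(derivs, vec)
    mirrored = amp.quadratic_form_projection(table_sw, vec[::-1])
    assert np.allclose(direct, mirrored[::-1], rtol=1e-12)


def test_dirichlet_quadratic_coefficients(schnak, derivs, lin, analysis):
    p1, p2 = amp.dirichlet_quadratic_coefficients(schnak, derivs, lin)
    assert round(p1, 2) == 13.93
    assert round(p2, 2) == 15.19
    tc = analysis["transcritical"]
    # same values reappear in the third-order assembly
    assert tc.p1 == pytest.approx(p1, abs=1e-10)
    assert tc.p2 == pytest.approx(p2, abs=1e-10)


def test_p1_equals_dispersion_derivative(schnak, derivs, lin, analysis):
    """Independent oracle: p1 = d(max Re lambda(pi; L))/dL at L_c."""
    h = 1e-6 * lin.L_c
    lo = linear.dispersion_eigenvalues(schnak, derivs, np.pi, lin.L_c - h).max_real
    hi = linear.dispersion_eigenvalues(schnak, derivs, np.pi, lin.L_c + h).max_real
    slope = (hi - lo) / (2 * h)
    assert analysis["transcritical"].p1 == pytest.approx(slope, rel=1e-4)
    assert analysis["pitchfork"].lin == pytest.approx(slope, rel=1e-4)


def test_vanishing_second_derivatives_give_zero_p2():
    # purely linear kinetics with a Turing-capable Jacobian: no quadratic term
    system = systems.ReactionDiffusionSystem(
        (U - 1) + 4 * (V - 1), -3 * (U - 1) - 4 * (V - 1), 1e-3, 0.1
    )
    ss = systems.find_steady_state(system, (1.0, 1.0))
    table = systems.derivative_table(system, ss)
    lin_res = linear.linear_analysis(system, table)
    _, p2 = amp.dirichlet_quadratic_coefficients(system, table, lin_res)
    assert p2 == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("bc", ["dirichlet", "neumann"])
def test_second_order_field_residuals(schnak, derivs, lin, bc):
    field2 = amp.solve_second_order(schnak, derivs, lin, bc, truncation_N=32)
    assert field2.max_mode_residual(schnak, derivs, lin) <= 1e-8


def test_neumann_second_order_has_two_modes(schnak, derivs, lin):
    field2 = amp.solve_second_order(schnak, derivs, lin, "neumann")
    assert list(field2.wavenumbers) == [0.0, 2 * np.pi]


def test_dirichlet_mode_coefficients_decay_cubically(schnak, derivs, lin):
    field2 = amp.solve_second_order(schnak, derivs, lin, "dirichlet", truncation_N=64)
    norms = np.linalg.norm(field2.quad, axis=1)[5:]
    modes = 2 * np.arange(5, 65) + 1.0
    slope = np.polyfit(np.log(modes), np.log(norms), 1)[0]
    assert slope <= -3.0


def test_v0_gauge_zeroes_critical_v_component(schnak, derivs, lin):
    field2 = amp.solve_second_order(schnak, derivs, lin, "dirichlet", 16, gauge="v0")
    assert field2.quad[0][1] == 0.0
    assert field2.crit_linear[1] == 0.0


def test_dirichlet_cubic_coefficients(analysis):
    tc = analysis["transcritical"]
    assert round(tc.p3, 2) == 237.69
    assert round(tc.p4, 2) == 268.02
    assert round(tc.p5, 2) == 35.13
    assert tc.slope_m == pytest.approx(tc.p1 / tc.p2, abs=1e-10)


def test_cubic_coefficients_truncation_stable(schnak, derivs, lin):
    def coeffs(N):
        Phi, Psi = amp.oriented_vectors(schnak, derivs, lin)
        f2 = amp.solve_second_order(schnak, derivs, lin, "dirichlet", N)
        return amp._dirichlet_p345(schnak, derivs, lin, Phi, Psi, f2)

    c64, c128 = coeffs(64), coeffs(128)
    for a, b in zip(c64, c128):
        assert abs(a - b) / abs(b) <= 1e-6


def test_gauge_invariance_of_p3_p5(schnak, derivs, lin):
    vals = {}
    for gauge in ("v0", "u0", "kernel"):
        Phi, Psi = amp.oriented_vectors(schnak, derivs, lin)
        f2 = amp.solve_second_order(schnak, derivs, lin, "dirichlet", 64, gauge=gauge)
        vals[gauge] = amp._dirichlet_p345(schnak, derivs, lin, Phi, Psi, f2)
    for gauge in ("u0", "kernel"):
        assert vals[gauge][0] == pytest.approx(vals["v0"][0], rel=1e-9)  # p3
        assert vals[gauge][2] == pytest.approx(vals["v0"][2], rel=1e-9)  # p5


def test_neumann_pitchfork_coefficients(analysis):
    pf = analysis["pitchfork"]
    assert pf.lin == pytest.approx(analysis["transcritical"].p1, abs=1e-10)
    assert pf.cub == pytest.approx(222.81, abs=0.01)
    assert pf.cub > 0  # supercritical for the fixture


def test_amplitude_steady_states_transcritical(analysis):
    tc = analysis["transcritical"]
    quad = amp.TranscriticalCoefficients(p1=tc.p1, p2=tc.p2)
    at_onset = amp.amplitude_steady_states(quad, 0.0)
    assert at_onset == [(0.0, False)]
    below = amp.amplitude_steady_states(quad, -0.01)
    assert (0.0, True) in below
    a_star = -tc.p1 * (-0.01) / tc.p2
    assert a_star > 0
    (nontrivial,) = [s for s in below if s[0] != 0.0]
    assert nontrivial[0] == pytest.approx(a_star) and nontrivial[1] is False


def test_amplitude_steady_states_pitchfork(analysis):
    pf = analysis["pitchfork"]
    above = amp.amplitude_steady_states(pf, 0.01)
    amps = sorted(a for a, _ in above)
    assert amps[0] == pytest.approx(-amps[2])  # reflection symmetry
    assert dict(above)[0.0] is False
    below = amp.amplitude_steady_states(pf, -0.01)
    assert below == [(0.0, True)]


def test_transcritical_exchange_of_stability_by_integration(analysis):
    """Time integration oracle: a small positive seed departs 0 when L1 > 0."""
    tc = analysis["transcritical"]
    L1 = 0.01
    sol = integrate.solve_ivp(
        lambda t, a: tc.p1 * L1 * a + tc.p2 * a**2,
        (0.0, 40.0),
        [1e-6],
        rtol=1e-10,
        atol=1e-14,
    )
    assert sol.y[0, -1] > 10 * sol.y[0, 0]


def test_degenerate_quadratic_raises():
    with pytest.raises(amp.DegenerateBifurcationError):
        amp.amplitude_steady_states(
            amp.TranscriticalCoefficients(p1=1.0, p2=0.0), 0.1
        )


def test_predicted_branch_geometry(analysis, steady, lin):
    tc = analysis["transcritical"]
    Phi = analysis["Phi"]
    Ls = np.append(np.linspace(lin.L_c * 0.98, lin.L_c * 1.05, 30), lin.L_c)
    quad = amp.predicted_branch(tc, steady, Phi, Ls, lin.L_c, order=2)
    # passes through u_s at L_c and is a straight line of slope -m in a
    a_fit = np.polyfit(quad["L"] - lin.L_c, quad["a"], 1)
    assert a_fit[0] == pytest.approx(-tc.slope_m, rel=1e-10)
    assert a_fit[1] == pytest.approx(0.0, abs=1e-12)
    at_lc = quad.iloc[(quad["L"] - lin.L_c).abs().argmin()]
    assert at_lc["u_extremum"] == pytest.approx(steady.u, abs=1e-12)
    cubic = amp.predicted_branch(tc, steady, Phi, Ls, lin.L_c, order=3)
    multi = cubic[cubic["L"] > lin.L_c].groupby("L").size()
    assert (multi == 2).any()  # multivalued beyond onset at cubic order


def test_branch_slope_nonmonotonic_in_Dv(schnak):
    """m(D_v) rises to a single interior maximum then decays."""
    ms = []
    # start just above the region minimum D_vc; log spacing resolves the
    # narrow rising flank before the maximum near D_v ~ 0.05
    for dv in np.geomspace(0.042, 1.0, 40):
        system = schnak.with_(D_v=dv)
        ss = systems.find_steady_state(system, (1.0, 1.0))
        table = systems.derivative_table(system, ss)
        lin_res = linear.linear_analysis(system, table)
        p1, p2 = amp.dirichlet_quadratic_coefficients(system, table, lin_res)
        ms.append(p1 / p2)
    signs = np.sign(np.diff(ms))
    flips = np.flatnonzero(np.diff(signs) != 0)
    assert len(flips) == 1 and signs[0] > 0 and signs[-1] < 0
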