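import pytest

from turingbif import systems, workflows


@pytest.fixture(scope="session")
def schnak():
    return systems.schnakenberg()


@pytest.fixture(scope="session")
def steady(schnak):
    return systems.find_steady_state(schnak, (1.0, 1.0))


@pytest.fixture(scope="session")
def derivs(schnak, steady):
    return systems.derivative_table(schnak, steady)


@pytest.fixture(scope="session")
def analysis(schnak):
    """Full analysis chain on the activator-depletion fixture."""
    return workflows.full_analysis(schnak)


@pytest.fixture(scope="session")
def lin(analysis):
    return analysis["linear"]


@pytest.fixture(scope="session")
def subcritical_branch(schnak, analysis):
    """Subcritical Dirichlet branch traced through its fold (n = 128)."""
    _, br = workflows.trace_transcritical_branch(
        schnak, analysis, "subcritical", n_interior=128,
        L_window=(0.02, 0.22), max_steps=1000,
    )
    return br
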