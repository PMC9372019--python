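# turingbif

Bifurcation structure of Turing patterns in one dimension — and how it
depends on the boundary conditions.

Diffusion-driven (Turing) instability is the standard mechanism by which
a pair of reacting, diffusing morphogens turns a spatially uniform state
into a pattern.  The textbook picture is that the pattern is born at a
pitchfork bifurcation: two mirror-image patterns (peaks ↔ troughs)
emerge together as the domain scale `L` crosses its critical value
`L_c`.  That picture is tied to zero-flux (Neumann) boundaries.  If the
concentrations are instead *pinned to the homogeneous steady state* at
the walls — a Dirichlet condition natural for boundary sources or sinks —
the quadratic mode interaction `cos²(πx)` becomes resonant and the first
bifurcation is generically **transcritical**: a single asymmetric branch
crosses the homogeneous state, with an unstable subcritical side that can
fold back into large-amplitude stable patterns *below* `L_c`.

`turingbif` implements the full analysis chain for any two-species
reaction–diffusion system

    u_t = (D_u/L²) u_xx + f(u,v),    v_t = (D_v/L²) v_xx + g(u,v)

on a unit interval:

* **kinetics** (`turingbif.systems`) — closed-form kinetics via sympy,
  homogeneous steady states, exact partial derivatives to third order;
* **linear analysis** (`turingbif.linear`) — Routh–Hurwitz flags,
  dispersion relation, unstable wavenumber window `(k_-, k_+)`, critical
  scale `L_c`, kernel/adjoint vectors `(Λ, η)`, and the `(L, D_v)`
  patterning region with its closed-form extremes;
* **weakly nonlinear analysis** (`turingbif.amplitude`) — multiple-scales
  amplitude equations by Fredholm solvability: the Dirichlet
  transcritical equation `da/dt₁ = p1 L₁ a + p2 a²` with its third-order
  corrections `(p3, p4, p5)`, and the Neumann pitchfork
  `da/dt₂ = lin·L₂ a − cub·a³`;
* **PDE simulation** (`turingbif.simulate`) — implicit method-of-lines
  runs under either boundary condition, static or slowly growing
  `L(t) = L₀(1 + t/100)`, with the study's initial-condition
  constructions and critical-mode amplitude extraction;
* **continuation** (`turingbif.continuation`) — pseudo-arclength tracing
  of discretized steady states in `L`, stability via dense eigensolves,
  fold/bifurcation detection and branch switching;
* **CLI** (`turingbif.cli`) — `turingbif analyze | amplitude | simulate |
  continue | region | report`.

## Worked example

The built-in fixture is the classic activator-depletion ("cross")
kinetics `f = 1 − 2u + u²v`, `g = 3 − u²v` with `D_u = 1/1000`,
`D_v = 1/10`, whose steady state is `(2, 3/4)`:

```sh
$ turingbif amplitude --out out
```

```json
{
  "steady_state": {"u": 2.0, "v": 0.75},
  "L_c": 0.10664400569515249,
  "k_minus": 1.0239247001562415,
  "Lambda": -30.260479619776874,
  "eta": 22.695359714832644,
  "dirichlet": {"p1": 13.92547685537431, "p2": 15.192012221746735,
                "p3": 237.69014174875696, "p4": 268.02420699907316,
                "p5": 35.13061835704733, "m": 0.9166314937161891},
  "neumann":   {"lin": 13.92547685537431, "cub": 222.81432292919672}
}
```

Reading this: patterns first appear at domain scale `L_c ≈ 0.107`, where
the unstable wavenumber window is `(k_-, k_+) ≈ (1.02, π)`.  Under
Dirichlet walls the amplitude of the `cos(πx)` mode obeys the
transcritical equation `da/dt₁ ≈ 13.93 L₁ a + 15.19 a²`, so the
supercritical branch leaves onset with slope `m = p1/p2 ≈ 0.92`
(`a ≈ −0.92 (L − L_c)`) and the third-order corrections add
`−35.13 ε a³`, `−268.02 ε L₁ a²` and `−237.69 ε L₁² a`.  Under Neumann
walls the same kinetics instead give the supercritical pitchfork
`da/dt₂ ≈ 13.93 L₂ a − 222.81 a³`: a mirror pair of patterns of height
`±sqrt(13.93 (L − L_c) / 222.81)`.

The same numbers can be produced in Python, together with the
continuation that shows the subcritical branch folding into
large-amplitude "bat-ear" boundary-peak patterns:

```python
import turingbif as tb

system = tb.schnakenberg()               # the fixture above
analysis = tb.full_analysis(system)      # steady state -> amplitude eqs
op, branch = tb.trace_transcritical_branch(
    system, analysis, "subcritical", n_interior=128, L_window=(0.02, 0.22)
)
print(branch.events)        # [('fold', 0.0300...)] -- stable patterns below L_c
print(tb.supercritical_stability_loss(system, analysis))  # 0.3271...
```

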