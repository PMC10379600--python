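# Methods

## The game

County medical community (CMC) construction is modelled as an
evolutionary game among populations of boundedly rational organisations
that revise strategies by imitation. The two-subject game pits the lead
hospital (efficient vs. inefficient construction, frequency `x`) against
the primary healthcare institutions (active vs. passive participation,
frequency `y`); the tripartite game adds government departments
(adequate vs. prudent support, frequency `z`).

Pure-strategy payoffs combine the constants listed below. Two structural
couplings matter: the delivered resources `U` are simultaneously a cost
of the lead hospital and an income of the institutions (no separate
symbol is introduced), and the integration intensity `ξ` discounts the
costs/authority of whichever side plays passively.

| symbol | meaning | baseline | range |
|---|---|---|---|
| I | information-integration cost of the lead hospital | 26 | > 0 |
| U | medical resources delivered downward | 5 | > 0 |
| Sl, Sp | service capacity, lead hospital / institutions | 14, 2 | > 0 |
| Tp | authority ceded by the institutions | 12 | > 0 |
| R | performance allocation to the institutions | 3 | > 0 |
| D | attendance-loss of the institutions | 25 | > 0 |
| v | policy-effect coefficient | 0.5 | [0, 1] |
| pi (π) | integration coefficient | 0.5 | [0, 1] |
| eps (ε) | absorption ratio under passive play | 0.5 | [0, 1] |
| xi (ξ) | information-integration intensity | 0.5 | [0, 1] |
| Tg | authority ceded by government | 6 | > 0 |
| F | government construction funds | 6 | > 0 |
| A | political gains | 10 | > 0 |
| phi (φ) | government support intensity | 0.5 | [0, 1] |

The baselines ship as TOML files in `cmcgame/data/` and are the single
source of truth for the preset sweeps.

## Printed vs. derived drift

Replicator dynamics move each frequency `p` by `dp/dt = p(1−p)·f`, with
`f` the expected-payoff advantage of the aggressive strategy. The
package carries **two** drift variants because the source system's
typeset drift factors are not everywhere the ones implied by its own
payoff matrices:

* `mode="printed"` evaluates the factors exactly as typeset. The
  flattened journal notation is parsed as
  `f_x = (ξ−1)(I+U) + yπ(1−ξ)Tp [+ zπ(1−ξ)Tg] + πSl + ξTp [+ ξTg + (1−ξ)φF]`,
  `f_y = πSp + (1+v)R + (ξ−1)Tp + (1−ε)ξU + (1−ε)(1−ξ)Ux + (1−q)vD`
  (with `q = x` in the two-subject game, `q = z` tripartite), and
  `f_z = A(φ−v+φv)(xy−x−y) + (ξ−1)Tg − (1−φ)F + A`. This parse is pinned
  by an internal-consistency requirement: it makes the printed `f_y`
  agree *exactly* with the payoff-matrix derivation.
* `mode="derived"` recomputes `f = e1 − e2` from the expected payoffs.
  Since every factor is multilinear in the co-players' probabilities,
  the implementation evaluates the payoff gap at the co-player corners
  and interpolates — which is exact, and keeps the derived route
  genuinely independent of the printed formulas.

The two variants differ by closed forms: the two-subject `x`-factor by
the constant `ξTp(1−π)`, the tripartite `z`-factor by
`(ξ−1)Tg(1−x)(1−y)` (the `y`-factors agree identically). `printed` is
the default because it is the system the published simulations
integrated, and the reported integration-intensity crossover bracket
(0.3 < ξ < 0.5, exact root ξ* = 18/37 of `f_x` at `y = 1`) is only
consistent with the printed factor — the derived factor would place the
root at 18/31 ≈ 0.58. `derived` is retained as an audit tool, surfaced
through `drift_discrepancy` and the `compare-drifts` CLI command.

Where the tripartite payoff tables and the expectation expressions
disagree (the all-passive prudent-government cell, and whether the
attendance-loss reduction for passive institutions keys on the lead
hospital's or the government's strategy), the expectation-expression
reading is the executable one — it is the single source that feeds the
replicator construction. Asymmetric `Tg`/`F` terms inside those
expressions (e.g. prudent support grants `ξTg` to an efficient lead
hospital only against active institutions) are reproduced verbatim
rather than "repaired"; a repair would be a guess.

Two functional forms of the drift are exposed: the standard replicator
product `p(1−p)f` (default, `form="replicator"`) and the literal linear
reading `p·f` of the discretised recursion (`form="linear"`). With
clamping both share vertex attractors and factor signs; the replicator
form is the declared dynamic, the linear form reproduces the recursion
as literally printed.

## Stochastic scheme and numerical choices

Uncertainty of information transformation enters as multiplicative white
Gaussian noise `σ·p·dω` per role, discretised by Forward Euler
(Euler–Maruyama): `p_{n+1} = p_n + drift·h + σ·p_n·Δω_n`,
`Δω ~ N(0, h)`. Choices that the source leaves open, fixed here once:

* **σ = 0.05 default.** No noise intensity is printed anywhere; 0.05 is
  small against drift factors of order 1–10, so the qualitative
  transitions survive while paths visibly fluctuate. It is an explicit
  knob, not a constant.
* **h = 0.01, N = 10 000 steps (T = 100).** Neither step size nor
  horizon is printed. The slowest relevant drift factor at the baseline
  is 0.5, a timescale of ~2 time units, resolved by ≥ 200 steps; T = 100
  leaves every studied configuration fully converged in the
  deterministic limit. Explicit Euler is stable here (|f|·h ≤ ~0.25).
* **Clamping to [0, 1]** after every step keeps states valid
  probabilities; the paper is silent on boundary handling. Boundaries
  are absorbing for the noise-free component (drift and multiplicative
  noise both vanish at p = 0; at p = 1 the replicator drift vanishes and
  upward noise kicks are clamped back).
* **Independent Brownian streams per role** (the source writes a shared
  one-dimensional motion but perturbs each equation separately);
  disturbances to distinct organisations are distinct. A shared stream
  is available via `SimulationSettings(shared_noise=True)`.
* **Initial state (0.5, 0.5[, 0.5])**: never stated in the source;
  maximal-uncertainty start, symmetric across strategies.
* **Fixed-step Euler also for σ = 0** so the deterministic limit is the
  exact σ→0 arithmetic of the stochastic scheme (a σ = 0 stochastic run
  is bit-identical to `integrate_deterministic`). An adaptive RK45
  cross-check in the test suite confirms the terminal states to < 1e−3.
* **Degenerate vertices** (some drift factor exactly 0) are flagged, not
  force-classified — ties are measure-zero and the source gives no rule.

## Vertex analysis and convergence classification

`vertex_stability` classifies each corner of the state cube by drift-
factor signs: stable when every role's factor pushes it back (f > 0 at
p = 1, f < 0 at p = 0), unstable when every role is pushed away, saddle
otherwise. No Jacobian eigen-analysis is attempted — the source
classifies by simulation, and at vertices the factor signs are the
one-dimensional growth rates.

A simulated path counts as converged to a vertex when it stays within
0.05 (max-norm) of it over the final 10% of the horizon (sweep
classification); ensembles additionally report the fraction of
replicates *terminating* within 0.1 of each vertex, a looser terminal-
distance criterion suited to noisy paths that hover near an absorbing
corner. Convergence time is the first time from which the path remains
inside the tolerance.

## Preset sweeps

Seven presets vary one symbol at a time around the baselines: `Tp` over
{5,…,25}, `π`, `ξ`, `v`, `φ` over {0.1,…,0.9}, `U` over {1,3,5,7,9}
(grid not printed in the source; symmetric bracket of the baseline 5),
and the composite `Tp+Tg` over {5,…,25} split 2:1 (the only split
consistent with the stated baseline 12:6; configurable). Replicates
default to 1 — the source figures display a single path per grid value.
`threshold_scan` reports the smallest (largest) grid value whose
deterministic terminal crosses 0.9 (0.1) for a role, flagging
non-monotone patterns.

## What the synthetic conditions do and do not show

There is no empirical data in this model: the baseline constants are
stylised magnitudes chosen for theoretical exploration, and all results
are statements about the model, not about any county's healthcare
system. Passing tests demonstrate internal consistency (payoff ↔ drift
agreement, scheme correctness, seeded reproducibility) and reproduce the
qualitative policy findings in the deterministic limit; they cannot
validate parameter magnitudes, the linearity of the payoff structure, or
the adequacy of white noise as a model of institutional uncertainty.

## Known limitations

* Two reported sweep behaviours — inefficient construction at `Tp = 20`
  (two-subject) and at `Tp+Tg = 20` (tripartite) — are not reproduced by
  *any* drift variant implemented here: all give `f_x > 0` along the
  relevant paths. They likely depend on figure-specific noise settings
  or initial states that were never printed. The package records this
  and makes no claim either way.
* Interior (mixed) equilibria are only accessible through root-finding
  on drift factors; no Lyapunov analysis is provided.
* The Euler–Maruyama scheme is first order; no higher-order SDE schemes
  are offered since the discretisation itself is part of the model
  specification.
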