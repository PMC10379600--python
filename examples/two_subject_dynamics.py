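"""Deterministic two-subject dynamics at the baseline parameterisation.

The lead hospital (probability x of efficient construction) and the
primary healthcare institutions (probability y of active participation)
start undecided at (0.5, 0.5).  At the baseline the participation payoff
advantage is strongly positive, so y rises first; once the institutions
are active, the lead hospital's factor turns positive and x follows.
"""

from cmcgame import (
    GameState,
    SimulationSettings,
    baseline_parameters,
    drift,
    integrate_deterministic,
)

params = baseline_parameters("two")
settings = SimulationSettings(sigma=0.0, h=0.01, steps=10_000)

state0 = GameState(0.5, 0.5)
d = drift(state0, params)
print(f"drift factors at {state0.as_tuple()}: "
      f"f_x = {d.factors[0]:+.4g}, f_y = {d.factors[1]:+.4g}")

traj = integrate_deterministic(state0, params, settings)
for t in (0.0, 5.0, 10.0, 25.0, 100.0):
    idx = int(t / settings.h)
    x, y = traj.states[idx]
    print(f"t = {t:6.1f}:  x = {x:.4f}  y = {y:.4f}")

print(
    "\nBoth probabilities approach 1: the game settles on"
    " {efficient construction, active participation}."
)
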