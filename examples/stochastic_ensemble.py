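"""Effect of environmental uncertainty on the two-subject game.

White Gaussian noise (intensity sigma) perturbs each strategy probability
multiplicatively.  An ensemble of seeded Euler-Maruyama runs shows how
often the noisy system still reaches the deterministic attractor (1, 1).
"""

from cmcgame import (
    GameState,
    SimulationSettings,
    baseline_parameters,
    run_ensemble,
)

params = baseline_parameters("two")
state0 = GameState(0.5, 0.5)

for sigma in (0.05, 0.2):
    settings = SimulationSettings(sigma=sigma, h=0.01, steps=10_000)
    summary = run_ensemble(state0, params, settings, replicates=30, base_seed=2024)
    fractions = ", ".join(
        f"({label}): {frac:.2f}" for label, frac in summary.convergence_fraction.items()
    )
    mt = summary.mean_terminal
    print(f"sigma = {sigma}: vertex fractions {fractions}; "
          f"mean terminal = ({mt[0]:.3f}, {mt[1]:.3f})")

print(
    "\nFractions are the share of 30 seeded replicates ending within 0.1"
    " of each pure-strategy corner; mild noise leaves the cooperative"
    " outcome (1, 1) dominant."
)
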