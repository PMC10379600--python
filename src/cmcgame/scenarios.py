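"""Declarative parameter-sweep scenarios.

Seven preset sweeps probe the sensitivity of the game to one symbol at a
time, holding everything else at the baseline parameterisation shipped
with the package:

=====  ======  ==========  ===========================
name   model   varied      grid
=====  ======  ==========  ===========================
fig2   two     Tp          5, 10, 15, 20, 25
fig3   two     pi          0.1, 0.3, 0.5, 0.7, 0.9
fig4   two     xi          0.1, 0.3, 0.5, 0.7, 0.9
fig5   two     U           1, 3, 5, 7, 9
fig6   three   Tp+Tg       5, 10, 15, 20, 25 (2:1 split)
fig7   three   v           0.1, 0.3, 0.5, 0.7, 0.9
fig8   three   phi         0.1, 0.3, 0.5, 0.7, 0.9
=====  ======  ==========  ===========================

The composite ``Tp+Tg`` sweep allocates the grid total to Tp and Tg by a
configurable ratio, 2:1 by default (the baseline Tp:Tg ratio 12:6).
Convergence of a run is classified against the pure-strategy vertices:
a path counts as converged when it stays within 0.05 (max-norm) of one
vertex over the final 10% of the horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import Trajectory, classify_trajectory
from .errors import ParameterError, UsageError
from .io import baseline_parameters
from .params import ParameterSet
from .state import GameState
from .stochastic import SimulationSettings, simulate_stochastic, vertex_label

__all__ = [
    "SweepSpec",
    "SweepResult",
    "ThresholdScanResult",
    "build_scenario",
    "run_sweep",
    "threshold_scan",
    "SCENARIO_NAMES",
]

logger = logging.getLogger(__name__)

SCENARIO_NAMES = ("fig2", "fig3", "fig4", "fig5", "fig6", "fig7", "fig8")

_PRESETS: dict[str, tuple[str, str, tuple[float, ...]]] = {
    "fig2": ("two", "Tp", (5.0, 10.0, 15.0, 20.0, 25.0)),
    "fig3": ("two", "pi", (0.1, 0.3, 0.5, 0.7, 0.9)),
    "fig4": ("two", "xi", (0.1, 0.3, 0.5, 0.7, 0.9)),
    "fig5": ("two", "U", (1.0, 3.0, 5.0, 7.0, 9.0)),
    "fig6": ("three", "Tp+Tg", (5.0, 10.0, 15.0, 20.0, 25.0)),
    "fig7": ("three", "v", (0.1, 0.3, 0.5, 0.7, 0.9)),
    "fig8": ("three", "phi", (0.1, 0.3, 0.5, 0.7, 0.9)),
}

_ROLE_INDEX = {"LH": 0, "PHI": 1, "GD": 2}


@dataclass(frozen=True)
class SweepSpec:
    """One parameter sweep: a varied symbol, its grid, and run settings."""

    name: str
    model: str
    varied: str
    grid: tuple[float, ...]
    sim: SimulationSettings
    replicates: int = 1
    split_rule: tuple[float, float] | None = None
    overrides: dict = field(default_factory=dict)
    state0: GameState | None = None
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid:
            raise UsageError("sweep grid must be nonempty")
        if (self.varied == "Tp+Tg") != (self.split_rule is not None):
            raise UsageError("split_rule must be present iff the varied symbol is composite")
        if self.replicates < 1:
            raise UsageError("replicates must be >= 1")

    def initial_state(self) -> GameState:
        if self.state0 is not None:
            return self.state0
        return GameState(0.5, 0.5, 0.5) if self.model == "three" else GameState(0.5, 0.5)

    def parameters_at(self, value: float) -> ParameterSet:
        """Baseline parameters with the varied symbol set to ``value``."""
        base = baseline_parameters(self.model)
        changes = dict(self.overrides)
        if self.varied == "Tp+Tg":
            wp, wg = self.split_rule
            total = wp + wg
            changes["Tp"] = value * wp / total
            changes["Tg"] = value * wg / total
        else:
            changes[self.varied] = value
        return base.replace(**changes)


@dataclass(frozen=True)
class SweepResult:
    """Outcome of a sweep: one record per grid value per replicate.

    ``records`` columns: scenario, grid_value, replicate, seed,
    terminal_x, terminal_y, terminal_z, classification, convergence_time,
    fluctuation.
    """

    spec: SweepSpec
    records: pd.DataFrame
    trajectories: dict[tuple[float, int], Trajectory]

    def to_csv(self, path) -> None:
        """Write the per-run records as CSV (17-significant-digit floats)."""
        cols = [
            "scenario", "grid_value", "replicate", "seed",
            "terminal_x", "terminal_y", "terminal_z",
            "classification", "convergence_time",
        ]
        self.records[cols].to_csv(path, index=False, float_format="%.17g")

    def write_summary_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")

    def summary(self) -> dict:
        """Per-grid-value modal classification and terminal means (JSON-able)."""
        per_value = []
        for value, group in self.records.groupby("grid_value", sort=True):
            counts = group["classification"].value_counts()
            per_value.append(
                {
                    "grid_value": float(value),
                    "modal_classification": str(counts.index[0]),
                    "classification_counts": {str(k): int(c) for k, c in counts.items()},
                    "mean_terminal": [
                        float(group[col].mean())
                        for col in ("terminal_x", "terminal_y", "terminal_z")
                        if group[col].notna().all()
                    ],
                }
            )
        return {
            "scenario": self.spec.name,
            "varied": self.spec.varied,
            "replicates": self.spec.replicates,
            "sigma": self.spec.sim.sigma,
            "grid": per_value,
        }


@dataclass(frozen=True)
class ThresholdScanResult:
    """Extreme grid value at which a role's terminal strategy crosses over."""

    value: float | None
    monotone: bool
    terminals: dict[float, float]


def build_scenario(
    name: str,
    *,
    sigma: float | None = None,
    h: float = 0.01,
    steps: int = 10_000,
    replicates: int = 1,
    base_seed: int = 0,
    mode: str = "printed",
    form: str = "replicator",
    split_rule: tuple[float, float] | None = None,
    state0: GameState | None = None,
) -> SweepSpec:
    """Return a preset :class:`SweepSpec` by name (``fig2`` … ``fig8``).

    ``sigma`` defaults to the package's stochastic default 0.05; pass 0
    for the deterministic limit used in threshold scans.
    """
    if name not in _PRESETS:
        raise UsageError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    model, varied, grid = _PRESETS[name]
    _validate_grid(varied, grid)
    sim = SimulationSettings(
        sigma=0.05 if sigma is None else sigma, h=h, steps=steps, mode=mode, form=form
    )
    if varied == "Tp+Tg" and split_rule is None:
        split_rule = (2.0, 1.0)
    if varied != "Tp+Tg":
        split_rule = None
    return SweepSpec(
        name=name,
        model=model,
        varied=varied,
        grid=grid,
        sim=sim,
        replicates=replicates,
        split_rule=split_rule,
        state0=state0,
        base_seed=base_seed,
    )


def _validate_grid(varied: str, grid: tuple[float, ...]) -> None:
    coefficients = {"v", "pi", "eps", "xi", "phi"}
    for value in grid:
        if varied in coefficients:
            if not 0.0 <= value <= 1.0:
                raise ParameterError(
                    f"grid value {value} outside [0, 1] for coefficient {varied}"
                )
        elif not value > 0:
            raise ParameterError(f"grid value {value} must be > 0 for {varied}")


def run_sweep(spec: SweepSpec, *, keep_trajectories: bool = True) -> SweepResult:
    """Simulate every grid value × replicate and classify convergence.

    Replicate r of grid value i uses seed ``base_seed + i*replicates + r``,
    so results are deterministic given the sweep specification.
    """
    state0 = spec.initial_state()
    rows = []
    trajectories: dict[tuple[float, int], Trajectory] = {}
    for i, value in enumerate(spec.grid):
        try:
            params = spec.parameters_at(value)
        except Exception as exc:
            raise type(exc)(f"{spec.name} at {spec.varied}={value}: {exc}") from exc
        logger.info("%s: %s = %g", spec.name, spec.varied, value)
        for r in range(spec.replicates):
            seed = spec.base_seed + i * spec.replicates + r
            traj = simulate_stochastic(state0, params, spec.sim.with_(seed=seed))
            vertex, conv_time, fluct = classify_trajectory(traj)
            terminal = traj.states[-1]
            rows.append(
                {
                    "scenario": spec.name,
                    "grid_value": value,
                    "replicate": r,
                    "seed": seed,
                    "terminal_x": terminal[0],
                    "terminal_y": terminal[1],
                    "terminal_z": terminal[2] if spec.model == "three" else np.nan,
                    "classification": vertex_label(vertex) if vertex else "non-converged",
                    "convergence_time": conv_time if conv_time is not None else np.nan,
                    "fluctuation": fluct if fluct is not None else np.nan,
                }
            )
            if keep_trajectories:
                trajectories[(value, r)] = traj
    return SweepResult(spec=spec, records=pd.DataFrame(rows), trajectories=trajectories)


def threshold_scan(
    spec: SweepSpec,
    role: str,
    target: str,
    *,
    upper: float = 0.9,
    lower: float = 0.1,
) -> ThresholdScanResult:
    """Scan the sweep grid for a crossover in a role's terminal strategy.

    ``target="reaches_one"`` returns the smallest grid value whose
    terminal probability for ``role`` exceeds ``upper``;
    ``target="reaches_zero"`` the largest whose terminal probability is
    below ``lower``.  Uses the first replicate only; σ = 0 is recommended
    so the scan is deterministic.  When the qualifying indicator is not a
    clean one-sided step across the grid the result is flagged
    non-monotone but the extreme value is still reported.
    """
    if target not in ("reaches_one", "reaches_zero"):
        raise UsageError(f"target must be 'reaches_one' or 'reaches_zero', got {target!r}")
    idx = _ROLE_INDEX.get(role)
    if idx is None or (role == "GD" and spec.model != "three"):
        raise UsageError(f"role {role!r} invalid for model {spec.model!r}")

    state0 = spec.initial_state()
    terminals: dict[float, float] = {}
    for i, value in enumerate(sorted(spec.grid)):
        params = spec.parameters_at(value)
        seed = spec.base_seed + i * spec.replicates
        traj = simulate_stochastic(state0, params, spec.sim.with_(seed=seed))
        terminals[value] = float(traj.states[-1, idx])

    values = sorted(terminals)
    if target == "reaches_one":
        qualifying = [v for v in values if terminals[v] > upper]
        extreme = min(qualifying) if qualifying else None
        # monotone: qualifying values form a suffix of the grid
        monotone = qualifying == values[len(values) - len(qualifying):]
    else:
        qualifying = [v for v in values if terminals[v] < lower]
        extreme = max(qualifying) if qualifying else None
        monotone = qualifying == values[: len(qualifying)]
    return ThresholdScanResult(value=extreme, monotone=monotone, terminals=terminals)
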