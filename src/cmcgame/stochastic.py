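"""Stochastic simulation of the game under Gaussian disturbances.

The deterministic replicator system is perturbed by multiplicative white
Gaussian noise, giving a system of nonlinear Itô stochastic differential
equations: each strategy probability p receives a disturbance σ·p·dω,
where ω is standard Brownian motion and σ the disturbance intensity.
The system is discretised by the Forward Euler (Euler–Maruyama) scheme

    p_{n+1} = p_n + drift(p_n)·h + σ·p_n·Δω_n,

with Brownian increments Δω_n ~ N(0, h).  States are clamped to [0, 1]
after every step, so the boundary is absorbing for the noise-free
components (a probability at 0 stays at 0 under multiplicative noise).

By default each role receives an independent Brownian stream; setting
``shared_noise=True`` perturbs all roles with a single common stream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dynamics import FORMS, MODES, Trajectory, _euler_path
from .errors import ParameterError, UsageError
from .params import ParameterSet
from .state import GameState

__all__ = [
    "SimulationSettings",
    "NoisePath",
    "EnsembleSummary",
    "brownian_increments",
    "simulate_stochastic",
    "run_ensemble",
]


@dataclass(frozen=True)
class SimulationSettings:
    """Numerical settings of a simulation run.

    Parameters
    ----------
    sigma : float
        Random-disturbance intensity σ ≥ 0 (0 = deterministic limit).
    h : float
        Step size in model time units.
    steps : int
        Number of Euler steps N; the horizon is T = N·h.
    seed : int or None
        Seed of the Brownian increments; ``None`` draws fresh entropy
        (runs are then not reproducible).
    mode : {"printed", "derived"}
        Drift-factor variant (see :mod:`cmcgame.dynamics`).
    form : {"replicator", "linear"}
        Drift functional form.
    shared_noise : bool
        Perturb every role with one common Brownian stream instead of
        independent streams.
    """

    sigma: float = 0.05
    h: float = 0.01
    steps: int = 10_000
    seed: int | None = None
    mode: str = "printed"
    form: str = "replicator"
    shared_noise: bool = False

    def __post_init__(self) -> None:
        if not self.sigma >= 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma!r}")
        if not self.h > 0:
            raise ParameterError(f"step size h must be > 0, got {self.h!r}")
        if not (isinstance(self.steps, (int, np.integer)) and self.steps >= 1):
            raise ParameterError(f"steps must be a positive integer, got {self.steps!r}")
        if self.mode not in MODES:
            raise UsageError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.form not in FORMS:
            raise UsageError(f"form must be one of {FORMS}, got {self.form!r}")

    @property
    def horizon(self) -> float:
        return self.steps * self.h

    def with_(self, **changes) -> "SimulationSettings":
        return replace(self, **changes)


@dataclass(frozen=True)
class NoisePath:
    """Seeded Brownian increments, shape (steps, roles), each N(0, h)."""

    increments: np.ndarray
    seed: int | None


@dataclass(frozen=True)
class EnsembleSummary:
    """Summary of an ensemble of seeded replicate runs.

    ``convergence_fraction`` maps a vertex label (e.g. ``"1,1,1"``) to the
    fraction of replicates whose terminal state lies within ``vertex_tol``
    (max-norm) of that vertex; fractions sum to at most 1, the remainder
    being non-converged replicates.
    """

    mean_path: np.ndarray
    mean_terminal: np.ndarray
    convergence_fraction: dict[str, float]
    replicates: int
    seeds: list[int]


def brownian_increments(
    steps: int, h: float, seed: int | None, roles: int = 1
) -> NoisePath:
    """Draw ``roles`` independent sequences of Brownian increments.

    Each increment Δω = ω(t+h) − ω(t) is N(0, h); the same seed
    reproduces the same draws bit-for-bit.
    """
    if not h > 0:
        raise ParameterError(f"step size h must be > 0, got {h!r}")
    if not steps >= 1:
        raise ParameterError(f"steps must be >= 1, got {steps!r}")
    rng = np.random.default_rng(seed)
    increments = rng.normal(0.0, np.sqrt(h), size=(int(steps), int(roles)))
    return NoisePath(increments=increments, seed=seed)


def simulate_stochastic(
    state0: GameState, params: ParameterSet, settings: SimulationSettings
) -> Trajectory:
    """Euler–Maruyama path of the stochastic game system.

    With ``sigma == 0`` the run is arithmetically identical to
    :func:`cmcgame.dynamics.integrate_deterministic` under the same
    settings.
    """
    if settings.sigma == 0:
        noise = None
    else:
        roles = 1 if settings.shared_noise else state0.dims
        noise = brownian_increments(
            settings.steps, settings.h, settings.seed, roles=roles
        ).increments
    states = _euler_path(
        state0,
        params,
        h=settings.h,
        steps=settings.steps,
        mode=settings.mode,
        form=settings.form,
        sigma=settings.sigma,
        noise=noise,
        shared_noise=settings.shared_noise,
    )
    times = np.arange(settings.steps + 1, dtype=float) * settings.h
    return Trajectory(times=times, states=states, settings=settings)


def vertex_label(vertex: tuple[int, ...]) -> str:
    return ",".join(str(c) for c in vertex)


def run_ensemble(
    state0: GameState,
    params: ParameterSet,
    settings: SimulationSettings,
    replicates: int,
    base_seed: int,
    *,
    vertex_tol: float = 0.1,
) -> EnsembleSummary:
    """Run ``replicates`` seeded replicates; replicate r uses seed
    ``base_seed + r``.

    The summary is deterministic given ``base_seed``.
    """
    if replicates < 1:
        raise UsageError(f"replicates must be >= 1, got {replicates!r}")
    dims = state0.dims
    seeds = [base_seed + r for r in range(replicates)]
    mean_path = np.zeros((settings.steps + 1, dims))
    counts: dict[str, int] = {}
    for seed in seeds:
        traj = simulate_stochastic(state0, params, settings.with_(seed=seed))
        mean_path += traj.states
        terminal = traj.states[-1]
        for idx in range(2**dims):
            vertex = tuple((idx >> i) & 1 for i in range(dims))
            if np.abs(terminal - np.asarray(vertex, dtype=float)).max() <= vertex_tol:
                label = vertex_label(vertex)
                counts[label] = counts.get(label, 0) + 1
                break
    mean_path /= replicates
    fractions = {label: c / replicates for label, c in sorted(counts.items())}
    return EnsembleSummary(
        mean_path=mean_path,
        mean_terminal=mean_path[-1].copy(),
        convergence_fraction=fractions,
        replicates=replicates,
        seeds=seeds,
    )
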