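"""Replicator dynamics of the construction game.

Each player's strategy probability p evolves according to a replicator
equation dp/dt = p(1−p)·f, where the *drift factor* f is the payoff
advantage of the aggressive strategy over the passive one.  Two variants
of f are provided:

``mode="printed"``
    The drift factors exactly as typeset in the source system of
    equations, with the flattened journal notation parsed as

    * f_x = (ξ−1)(I+U) + yπ(1−ξ)Tp [+ zπ(1−ξ)Tg] + πSl + ξTp
      [+ ξTg + (1−ξ)φF]
    * f_y = πSp + (1+v)R + (ξ−1)Tp + (1−ε)ξU + (1−ε)(1−ξ)Ux + (1−q)vD
      with q = x in the two-subject game and q = z in the tripartite game
    * f_z = A(φ−v+φv)(xy−x−y) + (ξ−1)Tg − (1−φ)F + A

``mode="derived"``
    f = e1 − e2 recomputed from the expected payoffs of
    :mod:`cmcgame.payoffs`.  The printed and derived factors do not agree
    everywhere (see :func:`drift_discrepancy`); the printed variant is the
    default because it is the system the published simulations ran, while
    the derived variant serves as a consistency audit.

Two functional forms of the drift are supported: the standard replicator
product p(1−p)·f (``form="replicator"``, default) and the literal
linear reading p·f of the discretised recursion (``form="linear"``).
Both share vertex attractors and drift-factor signs once states are
clamped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import NumericalError, UsageError
from .params import ParameterSet
from .payoffs import expected_payoffs
from .state import GameState

__all__ = [
    "DriftVector",
    "Trajectory",
    "VertexReport",
    "drift",
    "drift_discrepancy",
    "integrate_deterministic",
    "vertex_stability",
    "classify_trajectory",
]

MODES = ("printed", "derived")
FORMS = ("replicator", "linear")


@dataclass(frozen=True)
class DriftVector:
    """Per-role drift factors and the resulting drifts at one state."""

    factors: tuple[float, ...]
    drifts: tuple[float, ...]
    mode: str
    form: str


@dataclass(frozen=True)
class Trajectory:
    """A fixed-step simulation path.

    ``states`` has shape (steps+1, dims); row 0 is the initial state.
    """

    times: np.ndarray
    states: np.ndarray
    settings: object  # SimulationSettings; kept loose to avoid an import cycle

    @property
    def terminal(self) -> GameState:
        return GameState.from_array(self.states[-1])

    def __len__(self) -> int:
        return self.states.shape[0]


@dataclass(frozen=True)
class VertexReport:
    """Stability classification of one pure-strategy vertex.

    ``classification`` is one of "stable", "unstable", "saddle", or
    ``None`` when some drift factor is exactly zero at the vertex
    (``degenerate`` is then True and no call is made).
    """

    vertex: tuple[int, ...]
    factors: tuple[float, ...]
    classification: str | None
    degenerate: bool


# ---------------------------------------------------------------------------
# drift-factor coefficient tables
#
# Every drift factor (printed or derived) is multilinear in the co-players'
# probabilities, so it is represented as
#     f_i = c0 + cu * s[iu] + cw * s[iw] + cuw * s[iu] * s[iw]
# with iu/iw the indices of the co-players (iw is None in the two-subject
# game).  The printed coefficients are transcribed from the parse above;
# the derived ones are obtained exactly by evaluating e1 − e2 at the
# co-player corners (multilinear interpolation is exact).
# ---------------------------------------------------------------------------

_Coeffs = tuple[float, float, float, float, int | None, int | None]


def _printed_coefficients(p: ParameterSet, model: str) -> list[_Coeffs]:
    base_x = (p.xi - 1) * (p.I + p.U) + p.pi * p.Sl + p.xi * p.Tp
    cy_x = p.pi * (1 - p.xi) * p.Tp
    base_y = (
        p.pi * p.Sp
        + (1 + p.v) * p.R
        + (p.xi - 1) * p.Tp
        + (1 - p.eps) * p.xi * p.U
        + p.v * p.D
    )
    cx_y = (1 - p.eps) * (1 - p.xi) * p.U

    if model == "two":
        return [
            (base_x, cy_x, 0.0, 0.0, 1, None),
            (base_y, cx_y - p.v * p.D, 0.0, 0.0, 0, None),
        ]

    p.require_tripartite()
    f_x: _Coeffs = (
        base_x + p.xi * p.Tg + (1 - p.xi) * p.phi * p.F,
        cy_x,
        p.pi * (1 - p.xi) * p.Tg,
        0.0,
        1,
        2,
    )
    f_y: _Coeffs = (base_y, cx_y, -p.v * p.D, 0.0, 0, 2)
    k = p.A * (p.phi - p.v + p.phi * p.v)
    f_z: _Coeffs = (
        (p.xi - 1) * p.Tg - (1 - p.phi) * p.F + p.A,
        -k,
        -k,
        k,
        0,
        1,
    )
    return [f_x, f_y, f_z]


def _derived_coefficients(p: ParameterSet, model: str) -> list[_Coeffs]:
    def gap(role: str, state: GameState) -> float:
        ep = expected_payoffs(state, p, role)
        return ep.e1 - ep.e2

    if model == "two":
        gx0, gx1 = gap("LH", GameState(0.5, 0.0)), gap("LH", GameState(0.5, 1.0))
        gy0, gy1 = gap("PHI", GameState(0.0, 0.5)), gap("PHI", GameState(1.0, 0.5))
        return [
            (gx0, gx1 - gx0, 0.0, 0.0, 1, None),
            (gy0, gy1 - gy0, 0.0, 0.0, 0, None),
        ]

    p.require_tripartite()
    coeffs: list[_Coeffs] = []
    for role, (iu, iw) in (("LH", (1, 2)), ("PHI", (0, 2)), ("GD", (0, 1))):
        corners = {}
        for u in (0.0, 1.0):
            for w in (0.0, 1.0):
                vals = [0.5, 0.5, 0.5]
                vals[iu], vals[iw] = u, w
                corners[(u, w)] = gap(role, GameState(*vals))
        c0 = corners[(0.0, 0.0)]
        cu = corners[(1.0, 0.0)] - c0
        cw = corners[(0.0, 1.0)] - c0
        cuw = corners[(1.0, 1.0)] - corners[(1.0, 0.0)] - corners[(0.0, 1.0)] + c0
        coeffs.append((c0, cu, cw, cuw, iu, iw))
    return coeffs


def _coefficients(p: ParameterSet, mode: str, model: str) -> list[_Coeffs]:
    if mode not in MODES:
        raise UsageError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "printed":
        return _printed_coefficients(p, model)
    return _derived_coefficients(p, model)


def _eval_factors(coeffs: Sequence[_Coeffs], s: Sequence[float]) -> list[float]:
    out = []
    for c0, cu, cw, cuw, iu, iw in coeffs:
        f = c0
        if iu is not None:
            f += cu * s[iu]
        if iw is not None:
            f += cw * s[iw] + cuw * s[iu] * s[iw]
        out.append(f)
    return out


def drift(
    state: GameState,
    params: ParameterSet,
    mode: str = "printed",
    form: str = "replicator",
) -> DriftVector:
    """Drift factors and drifts at ``state``.

    The model (two-subject or tripartite) is inferred from the state's
    dimensionality.
    """
    if form not in FORMS:
        raise UsageError(f"form must be one of {FORMS}, got {form!r}")
    model = "three" if state.z is not None else "two"
    coeffs = _coefficients(params, mode, model)
    s = state.as_tuple()
    factors = _eval_factors(coeffs, s)
    if form == "replicator":
        drifts = tuple(p * (1 - p) * f for p, f in zip(s, factors))
    else:
        drifts = tuple(p * f for p, f in zip(s, factors))
    return DriftVector(factors=tuple(factors), drifts=drifts, mode=mode, form=form)


def drift_discrepancy(state: GameState, params: ParameterSet) -> tuple[float, ...]:
    """Printed minus derived drift factor, per role.

    In the two-subject game the x-component equals ξTp(1−π) (a constant)
    and the y-component vanishes; in the tripartite game the z-component
    equals (ξ−1)Tg(1−x)(1−y).
    """
    printed = drift(state, params, mode="printed").factors
    derived = drift(state, params, mode="derived").factors
    return tuple(a - b for a, b in zip(printed, derived))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def _euler_path(
    state0: GameState,
    params: ParameterSet,
    *,
    h: float,
    steps: int,
    mode: str,
    form: str,
    sigma: float = 0.0,
    noise: np.ndarray | None = None,
    shared_noise: bool = False,
) -> np.ndarray:
    """Shared fixed-step Euler loop; ``noise`` is (steps, k) of Brownian
    increments or None for the deterministic limit.  Components are
    clamped to [0, 1] after every step."""
    model = "three" if state0.z is not None else "two"
    coeffs = _coefficients(params, mode, model)
    replicator = form == "replicator"
    dims = state0.dims
    out = np.empty((steps + 1, dims), dtype=float)
    s = list(state0.as_tuple())
    out[0] = s
    for n in range(steps):
        factors = _eval_factors(coeffs, s)
        nxt = []
        for i in range(dims):
            p = s[i]
            f = factors[i]
            dr = p * (1.0 - p) * f if replicator else p * f
            val = p + dr * h
            if noise is not None:
                val += sigma * p * noise[n, 0 if shared_noise else i]
            if not math.isfinite(val):
                raise NumericalError(
                    f"non-finite state component {i} at step {n + 1}", step=n + 1
                )
            if val < 0.0:
                val = 0.0
            elif val > 1.0:
                val = 1.0
            nxt.append(val)
        s = nxt
        out[n + 1] = s
    return out


def integrate_deterministic(
    state0: GameState,
    params: ParameterSet,
    settings,
    *,
    mode: str | None = None,
    form: str | None = None,
) -> Trajectory:
    """Fixed-step explicit Euler solution of the deterministic system.

    ``settings`` is a :class:`cmcgame.stochastic.SimulationSettings` with
    ``sigma == 0`` (the scheme is the σ→0 limit of the stochastic
    recursion, so deterministic and stochastic runs share one stepping
    rule).  ``mode``/``form`` override the settings when given.
    """
    if settings.sigma != 0:
        raise UsageError(
            f"integrate_deterministic requires sigma == 0, got {settings.sigma}"
        )
    mode = settings.mode if mode is None else mode
    form = settings.form if form is None else form
    if form not in FORMS:
        raise UsageError(f"form must be one of {FORMS}, got {form!r}")
    states = _euler_path(
        state0, params, h=settings.h, steps=settings.steps, mode=mode, form=form
    )
    times = np.arange(settings.steps + 1, dtype=float) * settings.h
    return Trajectory(times=times, states=states, settings=settings)


# ---------------------------------------------------------------------------
# vertex analysis
# ---------------------------------------------------------------------------


def vertex_stability(
    params: ParameterSet, mode: str = "printed", model: str | None = None
) -> list[VertexReport]:
    """Classify every pure-strategy vertex by drift-factor signs.

    A vertex is *stable* when each role's factor pushes its probability
    back toward the vertex value (factor > 0 at p = 1, factor < 0 at
    p = 0), *unstable* when every role is pushed away, and a *saddle*
    otherwise.  A factor that is exactly zero makes the vertex degenerate
    and no classification is given.
    """
    if model is None:
        model = "three" if params.is_tripartite else "two"
    if model == "three":
        params.require_tripartite()
    coeffs = _coefficients(params, mode, model)
    dims = 3 if model == "three" else 2
    reports = []
    for idx in range(2**dims):
        vertex = tuple((idx >> i) & 1 for i in range(dims))
        factors = _eval_factors(coeffs, [float(c) for c in vertex])
        if any(f == 0.0 for f in factors):
            reports.append(
                VertexReport(vertex, tuple(factors), classification=None, degenerate=True)
            )
            continue
        toward = [(f > 0) == (c == 1) for f, c in zip(factors, vertex)]
        if all(toward):
            label = "stable"
        elif not any(toward):
            label = "unstable"
        else:
            label = "saddle"
        reports.append(
            VertexReport(vertex, tuple(factors), classification=label, degenerate=False)
        )
    return reports


def classify_trajectory(
    trajectory: Trajectory, tol: float = 0.05, tail_frac: float = 0.1
) -> tuple[tuple[int, ...] | None, float | None, float | None]:
    """Classify a trajectory's convergence to a pure-strategy vertex.

    The trajectory converges to a vertex when every state over the final
    ``tail_frac`` of the horizon lies within ``tol`` (max-norm) of it.

    Returns
    -------
    (vertex, convergence_time, fluctuation)
        ``vertex`` is the 0/1 label tuple or ``None`` (non-converged);
        ``convergence_time`` is the first time from which the path stays
        within ``tol`` of the vertex; ``fluctuation`` is the maximum
        deviation from the vertex after that time.
    """
    states = trajectory.states
    n, dims = states.shape
    tail = states[max(0, n - max(1, int(round(tail_frac * n)))):]
    for idx in range(2**dims):
        vertex = tuple((idx >> i) & 1 for i in range(dims))
        v = np.asarray(vertex, dtype=float)
        if np.abs(tail - v).max() <= tol:
            dist = np.abs(states - v).max(axis=1)
            outside = np.nonzero(dist > tol)[0]
            conv_idx = 0 if outside.size == 0 else int(outside[-1]) + 1
            conv_time = float(trajectory.times[conv_idx])
            fluctuation = float(dist[conv_idx:].max())
            return vertex, conv_time, fluctuation
    return None, None, None
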