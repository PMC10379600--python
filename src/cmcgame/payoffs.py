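"""Pure-strategy payoffs and mixed-strategy expected payoffs.

Two-subject payoff matrix (lead hospital LH × primary institutions PHI),
cell = (LH payoff, PHI payoff):

* (efficient, active):      −I−U+(1+π)Sl+(1+π)Tp ,  −Tp+(1+π)Sp+(1+v)R+U−(1−v)D
* (efficient, passive):     −I−U+(1+π)Sl+(1+π)ξTp , −ξTp+Sp+εU−(1−v)D
* (inefficient, active):    −ξ(I+U)+Sl+Tp ,         −Tp+(1+π)Sp+(1+v)R+ξU−(1−v)D
* (inefficient, passive):   −ξ(I+U)+Sl+ξTp ,        −ξTp+Sp+εξU−D

The tripartite game (adding government departments GD with strategies
adequate/prudent support) takes its cell formulas term-by-term from the
players' expectation expressions rather than from the tabulated matrix:
the two presentations disagree in two cells, and only the expectation
expressions are consistent with the replicator construction used for the
dynamics.  Asymmetries in the Tg/F terms (e.g. prudent support grants
ξTg to an efficient lead hospital when the primary institutions are
active but the full Tg when they are passive) are reproduced exactly as
stated, not smoothed out.

Expected payoffs for a mixed state average the pure cells over the
co-players' mixing probabilities; a player's own probability enters only
the population-mean payoff.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UsageError
from .params import ParameterSet
from .state import GameState

__all__ = [
    "StrategyProfile",
    "PayoffOutcome",
    "ExpectedPayoffs",
    "payoff_two",
    "payoff_three",
    "expected_payoffs",
    "ROLES",
]

#: Role identifiers in state order: x ↔ LH, y ↔ PHI, z ↔ GD.
ROLES: tuple[str, ...] = ("LH", "PHI", "GD")

_LH_STRATEGIES = ("efficient", "inefficient")
_PHI_STRATEGIES = ("active", "passive")
_GD_STRATEGIES = ("adequate", "prudent")


@dataclass(frozen=True)
class StrategyProfile:
    """A pure-strategy profile.

    ``gd`` must be ``None`` for the two-subject game and present for the
    tripartite game.
    """

    lh: str
    phi_inst: str
    gd: str | None = None

    def __post_init__(self) -> None:
        if self.lh not in _LH_STRATEGIES:
            raise UsageError(f"lh strategy must be one of {_LH_STRATEGIES}, got {self.lh!r}")
        if self.phi_inst not in _PHI_STRATEGIES:
            raise UsageError(
                f"phi_inst strategy must be one of {_PHI_STRATEGIES}, got {self.phi_inst!r}"
            )
        if self.gd is not None and self.gd not in _GD_STRATEGIES:
            raise UsageError(f"gd strategy must be one of {_GD_STRATEGIES}, got {self.gd!r}")


@dataclass(frozen=True)
class PayoffOutcome:
    """Payoffs of one pure-strategy cell; ``gd`` is None for two subjects."""

    lh: float
    phi_inst: float
    gd: float | None = None


@dataclass(frozen=True)
class ExpectedPayoffs:
    """A role's aggressive (e1) and passive (e2) expected payoffs.

    ``mean`` is the role's population-average payoff p·e1 + (1−p)·e2,
    with p the role's own mixing probability.
    """

    e1: float
    e2: float
    mean: float


def payoff_two(profile: StrategyProfile, params: ParameterSet) -> PayoffOutcome:
    """Evaluate one cell of the two-subject payoff matrix."""
    if profile.gd is not None:
        raise UsageError("two-subject payoff requested with a government strategy set")
    p = params
    efficient = profile.lh == "efficient"
    active = profile.phi_inst == "active"

    if efficient:
        lh = -p.I - p.U + (1 + p.pi) * p.Sl + (1 + p.pi) * (p.Tp if active else p.xi * p.Tp)
    else:
        lh = -p.xi * (p.I + p.U) + p.Sl + (p.Tp if active else p.xi * p.Tp)

    delivered = p.U if efficient else p.xi * p.U
    if active:
        phi = -p.Tp + (1 + p.pi) * p.Sp + (1 + p.v) * p.R + delivered - (1 - p.v) * p.D
    else:
        # passive institutions absorb only a fraction eps of the delivered
        # resources; the attendance loss is softened only when the lead
        # hospital builds efficiently
        loss = (1 - p.v) * p.D if efficient else p.D
        phi = -p.xi * p.Tp + p.Sp + p.eps * delivered - loss
    return PayoffOutcome(lh=lh, phi_inst=phi)


def payoff_three(profile: StrategyProfile, params: ParameterSet) -> PayoffOutcome:
    """Evaluate one cell of the tripartite payoff matrix.

    Cell formulas follow the expectation-expression reading (see module
    docstring).
    """
    if profile.gd is None:
        raise UsageError("tripartite payoff requires a government strategy")
    params.require_tripartite()
    p = params
    efficient = profile.lh == "efficient"
    active = profile.phi_inst == "active"
    adequate = profile.gd == "adequate"

    # --- lead hospital ---------------------------------------------------
    if efficient:
        lh = -p.I - p.U + (1 + p.pi) * p.Sl
        lh += (1 + p.pi) * (p.Tp if active else p.xi * p.Tp)
        if adequate:
            lh += p.Tg + p.F
        else:
            # prudent support: authority is curtailed to xi*Tg only when the
            # primary institutions are active (asymmetry kept as stated)
            lh += (p.xi * p.Tg if active else p.Tg) + p.phi * p.F
    else:
        lh = -p.xi * (p.I + p.U) + p.Sl
        lh += p.Tp if active else p.xi * p.Tp
        if adequate:
            lh += p.Tg + p.xi * p.F
        else:
            lh += (p.xi * p.Tg if active else p.Tg) + p.phi * p.xi * p.F

    # --- primary healthcare institutions ----------------------------------
    delivered = p.U if efficient else p.xi * p.U
    if active:
        phi_pay = -p.Tp + (1 + p.pi) * p.Sp + (1 + p.v) * p.R + delivered - (1 - p.v) * p.D
    else:
        # with government in the game the attendance-loss reduction is tied
        # to adequate support rather than to the lead hospital's strategy
        loss = (1 - p.v) * p.D if adequate else p.D
        phi_pay = -p.xi * p.Tp + p.Sp + p.eps * delivered - loss

    # --- government departments -------------------------------------------
    both_passive = (not efficient) and (not active)
    if adequate:
        gd = -p.Tg - p.F + (p.A if both_passive else (1 + p.v) * p.A)
    else:
        if both_passive:
            gd = -p.Tg - p.phi * p.F
        else:
            gd = -p.xi * p.Tg - p.phi * p.F + p.phi * (1 + p.v) * p.A

    return PayoffOutcome(lh=lh, phi_inst=phi_pay, gd=gd)


def _expected_lh_two(y: float, p: ParameterSet) -> tuple[float, float]:
    tp_mix = p.Tp * (y + (1 - y) * p.xi)
    e1 = -p.I - p.U + (1 + p.pi) * p.Sl + (1 + p.pi) * tp_mix
    e2 = -p.xi * (p.I + p.U) + p.Sl + tp_mix
    return e1, e2


def _expected_phi_two(x: float, p: ParameterSet) -> tuple[float, float]:
    u_mix = p.U * (x + (1 - x) * p.xi)
    e1 = -p.Tp + (1 + p.pi) * p.Sp + (1 + p.v) * p.R + u_mix - (1 - p.v) * p.D
    e2 = -p.xi * p.Tp + p.Sp + p.eps * u_mix - p.D * (x * (1 - p.v) + (1 - x))
    return e1, e2


def _expected_lh_three(y: float, z: float, p: ParameterSet) -> tuple[float, float]:
    tp_mix = p.Tp * (y + (1 - y) * p.xi)
    # prudent-support authority is xi*Tg only against active institutions
    tg_weight = y * z + p.xi * y * (1 - z) + (1 - y)
    f_mix = z + p.phi * (1 - z)
    e1 = -p.I - p.U + (1 + p.pi) * p.Sl + (1 + p.pi) * tp_mix + p.Tg * tg_weight + p.F * f_mix
    e2 = -p.xi * (p.I + p.U) + p.Sl + tp_mix + p.Tg * tg_weight + p.xi * p.F * f_mix
    return e1, e2


def _expected_phi_three(x: float, z: float, p: ParameterSet) -> tuple[float, float]:
    u_mix = p.U * (x + (1 - x) * p.xi)
    e1 = -p.Tp + (1 + p.pi) * p.Sp + (1 + p.v) * p.R + u_mix - (1 - p.v) * p.D
    e2 = -p.xi * p.Tp + p.Sp + p.eps * u_mix - p.D * (z * (1 - p.v) + (1 - z))
    return e1, e2


def _expected_gd_three(x: float, y: float, p: ParameterSet) -> tuple[float, float]:
    s = x + y - x * y  # probability that at least one partner is aggressive
    e1 = -p.Tg - p.F + p.A * (1 + s * p.v)
    e2 = s * (-p.xi * p.Tg + p.phi * (1 + p.v) * p.A) + (1 - s) * (-p.Tg) - p.phi * p.F
    return e1, e2


def expected_payoffs(state: GameState, params: ParameterSet, role: str) -> ExpectedPayoffs:
    """Expected payoffs of ``role`` at a mixed state.

    ``e1`` / ``e2`` are the expectations of the role's aggressive/passive
    payoff over the co-players' mixing probabilities; they do not depend
    on the role's own probability, which enters only ``mean``.

    Parameters
    ----------
    state : GameState
        Two components select the two-subject game, three the tripartite
        game (then ``params`` must carry the government symbols).
    role : {"LH", "PHI", "GD"}
    """
    if role not in ROLES:
        raise UsageError(f"role must be one of {ROLES}, got {role!r}")
    tripartite = state.z is not None
    if role == "GD" and not tripartite:
        raise UsageError("role 'GD' requires a tripartite state (z present)")

    if tripartite:
        params.require_tripartite()
        if role == "LH":
            e1, e2 = _expected_lh_three(state.y, state.z, params)
            own = state.x
        elif role == "PHI":
            e1, e2 = _expected_phi_three(state.x, state.z, params)
            own = state.y
        else:
            e1, e2 = _expected_gd_three(state.x, state.y, params)
            own = state.z
    else:
        if role == "LH":
            e1, e2 = _expected_lh_two(state.y, params)
            own = state.x
        else:
            e1, e2 = _expected_phi_two(state.x, params)
            own = state.y

    return ExpectedPayoffs(e1=e1, e2=e2, mean=own * e1 + (1 - own) * e2)
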