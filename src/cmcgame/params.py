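"""Model parameters of the county-medical-community construction game.

The game is parameterised by the cost/benefit constants of the three
players.  Two-subject symbols (lead hospital LH and primary healthcare
institutions PHI):

======  ==============================================================
symbol  meaning
======  ==============================================================
I       information-integration cost borne by the lead hospital
U       medical resources delivered downward by the lead hospital
Sl      medical service capacity of the lead hospital
Tp      information/management authority ceded by the primary
        institutions to the lead hospital
R       performance allocation received by the primary institutions
Sp      medical service capacity of the primary institutions
D       loss of the primary institutions from decreased attendance
v       policy-effect coefficient of the community's construction
pi      integration coefficient of the information construction
eps     absorption ratio of delivered resources under passive play
xi      intensity factor of information integration
======  ==============================================================

Tripartite extension (government departments GD):

======  ==============================================================
Tg      portion of authority ceded by government departments
F       government construction funds
A       political gains from the community's construction
phi     intensity of government support
======  ==============================================================

Cost/benefit symbols must be strictly positive; the dimensionless
coefficients v, pi, eps, xi, phi lie in [0, 1].  Greek letters are
spelled in ASCII (pi, eps, xi, phi) so that configuration files
round-trip safely.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, ParameterError

__all__ = [
    "ParameterSet",
    "validate_parameters",
    "TWO_SUBJECT_KEYS",
    "TRIPARTITE_KEYS",
]

#: Symbols required for the two-subject game, in canonical spelling.
TWO_SUBJECT_KEYS: tuple[str, ...] = (
    "I", "U", "Sl", "Tp", "R", "Sp", "D", "v", "pi", "eps", "xi",
)

#: Additional symbols required for the tripartite game.
TRIPARTITE_EXTRA_KEYS: tuple[str, ...] = ("Tg", "F", "A", "phi")

#: All symbols of the tripartite game.
TRIPARTITE_KEYS: tuple[str, ...] = TWO_SUBJECT_KEYS + TRIPARTITE_EXTRA_KEYS

_POSITIVE = frozenset({"I", "U", "Sl", "Tp", "R", "Sp", "D", "Tg", "F", "A"})
_UNIT_INTERVAL = frozenset({"v", "pi", "eps", "xi", "phi"})

# case-insensitive lookup of canonical spellings
_CANONICAL = {key.lower(): key for key in TRIPARTITE_KEYS}


@dataclass(frozen=True)
class ParameterSet:
    """Validated constants of the game.

    The four tripartite symbols are ``None`` for a pure two-subject
    parameterisation; two-subject operations ignore them when present.
    """

    I: float
    U: float
    Sl: float
    Tp: float
    R: float
    Sp: float
    D: float
    v: float
    pi: float
    eps: float
    xi: float
    Tg: float | None = None
    F: float | None = None
    A: float | None = None
    phi: float | None = None

    @property
    def is_tripartite(self) -> bool:
        """True when all four government symbols are present."""
        return None not in (self.Tg, self.F, self.A, self.phi)

    def require_tripartite(self) -> None:
        missing = [
            name for name in TRIPARTITE_EXTRA_KEYS if getattr(self, name) is None
        ]
        if missing:
            raise ConfigurationError(
                "tripartite operation requires symbols "
                + ", ".join(missing)
                + " to be set"
            )

    def to_dict(self, *, drop_none: bool = True) -> dict[str, float]:
        """Canonical symbol → value mapping (insertion order = Table order)."""
        out: dict[str, float] = {}
        for f in fields(self):
            value = getattr(self, f.name)
            if value is None and drop_none:
                continue
            out[f.name] = value
        return out

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a revalidated copy with ``changes`` applied."""
        new = replace(self, **changes)
        _check_ranges(new)
        return new


def _check_ranges(params: ParameterSet) -> None:
    for f in fields(params):
        name, value = f.name, getattr(params, f.name)
        if value is None:
            continue
        if not np.isfinite(value):
            raise ParameterError(f"parameter {name} must be finite, got {value!r}")
        if name in _POSITIVE and not value > 0:
            raise ParameterError(f"parameter {name} must satisfy {name} > 0, got {value!r}")
        if name in _UNIT_INTERVAL and not 0.0 <= value <= 1.0:
            raise ParameterError(
                f"parameter {name} must satisfy 0 <= {name} <= 1, got {value!r}"
            )


def validate_parameters(raw: Mapping[str, float], model: str = "two") -> ParameterSet:
    """Build a :class:`ParameterSet` from a symbol → value mapping.

    Parameters
    ----------
    raw : mapping
        Keys are the parameter symbols (matched case-insensitively against
        the canonical spellings ``I, U, Sl, Tp, R, Sp, D, v, pi, eps, xi,
        Tg, F, A, phi``).  Unknown keys are rejected.
    model : {"two", "three"}
        Which game the set must be complete for.  ``"three"`` additionally
        requires Tg, F, A and phi.

    Raises
    ------
    ConfigurationError
        On an unknown or missing symbol.
    ParameterError
        On a value outside its admissible range.
    """
    if model not in ("two", "three"):
        raise ConfigurationError(f"model must be 'two' or 'three', got {model!r}")

    values: dict[str, float] = {}
    for key, value in raw.items():
        canon = _CANONICAL.get(str(key).lower())
        if canon is None:
            raise ConfigurationError(f"unknown parameter key {key!r}")
        if canon in values:
            raise ConfigurationError(f"duplicate parameter key {key!r}")
        try:
            values[canon] = float(value)
        except (TypeError, ValueError) as exc:
            raise ParameterError(f"parameter {canon} is not a number: {value!r}") from exc

    required = TRIPARTITE_KEYS if model == "three" else TWO_SUBJECT_KEYS
    missing = [key for key in required if key not in values]
    if missing:
        raise ConfigurationError(
            f"missing parameter symbol(s) for model={model!r}: " + ", ".join(missing)
        )

    params = ParameterSet(**values)
    _check_ranges(params)
    return params
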