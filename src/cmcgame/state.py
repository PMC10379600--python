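"""Strategy-probability state of the evolutionary game.

The state of the two-subject game is a point (x, y) in the unit square:
x is the probability that the lead hospital builds the medical community
efficiently, y the probability that the primary healthcare institutions
participate actively.  The tripartite game adds z, the probability that
government departments give adequate support, making the state space the
unit cube.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["GameState"]


@dataclass(frozen=True)
class GameState:
    """A point on the strategy simplex product [0, 1]^2 or [0, 1]^3.

    Parameters
    ----------
    x : float
        Probability of efficient construction by the lead hospital.
    y : float
        Probability of active participation by the primary institutions.
    z : float, optional
        Probability of adequate government support.  ``None`` selects the
        two-subject game.
    """

    x: float
    y: float
    z: float | None = None

    def __post_init__(self) -> None:
        for name, value in (("x", self.x), ("y", self.y), ("z", self.z)):
            if value is None:
                continue
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise DomainError(
                    f"strategy probability {name}={value!r} outside [0, 1]"
                )

    @property
    def dims(self) -> int:
        """Number of players: 2 for the two-subject game, 3 with government."""
        return 2 if self.z is None else 3

    def as_tuple(self) -> tuple[float, ...]:
        if self.z is None:
            return (self.x, self.y)
        return (self.x, self.y, self.z)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.as_tuple(), dtype=float)

    @classmethod
    def from_array(cls, arr) -> "GameState":
        vals = [float(v) for v in arr]
        if len(vals) == 2:
            return cls(vals[0], vals[1])
        if len(vals) == 3:
            return cls(vals[0], vals[1], vals[2])
        raise DomainError(f"state must have 2 or 3 components, got {len(vals)}")
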