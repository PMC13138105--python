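"""Arterial input function model.

The simulator's stand-in for a metabolite-corrected plasma curve is the
tri-exponential bolus model of Feng type,

    Cp(t) = (A1*(t - t0) - A2 - A3) * exp(-l1*(t - t0))
          + A2 * exp(-l2*(t - t0)) + A3 * exp(-l3*(t - t0)),   t > t0,

with Cp = 0 for t <= t0. The first term gives a sharp linear-rise bolus
peak; the slower exponentials form the tail. Continuity at t0 holds by
construction (Cp(t0) = -A2 - A3 + A2 + A3 = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["FengInput", "default_input"]


@dataclass(frozen=True)
class FengInput:
    """Tri-exponential plasma input. Rates in 1/min, amplitudes kBq/mL (A1 kBq/mL/min)."""

    A1: float = 850.0
    A2: float = 22.0
    A3: float = 21.0
    l1: float = 4.1
    l2: float = 0.12
    l3: float = 0.01
    t0: float = 0.5

    def __post_init__(self) -> None:
        if not (self.l1 > self.l2 > self.l3 > 0):
            raise ValueError(
                f"decay rates must satisfy l1 > l2 > l3 > 0 (got {self.l1}, {self.l2}, {self.l3})"
            )
        if self.t0 < 0:
            raise ValueError("t0 must be non-negative")

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tau = t - self.t0
        with np.errstate(over="ignore"):
            cp = (
                (self.A1 * tau - self.A2 - self.A3) * np.exp(-self.l1 * tau)
                + self.A2 * np.exp(-self.l2 * tau)
                + self.A3 * np.exp(-self.l3 * tau)
            )
        return np.where(tau > 0, cp, 0.0)

    def terms(self) -> list[tuple[float, float, float]]:
        """Decompose as sum of (c + d*tau) * exp(-lam*tau) terms for tau > 0."""
        return [
            (-(self.A2 + self.A3), self.A1, self.l1),
            (self.A2, 0.0, self.l2),
            (self.A3, 0.0, self.l3),
        ]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FengInput":
        return cls(**d)


def default_input() -> FengInput:
    """Default bolus: peak ~75 kBq/mL around 0.75 min, slow bi-exponential tail."""
    return FengInput()
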