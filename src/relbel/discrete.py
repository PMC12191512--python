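"""Probability mass functions on finite supports.

`DiscreteDistribution` is the workhorse container for exact discrete
computation: two-point models, finite parameter grids, and discretized
continuous posteriors all live here.  Support points may be arbitrary
hashable labels (``"a"``, ``"b"``) or real grid points; masses must be
nonnegative and sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["DiscreteDistribution"]

_MASS_TOL = 1e-12


@dataclass(frozen=True)
class DiscreteDistribution:
    """Probability mass on a finite, ordered support.

    Parameters
    ----------
    support : sequence
        Distinct labels or real grid points, in a fixed order.
    mass : sequence of float
        Nonnegative weights, one per support point, summing to 1
        within ``1e-12``.
    """

    support: tuple = field()
    mass: np.ndarray = field()

    def __init__(self, support: Sequence, mass: Iterable[float]):
        support = tuple(support)
        mass = np.asarray(list(mass), dtype=float)
        if len(support) != mass.size:
            raise ValueError(
                f"support ({len(support)}) and mass ({mass.size}) lengths differ"
            )
        if len(set(support)) != len(support):
            raise ValueError("support points must be distinct")
        if mass.size == 0:
            raise ValueError("empty support")
        if np.any(mass < 0):
            raise ValueError("masses must be nonnegative")
        total = mass.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"masses sum to {total!r}, not 1")
        # exact renormalization of float dust keeps downstream sums honest
        if abs(total - 1.0) > _MASS_TOL:
            mass = mass / total
        mass.flags.writeable = False
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "mass", mass)

    def __len__(self) -> int:
        return len(self.support)

    def index(self, point) -> int:
        """Position of ``point`` in the support (raises if absent)."""
        try:
            return self.support.index(point)
        except ValueError:
            raise KeyError(f"{point!r} not in support") from None

    def prob(self, point) -> float:
        """Mass at a single support point."""
        return float(self.mass[self.index(point)])

    def prob_of(self, points: Iterable) -> float:
        """Total mass of a subset of the support."""
        idx = [self.index(p) for p in points]
        return float(self.mass[idx].sum())

    def same_support(self, other: "DiscreteDistribution") -> bool:
        return self.support == other.support

    # -- serialization (two-column CSV: support,mass) ------------------

    def to_csv(self, path) -> None:
        pd.DataFrame({"support": list(self.support), "mass": self.mass}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "DiscreteDistribution":
        df = pd.read_csv(path)
        if list(df.columns) != ["support", "mass"]:
            raise ValueError("expected columns 'support,mass'")
        return cls(df["support"].tolist(), df["mass"].to_numpy())

    @classmethod
    def uniform(cls, support: Sequence) -> "DiscreteDistribution":
        k = len(tuple(support))
        return cls(support, np.full(k, 1.0 / k))

    @classmethod
    def from_weights(cls, support: Sequence, weights) -> "DiscreteDistribution":
        """Normalize nonnegative weights into a distribution."""
        w = np.asarray(list(weights), dtype=float)
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("weights must have a positive, finite sum")
        return cls(support, w / total)
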