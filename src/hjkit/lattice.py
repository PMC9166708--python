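"""Idealized cavity-volume models and unit-cell group statistics.

Self-assembled DNA crystal lattices leave solvent channels whose size is
modeled here as ideal solid prisms (no van der Waals subtraction of the
DNA walls): a triangular prism for the tightly packed trigonal lattices
and a hexagonal prism for the open ones, with the prism height taken from
the crystal c-axis.  Group statistics over unit-cell constants use the
sample standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .structure_io import LatticeParams

__all__ = [
    "CavitySpec",
    "CellGroup",
    "cavity_volume",
    "volume_ratio",
    "cell_statistics",
]


@dataclass(frozen=True)
class CavitySpec:
    """A prism cavity model: kind ('triangular'|'hexagonal'), edge and height in nm."""

    kind: str
    edge: float
    height: float

    def __post_init__(self) -> None:
        if self.kind not in ("triangular", "hexagonal"):
            raise ValueError("kind must be 'triangular' or 'hexagonal'")
        if self.edge <= 0 or self.height <= 0:
            raise ValueError("edge and height must be positive")


def cavity_volume(c: CavitySpec) -> float:
    """Prism volume in nm³.

    Triangular: (√3/4)·edge²·height.  Hexagonal: (3√3/2)·edge²·height.
    """
    if c.kind == "triangular":
        return math.sqrt(3.0) / 4.0 * c.edge**2 * c.height
    return 3.0 * math.sqrt(3.0) / 2.0 * c.edge**2 * c.height


def volume_ratio(a: CavitySpec, b: CavitySpec) -> float:
    """Fold change in cavity volume, volume(a) / volume(b)."""
    return cavity_volume(a) / cavity_volume(b)


@dataclass(frozen=True)
class CellGroup:
    """A set of unit cells sharing a symmetry/motif label."""

    label: str
    members: tuple[LatticeParams, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a cell group must be non-empty")


def cell_statistics(g: CellGroup) -> pd.DataFrame:
    """Per-axis mean, sample σ (n ≥ 2), min and max over the group's cells.

    Returns a table indexed by axis/angle name with columns
    ``mean``, ``sigma`` (NaN for a single member), ``min``, ``max``, ``n``.
    Invariant under permutation of the members.
    """
    df = pd.DataFrame(
        {
            "a": [m.a for m in g.members],
            "b": [m.b for m in g.members],
            "c": [m.c for m in g.members],
            "alpha": [m.alpha for m in g.members],
            "beta": [m.beta for m in g.members],
            "gamma": [m.gamma for m in g.members],
        }
    )
    out = pd.DataFrame(
        {
            "mean": df.mean(),
            "sigma": df.std(ddof=1),  # NaN when n == 1, reported as absent
            "min": df.min(),
            "max": df.max(),
            "n": len(df),
        }
    )
    out.index.name = "axis"
    return out
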