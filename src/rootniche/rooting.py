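"""Functional rooting profiles.

A rooting profile describes how a plant strategy distributes its
water-absorbing root mass over depth.  Profiles are generated from a Beta
distribution rescaled to the 0-70 cm soil column; the per-layer root-mass
fractions R_{k,i} are differences of the Beta CDF at the layer boundaries,
so they are deterministic and sum to exactly 1.

Four standard strategies span the shallow-to-deep axis:

========  ========  ========  ==============================================
name      shape1    shape2    character
========  ========  ========  ==============================================
super-shallow  0.1    1       >75% of root mass in the top 5 cm (grass-like)
shallow        0.5    5       mass concentrated in the upper layers
intermediate   0.5    1       top-heavy but reaching depth
deep           1      1       uniform over the whole column
========  ========  ========  ==============================================

None of these are fits to field data; they are contrasting shapes with the
same maximum rooting depth, which is the point: competition here is about
the *shape* of the profile, not about who roots deepest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .grid import DEFAULT_GRID, LayerGrid

__all__ = [
    "RootingProfile",
    "STANDARD_SHAPES",
    "discretize",
    "standard_profiles",
    "profile_to_frame",
    "profile_from_frame",
]

#: (shape1, shape2) of the four standard strategies, shallowest first.
STANDARD_SHAPES: dict[str, tuple[float, float]] = {
    "super-shallow": (0.1, 1.0),
    "shallow": (0.5, 5.0),
    "intermediate": (0.5, 1.0),
    "deep": (1.0, 1.0),
}


@dataclass(frozen=True)
class RootingProfile:
    """A named depth distribution of functional root mass.

    ``fractions[i]`` is the share of total root mass in soil layer i; the
    shares are non-negative and sum to 1.
    """

    name: str
    shape1: float
    shape2: float
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < 0):
            raise ValueError(f"profile {self.name!r} has negative fractions")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"profile {self.name!r} fractions sum to {f.sum()}, not 1"
            )

    @property
    def fractions_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    def cumulative_above(self, depth_mm: float, grid: LayerGrid = DEFAULT_GRID) -> float:
        """Root-mass fraction above ``depth_mm`` (Beta CDF at depth/max)."""
        return float(beta_dist.cdf(depth_mm / grid.max_depth_mm, self.shape1, self.shape2))


def discretize(
    shape1: float,
    shape2: float,
    grid: LayerGrid = DEFAULT_GRID,
    name: str | None = None,
) -> RootingProfile:
    """Discretize Beta(shape1, shape2) over the layer grid.

    fractions[i] = F(b_{i+1}/z_max) - F(b_i/z_max), with F the Beta CDF and
    z_max the deepest boundary (700 mm by default).
    """
    if shape1 <= 0 or shape2 <= 0:
        raise ValueError("Beta shape parameters must be positive")
    b = np.asarray(grid.boundaries_mm, dtype=float) / grid.max_depth_mm
    cdf = beta_dist.cdf(b, shape1, shape2)
    frac = np.diff(cdf)
    # CDF spans [0, 1] over the column, so the fractions sum to 1 exactly
    return RootingProfile(
        name=name if name is not None else f"beta({shape1:g},{shape2:g})",
        shape1=float(shape1),
        shape2=float(shape2),
        fractions=tuple(frac),
    )


def standard_profiles(grid: LayerGrid = DEFAULT_GRID) -> list[RootingProfile]:
    """The four standard strategies, ordered shallowest to deepest."""
    return [
        discretize(s1, s2, grid=grid, name=name)
        for name, (s1, s2) in STANDARD_SHAPES.items()
    ]


def profile_to_frame(
    profile: RootingProfile, grid: LayerGrid = DEFAULT_GRID
) -> pd.DataFrame:
    """Tabulate a profile as (layer_top_mm, layer_bottom_mm, fraction)."""
    b = np.asarray(grid.boundaries_mm, dtype=float)
    return pd.DataFrame(
        {
            "layer_top_mm": b[:-1],
            "layer_bottom_mm": b[1:],
            "fraction": profile.fractions_array,
        }
    )


def profile_from_frame(frame: pd.DataFrame, name: str = "custom") -> RootingProfile:
    """Build a profile from a (layer_top_mm, layer_bottom_mm, fraction) table.

    Fractions are renormalized to sum to 1 so empirical tables with rounding
    are accepted; shape parameters are recorded as NaN.
    """
    frac = np.asarray(frame["fraction"], dtype=float)
    if np.any(frac < 0):
        raise ValueError("fractions must be non-negative")
    total = frac.sum()
    if total <= 0:
        raise ValueError("fractions must have a positive sum")
    return RootingProfile(
        name=name, shape1=float("nan"), shape2=float("nan"),
        fractions=tuple(frac / total),
    )
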