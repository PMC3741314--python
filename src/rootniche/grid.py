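"""Vertical discretization of the soil column.

The column spans the maximum rooting depth (700 mm by default) and is split
into eight layers: 0-5 cm, 5-10 cm, then 10-cm increments down to 70 cm.
All depths are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_BOUNDARIES_MM = (0.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0)


@dataclass(frozen=True)
class LayerGrid:
    """Layer boundaries (mm from the surface, increasing, starting at 0)."""

    boundaries_mm: tuple[float, ...] = DEFAULT_BOUNDARIES_MM

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries_mm, dtype=float)
        if b.size < 2:
            raise ValueError("grid needs at least one layer (two boundaries)")
        if b[0] != 0.0:
            raise ValueError("first boundary must be 0 (the soil surface)")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_layers(self) -> int:
        return len(self.boundaries_mm) - 1

    @property
    def thicknesses_mm(self) -> np.ndarray:
        """Layer thicknesses D_i in mm."""
        return np.diff(np.asarray(self.boundaries_mm, dtype=float))

    @property
    def max_depth_mm(self) -> float:
        return float(self.boundaries_mm[-1])

    def capacities_mm(self, porosity: float) -> np.ndarray:
        """Water storage capacity n*D_i of each layer (mm) at saturation."""
        return porosity * self.thicknesses_mm


DEFAULT_GRID = LayerGrid()
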