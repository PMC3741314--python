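"""Layered bucket model of soil moisture.

Each layer i holds water as a relative saturation S_i in [0, 1]; actual
storage is S_i * n * D_i mm, with n the porosity and D_i the layer
thickness.  Water enters the top layer as rain, cascades downward when a
layer saturates (the whole column full -> surface runoff), evaporates from
the top 5 cm, is withdrawn by roots, and drains from layer to layer by a
texture-dependent leakage law once a layer exceeds field capacity; leakage
out of the deepest layer is lost as deep drainage.

The daily step uses operator splitting over sub-daily increments
(default 24) because saturated conductivities of ~10^3 mm/d against layer
capacities of ~20-45 mm make a plain daily Euler step unstable.  A
`FluxLedger` records every daily flux so mass balance can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .grid import DEFAULT_GRID, LayerGrid

__all__ = [
    "SoilTexture",
    "COARSE",
    "FINE",
    "TEXTURES",
    "FluxLedger",
    "initial_state",
    "leakage_rate",
    "evaporation_rate",
    "step_day",
]


@dataclass(frozen=True)
class SoilTexture:
    """Texture-dependent hydraulic and demand parameters.

    S_f : field capacity (saturation above which drainage occurs)
    S_w : wilting point (no uptake or evaporation below)
    S_star : stress onset; uptake/evaporation ramp linearly S_w..S_star
    K_s : saturated conductivity, mm/d
    tau : exponent of the leakage law
    n : porosity
    E_max : maximum evaporative demand, mm/d
    T_atm : maximum atmospheric transpiration demand, mm/d (a joint cap
        over all layers and all competing profiles)
    """

    name: str
    S_f: float
    S_w: float
    S_star: float
    K_s: float
    tau: float
    n: float
    E_max: float
    T_atm: float

    def __post_init__(self) -> None:
        if not (0.0 < self.S_w < self.S_star < self.S_f < 1.0):
            raise ValueError(
                f"need 0 < S_w < S_star < S_f < 1, got "
                f"S_w={self.S_w}, S_star={self.S_star}, S_f={self.S_f}"
            )
        for attr in ("K_s", "tau", "n", "E_max", "T_atm"):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{attr} must be positive")

    def scaled(self, name: str = "scaled", **multipliers: float) -> "SoilTexture":
        """Return a copy with named fields multiplied (for sensitivity runs)."""
        fields = {
            f: getattr(self, f)
            for f in ("S_f", "S_w", "S_star", "K_s", "tau", "n", "E_max", "T_atm")
        }
        for key, m in multipliers.items():
            if key not in fields:
                raise KeyError(f"unknown texture field {key!r}")
            fields[key] *= m
        return SoilTexture(name=name, **fields)


COARSE = SoilTexture(
    name="coarse", S_f=0.30, S_w=0.05, S_star=0.10,
    K_s=1100.0, tau=4.5, n=0.42, E_max=1.5, T_atm=3.25,
)
FINE = SoilTexture(
    name="fine", S_f=0.50, S_w=0.10, S_star=0.20,
    K_s=300.0, tau=6.0, n=0.45, E_max=1.5, T_atm=3.25,
)
TEXTURES = {"coarse": COARSE, "fine": FINE}

#: leakage forms accepted by step_day / the engine:
#: "gated-power" (default): K_s * S**tau once S exceeds field capacity;
#: "normalized": K_s * ((S-S_f)/(1-S_f))**tau above field capacity;
#: "power": K_s * S**tau at any saturation (no field-capacity gate).
LEAK_FORMS = {"gated-power": 0, "normalized": 1, "power": 2}


@dataclass(frozen=True)
class FluxLedger:
    """One day's water accounting, all in mm."""

    rain_in: float
    surface_runoff: float
    evaporation: float
    transpiration: tuple[float, ...]  # per profile
    deep_drainage: float
    storage_change: float

    @property
    def transpiration_total(self) -> float:
        return float(sum(self.transpiration))

    def residual(self) -> float:
        """rain - runoff - evap - sum(T) - drainage - storage_change."""
        return (
            self.rain_in
            - self.surface_runoff
            - self.evaporation
            - self.transpiration_total
            - self.deep_drainage
            - self.storage_change
        )

    def closes(self, tol: float = 1e-6) -> bool:
        return abs(self.residual()) <= tol


def initial_state(
    texture: SoilTexture, grid: LayerGrid = DEFAULT_GRID, value: float | None = None
) -> np.ndarray:
    """Per-layer saturations; defaults to field capacity everywhere."""
    s = texture.S_f if value is None else value
    if not 0.0 <= s <= 1.0:
        raise ValueError("saturation must lie in [0, 1]")
    return np.full(grid.n_layers, s, dtype=float)


def leakage_rate(
    S_i: float | np.ndarray, texture: SoilTexture, form: str = "gated-power"
) -> float | np.ndarray:
    """Drainage rate out of a layer (mm/d) as a function of its saturation.

    Default ("gated-power"): no drainage at or below field capacity, then
    the soil-conductivity power law K_s * S**tau, reaching K_s at
    saturation.  Alternates for sensitivity checks: "normalized"
    (K_s * ((S - S_f)/(1 - S_f))**tau above S_f) and "power" (the ungated
    law, which drains below field capacity).
    """
    code = LEAK_FORMS[form]
    scalar = np.isscalar(S_i)
    s = np.atleast_1d(np.asarray(S_i, dtype=float))
    out = np.array(
        [_kernel._leakage_rate(v, texture.K_s, texture.tau, texture.S_f, code) for v in s]
    )
    return float(out[0]) if scalar else out


def evaporation_rate(S_1: float, texture: SoilTexture) -> float:
    """Bare-soil evaporation from the top layer (mm/d).

    E_max above the stress-onset saturation, linear down to 0 at the
    wilting point — the same moisture limitation shape as transpiration.
    """
    return float(
        _kernel._evaporation_rate(S_1, texture.E_max, texture.S_star, texture.S_w)
    )


def step_day(
    state: np.ndarray,
    rain_today: float,
    uptake_demands: np.ndarray,
    texture: SoilTexture,
    grid: LayerGrid = DEFAULT_GRID,
    n_substeps: int = 24,
    leak_form: str = "gated-power",
) -> tuple[np.ndarray, FluxLedger]:
    """Advance the soil column one day.

    ``uptake_demands`` is an (n_layers, K) array of stress-adjusted,
    atmosphere-capped demands in mm/d (one column per competing profile);
    withdrawals are floored at the water actually present and the realized
    (not demanded) per-profile transpiration is reported in the ledger.
    Returns a new state; the input state is not modified.
    """
    if rain_today < 0:
        raise ValueError("rain_today must be non-negative")
    demands = np.asarray(uptake_demands, dtype=float)
    if demands.ndim == 1:
        demands = demands[:, None]
    if demands.shape[0] != grid.n_layers:
        raise ValueError(
            f"demands have {demands.shape[0]} layers, grid has {grid.n_layers}"
        )
    if np.any(demands < 0):
        raise ValueError("uptake demands must be non-negative")
    if n_substeps < 1:
        raise ValueError("n_substeps must be >= 1")

    S = np.asarray(state, dtype=float).copy()
    caps = grid.capacities_mm(texture.n)
    transp = np.empty(demands.shape[1])
    fluxes = np.empty(_kernel.N_FLUX)
    _kernel._step_day_arrays(
        S, float(rain_today), np.ascontiguousarray(demands), caps,
        texture.S_f, texture.S_w, texture.S_star,
        texture.K_s, texture.tau, texture.E_max,
        n_substeps, LEAK_FORMS[leak_form],
        transp, fluxes,
    )
    ledger = FluxLedger(
        rain_in=float(fluxes[0]),
        surface_runoff=float(fluxes[1]),
        evaporation=float(fluxes[2]),
        transpiration=tuple(float(t) for t in transp),
        deep_drainage=float(fluxes[3]),
        storage_change=float(fluxes[4]),
    )
    return S, ledger
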