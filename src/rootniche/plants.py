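"""Plant water uptake and biomass dynamics.

Uptake follows a pipe model: roots in each soil layer connect independently
to the atmosphere, so the demand of profile k from layer i depends only on
the root biomass it holds there, r = B_k * RMR * R_{k,i}, and on that
layer's moisture.  Demand saturates in root biomass with Michaelis-Menten
kinetics,

    T_max(i,k) = T_atm * r / (B_hsat + r),

is downregulated linearly between the stress-onset saturation S* and the
wilting point S_w, and the whole matrix is rescaled so the grand total
never exceeds the atmospheric demand T_atm — a single cap shared by all
layers and all competing profiles, which is what couples the strategies.

Biomass then integrates water gains against maintenance costs:

    dB_k/dt = WUE_k * T_k - RESP * B_k,

with T_k the realized (water-limited) transpiration summed over layers;
1 mm of transpired water is 1 kg/m2.  Constant forcing gives the
equilibrium B* = WUE * T / RESP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .rooting import RootingProfile
from .soil import SoilTexture

__all__ = [
    "PlantParams",
    "max_layer_transpiration",
    "stress_factor",
    "demand_matrix",
    "rescale_to_atm",
    "biomass_step",
]


@dataclass(frozen=True)
class PlantParams:
    """Whole-plant parameters shared across rooting profiles.

    RMR : root mass ratio, root fraction of total biomass
    RESP : mass-specific respiration, g per g m2 per day
    B_hsat : root biomass (g/m2) at which layer demand is half of T_atm
    extinction_threshold : final biomass (g/m2) below which a profile is
        classified extinct at readout
    """

    RMR: float = 0.5
    RESP: float = 0.001
    B_hsat: float = 800.0
    extinction_threshold: float = 1.0

    def __post_init__(self) -> None:
        for attr in ("RMR", "RESP", "B_hsat", "extinction_threshold"):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{attr} must be positive")


DEFAULT_WUE = 4.0  # g biomass per m2 per kg (= per mm) water transpired

#: uptake variants: "mm" saturates demand in per-layer root biomass r with
#: half-saturation B_hsat; "linear" is its literal B_hsat -> 0 limit (T_atm
#: wherever r > 0); "prop" makes demand proportional to r (T_atm * r/B_hsat,
#: relying on the joint atmospheric cap).
UPTAKE_VARIANTS = {"mm": 0, "linear": 1, "prop": 2}


def max_layer_transpiration(
    B_k: float, R_ki: float, params: PlantParams, T_atm: float,
    variant: str = "mm",
) -> float:
    """Moisture-unlimited demand of one profile from one layer (mm/d)."""
    if B_k < 0 or R_ki < 0 or T_atm < 0:
        raise ValueError("inputs must be non-negative")
    code = UPTAKE_VARIANTS[variant]
    r = B_k * params.RMR * R_ki
    if r <= 0:
        return 0.0
    if code == 1:
        return T_atm
    if code == 2:
        return T_atm * r / params.B_hsat
    return T_atm * r / (params.B_hsat + r)


def stress_factor(S_i: float, texture: SoilTexture) -> float:
    """Moisture downregulation: 1 above S*, 0 at/below S_w, linear between."""
    return float(_kernel._stress_factor(S_i, texture.S_star, texture.S_w))


def demand_matrix(
    biomass: np.ndarray,
    profiles: list[RootingProfile],
    soil_state: np.ndarray,
    texture: SoilTexture,
    params: PlantParams,
    variant: str = "mm",
) -> np.ndarray:
    """Stress-adjusted demands, (n_layers, K) in mm/d, before the joint cap.

    entry (i, k) = T_max(B_k, R_{k,i}) * stress(S_i).
    """
    B = np.asarray(biomass, dtype=float)
    if len(profiles) != B.size:
        raise ValueError("one biomass per profile required")
    S = np.asarray(soil_state, dtype=float)
    R = np.ascontiguousarray([p.fractions_array for p in profiles])
    if R.shape[1] != S.size:
        raise ValueError("profiles and soil state disagree on layer count")
    out = np.empty((S.size, B.size))
    _kernel._demand_matrix(
        S, B, R, params.RMR, params.B_hsat, texture.T_atm,
        texture.S_star, texture.S_w, UPTAKE_VARIANTS[variant], out,
    )
    return out


def rescale_to_atm(demands: np.ndarray, T_atm: float) -> np.ndarray:
    """Cap the grand total at T_atm by proportional rescaling.

    The cap is joint across all layers *and* all profiles; relative shares
    are preserved.  Returns a new array.
    """
    d = np.asarray(demands, dtype=float)
    if np.any(d < 0):
        raise ValueError("demands must be non-negative")
    out = np.ascontiguousarray(d.copy())
    _kernel._rescale_to_atm(out, T_atm)
    return out


def linear_uptake_variant(
    biomass: np.ndarray,
    profiles: list[RootingProfile],
    soil_state: np.ndarray,
    texture: SoilTexture,
    params: PlantParams,
) -> np.ndarray:
    """Demand matrix in the B_hsat -> 0 limit of the MM uptake law."""
    return demand_matrix(
        biomass, profiles, soil_state, texture, params, variant="linear"
    )


def biomass_step(
    B_k: float, T_k_total: float, params: PlantParams, dt: float = 1.0,
    wue: float = DEFAULT_WUE,
) -> float:
    """One Euler step of dB/dt = WUE*T - RESP*B, floored at zero."""
    if B_k < 0 or T_k_total < 0 or dt <= 0:
        raise ValueError("biomass, transpiration must be >= 0 and dt > 0")
    return max(0.0, B_k + dt * (wue * T_k_total - params.RESP * B_k))
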