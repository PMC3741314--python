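"""Simulation engine: daily coupling of rainfall, soil and plants.

A `ScenarioConfig` fully determines a run, including its random seed, so
identical configurations reproduce identical trajectories.  Randomness is
split deterministically from the scenario seed: one stream drives rainfall
and a separate stream draws initial biomasses, so changing how biomass is
initialized never alters the rainfall realization.

Profiles below the extinction threshold are *not* zeroed during a run;
biomass may decay continuously and extinction is classified at readout
from final biomass.

The default uptake variant is "prop" — per-layer demand proportional to
root biomass, i.e. the weak-saturation regime of the Michaelis-Menten
uptake law, capped only by the joint atmospheric rescale.  The saturating
"mm" variant (half-saturation at B_hsat per layer) and its "linear"
(B_hsat -> 0) limit are available via ``ScenarioConfig.uptake``; strong
per-layer saturation makes demand concave in biomass, which hands rare
strategies a disproportionate water share and greatly strengthens
coexistence (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel, rainfall
from .grid import DEFAULT_GRID, LayerGrid
from .plants import DEFAULT_WUE, UPTAKE_VARIANTS, PlantParams
from .rooting import RootingProfile, standard_profiles
from .soil import LEAK_FORMS, TEXTURES, FluxLedger, SoilTexture, initial_state

__all__ = [
    "ProfileSpec",
    "ScenarioConfig",
    "Trajectory",
    "run",
    "classify_survivors",
    "steady_state_summary",
]

# offsets added to the scenario seed to derive independent substreams
_RAIN_STREAM = 0
_BIOMASS_STREAM = 1


@dataclass(frozen=True)
class ProfileSpec:
    """One competing strategy: a rooting profile, its WUE, and its start.

    ``initial_biomass`` is either a fixed value (g/m2) or a (lo, hi) range
    sampled uniformly from the scenario's biomass stream.
    """

    profile: RootingProfile
    wue: float = DEFAULT_WUE
    initial_biomass: float | tuple[float, float] = 1000.0


@dataclass(frozen=True)
class ScenarioConfig:
    profiles: tuple[ProfileSpec, ...]
    duration_years: int = 500
    texture: SoilTexture | str = "coarse"
    map_mm: float = 650.0
    rain_mode: str = "stochastic"  # stochastic | constant | series
    rain_params: rainfall.RainParams | None = None
    rain_series: np.ndarray | None = None
    uptake: str = "prop"  # prop | mm | linear
    seed: int = 0
    n_substeps: int = 24
    record_every: int = 10
    plant_params: PlantParams = field(default_factory=PlantParams)
    grid: LayerGrid = DEFAULT_GRID
    leak_form: str = "gated-power"
    initial_soil: np.ndarray | None = None  # defaults to field capacity

    def resolved_texture(self) -> SoilTexture:
        if isinstance(self.texture, SoilTexture):
            return self.texture
        try:
            return TEXTURES[self.texture]
        except KeyError:
            raise ValueError(
                f"unknown texture {self.texture!r}; expected one of {sorted(TEXTURES)}"
            ) from None

    def validate(self) -> None:
        if self.duration_years < 1:
            raise ValueError("duration_years must be >= 1")
        if not self.profiles:
            raise ValueError("at least one profile is required")
        if self.rain_mode not in ("stochastic", "constant", "series"):
            raise ValueError(f"unknown rain_mode {self.rain_mode!r}")
        if self.rain_mode == "series" and self.rain_series is None:
            raise ValueError("rain_mode='series' requires rain_series")
        if self.uptake not in UPTAKE_VARIANTS:
            raise ValueError(f"unknown uptake variant {self.uptake!r}")
        if self.leak_form not in LEAK_FORMS:
            raise ValueError(f"unknown leak_form {self.leak_form!r}")
        if self.n_substeps < 1 or self.record_every < 1:
            raise ValueError("n_substeps and record_every must be >= 1")
        for spec in self.profiles:
            b = spec.initial_biomass
            if isinstance(b, tuple):
                if not (0 <= b[0] <= b[1]):
                    raise ValueError("initial biomass range must be 0 <= lo <= hi")
            elif b < 0:
                raise ValueError("initial biomass must be >= 0")
        self.resolved_texture()


@dataclass(frozen=True)
class Trajectory:
    """Recorded run output plus final state.

    ``frame`` has one row per recorded day with columns
    day, S_1..S_L, B_<name>.., T_<name>.., rain, runoff, evap, drainage,
    storage_change.
    """

    config: ScenarioConfig
    frame: pd.DataFrame
    final_soil: np.ndarray
    final_biomass: np.ndarray
    profile_names: tuple[str, ...]

    def ledgers(self) -> list[FluxLedger]:
        t_cols = [f"T_{n}" for n in self.profile_names]
        out = []
        for _, row in self.frame.iterrows():
            out.append(
                FluxLedger(
                    rain_in=row["rain"],
                    surface_runoff=row["runoff"],
                    evaporation=row["evap"],
                    transpiration=tuple(row[c] for c in t_cols),
                    deep_drainage=row["drainage"],
                    storage_change=row["storage_change"],
                )
            )
        return out


def _build_rain(config: ScenarioConfig, n_days: int) -> np.ndarray:
    if config.rain_mode == "constant":
        return rainfall.generate_constant(config.map_mm, n_days)
    if config.rain_mode == "series":
        series = np.asarray(config.rain_series, dtype=float)
        if series.size < n_days:
            raise ValueError(
                f"rain series has {series.size} days, scenario needs {n_days}"
            )
        if np.any(series < 0):
            raise ValueError("rain series must be non-negative")
        return series[:n_days]
    params = config.rain_params
    if params is None:
        params = rainfall.params_from_map(config.map_mm)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(2)[_RAIN_STREAM]
    )
    return rainfall.generate_stochastic(params, n_days, rng)


def _initial_biomass(config: ScenarioConfig) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(2)[_BIOMASS_STREAM]
    )
    out = np.empty(len(config.profiles))
    for k, spec in enumerate(config.profiles):
        b = spec.initial_biomass
        out[k] = rng.uniform(b[0], b[1]) if isinstance(b, tuple) else float(b)
    return out


def run(config: ScenarioConfig) -> Trajectory:
    """Execute a scenario and return its trajectory.

    Daily cycle: rainfall -> stress-adjusted demand matrix -> joint
    rescale to T_atm -> soil step with water-limited withdrawals ->
    biomass update from realized transpiration.
    """
    config.validate()
    texture = config.resolved_texture()
    grid = config.grid
    n_days = config.duration_years * 365

    rain = _build_rain(config, n_days)
    B0 = _initial_biomass(config)
    S0 = (
        np.asarray(config.initial_soil, dtype=float).copy()
        if config.initial_soil is not None
        else initial_state(texture, grid)
    )
    if S0.size != grid.n_layers or np.any((S0 < 0) | (S0 > 1)):
        raise ValueError("initial_soil must have one saturation in [0,1] per layer")

    R = np.ascontiguousarray(
        [spec.profile.fractions_array for spec in config.profiles]
    )
    if R.shape[1] != grid.n_layers:
        raise ValueError("rooting profiles and grid disagree on layer count")
    wue = np.array([spec.wue for spec in config.profiles], dtype=float)
    caps = grid.capacities_mm(texture.n)
    p = config.plant_params

    rec_idx = np.arange(config.record_every - 1, n_days, config.record_every)
    if rec_idx.size == 0 or rec_idx[-1] != n_days - 1:
        rec_idx = np.append(rec_idx, n_days - 1)
    rec_idx = rec_idx.astype(np.int64)

    S_rec, B_rec, T_rec, flux_rec, S_fin, B_fin = _kernel._run_days(
        rain, R, caps, B0, S0, wue,
        texture.S_f, texture.S_w, texture.S_star,
        texture.K_s, texture.tau, texture.E_max, texture.T_atm,
        p.RMR, p.RESP, p.B_hsat,
        config.n_substeps, LEAK_FORMS[config.leak_form],
        UPTAKE_VARIANTS[config.uptake],
        rec_idx,
    )

    names_list: list[str] = []
    seen: dict[str, int] = {}
    for spec in config.profiles:  # disambiguate repeated profile entries
        n = spec.profile.name
        seen[n] = seen.get(n, 0) + 1
        names_list.append(n if seen[n] == 1 else f"{n}#{seen[n]}")
    names = tuple(names_list)
    data: dict[str, np.ndarray] = {"day": rec_idx}
    for i in range(grid.n_layers):
        data[f"S_{i + 1}"] = S_rec[:, i]
    for k, name in enumerate(names):
        data[f"B_{name}"] = B_rec[:, k]
    for k, name in enumerate(names):
        data[f"T_{name}"] = T_rec[:, k]
    for m, col in enumerate(("rain", "runoff", "evap", "drainage", "storage_change")):
        data[col] = flux_rec[:, m]
    return Trajectory(
        config=config,
        frame=pd.DataFrame(data),
        final_soil=S_fin,
        final_biomass=B_fin,
        profile_names=names,
    )


def classify_survivors(
    final_biomass: np.ndarray,
    names: tuple[str, ...] | None = None,
    threshold: float = 1.0,
) -> tuple[tuple[str, ...], int]:
    """Profiles with final biomass >= threshold (g/m2), and their count."""
    B = np.asarray(final_biomass, dtype=float)
    if names is None:
        names = tuple(str(k) for k in range(B.size))
    alive = B >= threshold
    return tuple(n for n, a in zip(names, alive) if a), int(alive.sum())


def steady_state_summary(traj: Trajectory, window_years: int) -> pd.DataFrame:
    """Per-profile mean and SD of biomass over the final window of a run."""
    if window_years < 1 or window_years > traj.config.duration_years:
        raise ValueError("window must be between 1 year and the run duration")
    n_days = traj.config.duration_years * 365
    start = n_days - window_years * 365
    sub = traj.frame[traj.frame["day"] >= start]
    rows = []
    for name in traj.profile_names:
        b = sub[f"B_{name}"].to_numpy()
        rows.append(
            {"profile": name, "mean_biomass": b.mean(), "sd_biomass": b.std(ddof=0)}
        )
    return pd.DataFrame(rows)


def standard_scenario(
    names: list[str] | None = None,
    wue: dict[str, float] | None = None,
    initial_biomass: float | tuple[float, float] = 1000.0,
    **kwargs,
) -> ScenarioConfig:
    """Convenience builder over the four standard rooting profiles.

    ``names`` selects a subset (default all four); ``wue`` overrides WUE per
    profile name; remaining keyword arguments go to ScenarioConfig.
    """
    profs = {p.name: p for p in standard_profiles()}
    if names is None:
        names = list(profs)
    wue = wue or {}
    specs = tuple(
        ProfileSpec(
            profile=profs[n],
            wue=wue.get(n, DEFAULT_WUE),
            initial_biomass=initial_biomass,
        )
        for n in names
    )
    return ScenarioConfig(profiles=specs, **kwargs)
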