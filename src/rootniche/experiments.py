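"""Named, seeded simulation experiments.

Each function reproduces one of the study designs — isolation viability,
four-way competition, the deterministic-rainfall exclusion sequence, the
water-use-efficiency advantage and invasibility analyses, the global
sensitivity analysis (GSA), and the climate/soil gradient sweep — and
returns tidy pandas tables.  Every experiment is a pure function of its
design arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import (
    ProfileSpec,
    ScenarioConfig,
    classify_survivors,
    run,
    standard_scenario,
    steady_state_summary,
)
from .plants import DEFAULT_WUE, PlantParams
from .rooting import STANDARD_SHAPES, standard_profiles
from .soil import TEXTURES

__all__ = [
    "GsaDesign",
    "GradientDesign",
    "run_isolation",
    "run_competition",
    "run_deterministic_sequence",
    "run_wue_advantage",
    "run_invasibility",
    "run_gsa",
    "run_gradient",
]

PROFILE_NAMES = tuple(STANDARD_SHAPES)  # shallowest to deepest
WUE_ADVANTAGE = 0.5  # g m-2 kg-1, added to the favored profile's WUE


def _seed_for(base: int, k: int) -> int:
    """Derive a per-run seed from an experiment seed, kept below 2**31."""
    return (base * 1_000_003 + k) % (2**31 - 1)


def run_isolation(
    years: int = 1000, map_mm: float = 650.0, texture: str = "coarse",
    seed: int = 0, window_years: int = 100,
) -> pd.DataFrame:
    """Each standard profile alone: is every strategy viable by itself?

    Returns one row per profile with final and steady-window biomass
    (total, g/m2) and the survival flag.
    """
    window_years = min(window_years, years)
    rows = []
    for k, name in enumerate(PROFILE_NAMES):
        cfg = standard_scenario(
            names=[name], duration_years=years, map_mm=map_mm,
            texture=texture, seed=_seed_for(seed, k),
        )
        traj = run(cfg)
        summ = steady_state_summary(traj, window_years)
        _, n = classify_survivors(traj.final_biomass)
        rows.append(
            {
                "profile": name,
                "final_biomass": float(traj.final_biomass[0]),
                "steady_mean_biomass": float(summ["mean_biomass"].iloc[0]),
                "steady_sd_biomass": float(summ["sd_biomass"].iloc[0]),
                "survived": bool(n),
            }
        )
    return pd.DataFrame(rows)


def run_competition(
    n_runs: int = 5, years: int = 500, uptake: str = "prop",
    map_mm: float = 650.0, texture: str = "coarse", seed: int = 0,
    biomass_range: tuple[float, float] = (1000.0, 2000.0),
) -> pd.DataFrame:
    """All four profiles competing, random initial biomasses per run."""
    rows = []
    for r in range(n_runs):
        cfg = standard_scenario(
            duration_years=years, map_mm=map_mm, texture=texture,
            uptake=uptake, seed=_seed_for(seed, r),
            initial_biomass=biomass_range,
        )
        traj = run(cfg)
        for k, name in enumerate(traj.profile_names):
            rows.append(
                {
                    "run": r,
                    "profile": name,
                    "final_biomass": float(traj.final_biomass[k]),
                    "survived": bool(traj.final_biomass[k] >= 1.0),
                }
            )
    return pd.DataFrame(rows)


def run_deterministic_sequence(
    years: int = 100, map_mm: float = 650.0, texture: str = "coarse",
) -> pd.DataFrame:
    """Sequential-exclusion tournament under constant (deterministic) rain.

    All profiles start at 1000 g/m2 under a constant input of MAP/365 mm/d.
    After each round the winner (largest final biomass) is removed and the
    remainder re-run, down to a single profile run in isolation.  With no
    rainfall variability a single strategy excludes all others each round.
    """
    remaining = list(PROFILE_NAMES)
    rows = []
    rnd = 0
    while remaining:
        cfg = standard_scenario(
            names=remaining, duration_years=years, map_mm=map_mm,
            texture=texture, rain_mode="constant", seed=0,
        )
        traj = run(cfg)
        _, n_surv = classify_survivors(traj.final_biomass, traj.profile_names)
        winner = traj.profile_names[int(np.argmax(traj.final_biomass))]
        for k, name in enumerate(traj.profile_names):
            rows.append(
                {
                    "round": rnd,
                    "profile": name,
                    "final_biomass": float(traj.final_biomass[k]),
                    "survived": bool(traj.final_biomass[k] >= 1.0),
                    "winner": name == winner,
                    "n_survivors": n_surv,
                }
            )
        remaining.remove(winner)
        rnd += 1
    return pd.DataFrame(rows)


def run_wue_advantage(
    target: str, n_runs: int = 5, years: int = 500,
    map_mm: float = 650.0, texture: str = "coarse", seed: int = 0,
    advantage: float = WUE_ADVANTAGE,
) -> pd.DataFrame:
    """Four-way competition with one profile given a higher WUE."""
    if target not in PROFILE_NAMES:
        raise ValueError(f"unknown profile {target!r}")
    rows = []
    for r in range(n_runs):
        cfg = standard_scenario(
            duration_years=years, map_mm=map_mm, texture=texture,
            seed=_seed_for(seed, r),
            wue={target: DEFAULT_WUE + advantage},
            initial_biomass=(1000.0, 2000.0),
        )
        traj = run(cfg)
        for k, name in enumerate(traj.profile_names):
            rows.append(
                {
                    "run": r,
                    "target": target,
                    "profile": name,
                    "final_biomass": float(traj.final_biomass[k]),
                    "survived": bool(traj.final_biomass[k] >= 1.0),
                }
            )
    return pd.DataFrame(rows)


def run_invasibility(
    resident: str, map_mm: float = 650.0, texture: str = "coarse",
    seed: int = 0, resident_years: int = 100, invasion_years: int = 100,
    advantage: float = WUE_ADVANTAGE,
    introduction_biomass: float = 10.0,
) -> pd.DataFrame:
    """Can the other strategies invade an established resident?

    The resident (with a WUE advantage) grows alone from 4000 g/m2 for
    ``resident_years``; the other three are then introduced at
    ``introduction_biomass`` and the system runs ``invasion_years`` more.
    Invasion succeeds if the invader ends above its introduction size.
    A self-invasion control introduces the resident's own profile at the
    default (lower) WUE, which should fail.
    """
    if resident not in PROFILE_NAMES:
        raise ValueError(f"unknown profile {resident!r}")
    profs = {p.name: p for p in standard_profiles()}
    res_wue = DEFAULT_WUE + advantage

    pre = ScenarioConfig(
        profiles=(ProfileSpec(profs[resident], wue=res_wue, initial_biomass=4000.0),),
        duration_years=resident_years, map_mm=map_mm, texture=texture,
        seed=_seed_for(seed, 0),
    )
    pre_traj = run(pre)
    resident_b = float(pre_traj.final_biomass[0])

    invaders = [n for n in PROFILE_NAMES if n != resident]
    rows = []
    for j, invader in enumerate(invaders + [resident]):
        self_control = invader == resident
        specs = (
            ProfileSpec(profs[resident], wue=res_wue, initial_biomass=resident_b),
            ProfileSpec(
                profs[invader],
                wue=DEFAULT_WUE,  # invader never gets the advantage
                initial_biomass=introduction_biomass,
            ),
        )
        cfg = ScenarioConfig(
            profiles=specs, duration_years=invasion_years,
            map_mm=map_mm, texture=texture, seed=_seed_for(seed, 1 + j),
            initial_soil=pre_traj.final_soil,
        )
        traj = run(cfg)
        rows.append(
            {
                "resident": resident,
                "invader": invader,
                "self_control": self_control,
                "invader_final_biomass": float(traj.final_biomass[1]),
                "invaded": bool(traj.final_biomass[1] > introduction_biomass),
            }
        )
    return pd.DataFrame(rows)


#: the 12 texture/plant parameters perturbed in the GSA, plus the WUE
#: advantage of the super-shallow profile
GSA_PARAMETERS = (
    "S_f", "S_w", "S_star", "K_s", "tau", "n", "E_max", "T_atm",
    "B_hsat", "RMR", "WUE", "RESP", "wue_advantage",
)


@dataclass(frozen=True)
class GsaDesign:
    n_runs: int = 400
    run_years: int = 500
    multiplier_range: tuple[float, float] = (0.8, 1.2)
    map_mm: float = 650.0
    texture: str = "coarse"
    biomass_range: tuple[float, float] = (1000.0, 2000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.multiplier_range
        if not 0 < lo < hi:
            raise ValueError("multiplier range must satisfy 0 < lo < hi")
        if self.n_runs < 1 or self.run_years < 1:
            raise ValueError("n_runs and run_years must be >= 1")


def run_gsa(design: GsaDesign = GsaDesign()) -> tuple[pd.DataFrame, dict]:
    """Global sensitivity analysis over all 13 parameters.

    Each run multiplies every parameter by an independent uniform offset
    from ``multiplier_range``; the super-shallow profile's WUE advantage
    (default 0.5 g/m2 per kg) scales through its own multiplier.  Returns
    (per-run table, summary).  The summary reports the coexistence
    fraction, the median survivor count, the per-parameter share of
    variance in final total biomass (univariate regression R-squared, with
    a Spearman rank variant alongside), and the same statistics within the
    subset of runs whose field-capacity multiplier is within 5% of 1.
    """
    base = TEXTURES[design.texture]
    base_plants = PlantParams()
    rng = np.random.default_rng(design.seed)
    lo, hi = design.multiplier_range

    rows = []
    for r in range(design.n_runs):
        m = dict(zip(GSA_PARAMETERS, rng.uniform(lo, hi, size=len(GSA_PARAMETERS))))
        texture = base.scaled(
            name=f"gsa-{r}",
            S_f=m["S_f"], S_w=m["S_w"], S_star=m["S_star"], K_s=m["K_s"],
            tau=m["tau"], n=m["n"], E_max=m["E_max"], T_atm=m["T_atm"],
        )
        plants = PlantParams(
            RMR=base_plants.RMR * m["RMR"],
            RESP=base_plants.RESP * m["RESP"],
            B_hsat=base_plants.B_hsat * m["B_hsat"],
        )
        wue_base = DEFAULT_WUE * m["WUE"]
        wue = {name: wue_base for name in PROFILE_NAMES}
        wue["super-shallow"] = wue_base + WUE_ADVANTAGE * m["wue_advantage"]

        cfg = standard_scenario(
            duration_years=design.run_years, texture=texture,
            map_mm=design.map_mm, seed=_seed_for(design.seed, r),
            wue=wue, initial_biomass=design.biomass_range,
            plant_params=plants,
        )
        traj = run(cfg)
        _, n_surv = classify_survivors(traj.final_biomass, traj.profile_names)
        row = {"run": r, **{f"m_{k}": v for k, v in m.items()}}
        for k, name in enumerate(traj.profile_names):
            row[f"B_{name}"] = float(traj.final_biomass[k])
        row["total_biomass"] = float(traj.final_biomass.sum())
        row["n_surviving"] = n_surv
        rows.append(row)
    table = pd.DataFrame(rows)

    summary = _summarize_gsa(table)
    return table, summary


def _variance_decomposition(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    y = table["total_biomass"].to_numpy()
    out = {}
    for name in GSA_PARAMETERS:
        x = table[f"m_{name}"].to_numpy()
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2) if y.std() > 0 else 0.0
        rx, ry = pd.Series(x).rank(), pd.Series(y).rank()
        rho2 = float(np.corrcoef(rx, ry)[0, 1] ** 2) if y.std() > 0 else 0.0
        out[name] = {"r_squared": r2, "spearman_rho_squared": rho2}
    return out


def _summarize_gsa(table: pd.DataFrame) -> dict:
    coexist = table["n_surviving"] >= 2
    subset = (table["m_S_f"] - 1.0).abs() <= 0.05
    sub = table[subset]
    return {
        "n_runs": int(len(table)),
        "prop_coexisting": float(coexist.mean()),
        "median_n_surviving": float(table["n_surviving"].median()),
        "variance_decomposition": _variance_decomposition(table),
        "subset_S_f": {
            "n_runs": int(subset.sum()),
            "fraction_of_runs": float(subset.mean()),
            "prop_coexisting": float((sub["n_surviving"] >= 2).mean())
            if len(sub)
            else float("nan"),
            "median_n_surviving": float(sub["n_surviving"].median())
            if len(sub)
            else float("nan"),
        },
    }


@dataclass(frozen=True)
class GradientDesign:
    map_grid: tuple[float, ...] = (300.0, 600.0, 900.0, 1200.0, 1500.0)
    textures: tuple[str, ...] = ("coarse", "fine")
    #: which profiles receive the WUE advantage, one sweep per condition
    conditions: tuple[str, ...] = PROFILE_NAMES
    runs_per_cell: int = 5
    run_years: int = 500
    biomass_range: tuple[float, float] = (1000.0, 2000.0)
    window_years: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.map_grid or not self.textures or not self.conditions:
            raise ValueError("map_grid, textures and conditions must be non-empty")
        if self.runs_per_cell < 1:
            raise ValueError("runs_per_cell must be >= 1")


def run_gradient(design: GradientDesign = GradientDesign()) -> pd.DataFrame:
    """Sweep competition outcomes over MAP and soil texture.

    For every (MAP, texture, WUE condition) cell, ``runs_per_cell``
    stochastic competitions are run and the per-profile steady-window
    biomass is averaged; the returned table has the across-run mean and SD
    for each profile in each cell.
    """
    rows = []
    cell = 0
    for condition in design.conditions:
        for texture in design.textures:
            for map_mm in design.map_grid:
                per_run = []
                for r in range(design.runs_per_cell):
                    cfg = standard_scenario(
                        duration_years=design.run_years, texture=texture,
                        map_mm=map_mm,
                        seed=_seed_for(design.seed, cell * 1009 + r),
                        wue={condition: DEFAULT_WUE + WUE_ADVANTAGE},
                        initial_biomass=design.biomass_range,
                    )
                    traj = run(cfg)
                    summ = steady_state_summary(traj, design.window_years)
                    per_run.append(summ.set_index("profile")["mean_biomass"])
                cell += 1
                stacked = pd.concat(per_run, axis=1)
                for name in stacked.index:
                    vals = stacked.loc[name].to_numpy()
                    rows.append(
                        {
                            "map_mm": map_mm,
                            "texture": texture,
                            "condition": condition,
                            "profile": name,
                            "mean_biomass": float(vals.mean()),
                            "sd_biomass": float(vals.std(ddof=0)),
                        }
                    )
    return pd.DataFrame(rows)
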