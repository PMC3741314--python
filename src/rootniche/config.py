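"""Build scenario configurations from plain dictionaries / YAML.

Schema (all keys optional unless noted)::

    duration_years: 500
    texture: coarse            # coarse | fine
    uptake: prop               # prop | mm | linear
    seed: 1
    n_substeps: 24
    record_every: 10
    leak_form: gated-power     # gated-power | normalized | power
    rainfall:
      map: 650                 # mm/y
      constant: false          # true -> map/365 every day
      lambda: 0.2              # optional explicit generator parameters;
      mu: 1.5                  # all three must be given together
      sigma: 1.1
      file: rain.csv           # optional daily series (column rain_mm)
    profiles:                  # required, at least one entry
      - name: shallow          # a standard profile name, or shape1+shape2
        wue: 4.0
        initial_biomass: 1000  # or [lo, hi] for uniform sampling
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import ProfileSpec, ScenarioConfig
from .plants import DEFAULT_WUE
from .rooting import STANDARD_SHAPES, discretize, standard_profiles

__all__ = ["scenario_from_dict", "scenario_from_yaml"]


def _profile_spec(entry: dict) -> ProfileSpec:
    if "name" in entry and entry["name"] in STANDARD_SHAPES:
        profile = next(
            p for p in standard_profiles() if p.name == entry["name"]
        )
    elif "shape1" in entry and "shape2" in entry:
        profile = discretize(
            float(entry["shape1"]), float(entry["shape2"]),
            name=str(entry.get("name", "custom")),
        )
    else:
        raise ValueError(
            f"profile entry needs a standard name {sorted(STANDARD_SHAPES)} "
            f"or shape1/shape2: {entry!r}"
        )
    b = entry.get("initial_biomass", 1000.0)
    if isinstance(b, (list, tuple)):
        b = (float(b[0]), float(b[1]))
    else:
        b = float(b)
    return ProfileSpec(
        profile=profile, wue=float(entry.get("wue", DEFAULT_WUE)),
        initial_biomass=b,
    )


def scenario_from_dict(cfg: dict) -> ScenarioConfig:
    entries = cfg.get("profiles")
    if not entries:
        raise ValueError("config needs a non-empty 'profiles' list")
    rain = dict(cfg.get("rainfall", {}))

    kwargs: dict = {}
    rain_mode = "stochastic"
    if rain.get("constant"):
        rain_mode = "constant"
    if "file" in rain:
        series = pd.read_csv(rain["file"])["rain_mm"].to_numpy(dtype=float)
        kwargs["rain_series"] = series
        rain_mode = "series"
    if any(k in rain for k in ("lambda", "mu", "sigma")):
        from .rainfall import RainParams

        try:
            kwargs["rain_params"] = RainParams(
                lambda_rate=float(rain["lambda"]),
                mu=float(rain["mu"]),
                sigma=float(rain["sigma"]),
            )
        except KeyError as missing:
            raise ValueError(
                f"explicit rainfall parameters need lambda, mu and sigma "
                f"(missing {missing})"
            ) from None

    for key in ("duration_years", "seed", "n_substeps", "record_every"):
        if key in cfg:
            kwargs[key] = int(cfg[key])
    for key in ("texture", "uptake", "leak_form"):
        if key in cfg:
            kwargs[key] = str(cfg[key])
    if "map" in rain:
        kwargs["map_mm"] = float(rain["map"])

    return ScenarioConfig(
        profiles=tuple(_profile_spec(e) for e in entries),
        rain_mode=rain_mode,
        **kwargs,
    )


def scenario_from_yaml(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
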