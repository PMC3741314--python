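"""Layered soil bucket: leakage, evaporation, daily stepping, mass balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootniche.soil import (
    COARSE,
    FINE,
    SoilTexture,
    evaporation_rate,
    initial_state,
    leakage_rate,
    step_day,
)


class TestLeakageRate:
    def test_zero_at_and_below_field_capacity(self, coarse):
        for form in ("gated-power", "normalized"):
            assert leakage_rate(coarse.S_f, coarse, form) == 0.0
            assert leakage_rate(0.1, coarse, form) == 0.0

    def test_saturation_limit_is_K_s(self, coarse):
        for form in ("gated-power", "normalized", "power"):
            assert leakage_rate(1.0, coarse, form) == pytest.approx(1100.0)

    def test_known_values_above_threshold(self, coarse):
        # direct evaluation of each functional form at S=0.65, coarse texture
        assert leakage_rate(0.65, coarse, "normalized") == pytest.approx(
            1100.0 * (0.35 / 0.70) ** 4.5, rel=1e-12
        )
        assert leakage_rate(0.65, coarse, "gated-power") == pytest.approx(
            1100.0 * 0.65**4.5, rel=1e-12
        )

    def test_monotone_nondecreasing(self, coarse):
        s = np.linspace(0.0, 1.0, 201)
        for form in ("gated-power", "normalized", "power"):
            rates = leakage_rate(s, coarse, form)
            assert np.all(np.diff(rates) >= 0)


class TestEvaporationRate:
    def test_maximum_at_stress_onset(self, coarse):
        assert evaporation_rate(coarse.S_star, coarse) == pytest.approx(1.5)
        assert evaporation_rate(0.9, coarse) == pytest.approx(1.5)

    def test_zero_at_wilting_point(self, coarse):
        assert evaporation_rate(coarse.S_w, coarse) == 0.0
        assert evaporation_rate(0.0, coarse) == 0.0

    def test_linear_midpoint(self, coarse):
        mid = 0.5 * (coarse.S_w + coarse.S_star)
        assert evaporation_rate(mid, coarse) == pytest.approx(0.75)


class TestTextureInvariants:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            SoilTexture("bad", S_f=0.3, S_w=0.2, S_star=0.1,
                        K_s=100, tau=4, n=0.4, E_max=1.5, T_atm=3.25)

    def test_presets_match_published_values(self):
        assert (COARSE.S_f, COARSE.S_w, COARSE.S_star) == (0.30, 0.05, 0.10)
        assert (COARSE.K_s, COARSE.tau, COARSE.n) == (1100.0, 4.5, 0.42)
        assert (FINE.S_f, FINE.S_w, FINE.S_star) == (0.50, 0.10, 0.20)
        assert (FINE.K_s, FINE.tau, FINE.n) == (300.0, 6.0, 0.45)
        assert COARSE.E_max == FINE.E_max == 1.5
        assert COARSE.T_atm == FINE.T_atm == 3.25


def _zero_demands(grid, k=1):
    return np.zeros((grid.n_layers, k))


class TestStepDay:
    def test_no_flow_fixed_point(self, coarse, grid):
        # at the wilting point every flux is shut off: no drainage (below
        # field capacity), no evaporation, no uptake -> exact fixed point
        dry = initial_state(coarse, grid, value=coarse.S_w)
        new, ledger = step_day(dry, 0.0, _zero_demands(grid), coarse, grid)
        np.testing.assert_array_equal(new, dry)
        assert ledger.rain_in == ledger.surface_runoff == 0.0
        assert ledger.evaporation == ledger.deep_drainage == 0.0
        assert ledger.storage_change == 0.0

    def test_below_field_capacity_only_evaporation_moves_water(
        self, coarse, grid
    ):
        # S = S_f everywhere: no drainage or runoff; the top layer loses
        # water to evaporation only
        state = initial_state(coarse, grid)
        new, ledger = step_day(state, 0.0, _zero_demands(grid), coarse, grid)
        assert ledger.surface_runoff == ledger.deep_drainage == 0.0
        assert ledger.evaporation > 0.0
        np.testing.assert_array_equal(new[1:], state[1:])
        assert new[0] < state[0]
        assert ledger.closes()

    def test_column_saturating_rain_produces_runoff(self, coarse, grid):
        # rain exceeding column storage plus a full day of drainage must
        # saturate the column and shed the remainder as surface runoff;
        # day-end saturations sit below 1 only because drainage keeps
        # running after the rain stops
        state = initial_state(coarse, grid, value=0.5)
        caps = grid.capacities_mm(coarse.n)
        rain = float(((1 - state) * caps).sum() + coarse.K_s + 100.0)
        new, ledger = step_day(state, rain, _zero_demands(grid), coarse, grid)
        assert ledger.surface_runoff > 0
        assert ledger.deep_drainage > 0
        assert np.all(new >= coarse.S_f)  # wetted throughout
        assert ledger.closes()

    def test_substep_refinement_agreement(self, coarse, grid):
        state = np.full(grid.n_layers, 0.8)
        a, _ = step_day(state, 0.0, _zero_demands(grid), coarse, grid,
                        n_substeps=24)
        b, _ = step_day(state, 0.0, _zero_demands(grid), coarse, grid,
                        n_substeps=240)
        np.testing.assert_allclose(a, b, atol=1e-3)

    def test_substep_halving_changes_fluxes_under_one_percent(
        self, coarse, grid
    ):
        state = np.full(grid.n_layers, 0.45)
        demands = np.full((grid.n_layers, 2), 0.15)
        out = {}
        for n_sub in (24, 48):
            _, ledger = step_day(state, 12.0, demands, coarse, grid,
                                 n_substeps=n_sub)
            out[n_sub] = np.array([
                ledger.evaporation, ledger.transpiration_total,
                ledger.deep_drainage, ledger.storage_change,
            ])
        diff = np.abs(out[24] - out[48])
        assert np.all(diff <= np.maximum(0.01 * np.abs(out[48]), 1e-9))

    def test_monotone_drainage_without_inputs(self, coarse, grid):
        caps = grid.capacities_mm(coarse.n)
        state = np.full(grid.n_layers, 0.9)
        prev = float((state * caps).sum())
        for _ in range(10):
            state, ledger = step_day(state, 0.0, _zero_demands(grid), coarse,
                                     grid)
            total = float((state * caps).sum())
            assert total <= prev + 1e-12
            assert ledger.closes()
            prev = total

    def test_negative_inputs_rejected(self, coarse, grid):
        state = initial_state(coarse, grid)
        with pytest.raises(ValueError):
            step_day(state, -1.0, _zero_demands(grid), coarse, grid)
        bad = _zero_demands(grid)
        bad[0, 0] = -0.1
        with pytest.raises(ValueError):
            step_day(state, 5.0, bad, coarse, grid)

    def test_realized_transpiration_never_exceeds_demand(self, coarse, grid):
        state = initial_state(coarse, grid, value=0.06)  # nearly dry
        demands = np.full((grid.n_layers, 3), 0.4)
        _, ledger = step_day(state, 0.0, demands, coarse, grid)
        for k in range(3):
            assert ledger.transpiration[k] <= demands[:, k].sum() + 1e-12


@given(
    rain=st.floats(0.0, 120.0),
    s0=st.floats(0.0, 1.0),
    demand=st.floats(0.0, 0.5),
    form=st.sampled_from(["gated-power", "normalized", "power"]),
    texture_name=st.sampled_from(["coarse", "fine"]),
)
@settings(max_examples=80, deadline=None)
def test_daily_mass_balance_closes_and_state_stays_bounded(
    rain, s0, demand, form, texture_name
):
    from rootniche.grid import DEFAULT_GRID
    from rootniche.soil import TEXTURES

    texture = TEXTURES[texture_name]
    grid = DEFAULT_GRID
    state = np.full(grid.n_layers, s0)
    demands = np.full((grid.n_layers, 2), demand)
    new, ledger = step_day(state, rain, demands, texture, grid,
                           leak_form=form)
    assert ledger.closes(1e-6)
    assert np.all(new >= 0.0) and np.all(new <= 1.0)
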