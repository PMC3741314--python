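"""Experiment suite: structure, reproducibility, and exclusion dynamics.

Long-horizon quantitative outcomes live in test_acceptance; here the
experiments run at reduced durations to check their contracts and the
qualitative competition behavior of the default (proportional-uptake)
model.
"""

import numpy as np
import pandas as pd
import pytest

from rootniche import experiments as ex


class TestIsolation:
    def test_all_profiles_viable_alone(self):
        table = ex.run_isolation(years=60, seed=1, window_years=10)
        assert list(table["profile"]) == list(ex.PROFILE_NAMES)
        assert table["survived"].all()
        assert (table["final_biomass"] > 1000).all()


class TestCompetition:
    def test_super_shallow_excluded_at_equal_wue(self):
        # under stochastic rain with no WUE advantage the super-shallow
        # strategy loses to less extreme shapes
        table = ex.run_competition(n_runs=2, years=400, seed=1)
        ss = table[table.profile == "super-shallow"]
        assert not ss["survived"].any()
        mid = table[table.profile.isin(["shallow", "intermediate"])]
        assert mid["survived"].all()

    def test_zero_initial_biomass_stays_zero(self):
        table = ex.run_competition(
            n_runs=1, years=2, seed=0, biomass_range=(0.0, 0.0)
        )
        assert (table["final_biomass"] == 0.0).all()

    def test_reproducible(self):
        a = ex.run_competition(n_runs=2, years=3, seed=5)
        b = ex.run_competition(n_runs=2, years=3, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestDeterministicSequence:
    def test_winner_is_always_the_shallowest_remaining(self):
        table = ex.run_deterministic_sequence(years=100)
        winners = list(table[table.winner]["profile"])
        assert winners == list(ex.PROFILE_NAMES)

    def test_later_rounds_collapse_to_single_survivor(self):
        table = ex.run_deterministic_sequence(years=100)
        by_round = table.groupby("round")["n_survivors"].first()
        assert (by_round.loc[1:] == 1).all()

    def test_deep_alone_is_viable_under_constant_rain(self):
        table = ex.run_deterministic_sequence(years=100)
        last = table[table["round"] == table["round"].max()]
        assert list(last["profile"]) == ["deep"]
        assert last["survived"].all()


class TestWueAdvantage:
    def test_intermediate_advantage_coexists_with_shallow(self):
        table = ex.run_wue_advantage(
            "intermediate", n_runs=2, years=400, seed=1
        )
        surv = set(table[table.survived]["profile"])
        assert surv == {"intermediate", "shallow"}

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            ex.run_wue_advantage("taproot")


class TestInvasibility:
    def test_self_invasion_at_default_wue_fails(self):
        table = ex.run_invasibility("shallow", seed=2)
        control = table[table.self_control]
        assert len(control) == 1
        assert not control["invaded"].iloc[0]

    def test_some_alternative_profile_invades(self):
        table = ex.run_invasibility("shallow", seed=2)
        assert table[~table.self_control]["invaded"].any()

    def test_zero_introduction_stays_zero(self):
        table = ex.run_invasibility(
            "deep", seed=0, introduction_biomass=0.0,
            resident_years=2, invasion_years=2,
        )
        assert (table["invader_final_biomass"] == 0.0).all()


@pytest.fixture(scope="module")
def small_gsa():
    design = ex.GsaDesign(n_runs=16, run_years=25, seed=11)
    return ex.run_gsa(design)


class TestGsa:
    def test_multipliers_within_design_range(self, small_gsa):
        table, _ = small_gsa
        m = table[[f"m_{p}" for p in ex.GSA_PARAMETERS]].to_numpy()
        assert m.min() >= 0.8 and m.max() <= 1.2

    def test_summary_structure(self, small_gsa):
        _, summary = small_gsa
        assert summary["n_runs"] == 16
        assert 0.0 <= summary["prop_coexisting"] <= 1.0
        assert set(summary["variance_decomposition"]) == set(ex.GSA_PARAMETERS)
        for stats in summary["variance_decomposition"].values():
            assert 0.0 <= stats["r_squared"] <= 1.0

    def test_subset_is_runs_with_near_default_field_capacity(self, small_gsa):
        table, summary = small_gsa
        expected = int(((table["m_S_f"] - 1.0).abs() <= 0.05).sum())
        assert summary["subset_S_f"]["n_runs"] == expected

    def test_reproducible(self):
        design = ex.GsaDesign(n_runs=4, run_years=5, seed=3)
        a, _ = ex.run_gsa(design)
        b, _ = ex.run_gsa(design)
        pd.testing.assert_frame_equal(a, b)

    def test_subset_selection_probability(self):
        # |m - 1| <= 0.05 under U(0.8, 1.2) selects 25% in expectation;
        # check the sampled S_f multipliers directly at 3 SE
        rng = np.random.default_rng(0)
        m = rng.uniform(0.8, 1.2, size=4000)
        frac = np.mean(np.abs(m - 1) <= 0.05)
        se = np.sqrt(0.25 * 0.75 / m.size)
        assert abs(frac - 0.25) <= 3 * se


class TestGradient:
    def test_single_run_cells_have_zero_sd(self):
        design = ex.GradientDesign(
            map_grid=(600.0,), textures=("coarse",),
            conditions=("shallow",), runs_per_cell=1, run_years=10,
            window_years=2, seed=1,
        )
        table = ex.run_gradient(design)
        assert (table["sd_biomass"] == 0.0).all()
        assert set(table["profile"]) == set(ex.PROFILE_NAMES)

    def test_combined_biomass_increases_with_rainfall(self):
        design = ex.GradientDesign(
            map_grid=(300.0, 900.0, 1500.0), textures=("coarse",),
            conditions=("shallow",), runs_per_cell=1, run_years=120,
            window_years=20, seed=4,
        )
        table = ex.run_gradient(design)
        totals = table.groupby("map_mm")["mean_biomass"].sum()
        assert totals.loc[300.0] < totals.loc[900.0] < totals.loc[1500.0]

    def test_fine_texture_favors_shallower_profiles(self):
        design = ex.GradientDesign(
            map_grid=(600.0,), textures=("coarse", "fine"),
            conditions=("shallow",), runs_per_cell=1, run_years=120,
            window_years=20, seed=6,
        )
        table = ex.run_gradient(design)
        piv = table.pivot_table(
            index="texture", columns="profile", values="mean_biomass"
        )
        shallow_share = piv[["super-shallow", "shallow"]].sum(axis=1) / piv.sum(
            axis=1
        )
        assert shallow_share["fine"] > shallow_share["coarse"]
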