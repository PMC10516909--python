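"""Scan initialisation, schedule, profile collection and classification."""

import math

import pytest
from cobra import Reaction

import fluxscan as fs
from fluxscan.scan import (
    ScanError,
    ScanInitializationError,
    ScanProfile,
    ScanTable,
    StepSchedule,
)

from conftest import FIXTURE_SEEDS


class TestInitializeScan:
    def test_toy1_anchor_fluxes(self, toy1_pipeline):
        init = toy1_pipeline["init"]
        assert init.biomass_max == pytest.approx(10.0)
        assert init.target_max == pytest.approx(10.0)
        assert init.atp_maintenance_floor == 0.0
        assert init.biomass_min == pytest.approx(0.0)

    def test_maintenance_floor_read_from_bound(self, toy1):
        atpm = Reaction("ATPM", name="non-growth maintenance",
                        lower_bound=1.0, upper_bound=1000.0)
        atpm.add_metabolites({toy1.metabolites.A: -1})
        toy1.add_reactions([atpm])
        init = fs.initialize_scan(toy1, "R2", "EX_P")
        assert init.atp_maintenance_floor == pytest.approx(1.0)
        assert init.biomass_max == pytest.approx(9.0)

    def test_override_wins_over_bound(self, toy1):
        init = fs.initialize_scan(toy1, "R2", "EX_P", atp_maintenance_override=2.5)
        assert init.atp_maintenance_floor == pytest.approx(2.5)

    def test_infeasible_model_names_failing_stage(self, toy1):
        toy1.reactions.EX_P.lower_bound = 20.0
        with pytest.raises(ScanInitializationError, match="biomass_max"):
            fs.initialize_scan(toy1, "R2", "EX_P")


class TestStepSchedule:
    def test_default_schedule_for_target_max_10(self):
        schedule = fs.build_step_schedule(10.0)
        assert schedule.enforced_values == pytest.approx((1.8, 3.6, 5.4, 7.2, 9.0))
        assert schedule.enforced_values[-1] == pytest.approx(0.9 * 10.0)

    def test_two_steps_full_cap(self):
        schedule = fs.build_step_schedule(10.0, n_steps=2, cap_fraction=1.0)
        assert schedule.enforced_values == pytest.approx((5.0, 10.0))

    def test_zero_target_max_is_an_error(self):
        with pytest.raises(ScanError, match="cannot carry flux"):
            fs.build_step_schedule(0.0)

    @pytest.mark.parametrize("kwargs", [{"n_steps": 1}, {"cap_fraction": 0.0},
                                        {"cap_fraction": 1.5}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fs.build_step_schedule(10.0, **kwargs)

    def test_non_increasing_values_rejected(self):
        with pytest.raises(ValueError):
            StepSchedule(enforced_values=(1.0, 1.0), n_steps=2)


class TestRunScan:
    def test_toy1_biomass_trajectory(self, toy1_pipeline):
        assert toy1_pipeline["table"].biomass_per_step == pytest.approx(
            [8.2, 6.4, 4.6, 2.8, 1.0]
        )

    def test_target_pathway_profile_tracks_schedule(self, toy1_pipeline):
        table = toy1_pipeline["table"]
        assert table.profile("R3").flux_values == pytest.approx(
            [1.8, 3.6, 5.4, 7.2, 9.0]
        )

    def test_saturated_uptake_is_constant(self, toy1_pipeline):
        uptake = toy1_pipeline["table"].profile("EX_A").flux_values
        assert uptake == pytest.approx([-10.0] * 5)

    def test_bounds_restored_after_scan(self, toy1):
        before = toy1.reactions.EX_P.bounds
        fs.run_scan(toy1, "R2", "EX_P", fs.build_step_schedule(10.0))
        assert toy1.reactions.EX_P.bounds == before

    def test_zero_enforcement_reproduces_unconstrained_optimum(self, toy1):
        baseline = fs.optimize(toy1, "R2")
        schedule = StepSchedule(enforced_values=(0.0, 1.8), n_steps=2)
        table = fs.run_scan(toy1, "R2", "EX_P", schedule)
        for profile in table.profiles:
            assert profile.flux_values[0] == pytest.approx(
                baseline.fluxes[profile.reaction_id], abs=1e-6
            )

    def test_infeasible_step_flagged_not_fatal(self, toy1):
        schedule = StepSchedule(enforced_values=(5.0, 2000.0), n_steps=2)
        table = fs.run_scan(toy1, "R2", "EX_P", schedule)
        assert math.isnan(table.biomass_per_step[1])
        assert all(not p.all_feasible for p in table.profiles)
        assert fs.filter_valid_profiles(table).profiles == []

    def test_biomass_never_increases_across_steps(self, fixture_scans):
        for seed in FIXTURE_SEEDS:
            trajectory = fixture_scans[seed]["table"].biomass_per_step
            for earlier, later in zip(trajectory, trajectory[1:]):
                assert later <= earlier + 1e-6


def _table_from_profiles(profiles):
    init = fs.ScanInit(0.0, 0.0, 10.0, 10.0)
    schedule = fs.build_step_schedule(10.0)
    return ScanTable(profiles=profiles, init=init, schedule=schedule,
                     biomass_per_step=[8.2, 6.4, 4.6, 2.8, 1.0])


def _profile(rid, values, feasible=True):
    return ScanProfile(reaction_id=rid, reaction_name=rid, subsystem="",
                       stoichiometry_text="", flux_values=values,
                       all_feasible=feasible)


class TestFilterValidProfiles:
    def test_non_monotone_profile_removed(self):
        table = _table_from_profiles([_profile("X", [1, 5, 2, 8, 3])])
        assert fs.filter_valid_profiles(table).profiles == []

    def test_strictly_decreasing_profile_retained(self):
        table = _table_from_profiles([_profile("X", [8.2, 6.4, 4.6, 2.8, 1.0])])
        survivors = fs.filter_valid_profiles(table).profiles
        assert [p.reaction_id for p in survivors] == ["X"]
        assert survivors[0].steadily_changing

    def test_infeasible_step_profile_removed(self):
        table = _table_from_profiles(
            [_profile("X", [1, 2, math.nan, 4, 5], feasible=False)]
        )
        assert fs.filter_valid_profiles(table).profiles == []

    def test_constant_profile_counts_as_monotone(self):
        table = _table_from_profiles([_profile("X", [-10.0] * 5)])
        assert len(fs.filter_valid_profiles(table).profiles) == 1


class TestClassifyReactions:
    def test_toy1_truth_table(self, toy1_pipeline):
        from fluxscan.toyfixtures import TOY1_TRUTH

        verdicts = {
            c.reaction_id: (c.reaction_type, c.proportionality)
            for c in toy1_pipeline["classifications"]
        }
        assert verdicts == TOY1_TRUTH

    def test_classes_are_disjoint_and_cover_retained(self, fixture_scans):
        for seed in FIXTURE_SEEDS:
            table = fixture_scans[seed]["table"]
            filtered = fs.filter_valid_profiles(table)
            records = fs.classify_reactions(filtered)
            assert sorted(c.reaction_id for c in records) == sorted(
                p.reaction_id for p in filtered.profiles
            )
            for record in records:
                assert (record.reaction_type == "unaffected") == (
                    record.proportionality == "none"
                )

    def test_reversed_reaction_gets_negative_proportionality(self):
        table = _table_from_profiles([_profile("REV", [-1.8, -3.6, -5.4, -7.2, -9.0])])
        filtered = fs.filter_valid_profiles(table)
        (record,) = fs.classify_reactions(filtered)
        assert record.reaction_type == "flux_increasing"
        assert record.proportionality == "negative_directly"
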