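"""The three-strategy allocation engine: hand examples, errors, invariants."""

from decimal import Decimal
from fractions import Fraction

import pytest

from rhsa import (
    Earmark,
    Function,
    LedgerEntry,
    MissingUnitCostError,
    ServiceVolumeRecord,
    ShareMatrix,
    Tier,
    UnitCost,
    ZeroTierError,
    admin_distribution_factor,
    allocate_admin,
    allocate_earmarked,
    allocate_facility_funds,
    compute_share_matrix,
    conservation_audit,
    estimate_tier_totals,
    run_pipeline,
    tier_weights_from_totals,
)
from rhsa.allocation import AllocationError

F = Fraction
PHC, REF, TER = Tier.PHC_CLINIC, Tier.REF_HOSPITAL_1_2, Tier.REF_HOSPITAL_3
MH, FP, OTHER = Function.MATERNAL_HEALTH, Function.FAMILY_PLANNING, Function.OTHER_HEALTH


def shares_row(mh, fp, other):
    return {MH: F(mh), FP: F(fp), OTHER: F(other)}


class TestTierTotals:
    def test_zero_volumes_give_zero_totals(self):
        vols = [ServiceVolumeRecord(2012, PHC, "a", 0)]
        costs = [UnitCost("a", Decimal(2), MH)]
        assert estimate_tier_totals(vols, costs, 2012)[PHC] == 0

    def test_totals_are_volume_times_cost_summed(self):
        vols = [
            ServiceVolumeRecord(2012, PHC, "a", 10),
            ServiceVolumeRecord(2012, PHC, "b", 5),
        ]
        costs = [UnitCost("a", Decimal(2), MH), UnitCost("b", Decimal(3), FP)]
        assert estimate_tier_totals(vols, costs, 2012)[PHC] == 35

    def test_missing_unit_cost_names_the_service(self):
        vols = [ServiceVolumeRecord(2012, PHC, "mystery", 1)]
        with pytest.raises(MissingUnitCostError, match="mystery"):
            estimate_tier_totals(vols, [], 2012)

    def test_synthetic_totals_match_generator_targets(self, scenario):
        totals = estimate_tier_totals(scenario.volumes, scenario.costs, 2012)
        for tier, split in scenario.config.tier_split.items():
            target = scenario.config.facility_scale * split
            assert abs(totals[tier] / target - 1) < F(1, 10**6)


class TestShareMatrix:
    def test_single_function_tier_is_a_unit_row(self):
        vols = [ServiceVolumeRecord(2012, PHC, "a", 7)]
        costs = [UnitCost("a", Decimal(4), MH)]
        sm = compute_share_matrix(vols, costs, 2012)
        assert sm.row(PHC) == shares_row(1, 0, 0)

    def test_toy_shares_are_hand_divisions(self):
        vols = [
            ServiceVolumeRecord(2012, PHC, "m", 28),
            ServiceVolumeRecord(2012, PHC, "f", 7),
            ServiceVolumeRecord(2012, PHC, "o", 65),
        ]
        costs = [
            UnitCost("m", Decimal(1), MH),
            UnitCost("f", Decimal(1), FP),
            UnitCost("o", Decimal(1), OTHER),
        ]
        sm = compute_share_matrix(vols, costs, 2012)
        assert sm.row(PHC) == shares_row("0.28", "0.07", "0.65")
        assert sm.rh_share(PHC) == F(35, 100)

    def test_zero_total_tier_has_no_row_and_raises_on_access(self):
        sm = compute_share_matrix([], [], 2012)
        with pytest.raises(ZeroTierError):
            sm.row(PHC)

    def test_rows_must_normalize_and_be_nonnegative(self):
        with pytest.raises(AllocationError):
            ShareMatrix({PHC: shares_row("0.5", "0.1", "0.1")})
        with pytest.raises(AllocationError):
            ShareMatrix({PHC: shares_row("-0.1", "0.4", "0.7")})

    def test_calibrated_fixture_reproduces_published_phc_composition(self, scenario):
        """PHC clinics: 25.8 % maternal + 2.2 % family planning = 28 % RH."""
        sm = compute_share_matrix(scenario.volumes, scenario.costs, 2012)
        row = sm.row(PHC)
        assert row[MH] == F("0.258")
        assert row[FP] == F("0.022")
        assert sm.rh_share(PHC) == F("0.280")

    def test_increasing_maternal_volume_never_decreases_maternal_share(self):
        costs = [UnitCost("m", Decimal(5), MH), UnitCost("o", Decimal(3), OTHER)]
        prev = F(0)
        for v in (0, 1, 5, 50, 500):
            vols = [
                ServiceVolumeRecord(2012, PHC, "m", v),
                ServiceVolumeRecord(2012, PHC, "o", 100),
            ]
            share = compute_share_matrix(vols, costs, 2012).row(PHC)[MH]
            assert share >= prev
            prev = share


def earmarked(amount, fn, agent="MSPLS", tier=None):
    return LedgerEntry(
        2012, agent, Decimal(amount), Earmark.EARMARKED_RH, function_hint=fn, tier_hint=tier
    )


class TestEarmarkedPassThrough:
    def test_empty_slice_gives_empty_cube(self):
        assert allocate_earmarked([]).cells == {}

    def test_entry_maps_one_to_one_without_splitting(self):
        cube = allocate_earmarked([earmarked(568, FP)])
        assert cube.cells == {(2012, "MSPLS", PHC, FP): F(568)}

    def test_two_entries_to_the_same_cell_sum(self):
        cube = allocate_earmarked([earmarked(500, FP), earmarked(68, FP)])
        assert cube.cells == {(2012, "MSPLS", PHC, FP): F(568)}

    def test_tier_hint_overrides_default_tier(self):
        cube = allocate_earmarked([earmarked(10, MH, tier=REF)])
        assert (2012, "MSPLS", REF, MH) in cube.cells


class TestFacilityAllocation:
    def facility(self, amount, tier=None):
        return LedgerEntry(
            2012, "MSPLS", Decimal(amount), Earmark.FACILITY_NONEARMARKED, tier_hint=tier
        )

    def test_single_tier_split_is_hand_multiplication(self):
        sm = ShareMatrix({PHC: shares_row("0.28", "0.07", "0.65")})
        cube = allocate_facility_funds([self.facility(100)], {PHC: F(1)}, sm)
        assert cube.cells[(2012, "MSPLS", PHC, MH)] == 28
        assert cube.cells[(2012, "MSPLS", PHC, FP)] == 7
        assert cube.cells[(2012, "MSPLS", PHC, OTHER)] == 65

    def test_zero_amount_allocates_nothing_nonzero(self):
        sm = ShareMatrix({PHC: shares_row("0.28", "0.07", "0.65")})
        cube = allocate_facility_funds([self.facility(0)], {PHC: F(1)}, sm)
        assert all(v == 0 for v in cube.cells.values())

    def test_tier_weights_reproduce_tier_marginals(self):
        """Half / 40 % / 16-18 % of facility funds land on the three tiers."""
        weights = {PHC: F(47, 100), REF: F(37, 100), TER: F(16, 100)}
        sm = ShareMatrix({t: shares_row(1, 0, 0) for t in (PHC, REF, TER)})
        cube = allocate_facility_funds([self.facility(1000)], weights, sm)
        marginals = {t: cube.cells[(2012, "MSPLS", t, MH)] for t in weights}
        assert marginals == {PHC: 470, REF: 370, TER: 160}

    def test_unnormalized_weights_are_rejected(self):
        sm = ShareMatrix({PHC: shares_row(1, 0, 0)})
        with pytest.raises(AllocationError):
            allocate_facility_funds([self.facility(1)], {PHC: F(1, 2)}, sm)

    def test_positive_weight_on_undefined_row_is_an_error_not_silent_zero(self):
        sm = ShareMatrix({PHC: shares_row(1, 0, 0)})
        with pytest.raises(ZeroTierError):
            allocate_facility_funds(
                [self.facility(1)], {PHC: F(1, 2), REF: F(1, 2)}, sm
            )


class TestAdminApportionment:
    @pytest.mark.parametrize("rh, total, expected", [(0, 7, 0), (7, 7, 1), (30, 120, F(1, 4))])
    def test_distribution_factor_is_direct_rh_over_direct_total(self, rh, total, expected):
        assert admin_distribution_factor(rh, total) == expected

    def test_zero_direct_total_has_no_basis_for_apportionment(self):
        with pytest.raises(AllocationError):
            admin_distribution_factor(0, 0)

    def test_factor_splits_admin_into_rh_and_residual(self):
        e = LedgerEntry(2012, "MSPLS", Decimal(1000), Earmark.ADMIN_NATIONAL)
        cube = allocate_admin([e], F(1, 4))
        assert cube.cells[(2012, "MSPLS", Tier.ADMIN_NATIONAL, Function.ADMIN_MOH)] == 250
        assert cube.cells[(2012, "MSPLS", Tier.ADMIN_NATIONAL, OTHER)] == 750

    def test_mfp_admin_lands_in_social_security_function(self):
        e = LedgerEntry(2012, "MFP", Decimal(100), Earmark.ADMIN_NATIONAL)
        cube = allocate_admin([e], F(1, 2))
        assert cube.cells[(2012, "MFP", Tier.ADMIN_NATIONAL, Function.ADMIN_MFP)] == 50

    def test_zero_factor_books_no_rh_admin(self):
        e = LedgerEntry(2012, "MFP", Decimal(100), Earmark.ADMIN_NATIONAL)
        cube = allocate_admin([e], F(0))
        assert cube.rh_total(2012) == 0
        assert cube.total(2012) == 100


class TestPipeline:
    def test_recovers_generator_ground_truth_exactly(self, scenario, pipeline_cube):
        assert pipeline_cube.cells == scenario.ground_truth.cells

    def test_conservation_per_agent_year_is_exact(self, scenario, pipeline_cube):
        residuals = conservation_audit(pipeline_cube, scenario.ledger, scenario.ctx)
        assert residuals and all(v == 0 for v in residuals.values())

    def test_earmarked_only_ledger_is_pure_pass_through(self, scenario):
        ledger = [earmarked(100, MH), earmarked(50, FP)]
        cube = run_pipeline(ledger, scenario.volumes, scenario.costs, scenario.ctx)
        factor = scenario.ctx.ppp_factor  # base-year entries: PPP division only
        assert cube.cells == {
            (2012, "MSPLS", PHC, MH): F(100) / factor,
            (2012, "MSPLS", PHC, FP): F(50) / factor,
        }

    def test_doubling_the_ledger_doubles_every_cell(self, scenario, pipeline_cube):
        doubled = [
            LedgerEntry(e.year, e.agent_id, e.amount * 2, e.earmark,
                        e.function_hint, e.tier_hint, e.category)
            for e in scenario.ledger
        ]
        cube2 = run_pipeline(doubled, scenario.volumes, scenario.costs, scenario.ctx)
        assert cube2.cells == {k: 2 * v for k, v in pipeline_cube.cells.items()}

    def test_stage_labels_on_errors(self, scenario):
        ledger = [LedgerEntry(2012, "MSPLS", Decimal(5), Earmark.FACILITY_NONEARMARKED)]
        with pytest.raises(AllocationError, match=r"strategy 2, year 2012"):
            run_pipeline(ledger, [], scenario.costs, scenario.ctx)

    def test_tier_weight_vector_sums_to_one(self, scenario):
        totals = estimate_tier_totals(scenario.volumes, scenario.costs, 2011)
        weights = tier_weights_from_totals(totals)
        assert sum(weights.values()) == 1
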