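"""Deterministic model core: hand-calculation oracles and exact identities.

The oracle values are recomputed here by independent brute-force routes
(root-finding for the annuity factor, literal arithmetic on the published
central values) rather than asserted as bare constants, so a transcription
slip in either side surfaces as a mismatch.
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st
from scipy.optimize import brentq

from stovecba import ModelConfig, Scenario, evaluate
from stovecba.model import (
    baseline_energy_and_fuel,
    candidate_fuel_use,
    capital_recovery_factor,
    environmental_benefits,
    fixed_costs,
    health_benefits,
    net_fuel_cost,
    time_savings,
)
from stovecba.sampler import sample

WOOD_ICS_SOCIAL = Scenario("wood_traditional", "wood_ics", perspective="social")
WOOD_ICS_PRIVATE = Scenario("wood_traditional", "wood_ics")
LPG_SOCIAL = Scenario("wood_traditional", "lpg", perspective="social")


def crf_oracle(rate: float, lifespan: int) -> float:
    """Payment whose discounted sum over the lifespan repays a unit loan."""
    def npv_gap(payment):
        return sum(payment / (1 + rate) ** t for t in range(1, lifespan + 1)) - 1.0
    return brentq(npv_gap, 1e-9, 10.0, xtol=1e-14)


class TestCapitalRecoveryFactor:
    def test_matches_npv_root_finding(self):
        got = capital_recovery_factor(0.045, 3)
        assert got == pytest.approx(crf_oracle(0.045, 3), rel=1e-6)
        assert got == pytest.approx(0.36377, abs=5e-6)
        assert capital_recovery_factor(0.15, 3) == pytest.approx(
            crf_oracle(0.15, 3), rel=1e-6
        )

    @given(delta=st.floats(0.001, 0.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_single_period_repays_principal_plus_interest(self, delta):
        assert capital_recovery_factor(delta, 1) == pytest.approx(1 + delta)

    @pytest.mark.parametrize("lifespan", [1, 3, 10])
    def test_zero_rate_is_straight_line(self, lifespan):
        assert capital_recovery_factor(0.0, lifespan) == pytest.approx(1 / lifespan)

    def test_zero_lifespan_rejected(self):
        with pytest.raises(ValueError, match="lifespan"):
            capital_recovery_factor(0.045, 0)

    def test_vectorized_over_draws(self):
        rates = np.array([0.0, 0.045, 0.15])
        out = capital_recovery_factor(rates, np.array([4, 3, 3]))
        assert out[0] == pytest.approx(0.25)
        assert out[1] == pytest.approx(crf_oracle(0.045, 3))


class TestFuelQuantities:
    def test_wood_baseline_mass_and_useful_energy(self, catalog, mid):
        kg, mj = baseline_energy_and_fuel(catalog, mid, WOOD_ICS_SOCIAL)
        assert kg == pytest.approx(3 * 0.6 * 30, rel=1e-6)        # 54 kg
        assert mj == pytest.approx(54 * 16 * 0.11, rel=1e-6)      # 95.04 MJ

    def test_no_cooking_no_fuel(self, catalog, mid):
        d = dict(mid, baseline_cooking_time=0.0)
        kg, mj = baseline_energy_and_fuel(catalog, d, WOOD_ICS_SOCIAL)
        assert kg == 0.0 and mj == 0.0

    def test_candidate_scales_by_energy_and_efficiency(self, catalog, mid):
        assert candidate_fuel_use(catalog, mid, WOOD_ICS_SOCIAL) == pytest.approx(
            54 * (0.11 / 0.25), rel=1e-6                           # 23.76 kg
        )
        assert candidate_fuel_use(catalog, mid, LPG_SOCIAL) == pytest.approx(
            95.04 / (45 * 0.55), rel=1e-6                          # ~3.84 kg
        )

    def test_equal_useful_heat_rate_gives_identical_use(self, catalog, mid):
        # candidate with mu_i * eps_fi == mu_0 * eps_f0 burns the same mass
        d = dict(mid)
        d["charcoal_ics.heat_efficiency"] = (
            mid["fuel.wood.energy_content"]
            * mid["wood_traditional.heat_efficiency"]
            / mid["fuel.charcoal.energy_content"]
        )
        sc = Scenario("wood_traditional", "charcoal_ics")
        base, _ = baseline_energy_and_fuel(catalog, d, sc)
        assert candidate_fuel_use(catalog, d, sc) == pytest.approx(base, rel=1e-12)

    def test_charcoal_baseline_by_useful_energy_equivalence(self, catalog, mid):
        sc = Scenario("charcoal_traditional", "charcoal_ics")
        kg, mj = baseline_energy_and_fuel(catalog, mid, sc)
        assert mj == pytest.approx(95.04, rel=1e-6)
        assert kg == pytest.approx(95.04 / (30 * 0.20), rel=1e-6)

    def test_electric_use_is_per_cooking_hour(self, catalog, mid):
        sc = Scenario("wood_traditional", "electric")
        kwh = candidate_fuel_use(catalog, mid, sc)
        assert kwh == pytest.approx(3 * 0.63 * 30 * 1.65, rel=1e-6)


class TestNetFuelCost:
    def test_wood_ics_literal_arithmetic(self, catalog, mid):
        # C0 = f*p0*F0 + collt*days*vt*w; Ci adds prep and scales collection
        c0 = 0.25 * 0.12 * 54 + 1.0 * 30 * 0.3 * 0.2
        ci = (
            0.25 * 0.12 * 23.76
            + 1.0 * (23.76 / 54) * 30 * 0.3 * 0.2
            + 0.33 * 30 * 0.3 * 0.2
        )
        expected = 0.5 * (ci - c0)
        got = net_fuel_cost(catalog, mid, WOOD_ICS_PRIVATE)
        assert got == pytest.approx(expected, rel=1e-6)
        assert got == pytest.approx(-0.6606, abs=1e-4)

    def test_no_use_no_net_change(self, catalog, mid):
        d = dict(mid, sustained_use=0.0)
        assert net_fuel_cost(catalog, d, WOOD_ICS_PRIVATE) == 0.0

    def test_identity_stove_costs_nothing(self, catalog, mid):
        # clone the charcoal baseline into the candidate: same fuel bill
        d = dict(mid)
        sc = Scenario("charcoal_traditional", "charcoal_ics")
        d["charcoal_ics.heat_efficiency"] = d["charcoal_traditional.heat_efficiency"]
        for chi in (0.2, 0.9):
            d["sustained_use"] = chi
            assert net_fuel_cost(catalog, d, sc) == pytest.approx(0.0, abs=1e-12)

    def test_purchased_fuel_candidates_have_pure_money_cost(self, catalog, mid):
        sc = Scenario("wood_traditional", "kerosene")
        qty = candidate_fuel_use(catalog, mid, sc)
        c0 = 0.25 * 0.12 * 54 + 1.0 * 30 * 0.3 * 0.2
        expected = 0.5 * (0.5 * qty - c0)
        assert net_fuel_cost(catalog, mid, sc) == pytest.approx(expected, rel=1e-12)


class TestFixedCosts:
    def test_private_capital_annualized(self, catalog, mid):
        cap, prog, om, learn = fixed_costs(catalog, mid, WOOD_ICS_PRIVATE)
        assert cap == pytest.approx(15 * crf_oracle(0.15, 3) / 12, rel=1e-6)
        assert prog == pytest.approx(2.0 / 12, rel=1e-12)
        assert om == pytest.approx(0.5 * 1.4 / 12, rel=1e-12)
        assert learn == 0.0

    def test_full_subsidy_zeroes_private_capital(self, catalog, mid):
        sc = dataclasses.replace(WOOD_ICS_PRIVATE, capital_subsidy_fraction=1.0)
        cap, *_ = fixed_costs(catalog, mid, sc)
        assert cap == 0.0

    def test_social_perspective_ignores_subsidy(self, catalog, mid):
        sc = dataclasses.replace(WOOD_ICS_SOCIAL, capital_subsidy_fraction=1.0)
        cap, *_ = fixed_costs(catalog, mid, sc)
        assert cap == pytest.approx(15 * crf_oracle(0.045, 3) / 12, rel=1e-6)

    def test_learning_time_annualized_like_capital(self, catalog, mid):
        cat = dataclasses.replace(catalog, learning_hours=10.0)
        *_, learn = fixed_costs(cat, mid, WOOD_ICS_PRIVATE)
        assert learn == pytest.approx(10 * 0.3 * 0.2 * crf_oracle(0.15, 3) / 12,
                                      rel=1e-6)


class TestHealthBenefits:
    def test_ari_morbidity_term(self, catalog, mid):
        d = dict(mid)
        d["wood_ics.copd_effectiveness"] = 0.0   # isolate the ARI term
        morb, _ = health_benefits(catalog, d, WOOD_ICS_SOCIAL)
        assert morb == pytest.approx(0.5 * 5 * 0.5 * 0.4 * 15 / 12, rel=1e-6)

    def test_copd_morbidity_discounted_by_onset_delay(self, catalog, mid):
        d = dict(mid)
        d["wood_ics.ari_effectiveness"] = 0.0
        morb, _ = health_benefits(catalog, d, WOOD_ICS_PRIVATE)
        expected = 0.5 * 5 * 0.045 * 0.15 * 35 / (1.15 ** 15) / 12
        assert morb == pytest.approx(expected, rel=1e-6)
        assert morb == pytest.approx(0.0061, abs=2e-4)

    def test_no_effectiveness_no_benefit(self, catalog, mid):
        d = dict(mid)
        d["wood_ics.ari_effectiveness"] = 0.0
        d["wood_ics.copd_effectiveness"] = 0.0
        morb, mort = health_benefits(catalog, d, WOOD_ICS_SOCIAL)
        assert morb == 0.0 and mort == 0.0

    def test_mortality_scales_with_configured_risk_pool(self, catalog, mid):
        base = health_benefits(
            catalog, mid, WOOD_ICS_SOCIAL, ModelConfig(mortality_risk_multiplier=1.0)
        )[1]
        half = health_benefits(
            catalog, mid, WOOD_ICS_SOCIAL, ModelConfig(mortality_risk_multiplier=0.5)
        )[1]
        assert half == pytest.approx(base / 2, rel=1e-12)
        with_hh = health_benefits(
            catalog, mid, WOOD_ICS_SOCIAL,
            ModelConfig(mortality_includes_hhsize=True, mortality_risk_multiplier=1.0),
        )[1]
        assert with_hh == pytest.approx(base * mid["household_size"], rel=1e-12)

    def test_incremental_effectiveness_for_charcoal_transition(self, catalog, mid):
        morb, _ = health_benefits(
            catalog, mid, Scenario("charcoal_traditional", "charcoal_ics")
        )
        # only the 0.4 - 0.2 ARI and 0.15 - 0.05 COPD increments count
        expected = (
            0.5 * 5 * (0.5 * (0.4 - 0.2) * 15
                       + 0.045 * (0.15 - 0.05) * 35 / 1.15 ** 15) / 12
        )
        assert morb == pytest.approx(expected, rel=1e-6)


class TestTimeSavings:
    def test_lpg_at_central_values(self, catalog, mid):
        assert time_savings(catalog, mid, LPG_SOCIAL) == pytest.approx(
            0.5 * 3 * (1 - 0.67) * 30 * 0.3 * 0.2, rel=1e-6
        )

    def test_equal_time_efficiency_saves_nothing(self, catalog, mid):
        d = dict(mid)
        d["wood_ics.time_efficiency"] = 1.0
        assert time_savings(catalog, d, WOOD_ICS_SOCIAL) == 0.0

    def test_slower_stove_costs_time(self, catalog, mid):
        d = dict(mid)
        d["wood_ics.time_efficiency"] = 1.5
        assert time_savings(catalog, d, WOOD_ICS_SOCIAL) < 0.0


class TestEnvironmentalBenefits:
    def test_wood_baseline_emissions_magnitude(self, catalog, mid):
        carb, _ = environmental_benefits(catalog, mid, WOOD_ICS_SOCIAL)
        e0 = 54 * 16 * 12.1                     # ~10,454 g CO2-eq/month
        e1 = 23.76 * 16 * 12.1
        assert carb == pytest.approx(20 * 0.5 * (e0 - e1) / 1e6, rel=1e-6)

    def test_lpg_bio_credit_is_avoided_wood_mass(self, catalog, mid):
        _, bio = environmental_benefits(catalog, mid, LPG_SOCIAL)
        assert bio == pytest.approx(0.01 * 0.5 * 54, rel=1e-6)     # 0.27

    def test_identity_candidate_has_no_environmental_effect(self, catalog, mid):
        d = dict(mid)
        d["charcoal_ics.heat_efficiency"] = d["charcoal_traditional.heat_efficiency"]
        carb, bio = environmental_benefits(
            catalog, d, Scenario("charcoal_traditional", "charcoal_ics")
        )
        assert carb == pytest.approx(0.0, abs=1e-12)
        assert bio == 0.0

    def test_useful_energy_basis_scales_by_efficiency(self, catalog, mid):
        cfg = ModelConfig(gamma_basis="useful")
        carb, _ = environmental_benefits(catalog, mid, WOOD_ICS_SOCIAL, cfg)
        e0 = 54 * 16 * 0.11 * 12.1
        e1 = 23.76 * 16 * 0.25 * 12.1
        assert carb == pytest.approx(20 * 0.5 * (e0 - e1) / 1e6, rel=1e-6)

    def test_extended_accounting_uses_footnote_intensities(self, catalog, mid):
        sc = dataclasses.replace(WOOD_ICS_SOCIAL, accounting="extended")
        carb, _ = environmental_benefits(catalog, mid, sc)
        assert carb == pytest.approx(
            20 * 0.5 * (54 - 23.76) * 16 * 225 / 1e6, rel=1e-6
        )


class TestEvaluate:
    def test_zero_use_leaves_only_fixed_costs(self, catalog, mid):
        d = dict(mid, sustained_use=0.0)
        bd = evaluate(catalog, d, WOOD_ICS_PRIVATE)
        assert bd.net == pytest.approx(-(bd.cap + bd.prog + bd.learn), rel=1e-12)

    def test_social_equals_private_plus_environment_at_common_rate(
        self, catalog, draws10k
    ):
        m = draws10k.as_mapping()
        m_social_rate = dict(m, discount_rate_private=m["discount_rate_social"])
        social = evaluate(catalog, m_social_rate, WOOD_ICS_SOCIAL)
        private = evaluate(catalog, m_social_rate, WOOD_ICS_PRIVATE)
        np.testing.assert_allclose(
            social.net, private.net + social.carb + social.bio, rtol=0, atol=1e-10
        )

    def test_offset_transfer_adds_carbon_only(self, catalog, mid):
        plain = evaluate(catalog, mid, WOOD_ICS_PRIVATE)
        offset = evaluate(
            catalog, mid,
            dataclasses.replace(WOOD_ICS_PRIVATE, carbon_offset_transfer=True),
        )
        assert offset.net - plain.net == pytest.approx(plain.carb, rel=1e-12)
        assert plain.bio != 0.0  # bio exists but is never transferred privately

    @given(chi=st.floats(0.05, 0.95), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_net_is_affine_in_sustained_use(self, catalog, chi, seed):
        d = sample(catalog, 2, seed).draw(0)
        nets = []
        for x in (0.0, chi, 1.0):
            d["sustained_use"] = x
            nets.append(evaluate(catalog, d, WOOD_ICS_SOCIAL).net)
        interp = nets[0] + chi * (nets[2] - nets[0])
        assert nets[1] == pytest.approx(interp, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize(
        "symbol,direction",
        [
            ("wood_ics.capital_cost", -1),
            ("fuel.wood.price", +1),   # candidate burns less purchased wood
            ("coi_ari", +1),
            ("ari_incidence", +1),
        ],
    )
    def test_net_monotone_in_key_drivers(self, catalog, mid, symbol, direction):
        lo_draw, hi_draw = dict(mid), dict(mid)
        rng = catalog.parameter_ranges()[symbol]
        lo_draw[symbol], hi_draw[symbol] = rng.low, rng.high
        lo = evaluate(catalog, lo_draw, WOOD_ICS_PRIVATE).net
        hi = evaluate(catalog, hi_draw, WOOD_ICS_PRIVATE).net
        assert direction * (hi - lo) > 0

    def test_candidate_fuel_price_raises_costs(self, catalog, mid):
        sc = Scenario("wood_traditional", "kerosene")
        lo_draw, hi_draw = dict(mid), dict(mid)
        rng = catalog.parameter_ranges()["fuel.kerosene.price"]
        lo_draw["fuel.kerosene.price"], hi_draw["fuel.kerosene.price"] = rng.low, rng.high
        assert evaluate(catalog, hi_draw, sc).net < evaluate(catalog, lo_draw, sc).net

    def test_fuel_and_time_terms_take_both_signs_within_ranges(
        self, catalog, draws10k
    ):
        bd = evaluate(catalog, draws10k.as_mapping(), WOOD_ICS_PRIVATE)
        assert np.min(bd.fuel_net) < 0 < np.max(bd.fuel_net)
        assert np.min(bd.timesav) < 0 < np.max(bd.timesav)


class TestScenarioValidation:
    def test_charcoal_baseline_restricted(self):
        with pytest.raises(ValueError, match="charcoal_ics"):
            Scenario("charcoal_traditional", "lpg")

    def test_candidate_must_differ(self):
        with pytest.raises(ValueError, match="differ"):
            Scenario("wood_traditional", "wood_traditional")

    def test_unknown_accounting_rejected(self):
        with pytest.raises(ValueError, match="accounting"):
            Scenario("wood_traditional", "lpg", accounting="full")
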