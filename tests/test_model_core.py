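"""Decision-tree core: expected utilities, the evidence-based utility
parameterization, and the Monte-Carlo oracle."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxthreshold import (
    DomainError,
    EbmScenario,
    InvalidScenarioError,
    UtilityQuadruple,
    classic_threshold,
    ebm_probability_threshold,
    expected_utility_notreat,
    expected_utility_treat,
    generate_scenarios,
    mc_expected_utility,
    net_benefit,
    net_harm,
    utilities_from_ebm,
)


class TestUtilityQuadruple:
    def test_rejects_out_of_range_utility(self):
        with pytest.raises(DomainError, match="outside"):
            UtilityQuadruple(1.2, 0.9, 0.4, 1.0)
        with pytest.raises(DomainError):
            UtilityQuadruple(0.8, 0.9, -0.1, 1.0)

    def test_rejects_non_finite(self):
        with pytest.raises(DomainError, match="finite"):
            UtilityQuadruple(float("nan"), 0.9, 0.4, 1.0)


class TestExpectedUtility:
    @pytest.mark.parametrize("p, expected_rx, expected_norx", [
        (0.0, 0.9, 1.0),    # no-disease branch only
        (1.0, 0.8, 0.4),    # disease branch only
        (0.5, 0.85, 0.70),  # hand arithmetic
    ])
    def test_branch_weighting(self, simple_quadruple, p, expected_rx,
                              expected_norx):
        assert expected_utility_treat(p, simple_quadruple) == pytest.approx(
            expected_rx, abs=1e-15)
        assert expected_utility_notreat(p, simple_quadruple) == pytest.approx(
            expected_norx, abs=1e-15)

    @pytest.mark.parametrize("p", [-0.01, 1.01])
    def test_rejects_invalid_probability(self, simple_quadruple, p):
        with pytest.raises(DomainError):
            expected_utility_treat(p, simple_quadruple)
        with pytest.raises(DomainError):
            expected_utility_notreat(p, simple_quadruple)

    @settings(derandomize=True, max_examples=100)
    @given(p=st.floats(0.0, 1.0),
           us=st.tuples(*[st.floats(0.0, 1.0) for _ in range(4)]))
    def test_linearity_in_p(self, p, us):
        """EU at p is the p-weighted average of EU at the endpoints."""
        u = UtilityQuadruple(*us)
        for eu in (expected_utility_treat, expected_utility_notreat):
            blended = p * eu(1.0, u) + (1.0 - p) * eu(0.0, u)
            assert eu(p, u) == pytest.approx(blended, abs=1e-15)


class TestNetBenefitHarm:
    def test_simple_differences(self, simple_quadruple):
        assert net_benefit(simple_quadruple) == pytest.approx(0.4)
        assert net_harm(simple_quadruple) == pytest.approx(0.1)

    def test_degenerate_zero(self):
        u = UtilityQuadruple(0.6, 0.7, 0.6, 0.7)
        assert net_benefit(u) == 0.0
        assert net_harm(u) == 0.0

    def test_einstein_quadruple_reduces_to_effect_algebra(
            self, einstein_scenario):
        """B = M*RRR - RV_H*H_rx and H = RV_H*H_rx on the reconstructed
        utilities."""
        u = utilities_from_ebm(einstein_scenario)
        assert net_benefit(u) == pytest.approx(
            0.071 * 0.812 - 0.048, abs=1e-12)
        assert net_benefit(u) == pytest.approx(0.0097, abs=5e-5)
        assert net_harm(u) == pytest.approx(0.048, abs=1e-12)


class TestUtilitiesFromEbm:
    def test_no_disutility_anywhere(self):
        s = EbmScenario(baseline_risk=0.0, rrr=0.5, harm_rx=0.0)
        u = utilities_from_ebm(s)
        assert u == UtilityQuadruple(1.0, 1.0, 1.0, 1.0)

    def test_einstein_values(self, einstein_scenario):
        u = utilities_from_ebm(einstein_scenario)
        assert u.u_notreat_disease == pytest.approx(0.929)
        assert u.u_notreat_nodisease == 1.0
        assert u.u_treat_nodisease == pytest.approx(0.952)
        assert u.u_treat_disease == pytest.approx(0.9387, abs=5e-5)

    def test_fully_preventable_harmless_treatment(self):
        s = EbmScenario(baseline_risk=0.3, rrr=1.0, harm_rx=0.0)
        assert utilities_from_ebm(s).u_treat_disease == 1.0

    def test_rejects_negative_utility_instead_of_clamping(self):
        s = EbmScenario(baseline_risk=0.9, rrr=0.05, harm_rx=0.9,
                        rv_harm=1.5)
        with pytest.raises(InvalidScenarioError, match="u_treat"):
            utilities_from_ebm(s)


class TestScenarioValidation:
    def test_requires_one_effect_parameter(self):
        with pytest.raises(ValueError, match="treated_risk or rrr"):
            EbmScenario(baseline_risk=0.1, harm_rx=0.05)

    def test_consistent_risks_and_rrr_accepted(self):
        s = EbmScenario(baseline_risk=0.2, treated_risk=0.1, rrr=0.5,
                        harm_rx=0.0)
        assert s.relative_risk_reduction == 0.5

    def test_inconsistent_risks_and_rrr_rejected(self):
        with pytest.raises(ValueError, match="implies RRR"):
            EbmScenario(baseline_risk=0.2, treated_risk=0.1, rrr=0.7,
                        harm_rx=0.0)

    def test_derivations_match_each_direction(self):
        from_risks = EbmScenario(baseline_risk=0.2, treated_risk=0.05,
                                 harm_rx=0.0)
        from_rrr = EbmScenario(baseline_risk=0.2, rrr=0.75, harm_rx=0.0)
        assert from_risks.relative_risk_reduction == pytest.approx(
            0.75, abs=1e-12)
        assert from_rrr.treated_risk_value == pytest.approx(0.05, abs=1e-12)

    def test_dependent_regime_forces_certain_disease(
            self, einstein_dependent):
        assert einstein_dependent.effective_disease_prob == 1.0


def test_classic_threshold_equals_ebm_form_on_reconstructed_utilities():
    """Algebraic identity: H/(B+H) on the reconstructed quadruple equals
    RV_H*H_rx/(RRR*M), across 1,000 random scenarios."""
    for s in generate_scenarios(1000, seed=20260928):
        if s.rv_harm * s.harm_rx == 0.0:
            continue
        u = utilities_from_ebm(s)
        generic = classic_threshold(net_benefit(u), net_harm(u))
        ebm = ebm_probability_threshold(
            s.rv_harm, s.harm_rx, s.relative_risk_reduction, s.baseline_risk)
        if generic.value is None:  # negative net benefit: both never-treat
            assert ebm.never_treat
            continue
        assert generic.value == pytest.approx(ebm.value, abs=1e-12)


class TestMonteCarlo:
    def test_no_disease_no_treatment_is_certain_health(
            self, einstein_scenario):
        est = mc_expected_utility(einstein_scenario, "notreat", 0.0,
                                  n=1000, seed=1)
        assert est.mean_utility == 1.0
        assert est.std_error == 0.0

    @pytest.mark.parametrize("arm, closed_form", [
        ("notreat", 0.929),              # U3 at certain disease
        ("treat", 1 - 0.071 * (1 - 0.812) - 0.048),  # U1
    ])
    def test_matches_closed_form_at_certain_disease(
            self, einstein_scenario, arm, closed_form):
        est = mc_expected_utility(einstein_scenario, arm, 1.0,
                                  n=200_000, seed=7)
        assert abs(est.mean_utility - closed_form) < 4 * est.std_error

    def test_same_seed_reproduces(self, einstein_scenario):
        a = mc_expected_utility(einstein_scenario, "treat", 0.4, 5000, 99)
        b = mc_expected_utility(einstein_scenario, "treat", 0.4, 5000, 99)
        assert a == b

    def test_standard_error_shrinks_like_sqrt_n(self, einstein_scenario):
        small = mc_expected_utility(einstein_scenario, "treat", 0.5,
                                    20_000, 3)
        large = mc_expected_utility(einstein_scenario, "treat", 0.5,
                                    80_000, 4)
        # quadrupling n should halve the SE, within sampling noise
        assert large.std_error == pytest.approx(small.std_error / 2,
                                                rel=0.15)

    def test_coverage_of_closed_form_across_seeds(self, einstein_scenario):
        """The 4-SE interval covers the closed-form EU in >= 99 of 100
        seeded runs."""
        from rxthreshold import expected_utility_treat, utilities_from_ebm
        u = utilities_from_ebm(einstein_scenario)
        p = 0.3
        truth = expected_utility_treat(p, u)
        hits = 0
        for seed in range(100):
            est = mc_expected_utility(einstein_scenario, "treat", p,
                                      20_000, seed)
            hits += abs(est.mean_utility - truth) < 4 * est.std_error
        assert hits >= 99

    def test_invalid_arm_and_n(self, einstein_scenario):
        with pytest.raises(DomainError, match="arm"):
            mc_expected_utility(einstein_scenario, "placebo", 0.5, 10, 0)
        with pytest.raises(DomainError, match="n must"):
            mc_expected_utility(einstein_scenario, "treat", 0.5, 0, 0)
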