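"""Covariate encoding, PRS, family-history attenuation, linear predictor."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcrisk.cohort import Cohort
from bcrisk.relative_risk import (
    CoefficientError,
    CoefficientSet,
    GeneticEffect,
    ModelVariant,
    NotImputedError,
    SnvWeight,
    adjust_family_history,
    combine_hybrid_prs,
    compute_prs,
    default_coefficients,
    encode_cohort,
    encode_covariates,
    linear_predictor,
    linear_predictors,
    polygenic_attenuation,
)

from conftest import complete_row, make_cohort_frame


def _profile(**overrides):
    df = make_cohort_frame([complete_row("p", 0, 40.0, **overrides)])
    return Cohort(df, imputed=True).profile(0)


class TestEncoding:
    @pytest.mark.parametrize(
        "parity,first,additional",
        [(0, 0.0, 0.0), (1, 1.0, 0.0), (4, 1.0, 3.0)],
    )
    def test_parity_spline(self, parity, first, additional):
        terms = encode_covariates(_profile(parity=parity))
        assert terms["first_live_birth"] == first
        assert terms["additional_live_births"] == additional

    def test_height_per_10cm_centered_at_160(self):
        assert encode_covariates(_profile(height_cm=170.0))["height_per_10cm"] == 1.0

    @pytest.mark.parametrize(
        "bmi,expected",
        [
            (17.0, "bmi_under_18_5"),
            (18.5, None),
            (24.9, None),
            (25.0, "bmi_25_29_9"),
            (29.99, "bmi_25_29_9"),
            (30.0, "bmi_30_plus"),
        ],
    )
    def test_bmi_category_indicators(self, bmi, expected):
        terms = encode_covariates(_profile(bmi=bmi))
        indicators = {k: v for k, v in terms.items() if k.startswith("bmi_")}
        assert sum(indicators.values()) == (0 if expected is None else 1)
        if expected:
            assert indicators[expected] == 1.0

    def test_unimputed_profile_rejected(self):
        p = _profile()
        broken = p.__class__(**{**p.__dict__, "bmi": float("nan")})
        with pytest.raises(NotImputedError, match="bmi"):
            encode_covariates(broken)

    @given(p=st.floats(min_value=0.0, max_value=15.0))
    @settings(deadline=None, max_examples=50)
    def test_parity_contribution_continuous_at_knot(self, p):
        """The spline contribution approaches the p=1 value from above."""
        betas = default_coefficients().epi
        terms = encode_covariates(_profile(parity=max(p, 1.0)))
        at_knot = encode_covariates(_profile(parity=1.0))
        contrib = (
            terms["first_live_birth"] * betas["first_live_birth"]
            + terms["additional_live_births"] * betas["additional_live_births"]
        )
        knot_contrib = at_knot["first_live_birth"] * betas["first_live_birth"]
        assert contrib == pytest.approx(
            knot_contrib + max(p - 1.0, 0.0) * betas["additional_live_births"]
        )

    def test_vectorized_encoding_matches_per_profile(self, small_cohort):
        enc = encode_cohort(small_cohort)
        for i in range(len(small_cohort)):
            single = encode_covariates(small_cohort.profile(i))
            for term, value in single.items():
                assert enc.iloc[i][term] == pytest.approx(value)


class TestPrs:
    W = {
        "v1": SnvWeight(0.1, 0.2),
        "v2": SnvWeight(-0.2, 0.5),
        "v3": SnvWeight(0.3, 0.1),
    }

    def test_zero_weights_give_zero(self):
        w = {k: SnvWeight(0.0, v.freq) for k, v in self.W.items()}
        assert compute_prs({"v1": 2, "v2": 1, "v3": 0}, w) == 0.0

    def test_hand_dot_product(self):
        assert compute_prs({"v1": 0, "v2": 1, "v3": 2}, self.W) == pytest.approx(0.4)

    def test_linearity_in_weights(self):
        d = {"v1": 1, "v2": 2, "v3": 0.5}
        doubled = {k: SnvWeight(2 * v.beta, v.freq) for k, v in self.W.items()}
        assert compute_prs(d, doubled) == pytest.approx(2 * compute_prs(d, self.W))

    def test_dosage_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="v1"):
            compute_prs({"v1": 2.5, "v2": 0, "v3": 0}, self.W)

    def test_absent_variant_imputed_at_population_mean(self):
        got = compute_prs({"v1": 1, "v2": 1}, self.W)
        assert got == pytest.approx(0.1 - 0.2 + 2 * 0.1 * 0.3)

    def test_strict_mode_rejects_absent_variants(self):
        with pytest.raises(KeyError, match="v3"):
            compute_prs({"v1": 1, "v2": 1}, self.W, on_missing="strict")

    def test_order_invariance(self):
        d = {"v3": 1.0, "v1": 2.0, "v2": 0.0}
        shuffled = dict(reversed(list(self.W.items())))
        assert compute_prs(d, shuffled) == pytest.approx(compute_prs(d, self.W))


class TestHybridPrs:
    def test_degenerate_weight_returns_erpos(self):
        assert combine_hybrid_prs(0.7, -0.1, 1.0) == pytest.approx(0.7)

    def test_midpoint(self):
        assert combine_hybrid_prs(0.2, 0.4, 0.5) == pytest.approx(0.3)

    @given(w=st.floats(min_value=0, max_value=1), s=st.floats(-2, 2))
    @settings(deadline=None, max_examples=50)
    def test_equal_subtype_scores_fixed_point(self, w, s):
        assert combine_hybrid_prs(s, s, w) == pytest.approx(s)

    def test_weight_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_hybrid_prs(0.2, 0.4, 1.2)


class TestFamilyHistoryAttenuation:
    def test_no_genetic_terms_leaves_fh_unchanged(self, coeffs):
        adj = adjust_family_history(coeffs, ModelVariant.EPI_ONLY)
        assert adj.adjusted_family_history == coeffs.family_history

    def test_single_variant_magnitude(self):
        cs = CoefficientSet(
            epi={"family_history": 0.47},
            snv_weights={"v": SnvWeight(0.2, 0.5)},
        )
        adj = adjust_family_history(cs, ModelVariant.COMBINED)
        assert adj.adjusted_family_history == pytest.approx(0.46)

    def test_adding_variants_never_increases(self, coeffs):
        base = adjust_family_history(coeffs, ModelVariant.COMBINED)
        more = adjust_family_history(
            coeffs, ModelVariant.COMBINED, prs_variance=0.314**2
        )
        assert more.adjusted_family_history <= base.adjusted_family_history

    def test_floored_at_zero(self):
        cs = CoefficientSet(
            epi={"family_history": 0.01},
            snv_weights={"v": SnvWeight(2.0, 0.5)},
        )
        adj = adjust_family_history(cs, ModelVariant.COMBINED)
        assert adj.adjusted_family_history == 0.0

    def test_idempotent_and_order_independent(self, coeffs):
        once = adjust_family_history(coeffs, ModelVariant.COMBINED)
        twice = adjust_family_history(once, ModelVariant.COMBINED)
        assert twice.adjusted_family_history == once.adjusted_family_history
        # re-adjusting for a different variant starts from the unadjusted FH
        epi_then_combined = adjust_family_history(
            adjust_family_history(coeffs, ModelVariant.EPI_ONLY), ModelVariant.COMBINED
        )
        assert (
            epi_then_combined.adjusted_family_history == once.adjusted_family_history
        )

    def test_prs_variance_route_equals_snv_route_for_independent_snvs(self):
        """Var(PRS) = sum 2 f (1-f) beta^2 makes the two accountings agree."""
        snvs = {f"v{i}": SnvWeight(0.1 * (i + 1), 0.1 * (i + 1)) for i in range(5)}
        var_prs = sum(2 * w.freq * (1 - w.freq) * w.beta**2 for w in snvs.values())
        via_snvs = polygenic_attenuation(
            CoefficientSet(epi={"family_history": 1.0}, snv_weights=snvs),
            ModelVariant.PRS_ONLY,
        )
        via_score = polygenic_attenuation(
            CoefficientSet(epi={"family_history": 1.0}, prs_coefficient=1.0),
            ModelVariant.PRS_ONLY,
            prs_variance=var_prs,
        )
        assert via_score == pytest.approx(via_snvs)

    def test_frequency_required_for_genetic_terms(self):
        with pytest.raises(CoefficientError, match="v"):
            CoefficientSet(
                epi={"family_history": 0.5},
                snv_weights={"v": SnvWeight(0.2, float("nan"))},
            )


class TestLinearPredictor:
    def test_reference_profile_scores_zero(self, coeffs):
        adj = adjust_family_history(coeffs, ModelVariant.COMBINED)
        assert linear_predictor(_profile(), adj, ModelVariant.COMBINED) == 0.0

    def test_prs_only_single_term(self):
        cs = adjust_family_history(
            CoefficientSet(epi={"family_history": 0.4}, prs_coefficient=1.2),
            ModelVariant.PRS_ONLY,
        )
        assert linear_predictor(
            _profile(prs=0.5), cs, ModelVariant.PRS_ONLY
        ) == pytest.approx(0.6)

    def test_combined_is_sum_of_disjoint_blocks(self, coeffs):
        adj = adjust_family_history(coeffs, ModelVariant.COMBINED, prs_variance=0.1)
        p = _profile(
            parity=3, bmi=31.0, family_history=1.0, prs=0.4, pv_BRCA1=1.0, alcohol=1.0
        )
        combined = linear_predictor(p, adj, ModelVariant.COMBINED)
        # epi block evaluated with the attenuated FH coefficient
        epi_terms = encode_covariates(p, adj.centering)
        epi_with_adj_fh = sum(
            v * (adj.adjusted_family_history if t == "family_history" else adj.epi[t])
            for t, v in epi_terms.items()
        )
        genetic = linear_predictor(p, adj, ModelVariant.PRS_PLUS_PV)
        assert combined == pytest.approx(epi_with_adj_fh + genetic)

    def test_genetic_variant_requires_prior_attenuation(self, coeffs):
        with pytest.raises(CoefficientError, match="adjust_family_history"):
            linear_predictor(_profile(prs=0.1), coeffs, ModelVariant.COMBINED)

    def test_epi_only_uses_unadjusted_fh(self, coeffs):
        p = _profile(family_history=1.0)
        lp = linear_predictor(p, coeffs, ModelVariant.EPI_ONLY)
        assert lp == pytest.approx(coeffs.family_history)

    def test_carrier_without_coefficient_named(self):
        cs = adjust_family_history(
            CoefficientSet(epi={"family_history": 0.4}, prs_coefficient=1.0),
            ModelVariant.PRS_PLUS_PV,
        )
        with pytest.raises(CoefficientError, match="BRCA1"):
            linear_predictor(
                _profile(prs=0.0, pv_BRCA1=1.0), cs, ModelVariant.PRS_PLUS_PV
            )

    def test_vectorized_matches_per_profile(self, small_cohort, coeffs):
        for variant in ModelVariant:
            adj = adjust_family_history(coeffs, variant, prs_variance=0.1)
            vec = linear_predictors(small_cohort, adj, variant)
            for i in range(len(small_cohort)):
                assert vec[i] == pytest.approx(
                    linear_predictor(small_cohort.profile(i), adj, variant)
                )


class TestCoefficientIO:
    def test_round_trip(self, tmp_path, coeffs):
        path = tmp_path / "coeffs.csv"
        coeffs.to_csv(path)
        back = CoefficientSet.from_csv(path)
        assert back.epi == dict(coeffs.epi)
        assert back.prs_coefficient == coeffs.prs_coefficient
        for gene, eff in coeffs.pv.items():
            assert back.pv[gene].beta == pytest.approx(eff.beta)
            assert back.pv[gene].freq == pytest.approx(eff.freq)
        assert back.centering == dict(coeffs.centering)
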