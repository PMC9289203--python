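"""Causal-effect estimators: published values, closed-form reductions and
independent weighted-least-squares oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import cecmr
from cecmr import (
    CollinearityError,
    DegenerateInstrumentError,
    HarmonizedInstrument,
    InsufficientInstrumentsError,
    ivw,
    mr_egger,
    multivariable_ivw,
    simple_median,
    wald_ratio,
    weighted_median,
)
from cecmr.estimators import weighted_median_point


def make_inst(snp="rs1", bx=0.2, sex=0.03, by=0.05, sey=0.02):
    return HarmonizedInstrument(snp_id=snp, beta_exposure=bx, se_exposure=sex,
                                beta_outcome=by, se_outcome=sey)


class TestWaldRatio:
    def test_published_cad_single_snp(self, single_snp_cad):
        """rs141622900 on CAD: ratio of the printed table entries."""
        est = wald_ratio(single_snp_cad)
        assert est.theta == pytest.approx(-0.50159, abs=5e-6)
        assert est.se == pytest.approx(0.09813, abs=5e-6)
        assert est.odds_ratio == pytest.approx(0.6055, abs=1e-4)

    def test_published_is_single_snp(self):
        (inst,) = cecmr.instrument_for("IS", cecmr.SINGLE_SNP)
        est = wald_ratio(inst)
        assert est.theta == pytest.approx(-0.20438, abs=5e-6)
        assert est.odds_ratio == pytest.approx(0.8152, abs=1e-4)

    def test_null_numerator(self):
        est = wald_ratio(make_inst(by=0.0))
        assert est.theta == 0.0 and est.odds_ratio == 1.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(make_inst(bx=0.0))

    def test_ci_and_or_consistency(self, single_snp_cad):
        est = wald_ratio(single_snp_cad)
        assert est.ci_low <= est.theta <= est.ci_high
        assert est.or_ci_low == pytest.approx(np.exp(est.ci_low))
        assert est.or_ci_high == pytest.approx(np.exp(est.ci_high))


class TestIVW:
    def test_published_five_snp_ors(self, cad_instruments, mi_instruments,
                                    is_instruments):
        """Five-SNP IVW odds ratios: CAD 0.85 (0.79-0.90), MI 0.86, IS 1.02."""
        cad = ivw(cad_instruments)
        assert round(cad.odds_ratio, 2) == 0.85
        assert (round(cad.or_ci_low, 2), round(cad.or_ci_high, 2)) == (0.79, 0.90)
        assert round(ivw(mi_instruments).odds_ratio, 2) == 0.86
        assert round(ivw(is_instruments).odds_ratio, 2) == 1.02

    def test_single_instrument_reduces_to_wald(self, single_snp_cad):
        assert ivw([single_snp_cad]).theta == pytest.approx(
            wald_ratio(single_snp_cad).theta, abs=1e-15)
        assert ivw([single_snp_cad]).se == pytest.approx(
            wald_ratio(single_snp_cad).se, abs=1e-15)

    def test_matches_through_origin_wls_oracle(self, cad_instruments):
        """Closed-form weight combination equals the through-origin WLS
        slope computed independently by statsmodels, to 1e-12."""
        bx = np.array([i.beta_exposure for i in cad_instruments])
        by = np.array([i.beta_outcome for i in cad_instruments])
        sey = np.array([i.se_outcome for i in cad_instruments])
        fit = sm.WLS(by, bx[:, None], weights=1.0 / sey**2).fit()
        assert ivw(cad_instruments).theta == pytest.approx(
            fit.params[0], abs=1e-12)

    def test_allele_relabel_invariance(self, cad_instruments):
        """Jointly negating one instrument's betas (relabelling its effect
        allele) must not change the estimate."""
        flipped = list(cad_instruments)
        i0 = flipped[0]
        flipped[0] = HarmonizedInstrument(
            snp_id=i0.snp_id, beta_exposure=-i0.beta_exposure,
            se_exposure=i0.se_exposure, beta_outcome=-i0.beta_outcome,
            se_outcome=i0.se_outcome)
        assert ivw(flipped).theta == pytest.approx(
            ivw(cad_instruments).theta, abs=1e-14)

    def test_multiplicative_model_inflates_under_heterogeneity(
            self, cad_instruments, is_instruments):
        # CAD shows strong heterogeneity (Q >> k-1): SE must inflate
        assert ivw(cad_instruments, "multiplicative").se > \
            ivw(cad_instruments, "fixed").se
        # IS has Q close to k-1: inflation bounded below by 1
        assert ivw(is_instruments, "multiplicative").se >= \
            ivw(is_instruments, "fixed").se
        assert ivw(is_instruments, "multiplicative").theta == \
            ivw(is_instruments, "fixed").theta

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ivw([])


class TestMREgger:
    def test_published_table5_cad_row(self, cad_instruments):
        """CAD: slope OR 0.35 (CI 0.14-0.89), intercept 0.156, upper CI
        0.319.  The lower intercept bound evaluates to -0.0064 (-0.006 at
        3 decimals); the published -0.007 matches only the symmetric
        half-width of the already-rounded display values."""
        fit = mr_egger(cad_instruments)
        assert round(fit.slope.odds_ratio, 2) == 0.35
        assert round(fit.slope.or_ci_low, 2) == 0.14
        assert round(fit.slope.or_ci_high, 2) == 0.89
        assert round(fit.intercept.value, 3) == 0.156
        assert fit.intercept.ci_low == pytest.approx(-0.0064, abs=5e-5)
        assert round(fit.intercept.ci_high, 3) == 0.319
        assert fit.intercept.ci_low <= fit.intercept.value <= fit.intercept.ci_high

    def test_matches_statsmodels_wls_oracle(self, cad_instruments):
        bx = np.array([i.beta_exposure for i in cad_instruments])
        by = np.array([i.beta_outcome for i in cad_instruments])
        sey = np.array([i.se_outcome for i in cad_instruments])
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sey**2).fit()
        ours = mr_egger(cad_instruments)
        assert ours.intercept.value == pytest.approx(fit.params[0], abs=1e-12)
        assert ours.slope.theta == pytest.approx(fit.params[1], abs=1e-12)
        assert ours.slope.se == pytest.approx(fit.bse[1], rel=1e-10)

    def test_exact_linear_fit_recovers_slope_zero_intercept(self):
        insts = [make_inst(snp=f"rs{i}", bx=b, by=0.4 * b, sey=0.01 + 0.001 * i)
                 for i, b in enumerate([0.1, 0.2, 0.3, 0.4])]
        fit = mr_egger(insts)
        assert fit.intercept.value == pytest.approx(0.0, abs=1e-12)
        assert fit.slope.theta == pytest.approx(0.4, abs=1e-12)

    def test_orientation_to_positive_exposure_effect(self):
        """Negating one instrument's betas jointly leaves Egger unchanged
        because instruments are re-oriented to betaX >= 0 before the fit."""
        by_vals = [0.05, 0.09, 0.10]  # not an exact linear fit
        insts = [make_inst(snp=f"rs{i}", bx=b, by=y, sey=0.02)
                 for i, (b, y) in enumerate(zip([0.1, 0.25, 0.4], by_vals))]
        flipped = list(insts)
        flipped[1] = make_inst(snp="rs1", bx=-0.25, by=-0.09, sey=0.02)
        assert mr_egger(flipped).slope.theta == pytest.approx(
            mr_egger(insts).slope.theta, abs=1e-12)

    def test_two_instruments_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger([make_inst(snp="rs1"), make_inst(snp="rs2")])


class TestMedians:
    def test_published_table5_cad_medians(self, cad_instruments):
        """CAD: simple median OR 0.78, weighted median OR 0.79."""
        sm_ = simple_median(cad_instruments, seed=0)
        wm = weighted_median(cad_instruments, seed=0)
        assert round(sm_.odds_ratio, 2) == 0.78
        assert round(wm.odds_ratio, 2) == 0.79

    def test_interpolation_rule_hand_computed(self):
        """Equal-weight interpolation over the five CAD ratio estimates,
        evaluated by hand from the p_j = (cum w - w/2)/total rule."""
        ratios = np.array([-0.3981, -0.2560, -0.2476, -0.2128, 0.2612])
        assert weighted_median_point(ratios, np.full(5, 0.2)) == \
            pytest.approx(-0.2476, abs=1e-12)

    def test_odd_k_equal_weights_is_middle_order_statistic(self):
        ratios = np.array([0.9, -0.4, 0.1, 0.7, -0.2])
        assert weighted_median_point(ratios, np.ones(5)) == pytest.approx(0.1)

    def test_equal_weights_reduce_weighted_to_simple(self):
        insts = [make_inst(snp=f"rs{i}", bx=0.2, by=by, sey=0.02)
                 for i, by in enumerate([0.01, 0.03, 0.05, 0.07, 0.2])]
        # identical bx and sey -> identical weights for every SNP
        assert weighted_median(insts, n_boot=10, seed=1).theta == \
            pytest.approx(simple_median(insts, n_boot=10, seed=1).theta,
                          abs=1e-15)

    def test_dominant_weight_pins_estimate(self):
        insts = [make_inst(snp="rs0", bx=0.5, by=0.15, sey=1e-5)] + [
            make_inst(snp=f"rs{i}", bx=0.1, by=0.08, sey=0.5)
            for i in range(1, 4)]
        est = weighted_median(insts, n_boot=10, seed=1)
        assert round(est.theta, 4) == round(0.15 / 0.5, 4)

    def test_estimate_within_ratio_range(self, cad_instruments):
        ratios = [i.beta_outcome / i.beta_exposure for i in cad_instruments]
        for est in (simple_median(cad_instruments, n_boot=10, seed=0),
                    weighted_median(cad_instruments, n_boot=10, seed=0)):
            assert min(ratios) <= est.theta <= max(ratios)

    def test_bootstrap_reproducible_bit_for_bit(self, cad_instruments):
        a = weighted_median(cad_instruments, n_boot=200, seed=42)
        b = weighted_median(cad_instruments, n_boot=200, seed=42)
        assert a.se == b.se

    def test_too_few_instruments_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            simple_median([make_inst(snp="rs1"), make_inst(snp="rs2")])


class TestMultivariableIVW:
    def test_single_exposure_reduces_to_ivw(self, cad_instruments):
        bx = np.array([[i.beta_exposure] for i in cad_instruments])
        by = np.array([i.beta_outcome for i in cad_instruments])
        sey = np.array([i.se_outcome for i in cad_instruments])
        (mv,) = multivariable_ivw(bx, by, sey, ["CEC"])
        uni = ivw(cad_instruments, "fixed")
        assert mv.theta == pytest.approx(uni.theta, abs=1e-14)
        assert mv.se == pytest.approx(uni.se, abs=1e-14)

    def test_noiseless_design_recovers_effect_vector(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 0.2, size=(20, 2))
        truth = np.array([0.5, -0.2])
        y = X @ truth
        ests = multivariable_ivw(X, y, np.full(20, 0.02), ["a", "b"])
        assert ests[0].theta == pytest.approx(0.5, abs=1e-6)
        assert ests[1].theta == pytest.approx(-0.2, abs=1e-6)

    def test_duplicated_exposure_column_rejected(self):
        X = np.column_stack([np.linspace(0.1, 0.5, 6)] * 2)
        with pytest.raises(CollinearityError, match="dependent"):
            multivariable_ivw(X, np.zeros(6), np.full(6, 0.1), ["a", "a_dup"])

    def test_too_few_instruments_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            multivariable_ivw(np.ones((2, 2)), np.zeros(2), np.ones(2))


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(0.05, 0.5), st.floats(-0.2, 0.2), st.floats(0.01, 0.1)
        ),
        min_size=3, max_size=8,
    )
)
def test_ivw_equals_wls_oracle_property(rows):
    """IVW closed form and through-origin WLS agree on arbitrary inputs."""
    insts = [make_inst(snp=f"rs{i}", bx=bx, by=by, sey=sey)
             for i, (bx, by, sey) in enumerate(rows)]
    bx = np.array([r[0] for r in rows])
    by = np.array([r[1] for r in rows])
    sey = np.array([r[2] for r in rows])
    fit = sm.WLS(by, bx[:, None], weights=1.0 / sey**2).fit()
    assert ivw(insts).theta == pytest.approx(fit.params[0], abs=1e-12)
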