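"""Binary-endpoint effect measures and their confidence intervals."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rnt import (
    BinaryArm,
    BoundaryRateError,
    UndefinedMeasureError,
    arr,
    arr_wald_ci,
    nnt,
    nnt_ci,
    rnt,
    rnt_bootstrap_ci,
    rnt_exact_ci,
    rnt_wald_ci,
    rr,
    rrr,
)
from rnt._utils import round_half_away, z_quantile
from rnt.reference import run_reference_checks

@st.composite
def arms(draw):
    n = draw(st.integers(2, 400))
    return BinaryArm(n, draw(st.integers(1, n - 1)))


def arm_pair():
    return st.tuples(arms(), arms())


class TestPointMeasures:
    def test_arr_is_exact_rate_difference(self, kcsg_arms):
        control, treatment = kcsg_arms
        expected = Fraction(90, 209) - Fraction(81, 211)
        assert arr(control, treatment) == pytest.approx(float(expected), abs=1e-15)

    @pytest.mark.parametrize(
        "p_c, p_e, exp_rr, exp_rrr",
        [(0.1, 0.2, 2.0, 1.0), (0.4, 0.5, 1.25, 0.25), (0.3, 0.3, 1.0, 0.0)],
    )
    def test_rr_and_rrr(self, p_c, p_e, exp_rr, exp_rrr):
        control = BinaryArm.from_rate(100, p_c)
        treatment = BinaryArm.from_rate(100, p_e)
        assert rr(control, treatment) == pytest.approx(exp_rr)
        assert rrr(control, treatment) == pytest.approx(exp_rrr)

    @pytest.mark.parametrize(
        "p_c, p_e, expected",
        [(0.1, 0.2, 10.0), (0.4, 0.5, 10.0), (0.25, 0.25, math.inf)],
    )
    def test_nnt_depends_only_on_the_difference(self, p_c, p_e, expected):
        control = BinaryArm.from_rate(200, p_c)
        treatment = BinaryArm.from_rate(200, p_e)
        assert nnt(control, treatment) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "p_c, p_e, expected, ndigits",
        [(0.1, 0.2, 5.0, 2), (0.4, 0.5, 0.5, 2), (0.8, 0.9, 0.14, 2)],
    )
    def test_rnt_retains_the_baseline(self, p_c, p_e, expected, ndigits):
        control = BinaryArm.from_rate(1000, p_c)
        treatment = BinaryArm.from_rate(1000, p_e)
        assert round_half_away(rnt(control, treatment), ndigits) == expected

    def test_trial_nnt_values(self, kcsg_arms, gilt_arms):
        assert round_half_away(nnt(*kcsg_arms), 1) == 21.4
        assert round_half_away(nnt(*gilt_arms), 1) == 22.7

    def test_zero_rate_measures_raise(self):
        zero = BinaryArm(50, 0)
        some = BinaryArm(50, 10)
        with pytest.raises(UndefinedMeasureError):
            rr(zero, some)
        with pytest.raises(UndefinedMeasureError):
            rnt(zero, some)
        with pytest.raises(UndefinedMeasureError):
            rnt(some, zero)


class TestInvariants:
    @given(arm_pair())
    def test_identity_chain(self, pair):
        control, treatment = pair
        p_c, p_e = control.rate, treatment.rate
        value = rnt(control, treatment)
        assert value == pytest.approx(arr(control, treatment) / (p_e * p_c), abs=1e-12)
        assert value == pytest.approx(rrr(control, treatment) / p_e, abs=1e-12)
        if arr(control, treatment) != 0.0:
            assert value * nnt(control, treatment) * p_e * p_c == pytest.approx(
                1.0, abs=1e-12
            )

    @given(arm_pair())
    def test_antisymmetry_under_arm_swap(self, pair):
        control, treatment = pair
        assert arr(treatment, control) == pytest.approx(-arr(control, treatment), abs=1e-15)
        assert rnt(treatment, control) == pytest.approx(-rnt(control, treatment), abs=1e-12)
        fwd, rev = nnt(control, treatment), nnt(treatment, control)
        if math.isinf(fwd):
            assert math.isinf(rev)
        else:
            assert rev == pytest.approx(-fwd)

    @given(arm_pair())
    def test_rnt_sign_matches_arr_and_vanishes_only_at_equality(self, pair):
        control, treatment = pair
        a, r = arr(control, treatment), rnt(control, treatment)
        assert np.sign(r) == np.sign(a)
        assert (r == 0.0) == (control.rate == treatment.rate)

    def test_fixed_difference_rnt_decreases_with_baseline_nnt_constant(self):
        baselines = [0.1, 0.2, 0.4, 0.6, 0.8]
        values = [
            rnt(BinaryArm.from_rate(1000, b), BinaryArm.from_rate(1000, b + 0.1))
            for b in baselines
        ]
        nnts = [
            nnt(BinaryArm.from_rate(1000, b), BinaryArm.from_rate(1000, b + 0.1))
            for b in baselines
        ]
        assert all(v1 > v2 for v1, v2 in zip(values, values[1:]))
        assert nnts == pytest.approx([10.0] * len(baselines))

    def test_nnt_magnitude_at_least_one(self):
        # extreme rates give |ARR| <= 1, hence |NNT| >= 1
        a = nnt(BinaryArm(10, 0), BinaryArm(10, 10))
        b = nnt(BinaryArm(10, 10), BinaryArm(10, 0))
        assert a == 1.0 and b == -1.0


class TestWaldIntervals:
    @pytest.mark.parametrize(
        "fixture, point, lower, upper",
        [("kcsg_arms", 0.28, -0.29, 0.86), ("gilt_arms", 0.61, -1.11, 2.33)],
    )
    def test_rnt_wald_ci_reproduces_trial_reports(self, request, fixture, point, lower, upper):
        control, treatment = request.getfixturevalue(fixture)
        est = rnt_wald_ci(control, treatment, alpha=0.05)
        assert round_half_away(est.point, 2) == point
        assert round_half_away(est.ci.lower, 2) == lower
        assert round_half_away(est.ci.upper, 2) == upper
        assert est.ci.lower <= est.point <= est.ci.upper

    @pytest.mark.parametrize(
        "fixture, nntb, nnth",
        [("kcsg_arms", 7.1, 21.2), ("gilt_arms", 6.0, 12.7)],
    )
    def test_nnt_ci_is_irregular_when_arr_ci_spans_zero(self, request, fixture, nntb, nnth):
        control, treatment = request.getfixturevalue(fixture)
        est = nnt_ci(control, treatment, alpha=0.05)
        assert est.ci.kind == "irregular_nnt"
        assert round_half_away(est.ci.benefit_bound, 1) == nntb
        assert round_half_away(est.ci.harm_bound, 1) == nnth
        assert "NNTB" in est.ci.render(1) and "∞" in est.ci.render(1)

    def test_nnt_ci_regular_for_clearly_separated_arms(self):
        est = nnt_ci(BinaryArm(10000, 1000), BinaryArm(10000, 3000))
        assert est.ci.kind == "regular"
        assert 0 < est.ci.lower <= est.point <= est.ci.upper

    def test_irregular_bounds_are_reciprocal_arr_bounds(self, kcsg_arms):
        lower_d, upper_d = arr_wald_ci(*kcsg_arms)
        est = nnt_ci(*kcsg_arms)
        assert est.ci.benefit_bound == pytest.approx(1.0 / upper_d)
        assert est.ci.harm_bound == pytest.approx(-1.0 / lower_d)

    def test_alpha_near_one_collapses_to_point(self, kcsg_arms):
        est = rnt_wald_ci(*kcsg_arms, alpha=0.9999)
        assert est.ci.upper - est.ci.lower < 1e-3

    def test_z_quantile_computed_not_hardcoded(self):
        assert z_quantile(0.05) == pytest.approx(1.959964, abs=1e-6)
        assert z_quantile(0.10) == pytest.approx(1.644854, abs=1e-6)

    def test_width_scales_inverse_sqrt_n(self):
        small = rnt_wald_ci(BinaryArm(50, 20), BinaryArm(50, 30))
        large = rnt_wald_ci(BinaryArm(5000, 2000), BinaryArm(5000, 3000))
        ratio = (small.ci.upper - small.ci.lower) / (large.ci.upper - large.ci.lower)
        assert ratio == pytest.approx(10.0, abs=1e-9)

    def test_boundary_rates_rejected_with_guidance(self):
        with pytest.raises(BoundaryRateError, match="bootstrap"):
            rnt_wald_ci(BinaryArm(50, 0), BinaryArm(50, 10))
        with pytest.raises(BoundaryRateError):
            rnt_wald_ci(BinaryArm(50, 10), BinaryArm(50, 50))


class TestResamplingIntervals:
    def test_bootstrap_reproducible_and_matches_manual_replicates(self):
        control, treatment = BinaryArm(80, 30), BinaryArm(90, 45)
        est = rnt_bootstrap_ci(control, treatment, reps=2, seed=123)
        rng = np.random.default_rng(123)
        r_c = rng.binomial(80, 30 / 80, size=2)
        r_e = rng.binomial(90, 45 / 90, size=2)
        vals = 80 / r_c - 90 / r_e
        lower, upper = np.quantile(vals, [0.025, 0.975])
        assert est.ci.lower == pytest.approx(lower)
        assert est.ci.upper == pytest.approx(upper)
        again = rnt_bootstrap_ci(control, treatment, reps=2, seed=123)
        assert (again.ci.lower, again.ci.upper) == (est.ci.lower, est.ci.upper)

    def test_bootstrap_identical_arms_covers_zero(self):
        arm = BinaryArm(120, 40)
        est = rnt_bootstrap_ci(arm, arm, reps=2000, seed=5)
        assert est.ci.lower < 0.0 < est.ci.upper

    def test_bootstrap_approaches_wald_for_large_trials(self):
        control, treatment = BinaryArm(10000, 3000), BinaryArm(10000, 3500)
        wald = rnt_wald_ci(control, treatment)
        boot = rnt_bootstrap_ci(control, treatment, reps=4000, seed=9)
        assert boot.ci.lower == pytest.approx(wald.ci.lower, abs=0.05)
        assert boot.ci.upper == pytest.approx(wald.ci.upper, abs=0.05)

    def test_bootstrap_rejects_zero_responder_arm(self):
        with pytest.raises(UndefinedMeasureError):
            rnt_bootstrap_ci(BinaryArm(50, 0), BinaryArm(50, 10), seed=0)

    def test_exact_ci_wider_than_wald_at_small_n(self):
        control, treatment = BinaryArm(20, 10), BinaryArm(20, 15)
        wald = rnt_wald_ci(control, treatment)
        exact = rnt_exact_ci(control, treatment)
        assert (exact.ci.upper - exact.ci.lower) > (wald.ci.upper - wald.ci.lower)
        assert exact.ci.lower <= exact.point <= exact.ci.upper

    def test_exact_ci_all_responders_contains_zero(self):
        est = rnt_exact_ci(BinaryArm(15, 15), BinaryArm(20, 20))
        assert est.point == 0.0
        assert est.ci.lower <= 0.0 <= est.ci.upper

    def test_exact_ci_zero_responders_flagged_one_sided(self):
        est = rnt_exact_ci(BinaryArm(20, 0), BinaryArm(20, 10))
        assert "one_sided_infinite" in est.flags
        assert math.isinf(est.ci.upper)


def test_reference_table_fully_reproduced():
    """Worked trial examples, toy cases, and the full RNT/NNT grid all match."""
    table = run_reference_checks()
    assert len(table) >= 60
    mismatches = table[~table["match"]]
    assert mismatches.empty, mismatches.to_string()


class TestBinaryArmValidation:
    @pytest.mark.parametrize("n, r", [(0, 0), (5, 6), (5, -1)])
    def test_invalid_counts_rejected(self, n, r):
        with pytest.raises(ValueError):
            BinaryArm(n, r)

    def test_from_rate_recovers_reported_counts(self):
        assert BinaryArm.from_rate(105, 0.248).responders == 26
        assert BinaryArm.from_rate(96, 0.291).responders == 28
        with pytest.raises(ValueError):
            BinaryArm.from_rate(100, 1.2)
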