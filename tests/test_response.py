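import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from truescore import (
    Arm,
    ArmChangeSummary,
    Direction,
    InvalidInputError,
    StudyDesign,
    Threshold,
    bootstrap_proportion_ci,
    change_scores,
    estimate_response,
    proportion_response,
    sigma_ir,
    simulate_study,
)


def summary(arm: Arm, sd: float, mean: float = 0.0, n: int = 10) -> ArmChangeSummary:
    return ArmChangeSummary(arm=arm, n=n, mean_change=mean, sd_change=sd)


class TestSigmaIR:
    def test_carnosine_worked_example(self):
        """sqrt(5.22^2 - 1.24^2) = 5.07 at 2 dp."""
        sigma, degenerate = sigma_ir(summary(Arm.INTERVENTION, 5.22),
                                     summary(Arm.CONTROL, 1.24))
        assert round(sigma, 2) == 5.07
        assert not degenerate

    def test_pythagorean_triple(self):
        sigma, _ = sigma_ir(summary(Arm.INTERVENTION, 5.0),
                            summary(Arm.CONTROL, 3.0))
        assert sigma == pytest.approx(4.0)

    def test_negative_variance_difference_clamped(self, caplog):
        with caplog.at_level(logging.WARNING, logger="truescore.response"):
            sigma, degenerate = sigma_ir(summary(Arm.INTERVENTION, 1.0),
                                         summary(Arm.CONTROL, 2.0))
        assert sigma == 0.0 and degenerate
        assert any("clamped" in r.message for r in caplog.records)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_variance_round_trip(self, sd_int, sd_con):
        sigma, degenerate = sigma_ir(summary(Arm.INTERVENTION, sd_int),
                                     summary(Arm.CONTROL, sd_con))
        if not degenerate:
            assert sigma ** 2 + sd_con ** 2 == pytest.approx(sd_int ** 2,
                                                             rel=1e-9)
        else:
            assert sigma == 0.0


class TestProportionResponse:
    def test_carnosine_proportion_0947(self):
        sigma, _ = sigma_ir(summary(Arm.INTERVENTION, 5.22),
                            summary(Arm.CONTROL, 1.24))
        p = proportion_response(10.20, sigma, Threshold(2.0))
        assert round(p, 3) == 0.947

    def test_half_at_the_threshold(self):
        assert proportion_response(2.0, 3.0, Threshold(2.0)) == pytest.approx(0.5)

    def test_degenerate_step_function(self):
        thr = Threshold(2.0)
        assert proportion_response(3.0, 0.0, thr) == 1.0
        assert proportion_response(2.0, 0.0, thr) == 0.0
        assert proportion_response(1.0, 0.0, thr) == 0.0

    def test_decrease_beneficial_mirror(self):
        thr_dec = Threshold(2.0, Direction.DECREASE_BENEFICIAL)
        thr_inc = Threshold(2.0, Direction.INCREASE_BENEFICIAL)
        assert proportion_response(-10.2, 5.07, thr_dec) == pytest.approx(
            proportion_response(10.2, 5.07, thr_inc))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(-10, 10), st.floats(0.1, 10),
           st.floats(0, 5), st.floats(0.01, 3), st.floats(0.01, 3))
    def test_monotone_in_swc_and_mean(self, mean, sigma, swc, swc_bump, mean_bump):
        base = proportion_response(mean, sigma, Threshold(swc))
        assert 0.0 <= base <= 1.0
        assert proportion_response(mean, sigma, Threshold(swc + swc_bump)) <= base
        assert proportion_response(mean + mean_bump, sigma, Threshold(swc)) >= base


class TestBootstrap:
    @pytest.fixture
    def arms(self):
        rng = np.random.default_rng(17)
        return rng.normal(10.2, 5.22, 30), rng.normal(0.0, 1.24, 30)

    def test_seeded_determinism(self, arms):
        ints, cons = arms
        thr = Threshold(2.0)
        a = bootstrap_proportion_ci(ints, cons, thr, n_boot=200, seed=5)
        b = bootstrap_proportion_ci(ints, cons, thr, n_boot=200, seed=5)
        assert (a.interval.lower, a.interval.upper) == (b.interval.lower,
                                                        b.interval.upper)
        assert a.degenerate_fraction == b.degenerate_fraction

    def test_bounds_in_unit_interval_and_contain_point(self, arms):
        ints, cons = arms
        diag = bootstrap_proportion_ci(ints, cons, Threshold(2.0),
                                       n_boot=500, seed=2)
        assert 0.0 <= diag.interval.lower <= diag.interval.upper <= 1.0
        assert diag.interval.lower <= diag.point_estimate <= diag.interval.upper

    def test_identical_arms_surface_degeneracy(self):
        vals = np.array([1.0, 2.5, -0.5, 3.0, 0.7, 1.2])
        diag = bootstrap_proportion_ci(vals, vals, Threshold(0.5),
                                       n_boot=500, seed=9)
        assert diag.point_estimate in (0.0, 1.0)
        assert diag.degenerate_fraction > 0.4

    def test_input_validation(self, arms):
        ints, cons = arms
        with pytest.raises(InvalidInputError):
            bootstrap_proportion_ci(ints, cons, Threshold(2.0), n_boot=50, seed=1)
        with pytest.raises(InvalidInputError):
            bootstrap_proportion_ci([1.0], cons, Threshold(2.0), n_boot=200,
                                    seed=1)

    def test_interval_contains_generator_truth(self):
        """Synthetic arms built so the true proportion is 0.90: the 95%
        percentile interval contains it in >= 90% of 50 outer replicates."""
        te, bio = 0.52, 1.0
        sigma_true = 5.07
        swc = 2.0
        # mean such that P(N(mean, sigma_true) > swc) = 0.90
        mean_true = swc + stats.norm.ppf(0.90) * sigma_true
        sd_con = math.sqrt(bio ** 2 + 2 * te ** 2)
        sd_int = math.sqrt(sigma_true ** 2 + sd_con ** 2)
        rng = np.random.default_rng(404)
        hits = 0
        for rep in range(50):
            ints = rng.normal(mean_true, sd_int, 200)
            cons = rng.normal(0.0, sd_con, 200)
            diag = bootstrap_proportion_ci(ints, cons, Threshold(swc),
                                           level=0.95, n_boot=2000,
                                           seed=int(rng.integers(2 ** 31)))
            if diag.interval.lower <= 0.90 <= diag.interval.upper:
                hits += 1
        assert hits >= 45


class TestChangeScoresAndEstimateResponse:
    def test_change_scores_shape(self, small_study):
        study, truth = small_study
        ch = change_scores(study, "MCARN")
        assert list(ch.columns) == ["subject_id", "arm", "pre", "post", "change"]
        assert len(ch) == 12
        assert np.allclose(ch["change"], ch["post"] - ch["pre"])

    def test_missing_post_subject_named(self, small_study):
        study, _ = small_study
        broken = study[~((study["subject_id"] == "I001")
                         & (study["time"] == "post"))]
        with pytest.raises(InvalidInputError, match="I001"):
            change_scores(broken, "MCARN")

    def test_missing_time_point_named(self, small_study):
        study, _ = small_study
        with pytest.raises(InvalidInputError, match="post"):
            change_scores(study[study["time"] == "pre"], "MCARN")

    def test_parameter_recovery_on_synthetic_study(self):
        """A large synthetic study generated with the default parameters
        returns a proportion near the generative truth."""
        design = StudyDesign(n_per_arm=4000, seed=88)
        study, _ = simulate_study(design)
        thr = Threshold(2.0, Direction.INCREASE_BENEFICIAL)
        est = estimate_response(study, "MCARN", thr, n_boot=None)
        sd_con = math.sqrt(design.bio_var_sd ** 2 + 2 * design.te ** 2)
        true_prop = stats.norm.sf(2.0, loc=design.effect_mean,
                                  scale=math.hypot(design.effect_sd, 0))
        assert est.sigma_ir == pytest.approx(design.effect_sd, rel=0.1)
        assert est.proportion == pytest.approx(true_prop, abs=0.03)
        assert est.sd_change_control == pytest.approx(sd_con, rel=0.1)

    def test_no_effect_no_heterogeneity_flagged(self):
        design = StudyDesign(n_per_arm=50, effect_mean=0.0, effect_sd=0.0,
                             seed=12)
        study, _ = simulate_study(design)
        est = estimate_response(study, "MCARN", Threshold(2.0), n_boot=None)
        assert est.degenerate or est.proportion in (0.0, 1.0) \
            or est.proportion < 0.2

    def test_bootstrap_requires_seed(self, small_study):
        study, _ = small_study
        with pytest.raises(InvalidInputError, match="seed"):
            estimate_response(study, "MCARN", Threshold(2.0))

    def test_sigma_ir_recovery_across_truths(self):
        """Median sigma_IR over 200 replicates is within 10% of truth for
        true values 2 and 5 (n = 1000/arm); with no true heterogeneity the
        degeneracy clamp fires in over 40% of replicates."""
        rng = np.random.default_rng(55)
        te, bio = 0.52, 1.0
        sd_con = math.sqrt(bio ** 2 + 2 * te ** 2)
        for sigma_true in (0.0, 2.0, 5.0):
            sd_int = math.sqrt(sigma_true ** 2 + sd_con ** 2)
            estimates, degenerates = [], 0
            for _ in range(200):
                ints = rng.normal(10.0, sd_int, 1000)
                cons = rng.normal(0.0, sd_con, 1000)
                sigma, degenerate = sigma_ir(
                    ArmChangeSummary.from_changes(Arm.INTERVENTION, ints),
                    ArmChangeSummary.from_changes(Arm.CONTROL, cons))
                estimates.append(sigma)
                degenerates += degenerate
            if sigma_true == 0.0:
                assert degenerates / 200 > 0.40
            else:
                assert np.median(estimates) == pytest.approx(sigma_true,
                                                             rel=0.10)
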