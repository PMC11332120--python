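"""Causal-inference model: pooling, integration, recalibration, closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from fir.cims_model import (
    EncodingDistribution,
    ModelConfig,
    RepresentationalSpace,
    classify_point,
    fit_p_common,
    integrate_causal,
    pool_av,
    posttest_fusion_probability,
    predict_cohort,
    shift_auditory,
    shift_fraction_for_fusion_probability,
    simulate_exposure_trial,
    simulate_exposure_trials,
    simulate_posttest,
    token_probability,
)
from fir.dataset_io import TrialRecord, trials_to_frame


def dist(center, variances, modality="pooled"):
    return EncodingDistribution(np.asarray(center), np.asarray(variances), modality)


class TestPooling:
    def test_precision_weighted_closed_form(self):
        a = dist((0, 0), (0.09, 1.0), "A")
        v = dist((2, 2), (1.0, 0.09), "V")
        pooled = pool_av(a, v)
        # per-axis inverse-variance weighting, computed by hand
        np.testing.assert_allclose(pooled.center, [0.16513761, 1.83486239], atol=1e-8)
        np.testing.assert_allclose(pooled.variances, [0.08256881, 0.08256881], atol=1e-8)

    def test_mirror_symmetry_centers_pooled_on_fusion_diagonal(self, s1_encoders):
        a, v = s1_encoders
        pooled = pool_av(a, v)
        # A and V sit symmetrically about the fusion token with mirrored
        # covariances, so the pooled diagonal coordinate equals the fusion one
        assert (pooled.center[0] + pooled.center[1]) / 2 == pytest.approx(1.0)

    def test_infinitely_unreliable_visual_cue_drops_out(self, s1_encoders):
        a, _ = s1_encoders
        v = dist((2, 2), (np.inf, np.inf), "pooled")
        pooled = pool_av(a, v)
        np.testing.assert_allclose(pooled.center, a.center)
        np.testing.assert_allclose(pooled.variances, a.variances)

    def test_anisotropy_contract_enforced(self):
        with pytest.raises(ValueError):
            dist((0, 0), (1.0, 0.09), "A")  # auditory must be noisier along y
        with pytest.raises(ValueError):
            dist((0, 0), (0.09, 1.0), "V")


class TestCausalIntegration:
    def test_endpoints(self, s1_encoders):
        a, v = s1_encoders
        pooled = pool_av(a, v)
        av1 = integrate_causal(a, pooled, 1.0)
        np.testing.assert_allclose(av1.center, pooled.center)
        np.testing.assert_allclose(av1.variances, pooled.variances)
        av0 = integrate_causal(a, pooled, 0.0)
        np.testing.assert_allclose(av0.center, a.center)

    def test_midpoint(self):
        a = dist((0, 0), (0.1, 0.2), "pooled")
        pooled = dist((1, 1), (0.1, 0.2), "pooled")
        av = integrate_causal(a, pooled, 0.5)
        np.testing.assert_allclose(av.center, [0.5, 0.5])

    def test_selection_convention(self, s1_encoders):
        a, v = s1_encoders
        pooled = pool_av(a, v)
        np.testing.assert_allclose(
            integrate_causal(a, pooled, 0.7, "select").center, pooled.center
        )
        np.testing.assert_allclose(
            integrate_causal(a, pooled, 0.3, "select").center, a.center
        )

    def test_out_of_range_rejected(self, s1_encoders):
        a, v = s1_encoders
        with pytest.raises(ValueError):
            integrate_causal(a, pool_av(a, v), 1.2)


class TestClassification:
    def test_token_mean_classifies_as_itself(self, s1_space):
        for token, mean in zip(s1_space.tokens, s1_space.means):
            assert classify_point(mean, s1_space) == token

    def test_nearest_mean(self, s1_space):
        assert classify_point((1.6, 1.6), s1_space) == "gaga"

    def test_tie_breaks_by_token_order(self, s1_space):
        # (0.5, 0.5) is equidistant from the auditory and fusion means
        assert classify_point((0.5, 0.5), s1_space) == "baba"


class TestClosedFormMasses:
    def test_unit_projected_sd_interval(self, s1_space):
        # A' at the fusion mean with projected-diagonal variance 0.25 and a
        # region half-width of 0.5 diagonal units: mass = Phi(1) - Phi(-1)
        a_prime = dist((1, 1), (0.5, 0.5), "A_shifted")
        assert posttest_fusion_probability(a_prime, s1_space) == pytest.approx(
            norm.cdf(1) - norm.cdf(-1), abs=1e-12
        )

    def test_far_tail_below_1e8(self, s1_encoders, s1_space):
        a, _ = s1_encoders
        assert posttest_fusion_probability(a, s1_space) < 1e-8

    def test_boundary_centered_mass(self, s1_space):
        # centered exactly on the auditory/fusion boundary: 0.5 minus far tail
        a_prime = dist((0.5, 0.5), (0.5, 0.5), "A_shifted")
        far_tail = 1 - norm.cdf((2.1213203435596424 - 0.7071067811865476) / np.sqrt(0.5))
        assert posttest_fusion_probability(a_prime, s1_space) == pytest.approx(
            0.5 - far_tail, abs=1e-12
        )

    def test_token_masses_sum_to_one(self, s1_space):
        d = dist((0.7, 0.9), (0.05, 0.2), "pooled")
        total = sum(token_probability(d, s1_space, t) for t in s1_space.tokens)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_non_collinear_fallback_matches_monte_carlo(self, rng):
        space = RepresentationalSpace(
            ("ba", "da", "ga"), np.array([[0.0, 0.0], [1.0, 0.4], [1.5, 1.9]]), "da"
        )
        assert space.line_direction is None
        d = dist((0.8, 0.5), (0.1, 0.3), "pooled")
        exact = token_probability(d, space, "da")
        sample = d.sample(200_000, rng)
        d2 = ((sample[:, None, :] - space.means[None]) ** 2).sum(axis=2)
        mc = float(np.mean(np.argmin(d2, axis=1) == 1))
        assert exact == pytest.approx(mc, abs=0.005)


class TestExposureSimulation:
    def test_no_common_cause_gives_zero_error_and_auditory_percepts(
        self, s1_encoders, s1_space, rng
    ):
        a, v = s1_encoders
        percepts, errors = simulate_exposure_trials(a, v, 0.0, s1_space, 500, rng)
        assert np.all(errors == 0)
        assert set(percepts) == {"baba"}

    def test_fixed_seed_reproducible(self, s1_encoders, s1_space):
        a, v = s1_encoders
        r1 = simulate_exposure_trials(a, v, 0.6, s1_space, 50, np.random.default_rng(7))
        r2 = simulate_exposure_trials(a, v, 0.6, s1_space, 50, np.random.default_rng(7))
        assert np.array_equal(r1[0], r2[0]) and np.array_equal(r1[1], r2[1])

    def test_single_trial_wrapper(self, s1_encoders, s1_space, rng):
        a, v = s1_encoders
        percept, error = simulate_exposure_trial(a, v, 0.5, s1_space, rng)
        assert percept in s1_space.tokens and error >= 0

    def test_fusion_fraction_matches_bivariate_mass(self, s1_encoders, s1_space, rng):
        a, v = s1_encoders
        av = integrate_causal(a, pool_av(a, v), 0.6)
        expected = posttest_fusion_probability(av, s1_space)
        n = 100_000
        percepts, _ = simulate_exposure_trials(a, v, 0.6, s1_space, n, rng)
        frac = np.mean(percepts == "dada")
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se


class TestFitPCommon:
    def test_clamps(self, s1_encoders, s1_space):
        a, v = s1_encoders
        assert fit_p_common(0.0, a, v, s1_space) == 0.0
        assert fit_p_common(1.0, a, v, s1_space) == 1.0

    def test_endpoint_exact(self, s1_encoders, s1_space):
        a, v = s1_encoders
        av = integrate_causal(a, pool_av(a, v), 1.0)
        q = posttest_fusion_probability(av, s1_space)
        assert fit_p_common(q, a, v, s1_space) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("q", [0.01, 0.05, 0.2, 0.5, 0.8, 0.95, 0.99])
    def test_round_trip_self_consistency(self, s1_encoders, s1_space, q):
        a, v = s1_encoders
        p = fit_p_common(q, a, v, s1_space)
        av = integrate_causal(a, pool_av(a, v), p)
        assert posttest_fusion_probability(av, s1_space) == pytest.approx(q, abs=1e-6)


class TestShift:
    def test_zero_fraction_identity(self, s1_encoders, s1_space):
        a, v = s1_encoders
        av = integrate_causal(a, pool_av(a, v), 0.8)
        a_prime = shift_auditory(a, av, 0.0)
        np.testing.assert_allclose(a_prime.center, a.center)
        np.testing.assert_allclose(a_prime.variances, a.variances)

    def test_full_shift_reaches_av(self, s1_encoders, s1_space):
        a, v = s1_encoders
        av = integrate_causal(a, pool_av(a, v), 0.8)
        np.testing.assert_allclose(shift_auditory(a, av, 1.0).center, av.center)

    def test_linear_interpolation(self):
        a = dist((0, 0), (0.1, 0.2), "pooled")
        av = dist((1, 1), (0.05, 0.05), "pooled")
        np.testing.assert_allclose(shift_auditory(a, av, 0.6).center, [0.6, 0.6])

    def test_covariance_conserved(self, s1_encoders):
        a, v = s1_encoders
        av = integrate_causal(a, pool_av(a, v), 1.0)
        for f in (0.2, 0.5, 1.0):
            np.testing.assert_array_equal(shift_auditory(a, av, f).variances, a.variances)

    def test_out_of_range_rejected(self, s1_encoders):
        a, v = s1_encoders
        with pytest.raises(ValueError):
            shift_auditory(a, pool_av(a, v), 1.5)

    def test_inverse_shift_for_target_probability(self, s1_encoders, s1_space):
        a, v = s1_encoders
        av = integrate_causal(a, pool_av(a, v), 0.7)
        for target in (0.05, 0.3, 0.6):
            f = shift_fraction_for_fusion_probability(a, av, s1_space, target)
            got = posttest_fusion_probability(shift_auditory(a, av, f), s1_space)
            assert got == pytest.approx(target, abs=1e-9)


class TestPosttestSimulation:
    def test_unshifted_far_representation_never_fuses(self, s1_encoders, s1_space, rng):
        a, _ = s1_encoders
        percepts = simulate_posttest(a, s1_space, 2000, rng)
        assert np.sum(percepts == "dada") == 0

    def test_converges_to_closed_form(self, s1_encoders, s1_space, rng):
        a, v = s1_encoders
        av = integrate_causal(a, pool_av(a, v), 0.62)
        a_prime = shift_auditory(a, av, 0.8)
        expected = posttest_fusion_probability(a_prime, s1_space)
        percepts = simulate_posttest(a_prime, s1_space, 100_000, rng)
        assert abs(np.mean(percepts == "dada") - expected) < 0.01

    def test_reproducible_percept_list(self, s1_encoders, s1_space):
        a, v = s1_encoders
        av = integrate_causal(a, pool_av(a, v), 0.62)
        a_prime = shift_auditory(a, av, 1.0)
        p1 = simulate_posttest(a_prime, s1_space, 10, np.random.default_rng(3))
        p2 = simulate_posttest(a_prime, s1_space, 10, np.random.default_rng(3))
        assert np.array_equal(p1, p2)


class TestPredictCohort:
    @staticmethod
    def _cohort_frame(day1_fusion_of_5: int, exposure_fraction: float):
        rows = []
        # day-1 exposure (day_index 2): 5 trials of S1
        for i in range(5):
            cat = "Fusion" if i < day1_fusion_of_5 else "Auditory"
            rows.append(TrialRecord("p1", "exposure", 2, "S1", coded_category=cat))
        # remaining exposure days: 5 trials each at the requested fraction
        for day in range(3, 16):
            k = round(5 * exposure_fraction)
            for i in range(5):
                cat = "Fusion" if i < k else "Auditory"
                rows.append(TrialRecord("p1", "exposure", day, "S1", coded_category=cat))
        for i in range(5):
            rows.append(
                TrialRecord("p1", "posttest_24h", 16, "S1_Aud", coded_category="Auditory")
            )
        return trials_to_frame(rows)

    def test_no_day1_fusion_predicts_baseline(self, stimuli):
        pred = predict_cohort(self._cohort_frame(0, 0.0), stimuli)
        assert pred.loc[0, "predicted_fir"] == pytest.approx(0.0, abs=1e-5)

    def test_full_fusion_full_common_cause(self, stimuli, model_config, s1_space, s1_encoders):
        pred = predict_cohort(self._cohort_frame(5, 1.0), stimuli)
        assert pred.loc[0, "p_common"] == 1.0
        a, v = s1_encoders
        pooled = pool_av(a, v)
        expected = 100 * posttest_fusion_probability(
            shift_auditory(a, pooled, 1.0), s1_space
        )
        assert pred.loc[0, "predicted_fir"] == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_day1_fraction(self, stimuli):
        preds = [
            predict_cohort(self._cohort_frame(k, 0.8), stimuli).loc[0, "predicted_fir"]
            for k in range(6)
        ]
        assert all(b >= a for a, b in zip(preds, preds[1:]))

    def test_participant_without_exposure_skipped_with_warning(self, stimuli):
        frame = trials_to_frame(
            [TrialRecord("p9", "posttest_24h", 16, "S1_Aud", coded_category="Auditory")]
        )
        with pytest.warns(UserWarning, match="p9"):
            pred = predict_cohort(frame, stimuli)
        assert pred.empty
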