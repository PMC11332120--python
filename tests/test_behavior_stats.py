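"""Descriptives, odds ratios, mixed models, decay fits, model evaluation."""

import numpy as np
import pandas as pd
import pytest

from fir import behavior_stats as bs
from fir.dataset_io import TrialRecord, trials_to_frame
from fir.synthetic_cohort import generate_cohort


def _trials(specs):
    """specs: iterable of (pid, phase, day, stim, category, n)."""
    rows = []
    for pid, phase, day, stim, cat, n in specs:
        months = 0.0 if phase == "longterm" else None
        rows.extend(
            TrialRecord(pid, phase, day, stim, months_since_exposure=months, coded_category=cat)
            for _ in range(n)
        )
    return trials_to_frame(rows)


class TestDescriptives:
    def test_percentages_from_counts(self):
        frame = _trials(
            [
                ("p1", "posttest_24h", 16, "S1_Aud", "Fusion", 3),
                ("p1", "posttest_24h", 16, "S1_Aud", "Auditory", 2),
            ]
        )
        out = bs.descriptives(frame, group_by=("phase", "stimulus_id"))
        fus = out[out.coded_category == "Fusion"].iloc[0]
        assert fus["count"] == 3 and fus["total"] == 5 and fus["pct"] == 60.0

    def test_single_category_cell(self):
        frame = _trials([("p1", "pretest", 1, "S1_Aud", "Auditory", 7)])
        out = bs.descriptives(frame, group_by=("phase",))
        assert len(out) == 1 and out.iloc[0]["pct"] == 100.0

    def test_empty_cells_missing_not_zero(self):
        frame = _trials([("p1", "pretest", 1, "S1_Aud", "Auditory", 5)])
        out = bs.descriptives(frame, group_by=("phase", "stimulus_id"))
        assert ("posttest_24h" not in set(out["phase"]))

    def test_order_invariance(self):
        frame = _trials(
            [
                ("p1", "pretest", 1, "S1_Aud", "Auditory", 4),
                ("p2", "pretest", 1, "S1_Aud", "Fusion", 2),
            ]
        )
        shuffled = frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = bs.descriptives(frame, group_by=("phase",)).reset_index(drop=True)
        b = bs.descriptives(shuffled, group_by=("phase",)).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_uncoded_trials_rejected(self):
        frame = _trials([("p1", "pretest", 1, "S1_Aud", "Auditory", 2)])
        frame.loc[0, "coded_category"] = ""
        with pytest.raises(ValueError):
            bs.descriptives(frame)


class TestClassifyPerceivers:
    @pytest.mark.parametrize(
        "n_fusion, n_total, expected",
        [
            (66, 70, "fusion_perceiver"),  # ~95% fusion during exposure
            (4, 70, "auditory_perceiver"),  # ~6%
            (35, 70, "fusion_perceiver"),  # exactly at threshold: >= rule
        ],
    )
    def test_threshold_rule(self, n_fusion, n_total, expected):
        frame = _trials(
            [
                ("p1", "exposure", 2, "S1", "Fusion", n_fusion),
                ("p1", "exposure", 2, "S1", "Auditory", n_total - n_fusion),
            ]
        )
        out = bs.classify_perceivers(frame, "S1", 0.5)
        assert out.iloc[0]["perceiver_class"] == expected
        assert out.iloc[0]["exposure_fusion_fraction"] == pytest.approx(n_fusion / n_total)

    def test_no_exposure_unclassified(self):
        frame = _trials([("p1", "pretest", 1, "S1_Aud", "Auditory", 5)])
        out = bs.classify_perceivers(frame, "S1")
        assert out.iloc[0]["perceiver_class"] == "unclassified"


class TestOddsRatio:
    def test_cross_product(self):
        assert bs.odds_ratio_2x2(10, 50, 20, 50) == pytest.approx(0.375)

    def test_identical_groups(self):
        assert bs.odds_ratio_2x2(7, 20, 7, 20) == 1.0

    def test_zero_cell_continuity_correction(self):
        # cells (0, 10, 5, 5) + 0.5 each -> (0.5/10.5) / (5.5/5.5)
        assert bs.odds_ratio_2x2(0, 10, 5, 10) == pytest.approx((0.5 / 10.5) / (5.5 / 5.5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            bs.odds_ratio_2x2(-1, 10, 2, 10)


class TestGlmm:
    @staticmethod
    def _counts(rates, n_participants=14, n_trials=10, seed=5):
        """rates: {(cls, time): fusion probability}."""
        rng = np.random.default_rng(seed)
        rows = []
        i = 0
        for cls in ("auditory_perceiver", "fusion_perceiver"):
            for _ in range(n_participants):
                i += 1
                for time in ("pre", "post"):
                    p = rates[(cls, time)]
                    rows.append(
                        (f"p{i:03d}", cls, time, int(rng.binomial(n_trials, p)), n_trials)
                    )
        return pd.DataFrame(rows, columns=["participant", "cls", "time", "fusion", "total"])

    def test_post_only_increase_detected(self):
        """A generated post-test increase confined to fusion perceivers yields a
        significant interaction and a post-hoc OR > 1 with CI excluding 1 in that
        class only."""
        counts = self._counts(
            {
                ("auditory_perceiver", "pre"): 0.05,
                ("auditory_perceiver", "post"): 0.05,
                ("fusion_perceiver", "pre"): 0.05,
                ("fusion_perceiver", "post"): 0.45,
            }
        )
        fit = bs.fit_fusion_glmm(counts)
        assert fit.converged
        assert fit.effects["interaction"].p_value < 0.05
        fus = fit.posthoc["fusion_perceiver"]
        assert fus.odds_ratio > 1 and fus.ci95[0] > 1
        aud = fit.posthoc["auditory_perceiver"]
        assert aud.ci95[0] <= 1 <= aud.ci95[1]

    def test_identical_cells_give_unit_odds_ratios(self):
        rows = []
        for i in range(6):
            for time in ("pre", "post"):
                cls = "fusion_perceiver" if i < 3 else "auditory_perceiver"
                rows.append((f"p{i}", cls, time, 5, 10))
        counts = pd.DataFrame(rows, columns=["participant", "cls", "time", "fusion", "total"])
        fit = bs.fit_fusion_glmm(counts)
        for contrast in fit.posthoc.values():
            assert contrast.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_posthoc_matches_sample_odds_ratio_without_random_variance(self):
        """With one participant per class the random effect vanishes and the
        post-hoc OR reduces to the sample cross-product odds ratio."""
        rows = [
            ("p1", "fusion_perceiver", "pre", 3, 10),
            ("p1", "fusion_perceiver", "post", 6, 10),
            ("p2", "auditory_perceiver", "pre", 2, 10),
            ("p2", "auditory_perceiver", "post", 2, 10),
        ]
        counts = pd.DataFrame(rows, columns=["participant", "cls", "time", "fusion", "total"])
        fit = bs.fit_fusion_glmm(counts)
        expected = bs.odds_ratio_2x2(6, 10, 3, 10, continuity=0)
        assert fit.posthoc["fusion_perceiver"].odds_ratio == pytest.approx(expected, rel=1e-3)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            bs.fit_fusion_glmm(pd.DataFrame({"participant": [], "cls": []}))


class TestDecayFit:
    def test_noiseless_recovery_to_optimizer_tolerance(self):
        t = np.arange(12, dtype=float)
        fit = bs.fit_decay(t, 90 * np.exp(-0.545 * t))
        assert fit.a == pytest.approx(90, abs=1e-6)
        assert fit.b == pytest.approx(-0.545, abs=1e-6)
        assert fit.monthly_decay_pct == pytest.approx(100 * (1 - np.exp(-0.545)), abs=1e-4)
        assert fit.model_comparison_p < 1e-6

    def test_constant_series_no_decay(self):
        fit = bs.fit_decay(np.arange(6, dtype=float), np.full(6, 40.0))
        assert fit.b == pytest.approx(0.0, abs=1e-9)
        assert fit.model_comparison_p == pytest.approx(1.0)

    def test_all_zero_series_flagged(self):
        fit = bs.fit_decay(np.arange(4, dtype=float), np.zeros(4))
        assert fit.flag == "all_zero" and fit.a == 0 and np.isnan(fit.b)

    def test_noisy_recovery_within_band(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = np.arange(12, dtype=float)
            y = 60 * np.exp(-0.545 * t) + rng.normal(0, 5, 12)
            errs.append(abs(bs.fit_decay(t, y).b - (-0.545)))
        assert np.mean(errs) < 0.15

    def test_enforce_decay_bound(self):
        t = np.arange(6, dtype=float)
        fit = bs.fit_decay(t, 10 + t, enforce_decay=True)  # growing series
        assert fit.b <= 0


class TestTrajectories:
    @staticmethod
    def _series(values):
        return pd.DataFrame(
            {
                "participant_id": "p1",
                "months": np.arange(len(values), dtype=float),
                "fir_pct": values,
            }
        )

    @pytest.mark.parametrize(
        "values, expected",
        [
            ([90, 88, 92, 91, 89, 90, 88], "persistent"),
            ([60, 35, 18, 8, 2], "decaying"),
            ([1, 0, 0], "absent"),
            ([40], "unclassifiable"),
        ],
    )
    def test_rules(self, values, expected):
        out = bs.group_trajectories(self._series(values))
        assert out.iloc[0]["trajectory"] == expected

    def test_final_below_threshold_counts_as_decaying(self):
        out = bs.group_trajectories(self._series([60, 5]))
        assert out.iloc[0]["trajectory"] == "decaying"

    def test_thresholds_reported(self):
        out = bs.group_trajectories(self._series([50, 50, 50]), low_threshold=20.0)
        assert out.attrs["low_threshold"] == 20.0


class TestEvaluateModel:
    def test_perfect_prediction(self):
        x = np.array([0, 10, 40, 80, 95.0])
        out = bs.evaluate_model(x, x)
        assert out.pearson_r == pytest.approx(1.0)
        assert out.ci95[0] <= 1.0 <= out.ci95[1] + 1e-12

    def test_ci_contains_point_estimate_and_widens_with_smaller_n(self):
        lo30, hi30 = bs.pearson_ci_fisher(0.6, 30)
        lo10, hi10 = bs.pearson_ci_fisher(0.6, 10)
        assert lo30 <= 0.6 <= hi30
        assert (hi10 - lo10) > (hi30 - lo30)

    def test_zero_variance_flagged(self):
        out = bs.evaluate_model([50, 50, 50, 50], [0, 20, 40, 60])
        assert out.flag == "undefined_r" and np.isnan(out.pearson_r)

    def test_null_calibration_ci_covers_zero(self):
        """Under independence the Fisher r-to-z CI covers 0 in ~95% of replicates."""
        rng = np.random.default_rng(99)
        covered = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=28)
            y = rng.normal(size=28)
            lo, hi = bs.pearson_ci_fisher(float(np.corrcoef(x, y)[0, 1]), 28)
            covered += lo <= 0 <= hi
        assert 0.90 <= covered / reps <= 0.99

    def test_sem_estimates_present_per_level(self):
        rng = np.random.default_rng(1)
        pred = np.array([5.0, 5.0, 50.0, 50.0, 90.0, 90.0])
        obs = pred + rng.normal(0, 5, 6)
        levels = [0, 0, 3, 3, 5, 5]
        out = bs.evaluate_model(pred, obs, day1_counts=levels, rng=rng)
        assert set(out.model_sem) == {0.0, 3.0, 5.0}
        assert all(v >= 0 for v in out.participant_sem.values())
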