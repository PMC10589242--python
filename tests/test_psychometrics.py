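"""Psychometric fitting, thresholds, suppression scores, exclusion rules."""

import math

import numpy as np
import pandas as pd
import pytest

from graspsupp import (
    DegenerateFitError,
    DetectionTable,
    MissingDataError,
    ObserverModel,
    apply_exclusion,
    false_alarm_rate,
    fit_psychometric,
    suppression_score,
    tabulate_responses,
    threshold,
)
from graspsupp.design import DEFAULT_GRID
from graspsupp.psychometrics import PsychometricFit, psychometric_function

from conftest import binomial_tables

LEVELS = np.array(DEFAULT_GRID.levels)


class TestTabulateResponses:
    def _trials(self, blocks, intensities, responses):
        return pd.DataFrame(
            {
                "trial_id": range(1, len(blocks) + 1),
                "condition": blocks,
                "intensity_um": intensities,
                "response": responses,
            }
        )

    def test_all_no_baseline(self):
        ints = list(LEVELS) * 5 + [0.0] * 15
        df = self._trials(["baseline_pre"] * 45, ints, [False] * 45)
        tables = tabulate_responses(df)
        t = tables["baseline"]
        assert t.n_yes.sum() == 0
        assert t.n_total.sum() == 45

    def test_merged_baselines_counts(self):
        ints = (list(LEVELS) * 5 + [0.0] * 15) * 2
        blocks = ["baseline_pre"] * 45 + ["baseline_post"] * 45
        df = self._trials(blocks, ints, [True, False] * 45)
        tables = tabulate_responses(df)
        t = tables["baseline"]
        assert set(tables) == {"baseline"}
        catch = t.n_total[t.intensity_um == 0.0][0]
        assert catch == 30
        assert all(n == 10 for n in t.n_total[t.intensity_um > 0])

    def test_partition_conserves_trials(self):
        rng = np.random.default_rng(0)
        n = 120
        conds = rng.choice(["baseline_pre", "MD_same", "MD_different"], size=n)
        ints = rng.choice(np.concatenate([[0.0], LEVELS]), size=n)
        df = self._trials(conds, ints, rng.random(n) < 0.5)
        tables = tabulate_responses(df)
        assert sum(t.n_total.sum() for t in tables.values()) == n

    def test_missing_response_rejected(self):
        df = self._trials(["baseline_pre"] * 2, [0.0, 9.4], [True, None])
        with pytest.raises(ValueError, match="without a response"):
            tabulate_responses(df)


class TestFit:
    def test_parameter_recovery_dense_data(self):
        """Generated from a known function at n=200/level, the location comes back."""
        rng = np.random.default_rng(42)
        obs = ObserverModel(
            guess_rate=0.05, lapse_rate=0.01, baseline_threshold_um=25.0, width_um=20.0,
            threshold_shift_um={"c": 0.0},
        )
        errors = []
        for _ in range(20):
            table = binomial_tables(rng, obs, "c", LEVELS, reps=200, n_catch=200)
            fit = fit_psychometric(table)
            errors.append(threshold(fit) - 25.0)
        # bootstrap-scale SE at n=200/level is well under 1 um; allow 2 of those
        assert abs(np.mean(errors)) < 0.5
        assert np.median(np.abs(errors)) < 1.0

    def test_doubling_counts_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(1)
        obs = ObserverModel(threshold_shift_um={"c": 0.0})
        t1 = binomial_tables(rng, obs, "c", LEVELS, reps=10, n_catch=30)
        t2 = DetectionTable("c", t1.intensity_um, t1.n_yes * 2, t1.n_total * 2)
        f1, f2 = fit_psychometric(t1), fit_psychometric(t2)
        assert f1.location == pytest.approx(f2.location, abs=1e-3)
        assert f1.width == pytest.approx(f2.width, rel=1e-3)

    def test_all_no_degenerate(self):
        t = DetectionTable("c", np.concatenate([[0.0], LEVELS]), np.zeros(7, int), np.full(7, 10))
        with pytest.raises(DegenerateFitError, match="no"):
            fit_psychometric(t)

    def test_all_yes_degenerate(self):
        t = DetectionTable("c", np.concatenate([[0.0], LEVELS]), np.full(7, 10), np.full(7, 10))
        with pytest.raises(DegenerateFitError, match="yes"):
            fit_psychometric(t)

    def test_separable_step_degenerate(self):
        x = np.concatenate([[0.0], LEVELS])
        k = np.array([0, 0, 0, 0, 10, 10, 10])
        t = DetectionTable("c", x, k, np.full(7, 10))
        with pytest.raises(DegenerateFitError, match="separable"):
            fit_psychometric(t)

    def test_too_few_levels_rejected(self):
        t = DetectionTable("c", np.array([0.0, 10.0, 20.0]), np.array([1, 2, 3]), np.full(3, 10))
        with pytest.raises(ValueError, match="3 distinct"):
            fit_psychometric(t)

    def test_fitted_function_monotone(self):
        rng = np.random.default_rng(3)
        obs = ObserverModel(threshold_shift_um={"c": 0.0})
        for _ in range(10):
            table = binomial_tables(rng, obs, "c", LEVELS, reps=5, n_catch=15)
            try:
                fit = fit_psychometric(table)
            except DegenerateFitError:
                continue
            xs = np.linspace(0, 80, 400)
            psi = fit.predict(xs)
            assert np.all(np.diff(psi) >= -1e-12)


class TestThreshold:
    def _fit(self, guess, lapse, m=30.0, w=20.0):
        return PsychometricFit(guess, lapse, m, w, loglik=0.0, converged=True, condition="c")

    def test_midpoint_equals_location(self):
        assert threshold(self._fit(0.1, 0.02)) == pytest.approx(30.0)

    def test_modes_coincide_without_guess_or_lapse(self):
        f = self._fit(0.0, 0.0)
        assert threshold(f, "midpoint") == pytest.approx(threshold(f, "absolute"))

    def test_absolute_mode_analytic(self):
        # gamma=0.2, lambda=0: solve 0.2 + 0.8 F = 0.5 -> F = 0.375, below the midpoint
        f = self._fit(0.2, 0.0)
        s = f.width / (2 * math.log(19.0))
        expected = f.location + s * math.log(0.375 / 0.625)
        got = threshold(f, "absolute")
        assert got == pytest.approx(expected)
        assert got < f.location

    def test_unreachable_absolute_criterion(self):
        with pytest.raises(ValueError, match="unreachable"):
            threshold(self._fit(0.5, 0.0), "absolute")

    def test_non_converged_fit_rejected(self):
        f = PsychometricFit(0.1, 0.02, 30.0, 20.0, 0.0, converged=False)
        with pytest.raises(DegenerateFitError):
            threshold(f)


class TestSuppression:
    def _fit(self, m):
        return PsychometricFit(0.1, 0.02, m, 20.0, 0.0, True, condition="grasp")

    def test_identical_fits_zero(self):
        assert suppression_score(self._fit(25.0), self._fit(25.0)).value_um == 0.0

    def test_swap_negates(self):
        a, b = self._fit(30.0), self._fit(22.0)
        assert suppression_score(a, b).value_um == pytest.approx(-suppression_score(b, a).value_um)

    def test_positive_means_suppression(self):
        score = suppression_score(self._fit(28.0), self._fit(18.0))
        assert score.value_um == pytest.approx(10.0)


class TestExclusion:
    def _catch_table(self, n_yes, n_total=30):
        x = np.concatenate([[0.0], LEVELS])
        k = np.array([n_yes] + [1] * 6)
        n = np.array([n_total] + [5] * 6)
        return DetectionTable("baseline", x, k, n)

    def test_zero_false_alarms_keep(self):
        r = false_alarm_rate(self._catch_table(0))
        assert r == 0.0
        assert apply_exclusion(r)

    def test_boundary_nine_of_thirty_drops(self):
        r = false_alarm_rate(self._catch_table(9))
        assert r == pytest.approx(0.30)
        assert not apply_exclusion(r)  # strictly-below rule

    def test_eight_of_thirty_keeps(self):
        r = false_alarm_rate(self._catch_table(8))
        assert r == pytest.approx(8 / 30)
        assert apply_exclusion(r)

    def test_no_catch_row_raises(self):
        t = DetectionTable("baseline", LEVELS, np.ones(6, int), np.full(6, 5))
        with pytest.raises(MissingDataError):
            false_alarm_rate(t)


def test_model_reduces_to_guess_rate_at_zero_stimulus():
    p = psychometric_function(0.0, guess=0.1, lapse=0.0, location=30.0, width=20.0)
    assert 0.1 <= p < 0.11
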