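"""Per-participant ordinal preference models: fitting, scoring, comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gazepref.feature_stats import VARIABLES
from gazepref.preference_model import (
    PREDICTOR_SETS,
    compare_models,
    cross_validated_auc,
    fit_participant_model,
    model_auc,
)


def brute_force_auc(pos, neg):
    """All-pairs Mann-Whitney probability, the AUC oracle."""
    wins = sum(
        1.0 if p > q else 0.5 if p == q else 0.0
        for p, q in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


def feature_frame(rng, n_trials=60, effect=None, pid="P1"):
    """Random trial x product feature table; ``effect`` maps variable name
    to the mean shift added to the chosen product's value."""
    effect = effect or {}
    rows = []
    for trial in range(1, n_trials + 1):
        chosen = int(rng.integers(1, 6))
        for p in range(1, 6):
            row = {"participant_id": pid, "trial_id": trial, "product_id": p,
                   "chosen": p == chosen}
            for var in VARIABLES:
                row[var] = rng.standard_normal() + (
                    effect.get(var, 0.0) if p == chosen else 0.0
                )
            rows.append(row)
    return pd.DataFrame(rows)


class TestFitParticipantModel:
    def test_separable_predictor_gives_auc_one_negative_beta(self, rng):
        f = feature_frame(rng, n_trials=20)
        f["total_dwell_time"] = f["chosen"].astype(float)  # perfect predictor
        m = fit_participant_model(f, "dwell_only")
        assert m.auc == 1.0
        assert m.betas["total_dwell_time"] < 0  # chosen is the LOWER category

    def test_permuted_labels_give_chance_auc(self, rng):
        aucs = [
            fit_participant_model(feature_frame(rng), "dwell_only").auc
            for _ in range(10)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_informative_predictor_recovers_signal(self, rng):
        f = feature_frame(rng, effect={"total_dwell_time": 2.0})
        m = fit_participant_model(f, "all_gaze")
        assert m.auc > 0.8
        assert m.betas["total_dwell_time"] < 0
        assert abs(m.betas["total_dwell_time"]) > abs(m.betas["n_dwells"])

    def test_beta_sign_recovery_large_sample(self, rng):
        f = feature_frame(rng, n_trials=500, effect={"total_dwell_time": 1.0,
                                                     "n_dwells": 0.5})
        m = fit_participant_model(f, "all_gaze")
        assert m.betas["total_dwell_time"] < 0
        assert m.betas["n_dwells"] < 0
        assert abs(m.betas["median_dwell_duration"]) < abs(m.betas["n_dwells"])

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError, match="trials"):
            fit_participant_model(feature_frame(rng, n_trials=5), "dwell_only")

    def test_missing_pupil_rows_dropped_not_fatal(self, rng):
        f = feature_frame(rng)
        f.loc[(~f["chosen"]) & (f["product_id"] == 5), "mean_pupil"] = np.nan
        m = fit_participant_model(f, "gaze_plus_pupil")
        assert 0.0 <= m.auc <= 1.0

    def test_nested_models_never_lose_likelihood(self, rng):
        f = feature_frame(rng, effect={"total_dwell_time": 1.0})
        lls = {
            name: fit_participant_model(f, name).llf
            for name in PREDICTOR_SETS
        }
        assert lls["all_gaze"] >= lls["dwell_only"] - 1e-6
        assert lls["gaze_plus_pupil"] >= lls["all_gaze"] - 1e-6


class TestModelScoring:
    def test_model_auc_matches_brute_force_oracle(self, rng):
        f = feature_frame(rng, effect={"total_dwell_time": 1.0})
        m = fit_participant_model(f, "all_gaze")
        # recompute the score by hand and compare against all-pairs counting
        sub = f[np.isfinite(f[list(m.predictors)].to_numpy()).all(axis=1)]
        X = sub[list(m.predictors)].to_numpy()
        mean = np.array([m.scale_mean[p] for p in m.predictors])
        sd = np.array([m.scale_sd[p] for p in m.predictors])
        score = -((X - mean) / sd) @ m.beta_vector
        chosen = sub["chosen"].to_numpy(bool)
        expected = brute_force_auc(score[chosen], score[~chosen])
        assert model_auc(m, f) == pytest.approx(expected, abs=1e-12)
        assert m.auc == pytest.approx(expected, abs=1e-12)

    def test_cross_validated_auc_is_chance_under_null(self, rng):
        vals = [
            cross_validated_auc(feature_frame(rng), "all_gaze", seed=0)
            for _ in range(8)
        ]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.06)

    def test_agreement_with_unpenalized_logistic_regression(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        f = feature_frame(rng, effect={"total_dwell_time": 1.5})
        m = fit_participant_model(f, "all_gaze")
        X = f[list(m.predictors)].to_numpy()
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        y = f["chosen"].to_numpy(bool).astype(int)
        lr = sklearn.LogisticRegression(C=np.inf, max_iter=2000).fit(Z, y)
        # 2-category cumulative link == binary logistic up to sign
        np.testing.assert_allclose(-m.beta_vector, lr.coef_[0], atol=1e-3)


class TestCompareModels:
    def test_identical_auc_vectors(self):
        with pytest.warns(UserWarning):
            c = compare_models([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        assert c.mean_diff == 0.0 and c.t == 0.0

    def test_constant_gain(self):
        a = np.array([0.70, 0.75, 0.80])
        with pytest.warns(UserWarning):
            c = compare_models(a, a + 0.06)
        assert c.mean_diff == pytest.approx(0.06)
        assert c.sd_diff == 0.0

    def test_df_is_n_minus_one(self, rng):
        a = rng.uniform(0.6, 0.9, 61)
        c = compare_models(a, a + rng.normal(0.05, 0.01, 61))
        assert c.df == 60
        assert c.mean_diff > 0
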