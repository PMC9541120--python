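"""Per-product variables, ranks, paired tests, AUC and event-locked traces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazepref.dwell_extraction import Dwell
from gazepref.feature_stats import (
    VARIABLES,
    compute_features,
    event_locked_pupil,
    paired_comparison,
    rank_choice_distribution,
    rank_products,
    roc_auc,
)

FS = 30.0


def dwell(product, i_start, n_samples, trial=1):
    return Dwell(
        trial_id=trial,
        product_id=product,
        t_start=i_start / FS,
        t_end=(i_start + n_samples) / FS,
        n_samples=n_samples,
        duration=n_samples / FS,
        i_start=i_start,
    )


class TestComputeFeatures:
    def test_dwell_arithmetic(self):
        dwells = [dwell(1, 0, 6), dwell(1, 10, 12), dwell(1, 30, 18)]
        pupil = np.full(60, 3.0)
        f = compute_features(dwells, pupil, pupil, baseline=3.1, chosen=1, trial_id=1)
        row = f[f["product_id"] == 1].iloc[0]
        assert row["total_dwell_time"] == pytest.approx(1.2)
        assert row["median_dwell_duration"] == pytest.approx(0.4)
        assert row["n_dwells"] == 3
        assert row["mean_pupil"] == pytest.approx(3.0)
        assert row["mean_pupil_minus_baseline"] == pytest.approx(-0.1)
        assert bool(row["chosen"])

    def test_unvisited_product_zero_gaze_missing_pupil(self):
        f = compute_features([dwell(1, 0, 3)], np.full(10, 3.0), np.full(10, 3.0),
                             baseline=3.0, chosen=2, trial_id=1)
        row = f[f["product_id"] == 4].iloc[0]
        assert row["total_dwell_time"] == 0.0
        assert row["n_dwells"] == 0
        assert np.isnan(row["mean_pupil"])
        assert np.isnan(row["mean_detrended_pupil"])

    def test_exactly_one_chosen_per_trial(self):
        f = compute_features([], np.empty(0), np.empty(0), 3.0, chosen=3, trial_id=9)
        assert f["chosen"].sum() == 1
        assert f.loc[f["chosen"], "product_id"].iloc[0] == 3

    def test_pupil_mean_uses_only_dwell_samples(self):
        pupil = np.arange(12, dtype=float)
        f = compute_features([dwell(2, 3, 3)], pupil, pupil, 0.0, chosen=2, trial_id=1)
        row = f[f["product_id"] == 2].iloc[0]
        assert row["mean_pupil"] == pytest.approx(np.mean([3, 4, 5]))


class TestRankProducts:
    def test_simple_ordering(self):
        assert rank_products([5, 3, 4, 1, 2]).tolist() == [1, 3, 2, 5, 4]

    def test_ties_broken_by_product_id(self):
        assert rank_products([2, 2, 1, 1, 1]).tolist() == [1, 2, 3, 4, 5]

    def test_missing_ranks_below_observed(self):
        assert rank_products([1.0, np.nan, 3.0, 2.0, 0.5]).tolist() == [3, 5, 1, 2, 4]

    @given(
        values=st.lists(
            st.one_of(st.floats(-100, 100), st.just(float("nan"))),
            min_size=5,
            max_size=5,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_ranks_are_a_permutation(self, values):
        ranks = rank_products(values)
        assert sorted(ranks.tolist()) == [1, 2, 3, 4, 5]
        assert ranks.sum() == 15


class TestRankChoiceDistribution:
    def _features(self, values_per_trial, chosen_per_trial):
        rows = []
        for trial, (values, chosen) in enumerate(
            zip(values_per_trial, chosen_per_trial), start=1
        ):
            for p, v in enumerate(values, start=1):
                row = {"participant_id": "P1", "trial_id": trial, "product_id": p,
                       "chosen": p == chosen}
                for var in VARIABLES:
                    row[var] = v
                rows.append(row)
        return pd.DataFrame(rows)

    def test_always_rank_one(self):
        f = self._features([[9, 1, 1, 1, 1]] * 4, [1] * 4)
        dist = rank_choice_distribution(f)
        assert dist["total_dwell_time"].tolist() == [100.0, 0.0, 0.0, 0.0, 0.0]

    def test_columns_sum_to_100(self, rng):
        values = [rng.uniform(0, 5, 5).tolist() for _ in range(30)]
        chosen = rng.integers(1, 6, 30).tolist()
        dist = rank_choice_distribution(self._features(values, chosen))
        np.testing.assert_allclose(dist.sum(axis=0), 100.0)

    def test_uniform_choices_near_20_percent(self, rng):
        n = 2000
        values = [rng.uniform(0, 5, 5).tolist() for _ in range(n)]
        chosen = (np.arange(n) % 5 + 1).tolist()  # uniform over products
        dist = rank_choice_distribution(self._features(values, chosen))
        np.testing.assert_allclose(dist["total_dwell_time"], 20.0, atol=3.0)


class TestPairedComparison:
    def test_identical_vectors_degenerate(self):
        with pytest.warns(UserWarning):
            res = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_closed_form_small_case(self):
        res = paired_comparison([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        # differences [1, 2, 3]: t = 2 / (1 / sqrt(3)) = 2 sqrt(3)
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert res.df == 2

    def test_df_is_n_minus_one(self, rng):
        a = rng.standard_normal(61)
        res = paired_comparison(a + 0.5, a)
        assert res.df == 60


class TestRocAuc:
    def test_identical_multisets_give_half(self):
        assert roc_auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert roc_auc([4, 5, 6], [1, 2, 3]) == 1.0

    def test_small_case_brute_force(self):
        # pairs: (3,1)+ (3,2.5)+ (2,1)+ (2,2.5)- => 3/4
        assert roc_auc([3, 2], [1, 2.5]) == pytest.approx(0.75)

    @given(
        a=st.lists(st.integers(0, 5), min_size=1, max_size=10),
        b=st.lists(st.integers(0, 5), min_size=1, max_size=10),
    )
    @settings(max_examples=200, deadline=None)
    def test_complement_symmetry(self, a, b):
        assert roc_auc(a, b) + roc_auc(b, a) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(40) - 0.3
        f = lambda v: np.exp(3 * np.asarray(v))  # strictly increasing
        assert roc_auc(f(a), f(b)) == pytest.approx(roc_auc(a, b))

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])


class TestEventLockedPupil:
    def test_constant_pupil_flat_trace(self):
        d = np.full(60, 3.2)
        t = np.arange(60) / FS
        lags, trace, n = event_locked_pupil(d, t, FS, onsets=[0.5], window=0.5)
        assert n == 1
        np.testing.assert_allclose(trace, 3.2)
        assert len(lags) == 15

    def test_mean_of_two_onsets(self):
        d = np.array([0, 1, 2, 2, 3, 4], dtype=float)
        t = np.arange(6) / FS
        lags, trace, n = event_locked_pupil(d, t, FS, onsets=[0.0, 3 / FS], window=3 / FS)
        assert n == 2
        np.testing.assert_allclose(trace, [1, 2, 3])

    def test_truncated_segment_dropped(self):
        d = np.full(30, 3.0)
        t = np.arange(30) / FS
        lags, trace, n = event_locked_pupil(d, t, FS, onsets=[29 / FS], window=1.0)
        assert n == 0
        assert np.isnan(trace).all()
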