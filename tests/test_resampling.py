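"""Sampling, splitting (random and Kennard–Stone) and the sweep engine."""

import numpy as np
import pandas as pd
import pytest

from qsarval import (
    Dataset,
    SweepResult,
    SyntheticConfig,
    draw_sample,
    kennard_stone_split,
    make_dataset,
    mlr_spec,
    random_split,
    run_sweep,
    standardize_responses,
    summarize_sweep,
)


@pytest.fixture(scope="module")
def linear100():
    dataset, _ = make_dataset(SyntheticConfig(n=100, p=3, seed=7))
    return dataset


class TestDrawSample:
    def test_full_size_is_a_permutation(self, linear100, rng):
        sub = draw_sample(linear100, 100, rng)
        assert sorted(sub.y.tolist()) == sorted(linear100.y.tolist())

    def test_deterministic_given_rng(self, linear100):
        a = draw_sample(linear100, 30, np.random.default_rng(5))
        b = draw_sample(linear100, 30, np.random.default_rng(5))
        np.testing.assert_array_equal(a.X, b.X)

    def test_uniform_inclusion_frequencies(self, linear100):
        # each case included with probability 0.1 over 2000 draws of size 10
        counts = np.zeros(100)
        rng = np.random.default_rng(11)
        n_draws = 2000
        for _ in range(n_draws):
            sub = draw_sample(linear100, 10, rng)
            # identify drawn rows by matching the (unique) first response
            counts[np.isin(linear100.y, sub.y)] += 1
        freq = counts / n_draws
        se = np.sqrt(0.1 * 0.9 / n_draws)
        assert np.all(np.abs(freq - 0.1) < 3.5 * se)

    def test_oversized_request_rejected(self, linear100, rng):
        with pytest.raises(ValueError):
            draw_sample(linear100, 101, rng)

    def test_group_sampling_is_atomic(self, rng):
        X = np.repeat(np.arange(20.0)[:, None], 3, axis=0)
        y = X[:, 0] + rng.standard_normal(60) * 0.1
        d = Dataset(X=X, Y=y, groups=np.repeat(np.arange(20), 3))
        sub = draw_sample(d, 30, rng)
        _, counts = np.unique(sub.groups, return_counts=True)
        assert np.all(counts == 3)


class TestRandomSplit:
    @pytest.mark.parametrize(
        "size,expected_train,expected_test", [(100, 80, 20), (99, 79, 20)]
    )
    def test_eighty_twenty_rounding(self, linear100, size, expected_train,
                                    expected_test, rng):
        sub = draw_sample(linear100, size, rng)
        train, test = random_split(sub, 0.8, rng)
        assert (train.n, test.n) == (expected_train, expected_test)

    def test_disjoint_and_exhaustive(self, linear100, rng):
        sub = draw_sample(linear100, 50, rng)
        train, test = random_split(sub, 0.8, rng)
        combined = sorted(train.y.tolist() + test.y.tolist())
        assert combined == sorted(sub.y.tolist())

    def test_groups_never_straddle(self, rng):
        X = rng.standard_normal((50, 2))
        d = Dataset(X=X, Y=rng.standard_normal(50),
                    groups=np.repeat(np.arange(10), 5))
        train, test = random_split(d, 0.8, rng)
        assert set(train.groups) & set(test.groups) == set()


class TestKennardStone:
    def test_hand_traced_one_dimensional_case(self):
        d = Dataset(X=np.array([[0.0], [1.0], [10.0]]), Y=np.array([0.0, 1.0, 2.0]))
        train, test = kennard_stone_split(d, 2 / 3)
        assert sorted(train.X[:, 0].tolist()) == [0.0, 10.0]
        assert test.X[:, 0].tolist() == [1.0]

    def test_deterministic(self, linear100):
        a_train, _ = kennard_stone_split(linear100, 0.8)
        b_train, _ = kennard_stone_split(linear100, 0.8)
        np.testing.assert_array_equal(a_train.X, b_train.X)

    def test_exact_duplicates_split_across_sides(self):
        # twin points have min-distance 0 to each other, so once one is in
        # the training set the other is picked last and stays in the test set
        X = np.array([[0.0], [0.0], [5.0], [10.0], [2.0], [7.0]])
        d = Dataset(X=X, Y=np.arange(6.0))
        train, test = kennard_stone_split(d, 4 / 6)
        train_rows = set(train.Y.ravel().astype(int).tolist())
        assert (0 in train_rows) != (1 in train_rows)


class TestRunSweep:
    def test_record_bookkeeping(self, linear100):
        sw = run_sweep(linear100, [mlr_spec()], sizes=[30], n_repeats=3)
        assert len(sw.records) == 3
        assert (sw.records["n_train"] + sw.records["n_test"] == 30).all()

    def test_bit_identical_rerun(self, linear100):
        a = run_sweep(linear100, [mlr_spec()], sizes=[30, 60], n_repeats=4, seed=9)
        b = run_sweep(linear100, [mlr_spec()], sizes=[30, 60], n_repeats=4, seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_requested_size_beyond_dataset_rejected(self, linear100):
        with pytest.raises(ValueError):
            run_sweep(linear100, [mlr_spec()], sizes=[101], n_repeats=2)


class TestSummarize:
    def make_sweep(self, values):
        records = pd.DataFrame(
            {
                "dataset": "d", "scheme": "none", "family": "mlr",
                "spec": "mlr", "response": "y1", "size": 30,
                "r2": values, "rmse": 1.0, "q2_loo": 0.5, "rmse_loo": 1.0,
                "q2_f2": 0.4, "rmse_test": 1.0,
            }
        )
        return SweepResult(records=records)

    def test_single_record_summary_is_the_record(self):
        sw = self.make_sweep([0.7])
        out = summarize_sweep(sw, "median")
        assert out.loc[0, "r2"] == pytest.approx(0.7)

    def test_median_resists_outlier_mean_does_not(self):
        sw = self.make_sweep([0.5, 0.5, 0.5, 0.5, 100.0])
        assert summarize_sweep(sw, "median").loc[0, "r2"] == pytest.approx(0.5)
        assert summarize_sweep(sw, "mean").loc[0, "r2"] > 10

    def test_quartiles_bracket_median(self):
        sw = self.make_sweep(list(np.linspace(0, 1, 11)))
        q = summarize_sweep(sw, "quartiles")
        vals = q.set_index("quantile")["r2"]
        assert vals[0.25] <= vals[0.5] <= vals[0.75]


def test_standardize_responses_zscores_each_column():
    d, _ = make_dataset(SyntheticConfig(n=50, q=2, structure="latent_factor_multiresponse",
                                        p=4, n_factors=2, seed=3))
    s = standardize_responses(d)
    assert s.y_standardized
    np.testing.assert_allclose(s.Y.mean(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(s.Y.std(axis=0), 1, atol=1e-12)
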