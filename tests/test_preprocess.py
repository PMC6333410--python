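"""Splitting, frozen transform, jitter augmentation and the (n, t) grid."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import LinearRegression

from cellfactory.preprocess import (AugmentationParams, FrozenTransform,
                                    LeakageAudit, augment,
                                    grid_search_augmentation, split_ids)


def _frame(n=100, seed=0, with_targets=True):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"),
                      index=[f"r{i}" for i in range(n)])
    if with_targets:
        df["titer"] = rng.uniform(1, 10, size=n)
        df["rate"] = rng.uniform(0.1, 1, size=n)
    return df


class TestSplit:
    def test_ten_percent_of_hundred_is_ten(self):
        spec = split_ids([f"r{i}" for i in range(100)], 0.1, seed=0)
        assert len(spec.test_ids) == 10
        assert len(spec.train_ids) == 90
        assert set(spec.train_ids) | set(spec.test_ids) == {f"r{i}" for i in range(100)}
        assert set(spec.train_ids) & set(spec.test_ids) == set()

    def test_same_seed_reproduces_partition(self):
        ids = [f"r{i}" for i in range(57)]
        assert split_ids(ids, seed=4).assignment == split_ids(ids, seed=4).assignment

    def test_different_seed_moves_rows_not_sizes(self):
        ids = [f"r{i}" for i in range(57)]
        a, b = split_ids(ids, seed=1), split_ids(ids, seed=2)
        assert a.assignment != b.assignment
        assert len(a.test_ids) == len(b.test_ids)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_fraction_outside_unit_interval_rejected(self, frac):
        with pytest.raises(ValueError):
            split_ids([f"r{i}" for i in range(20)], frac)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            split_ids(list("abc"))


class TestFrozenTransform:
    def test_projection_columns_are_orthogonal(self):
        X = _frame(with_targets=False)
        Z = FrozenTransform(4).fit(X).transform(X)
        gram = Z.values.T @ Z.values
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0.0, atol=1e-8)

    def test_rank_caps_component_count(self):
        X = _frame(with_targets=False)  # 5 columns
        ft = FrozenTransform(40).fit(X)
        assert ft.n_components_ == 5

    def test_inverse_reproduces_training_rows(self):
        X = _frame(with_targets=False)
        ft = FrozenTransform(5).fit(X)
        back = ft.inverse_transform(ft.transform(X))
        assert np.allclose(back.values, X.values, atol=1e-8)

    def test_train_fitted_transform_differs_from_all_fitted(self):
        """The leakage guard is observable: projecting test rows with a
        train-only transform is not the same as refitting on everything."""
        X = _frame(60, seed=3, with_targets=False)
        train, test = X.iloc[:40], X.iloc[40:]
        z_frozen = FrozenTransform(3).fit(train).transform(test)
        z_leaky = FrozenTransform(3).fit(X).transform(test)
        assert not np.allclose(z_frozen.values, z_leaky.values, atol=1e-6)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            FrozenTransform().fit(_frame(1, with_targets=False))


class TestAugment:
    def test_tuned_parameters_give_fifty_copies_each(self):
        df = _frame(100)
        out = augment(df, AugmentationParams(n=50, t=0.1, seed=0))
        assert len(out) == 100 * 51

    def test_zero_jitter_copies_are_identical(self):
        df = _frame(20)
        out = augment(df, AugmentationParams(n=3, t=0.0, seed=0))
        for k in range(1, 4):
            copy = out.loc[[f"r0#aug{k}"]]
            assert copy[list("abcde") + ["titer", "rate"]].iloc[0].equals(
                df.loc["r0", list("abcde") + ["titer", "rate"]])

    @settings(max_examples=25, deadline=None)
    @given(t=st.floats(min_value=0.0, max_value=100.0),
           seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_jitter_respects_hard_bound(self, t, seed):
        df = _frame(10, seed=1)
        out = augment(df, AugmentationParams(n=4, t=t, seed=seed))
        ratio = (out["titer"] / out["source_record_id"].map(df["titer"])).values
        assert np.all(ratio >= 1 - t / 100 - 1e-12)
        assert np.all(ratio <= 1 + t / 100 + 1e-12)

    def test_features_copied_verbatim(self):
        df = _frame(15)
        out = augment(df, AugmentationParams(n=2, t=1.0, seed=5))
        feats = out[list("abcde")].groupby(out["source_record_id"]).nunique()
        assert (feats == 1).all().all()

    def test_null_targets_stay_null(self):
        df = _frame(10)
        df.loc["r0", "rate"] = np.nan
        out = augment(df, AugmentationParams(n=3, t=0.5, seed=2))
        assert out.loc[out.source_record_id == "r0", "rate"].isna().all()

    def test_reproducible_under_seed(self):
        df = _frame(10)
        a = augment(df, AugmentationParams(n=5, t=0.3, seed=9))
        b = augment(df, AugmentationParams(n=5, t=0.3, seed=9))
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("kwargs", [{"n": -1}, {"t": -0.1}, {"t": 101.0}])
    def test_out_of_range_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AugmentationParams(**{"n": 5, "t": 0.1, **kwargs})


class TestGridSearch:
    def _xy(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"),
                         index=[f"r{i}" for i in range(n)])
        y = pd.Series(2 * X["a"] - X["b"] + 0.1 * rng.normal(size=n),
                      index=X.index, name="titer")
        return X, y

    def test_single_cell_grid_returns_that_cell(self):
        X, y = self._xy()
        best, table = grid_search_augmentation(X, y, [10], [0.5], LinearRegression)
        assert (best.n, best.t) == (10, 0.5)
        assert len(table) == 1 and not table.failed.any()

    def test_ties_break_toward_smaller_n_then_t(self):
        X, y = self._xy()
        best, table = grid_search_augmentation(
            X, y, [30, 10], [0.8, 0.2],
            lambda: DummyRegressor(strategy="constant", constant=0.0))
        # a constant predictor is jitter-insensitive -> all cells tie exactly
        assert table.cv_r2.nunique() == 1
        assert (best.n, best.t) == (10, 0.2)

    def test_failing_cell_marked_and_search_continues(self):
        X, y = self._xy()
        calls = {"k": 0}

        def factory():
            calls["k"] += 1
            if calls["k"] == 1:  # first cell aborts on its first fold
                raise RuntimeError("synthetic failure")
            return LinearRegression()

        best, table = grid_search_augmentation(X, y, [10, 20], [0.5], factory)
        assert table.failed.sum() == 1
        assert best.n == 20

    def test_empty_grid_rejected(self):
        X, y = self._xy()
        with pytest.raises(ValueError):
            grid_search_augmentation(X, y, [], [0.5], LinearRegression)

    def test_noise_amplification_detected_at_large_t(self):
        """When jitter is the only difference, very large t degrades the
        cross-validated score relative to tiny t."""
        X, y = self._xy(n=80, seed=3)
        _, table = grid_search_augmentation(
            X, y, [20], [0.1, 60.0], LinearRegression, seed=1)
        small = table.loc[table.t == 0.1, "cv_r2"].iloc[0]
        large = table.loc[table.t == 60.0, "cv_r2"].iloc[0]
        assert small > large


class TestLeakageAudit:
    def test_clean_run_passes_and_leak_is_caught(self):
        audit = LeakageAudit()
        audit.record("transform_fit", ["r1", "r2"])
        audit.record("augmentation", ["r1#aug3"])
        audit.assert_clean(["r9"])
        audit.record("augmentation", ["r9#aug1"])
        with pytest.raises(AssertionError, match="augmentation"):
            audit.assert_clean(["r9"])
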