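"""Feature selection: variance filter, ANOVA-F, top-fraction, scaling, PCA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.feature_selection import f_classif

from enosekit.selection import (
    SelectionError,
    SelectionState,
    anova_f_scores,
    apply_standardizer,
    drop_zero_variance,
    fit_standardizer,
    project_pca,
    select_top_fraction,
)


def _random_matrix(rng, n=20, p=30, prefix="f"):
    return pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"{prefix}{i:03d}" for i in range(p)]
    )


class TestDropZeroVariance:
    def test_54_of_924_constant_columns(self):
        """A 924-column matrix with exactly 54 constant columns keeps 870."""
        rng = np.random.default_rng(0)
        df = _random_matrix(rng, n=30, p=924)
        const_cols = list(df.columns[::17])[:54]
        assert len(const_cols) == 54
        df[const_cols] = 1.0
        kept, removed = drop_zero_variance(df)
        assert kept.shape[1] == 870
        assert sorted(removed) == sorted(const_cols)

    def test_no_constant_columns_identity(self):
        df = _random_matrix(np.random.default_rng(1))
        kept, removed = drop_zero_variance(df)
        assert removed == []
        pd.testing.assert_frame_equal(kept, df)

    def test_single_distinct_row_retained(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 2.0], "b": [1.0, 2.0, 3.0, 4.0]})
        kept, removed = drop_zero_variance(df)
        assert "a" in kept.columns and removed == []

    def test_all_constant_is_degenerate(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(SelectionError, match="degenerate"):
            drop_zero_variance(df)


class TestAnovaF:
    def test_hand_oracle(self):
        """group0=[1,2,3], group1=[2,3,4]: SSB=1.5, MSW=1 -> F=1.5."""
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        assert anova_f_scores(df, y)["x"] == pytest.approx(1.5)

    def test_identical_groups_score_zero(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        assert anova_f_scores(df, y)["x"] == 0.0

    def test_equals_squared_pooled_t_and_sklearn(self):
        """Two-group F == t^2 (pooled), and matches sklearn, on 100 features."""
        rng = np.random.default_rng(7)
        df = _random_matrix(rng, n=24, p=100)
        y = np.array([0] * 12 + [1] * 12)
        ours = anova_f_scores(df, y).to_numpy()
        ref, _ = f_classif(df.to_numpy(), y)
        np.testing.assert_allclose(ours, ref, rtol=1e-9)
        from scipy.stats import ttest_ind
        t, _ = ttest_ind(df[y == 0], df[y == 1], equal_var=True)
        np.testing.assert_allclose(ours, t**2, rtol=1e-9)

    def test_zero_within_variance_is_infinite_sentinel(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 2.0, 2.0], "y": [0.0, 1.0, 0.0, 1.1]})
        scores = anova_f_scores(df, np.array([0, 0, 1, 1]))
        assert np.isinf(scores["x"])
        sel = select_top_fraction(scores, 0.5)
        assert sel == ["x"]

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        df = _random_matrix(rng, n=30, p=20)
        y = rng.integers(0, 2, 30)
        y[:2], y[-2:] = 0, 1
        base = anova_f_scores(df, y)
        trans = anova_f_scores(df * -3.7 + 11.0, y)
        np.testing.assert_allclose(base.to_numpy(), trans.to_numpy(), rtol=1e-9)

    def test_single_class_rejected(self):
        df = _random_matrix(np.random.default_rng(9), n=6, p=3)
        with pytest.raises(SelectionError):
            anova_f_scores(df, np.zeros(6, dtype=int))


class TestSelectTopFraction:
    def test_ceiling_rule_870_to_27(self):
        rng = np.random.default_rng(10)
        scores = pd.Series(rng.random(870),
                           index=[f"f{i:03d}" for i in range(870)])
        assert len(select_top_fraction(scores, 0.03)) == 27

    def test_exact_product(self):
        scores = pd.Series(np.arange(100.0), index=[f"f{i}" for i in range(100)])
        sel = select_top_fraction(scores, 0.03)
        assert len(sel) == 3
        assert set(sel) == {"f97", "f98", "f99"}

    def test_all_equal_scores_take_canonical_prefix(self):
        scores = pd.Series(np.ones(10), index=[f"f{i}" for i in range(10)])
        assert select_top_fraction(scores, 0.25) == ["f0", "f1", "f2"]

    def test_at_least_one_kept(self):
        scores = pd.Series([0.5], index=["only"])
        assert select_top_fraction(scores, 0.001) == ["only"]

    def test_empty_scores_rejected(self):
        with pytest.raises(SelectionError):
            select_top_fraction(pd.Series(dtype=float), 0.03)


class TestStandardizer:
    def test_population_convention(self):
        std = fit_standardizer(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        mean, sd = std["a"]
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_self_transform_is_zero_mean_unit_sd(self):
        rng = np.random.default_rng(11)
        df = _random_matrix(rng, n=40, p=5)
        std = fit_standardizer(df)
        out = apply_standardizer(std, df)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_test_rows_use_training_parameters(self):
        train = pd.DataFrame({"a": [0.0, 2.0]})
        test = pd.DataFrame({"a": [10.0, 20.0]})
        std = fit_standardizer(train)
        out = apply_standardizer(std, test)
        np.testing.assert_allclose(out["a"], [9.0, 19.0])  # (x - 1) / 1

    def test_zero_sd_column_rejected(self):
        with pytest.raises(SelectionError, match="zero-SD"):
            fit_standardizer(pd.DataFrame({"a": [1.0, 1.0]}))

    def test_missing_column_named(self):
        std = fit_standardizer(pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(SelectionError, match="a"):
            apply_standardizer(std, pd.DataFrame({"b": [1.0]}))


class TestSelectionState:
    def test_fit_transform_separation(self):
        """Mutating held-out rows leaves the fitted state bit-identical."""
        rng = np.random.default_rng(12)
        df = _random_matrix(rng, n=40, p=50)
        y = np.array([0] * 20 + [1] * 20)
        train = df.iloc[:30]
        state_a = SelectionState.fit(train, y[:30])
        df.iloc[30:] = 1e6  # corrupt test rows only
        state_b = SelectionState.fit(df.iloc[:30], y[:30])
        assert state_a.selected == state_b.selected
        assert state_a.f_scores == state_b.f_scores
        assert state_a.standardizer == state_b.standardizer

    def test_json_round_trip(self):
        rng = np.random.default_rng(13)
        df = _random_matrix(rng, n=20, p=30)
        y = np.array([0] * 10 + [1] * 10)
        state = SelectionState.fit(df, y)
        back = SelectionState.from_json(state.to_json())
        assert back.selected == state.selected
        assert back.standardizer == state.standardizer
        pd.testing.assert_frame_equal(back.transform(df), state.transform(df))


class TestPCA:
    def test_rank_one_data(self):
        t = np.linspace(0, 1, 30)
        df = pd.DataFrame({"a": t, "b": 2 * t})
        res = project_pca(df, k=2)
        assert res.explained_variance_ratio[0] > 0.999

    def test_scores_uncorrelated(self):
        rng = np.random.default_rng(14)
        df = _random_matrix(rng, n=50, p=8)
        res = project_pca(df, k=3)
        corr = np.corrcoef(res.scores.to_numpy().T)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(15)
        df = _random_matrix(rng, n=30, p=6)
        a = project_pca(df, k=2)
        b = project_pca(df.copy(), k=2)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        for comp in a.loadings:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_k_too_large_rejected(self):
        df = _random_matrix(np.random.default_rng(16), n=5, p=3)
        with pytest.raises(SelectionError):
            project_pca(df, k=5)
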