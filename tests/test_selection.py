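"""LDA wrapper, forward search, iterated selection aggregation."""

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from gaitenv.errors import ConfigError
from gaitenv.selection import (IteratedForwardSelector, aggregate_selection,
                               forward_select, lda_cv_error,
                               participant_folds, run_selection)
from conftest import make_noise_table


def _folds(table, k=10, seed=0):
    rng = np.random.default_rng(seed)
    return participant_folds(table["participant"].to_numpy(),
                             table["condition"].to_numpy(), k, rng)


class TestParticipantFolds:
    def test_each_participant_one_fold(self):
        table, _ = make_noise_table(40, seed=1)
        folds = _folds(table)
        assert set(folds) == set(table["participant"])
        assert set(folds.values()) <= set(range(10))

    def test_stratified_balance(self):
        table, _ = make_noise_table(40, seed=1)
        folds = _folds(table)
        sizes = np.bincount(list(folds.values()), minlength=10)
        assert sizes.max() - sizes.min() <= 2

    def test_k_exceeding_participants_rejected(self):
        table, _ = make_noise_table(6, seed=1)
        with pytest.raises(ConfigError):
            _folds(table, k=10)


class TestLdaCvError:
    def test_separable_feature_zero_error(self):
        table, names = make_noise_table(40, informative="f00", shift=10.0,
                                        seed=2)
        err = lda_cv_error(table, ["f00"], _folds(table), feature_names=names)
        assert err == 0.0

    def test_permutation_null_near_half(self):
        table, names = make_noise_table(60, seed=3)
        errs = [lda_cv_error(table, names[:5], _folds(table, seed=s),
                             feature_names=names) for s in range(5)]
        assert np.mean(errs) == pytest.approx(0.5, abs=0.15)

    def test_matches_bayes_error_two_gaussians(self):
        """1-D equal-variance two-Gaussian data: CV error approaches the
        closed-form boundary error Phi(-delta / 2 sigma)."""
        rng = np.random.default_rng(4)
        n = 2000
        delta = 1.0
        x = np.concatenate([rng.normal(0, 1, n // 2),
                            rng.normal(delta, 1, n // 2)])
        import pandas as pd

        table = pd.DataFrame({
            "f00": x,
            "participant": [f"p{i}" for i in range(n)],
            "condition": ["treadmill"] * (n // 2) + ["sidewalk"] * (n // 2),
        })
        err = lda_cv_error(table, ["f00"], _folds(table, seed=1),
                           feature_names=["f00"])
        bayes = norm.cdf(-delta / 2)
        assert err == pytest.approx(bayes, abs=0.03)

    def test_agrees_with_sklearn_lda(self):
        """Closed-form pooled-covariance discriminant reproduces sklearn's
        equal-prior LDA predictions fold by fold."""
        table, names = make_noise_table(60, informative="f01", shift=1.0,
                                        seed=5)
        sub = names[:4]
        folds = _folds(table, seed=2)
        fold_of_row = table["participant"].map(folds).to_numpy()
        X = table[sub].to_numpy()
        y = table["condition"].to_numpy()
        mism = 0.0
        total = 0
        for f in range(10):
            va = fold_of_row == f
            lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
            lda.fit(X[~va], y[~va])
            mism += np.sum(lda.predict(X[va]) != y[va])
            total += va.sum()
        ours = lda_cv_error(table, sub, folds, feature_names=names,
                            standardize=False)
        # identical per-fold error averages (folds are equal-sized here)
        assert ours == pytest.approx(mism / total, abs=1e-12)


class TestForwardSelect:
    def test_planted_feature_selected_first(self):
        hits = 0
        for seed in range(20):
            table, names = make_noise_table(40, informative="f07", shift=3.0,
                                            seed=seed)
            order = forward_select(table, _folds(table, seed=seed), names)
            hits += bool(order) and order[0] == "f07"
        assert hits >= 19

    def test_duplicate_feature_selected_once(self):
        table, names = make_noise_table(40, informative="f00", shift=3.0,
                                        seed=8)
        table["f00_copy"] = table["f00"]
        names2 = names + ["f00_copy"]
        order = forward_select(table, _folds(table, seed=8), names2)
        assert ("f00" in order) ^ ("f00_copy" in order)

    def test_error_monotone_along_order(self):
        table, names = make_noise_table(40, informative="f03", shift=2.0,
                                        seed=9)
        folds = _folds(table, seed=9)
        order = forward_select(table, folds, names)
        errs = [lda_cv_error(table, order[: i + 1], folds, feature_names=names)
                for i in range(len(order))]
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_all_noise_selects_little(self):
        table, names = make_noise_table(40, seed=10)
        order = forward_select(table, _folds(table, seed=10), names)
        # nothing informative: the greedy run stops early
        assert len(order) <= 5


class TestAggregation:
    def test_retention_boundary_inclusive_at_threshold(self):
        names = [f"f{i:02d}" for i in range(5)]
        orders = [["f00"]] * 10 + [["f01"]] * 9 + [["f02", "f00"]] * 0 \
            + [[] for _ in range(81)]
        freq, retained, _ = aggregate_selection(orders, names, threshold=0.10)
        assert len(orders) == 100
        assert freq["f00"] == pytest.approx(0.10)
        assert "f00" in retained      # exactly 10 of 100: kept
        assert "f01" not in retained  # 9 of 100: dropped

    def test_mean_rank_always_first(self):
        names = ["a", "b"]
        orders = [["a", "b"], ["a"], ["a", "b"]]
        _, retained, mean_rank = aggregate_selection(orders, names, 0.10)
        assert mean_rank["a"] == 1.0
        assert mean_rank["b"] == 2.0


class TestRunSelection:
    def test_fixed_seed_reproducible(self):
        table, names = make_noise_table(30, informative="f02", shift=2.0,
                                        seed=11)
        a = run_selection(table, feature_names=names, n_iterations=10, seed=5)
        b = run_selection(table, feature_names=names, n_iterations=10, seed=5)
        assert a.per_iteration_orders == b.per_iteration_orders
        assert a.retained == b.retained

    def test_estimator_interface(self):
        table, names = make_noise_table(30, informative="f02", shift=3.0,
                                        seed=12)
        sel = IteratedForwardSelector(n_iterations=10, random_state=5)
        sel.fit(table[names + ["participant", "condition"]])
        assert "f02" in sel.retained_
        out = sel.transform(table)
        assert list(out.columns) == sel.retained_
        assert sel.get_support().sum() == len(sel.retained_)
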