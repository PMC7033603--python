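"""Binary SVM classification of running environment.

An RBF-kernel support vector machine is trained on the retained features,
with both hyper-parameters (box constraint C and kernel scale gamma) chosen
by an inner 5-fold grid search over a fixed logarithmic grid 10^{-3..3};
ties go to the smaller box constraint (then the smaller gamma), so the
search is deterministic given the fold draw.  Features are standardized
with training statistics.

Evaluation is participant-wise: training-set accuracy by 10-fold
cross-validation with each participant's rows in exactly one fold, and
independent-test accuracy on the held-out both-environments cohort.  The
whole procedure is repeated over iterations that differ only in their fold
partitions, and per-participant correct-prediction counts are tallied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigError, DatasetError
from .selection import participant_folds

DEFAULT_GRID = tuple(10.0 ** np.arange(-3, 4))


class EnvironmentSVC(ClassifierMixin, BaseEstimator):
    """RBF SVM with internal standardization and inner-CV grid search.

    Fitted attributes: ``best_C_``, ``best_gamma_``, ``inner_cv_accuracy_``,
    ``classes_``.  Predictions are invariant to affine rescaling of any
    input feature (absorbed by standardization).
    """

    def __init__(self, C_grid=DEFAULT_GRID, gamma_grid=DEFAULT_GRID,
                 inner_folds=5, random_state=0):
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.inner_folds = inner_folds
        self.random_state = random_state

    def _standardize(self, X):
        return (X - self.mean_) / self.scale_

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ConfigError("single-class training input")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Z = self._standardize(X)

        # cap inner splits by the smaller class so stratification is possible
        min_class = int(np.min(np.unique(y, return_counts=True)[1]))
        n_splits = max(2, min(self.inner_folds, min_class))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=self.random_state)
        splits = list(skf.split(Z, y))
        best = (-1.0, None, None)
        for C in self.C_grid:          # ascending; strict > keeps smaller C on ties
            for gamma in self.gamma_grid:
                accs = []
                for tr, va in splits:
                    svc = SVC(C=C, gamma=gamma, kernel="rbf")
                    svc.fit(Z[tr], y[tr])
                    accs.append(float(np.mean(svc.predict(Z[va]) == y[va])))
                acc = float(np.mean(accs))
                if acc > best[0] + 1e-12:
                    best = (acc, C, gamma)
        self.inner_cv_accuracy_, self.best_C_, self.best_gamma_ = best
        self.svc_ = SVC(C=self.best_C_, gamma=self.best_gamma_, kernel="rbf")
        self.svc_.fit(Z, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(self._standardize(np.asarray(X, dtype=float)))

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.decision_function(
            self._standardize(np.asarray(X, dtype=float)))


def train_svm(train_table: pd.DataFrame, features: list[str],
              seed: int = 0) -> EnvironmentSVC:
    """Fit :class:`EnvironmentSVC` on a feature table."""
    missing = [f for f in features if f not in train_table.columns]
    if missing:
        raise DatasetError(f"missing features: {missing}")
    model = EnvironmentSVC(random_state=seed)
    model.fit(train_table[features].to_numpy(dtype=float),
              train_table["condition"].to_numpy())
    return model


def participantwise_kfold_accuracy(
    train_table: pd.DataFrame,
    features: list[str],
    k: int = 10,
    seed: int = 0,
    return_folds: bool = False,
):
    """Accuracy (%) of participant-wise k-fold cross-validation.

    Participants (not rows) are partitioned; every row of a held-out
    participant is predicted by a model trained without that participant.
    """
    rng = np.random.default_rng(seed)
    folds = participant_folds(
        train_table["participant"].to_numpy(),
        train_table["condition"].to_numpy(), k, rng)
    fold_of_row = train_table["participant"].map(folds).to_numpy()
    correct = total = 0
    for f in range(k):
        va = fold_of_row == f
        if not va.any():
            continue
        model = train_svm(train_table.loc[~va], features,
                          seed=int(rng.integers(2**31)))
        pred = model.predict(train_table.loc[va, features].to_numpy(dtype=float))
        correct += int(np.sum(pred == train_table.loc[va, "condition"].to_numpy()))
        total += int(va.sum())
    acc = 100.0 * correct / total
    return (acc, folds) if return_folds else acc


def evaluate_independent(model: EnvironmentSVC, test_table: pd.DataFrame,
                         features: list[str]) -> tuple[pd.DataFrame, float]:
    """Predict every test row; return per-row results and accuracy (%)."""
    missing = [f for f in features if f not in test_table.columns]
    if missing:
        raise DatasetError(f"missing features in test table: {missing}")
    pred = model.predict(test_table[features].to_numpy(dtype=float))
    res = test_table[["participant", "condition"]].copy()
    res["predicted"] = pred
    res["correct"] = res["predicted"] == res["condition"]
    accuracy = 100.0 * float(res["correct"].mean())
    return res, accuracy


@dataclass
class EvalResult:
    """Per-iteration accuracies and per-participant correctness counts."""

    cv_accuracies: np.ndarray
    test_accuracies: np.ndarray
    per_participant_counts: pd.DataFrame
    n_iterations: int
    fold_assignments: list[dict[str, int]] = field(default_factory=list)

    @property
    def cv_mean(self) -> float:
        return float(np.mean(self.cv_accuracies))

    @property
    def cv_sd(self) -> float:
        return float(np.std(self.cv_accuracies, ddof=1))

    @property
    def test_mean(self) -> float:
        return float(np.mean(self.test_accuracies))

    @property
    def test_sd(self) -> float:
        return float(np.std(self.test_accuracies, ddof=1))

    def summary(self) -> str:
        return (
            f"cross-validated training accuracy: {self.cv_mean:.2f}% "
            f"(SD {self.cv_sd:.2f}%)\n"
            f"independent test accuracy: {self.test_mean:.2f}% "
            f"(SD {self.test_sd:.2f}%)"
        )


def run_experiment(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    features: list[str],
    n_iterations: int = 100,
    k: int = 10,
    seed: int = 0,
) -> EvalResult:
    """Repeat CV + independent evaluation over fresh fold partitions.

    Per iteration: a fresh participant-wise k-fold partition and a fresh
    inner-CV seed; the final model for independent testing is refit on the
    full training table.  Counts of correct predictions per test participant
    and condition are accumulated (max = ``n_iterations``).
    """
    if not features:
        raise ConfigError("retained feature set is empty")
    rng = np.random.default_rng(seed)
    cv_accs, test_accs, assignments = [], [], []
    participants = test_table["participant"].unique()
    conditions = sorted(test_table["condition"].unique())
    counts = pd.DataFrame(0, index=participants, columns=conditions)
    for _ in range(n_iterations):
        it_seed = int(rng.integers(2**31))
        acc, folds = participantwise_kfold_accuracy(
            train_table, features, k=k, seed=it_seed, return_folds=True)
        cv_accs.append(acc)
        assignments.append(folds)
        model = train_svm(train_table, features, seed=int(rng.integers(2**31)))
        res, test_acc = evaluate_independent(model, test_table, features)
        test_accs.append(test_acc)
        for _, row in res.iterrows():
            if row["correct"]:
                counts.loc[row["participant"], row["condition"]] += 1
    return EvalResult(
        cv_accuracies=np.asarray(cv_accs),
        test_accuracies=np.asarray(test_accs),
        per_participant_counts=counts,
        n_iterations=n_iterations,
        fold_assignments=assignments,
    )
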