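"""Iterated forward-sequential feature selection with an LDA wrapper.

Each iteration draws a fresh participant-wise 10-fold partition (no
participant's rows split across folds, stratified by condition where counts
allow), runs a greedy forward search scored by cross-validated
linear-discriminant misclassification, and logs the selection order.
Features selected in at least ``threshold`` (default 10%) of iterations are
retained, and each retained feature is reported with its mean 1-based
selection rank over the iterations in which it was selected.

The wrapper is a two-class pooled-covariance, equal-prior linear discriminant
evaluated in closed form: per training fold the class means and pooled
covariance of *all* candidate features are computed once and sliced per
subset, which makes the greedy search orders of magnitude faster than
refitting a model object per candidate.  Features are standardized with
training-fold statistics.  A singular pooled covariance receives a 1e-8
ridge (with a logged warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigError, FeatureError


# ---------------------------------------------------------------------------
# participant-wise fold construction

def participant_folds(
    participants: np.ndarray,
    conditions: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Assign each participant to one of ``k`` folds, stratified by condition.

    Rows of one participant always share a fold.  Participants are shuffled
    within each condition stratum and dealt round-robin, so folds are as
    balanced as the counts allow.
    """
    per_participant = pd.Series(conditions, index=participants)
    strata: dict[str, list[str]] = {}
    for pid in pd.unique(participants):
        conds = sorted(set(per_participant.loc[[pid]]))
        strata.setdefault("+".join(conds), []).append(pid)
    if len(pd.unique(participants)) < k:
        raise ConfigError(f"k={k} exceeds participant count")
    assignment: dict[str, int] = {}
    offset = 0
    for key in sorted(strata):
        pids = list(strata[key])
        order = rng.permutation(len(pids))
        for j, idx in enumerate(order):
            assignment[pids[idx]] = (offset + j) % k
        offset += len(pids)
    return assignment


# ---------------------------------------------------------------------------
# closed-form LDA wrapper

class _FoldLDA:
    """Per-fold sufficient statistics for subset-sliced LDA scoring."""

    def __init__(self, X_tr, y_tr, X_va, y_va, standardize=True):
        if len(np.unique(y_tr)) != 2:
            raise FeatureError("both classes required in every training fold")
        self.classes = np.unique(y_tr)
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        if not standardize:
            mu, sd = np.zeros_like(mu), np.ones_like(sd)
        Z_tr = (X_tr - mu) / sd
        self.Z_va = (X_va - mu) / sd
        self.y_va = y_va
        g0 = Z_tr[y_tr == self.classes[0]]
        g1 = Z_tr[y_tr == self.classes[1]]
        self.mu0, self.mu1 = g0.mean(axis=0), g1.mean(axis=0)
        n0, n1 = len(g0), len(g1)
        S0 = np.cov(g0, rowvar=False, ddof=1) if n0 > 1 else np.zeros((X_tr.shape[1],) * 2)
        S1 = np.cov(g1, rowvar=False, ddof=1) if n1 > 1 else np.zeros((X_tr.shape[1],) * 2)
        self.S = ((n0 - 1) * np.atleast_2d(S0) + (n1 - 1) * np.atleast_2d(S1)) / max(
            n0 + n1 - 2, 1
        )

    def error(self, idx: np.ndarray) -> float:
        S = self.S[np.ix_(idx, idx)]
        d = self.mu1[idx] - self.mu0[idx]
        try:
            w = np.linalg.solve(S, d)
        except np.linalg.LinAlgError:
            warnings.warn("singular pooled covariance; adding 1e-8 ridge")
            w = np.linalg.solve(S + 1e-8 * np.eye(len(idx)), d)
        mid = (self.mu0[idx] + self.mu1[idx]) / 2.0
        scores = (self.Z_va[:, idx] - mid) @ w
        pred = np.where(scores > 0, self.classes[1], self.classes[0])
        return float(np.mean(pred != self.y_va))


def _make_fold_stats(X, y, fold_of_row, k, standardize=True):
    stats = []
    for f in range(k):
        va = fold_of_row == f
        if not va.any():
            continue
        tr = ~va
        stats.append(_FoldLDA(X[tr], y[tr], X[va], y[va], standardize=standardize))
    return stats


def lda_cv_error(
    table: pd.DataFrame,
    subset: list[str],
    folds: dict[str, int],
    feature_names: list[str] | None = None,
    standardize: bool = True,
) -> float:
    """Cross-validated LDA misclassification rate of a feature subset.

    ``folds`` maps participant to fold id (from :func:`participant_folds`).
    The error is the unweighted mean of per-fold misclassification rates.
    """
    if not subset:
        raise FeatureError("subset must be non-empty")
    names = feature_names or list(subset)
    X = table[names].to_numpy(dtype=float)
    y = table["condition"].to_numpy()
    fold_of_row = table["participant"].map(folds).to_numpy()
    k = int(max(folds.values())) + 1
    stats = _make_fold_stats(X, y, fold_of_row, k, standardize=standardize)
    idx = np.array([names.index(f) for f in subset])
    return float(np.mean([s.error(idx) for s in stats]))


def forward_select(
    table: pd.DataFrame,
    folds: dict[str, int],
    feature_names: list[str],
    max_features: int | None = None,
    standardize: bool = True,
) -> list[str]:
    """Greedy forward search: add the feature minimizing the wrapper CV error.

    Stops when no candidate strictly reduces the error or ``max_features`` is
    reached.  Ties are broken by the lowest index in ``feature_names`` (the
    canonical ordering).
    """
    X = table[feature_names].to_numpy(dtype=float)
    y = table["condition"].to_numpy()
    fold_of_row = table["participant"].map(folds).to_numpy()
    k = int(max(folds.values())) + 1
    stats = _make_fold_stats(X, y, fold_of_row, k, standardize=standardize)

    selected: list[int] = []
    current_error = np.inf
    limit = max_features if max_features is not None else len(feature_names)
    while len(selected) < limit:
        best_j, best_err = None, current_error
        for j in range(len(feature_names)):
            if j in selected:
                continue
            idx = np.array(selected + [j])
            err = float(np.mean([s.error(idx) for s in stats]))
            if err < best_err - 1e-12:  # strict improvement; first j wins ties
                best_j, best_err = j, err
        if best_j is None:
            break
        selected.append(best_j)
        current_error = best_err
    return [feature_names[j] for j in selected]


# ---------------------------------------------------------------------------
# iteration and aggregation

@dataclass
class SelectionResult:
    """Aggregate of the iterated selection."""

    per_iteration_orders: list[list[str]]
    retention_frequency: pd.Series
    retained: list[str]
    mean_rank: pd.Series
    n_iterations: int
    threshold: float

    def rank_table(self) -> pd.DataFrame:
        """Retained features sorted by mean selection rank."""
        df = pd.DataFrame(
            {
                "mean_rank": self.mean_rank.loc[self.retained],
                "retention_frequency": self.retention_frequency.loc[self.retained],
            }
        )
        return df.sort_values(["mean_rank", "retention_frequency"]).rename_axis(
            "feature"
        )


def aggregate_selection(
    orders: list[list[str]],
    feature_names: list[str],
    threshold: float = 0.10,
) -> tuple[pd.Series, list[str], pd.Series]:
    """Retention frequencies, retained set and mean ranks from raw orders.

    The retention boundary is inclusive: a feature selected in exactly
    ``threshold``-fraction of iterations is retained.
    """
    n = len(orders)
    counts = pd.Series(0, index=list(feature_names), dtype=float)
    rank_sums = pd.Series(0.0, index=list(feature_names))
    for order in orders:
        for pos, feat in enumerate(order, start=1):
            counts[feat] += 1
            rank_sums[feat] += pos
    freq = counts / n
    retained = [f for f in feature_names if counts[f] >= threshold * n - 1e-9]
    with np.errstate(invalid="ignore"):
        mean_rank = rank_sums / counts
    return freq, retained, mean_rank


def run_selection(
    table: pd.DataFrame,
    feature_names: list[str] | None = None,
    n_iterations: int = 100,
    threshold: float = 0.10,
    k: int = 10,
    max_features: int | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Iterated forward selection over fresh participant-wise fold partitions."""
    from .features import FEATURE_NAMES

    names = list(feature_names or FEATURE_NAMES)
    rng = np.random.default_rng(seed)
    orders = []
    for _ in range(n_iterations):
        folds = participant_folds(
            table["participant"].to_numpy(), table["condition"].to_numpy(), k, rng
        )
        orders.append(forward_select(table, folds, names, max_features=max_features))
    freq, retained, mean_rank = aggregate_selection(orders, names, threshold)
    return SelectionResult(
        per_iteration_orders=orders,
        retention_frequency=freq,
        retained=retained,
        mean_rank=mean_rank,
        n_iterations=n_iterations,
        threshold=threshold,
    )


class IteratedForwardSelector(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer around :func:`run_selection`.

    Parameters mirror the procedure: ``n_iterations`` fold redraws,
    ``threshold`` retention fraction (inclusive boundary), ``k_folds``
    participant-wise folds, optional ``max_features`` cap.

    Fitted attributes: ``retained_``, ``retention_frequency_``,
    ``mean_rank_``, ``per_iteration_orders_``, ``feature_names_in_``.
    """

    def __init__(self, n_iterations=100, threshold=0.10, k_folds=10,
                 max_features=None, random_state=0):
        self.n_iterations = n_iterations
        self.threshold = threshold
        self.k_folds = k_folds
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None, groups=None):
        """``X``: feature columns; ``y``: condition labels; ``groups``:
        participant ids (defaults to ``X``'s 'participant' column)."""
        table = X.copy()
        if y is not None:
            table["condition"] = np.asarray(y)
        if groups is not None:
            table["participant"] = np.asarray(groups)
        names = [c for c in table.columns if c not in ("participant", "condition", "role")]
        result = run_selection(
            table,
            feature_names=names,
            n_iterations=self.n_iterations,
            threshold=self.threshold,
            k=self.k_folds,
            max_features=self.max_features,
            seed=self.random_state,
        )
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.result_ = result
        self.retained_ = result.retained
        self.retention_frequency_ = result.retention_frequency
        self.mean_rank_ = result.mean_rank
        self.per_iteration_orders_ = result.per_iteration_orders
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "retained_")
        return np.isin(self.feature_names_in_, self.retained_)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "retained_")
        return X[self.retained_]
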