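"""Feature ranking by permutation importance and binary-search selection.

Ranking. For a fitted random forest with per-tree bootstrap bookkeeping, the
importance of feature j on tree t is the change in that tree's out-of-bag
(OOB) loss when column j is randomly permuted over the tree's OOB records:
for regression the increase in mean-squared error, for binary labels the
decrease in accuracy. A feature never used by a tree contributes 0 on that
tree. The overall importance VI(x_j) is the mean over trees, and its
z-score is VI divided by the standard error of the per-tree values,
sd / sqrt(n_tree); features whose per-tree importances have zero spread get
z = 0. Features are ranked by descending z-score.

Selection (BSFS — binary search feature selection). Given the ranking and
an evaluation oracle mapping a threshold k to the score of a model built on
the top-k features, the search first evaluates the full set k = D and keeps
halving k (floor division) while the score does not decrease. When a
halving from k_hi to k_lo does decrease the score, the search bisects
upward inside (k_lo, k_hi): evaluate k_lo + (k_hi - k_lo) // 2, move the
lower bound up whenever the score does not exceed the best seen, and stop
when the interval is exhausted. The selected threshold is the evaluated k
with the maximal score, the earliest (largest-k) evaluation winning ties —
so a flat oracle returns the full feature set. Oracle calls are cached by k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImportanceReport",
    "BSFSTrace",
    "permutation_importance",
    "bsfs_search",
    "top_k_feature_names",
    "stub_oracle",
]

EvaluationOracle = Callable[[int], float]


@dataclass(frozen=True)
class ImportanceReport:
    """Per-feature importances, z-scores and ranks (rank 1 = largest z)."""

    table: pd.DataFrame  # columns: name, vi, z_score, rank; sorted by rank

    def __post_init__(self) -> None:
        ranks = sorted(self.table["rank"])
        if ranks != list(range(1, len(self.table) + 1)):
            raise ValueError("ranks must be a permutation of 1..D")

    @property
    def n_features(self) -> int:
        return len(self.table)

    def ranked_names(self) -> list[str]:
        return list(self.table["name"])

    def z_of(self, name: str) -> float:
        row = self.table.loc[self.table["name"] == name, "z_score"]
        if row.empty:
            raise KeyError(name)
        return float(row.iloc[0])


def _oob_indices(n_samples: int, sampled: np.ndarray) -> np.ndarray:
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.flatnonzero(mask)


def permutation_importance(
    model,
    X,
    y,
    *,
    mode: Literal["regression_mse", "classification_accuracy"] = "regression_mse",
    seed: int = 0,
) -> ImportanceReport:
    """Out-of-bag permutation importance of every feature of a fitted forest.

    Parameters
    ----------
    model : fitted sklearn forest
        Must expose ``estimators_`` and ``estimators_samples_`` (bootstrap
        bookkeeping), e.g. the output of
        :func:`sirnapred.model_eval.fit_forest`.
    X : DataFrame or array, shape (n, D)
        Feature matrix the forest was trained on.
    y : array-like, shape (n,)
        Activities (regression mode) or binary labels (classification mode).
    mode : str
        ``"regression_mse"``: per-tree OOB MSE after permutation minus
        before. ``"classification_accuracy"``: OOB accuracy before minus
        after.
    seed : int
        Seeds the permutations.

    Returns
    -------
    ImportanceReport
        Features sorted by descending z-score; ties broken by original
        column order for a deterministic ranking.
    """
    names = (
        list(X.columns)
        if isinstance(X, pd.DataFrame)
        else [f"x{j}" for j in range(np.asarray(X).shape[1])]
    )
    Xa = np.ascontiguousarray(np.asarray(X, dtype=float))
    ya = np.asarray(y)
    n, D = Xa.shape
    rng = np.random.default_rng(seed)
    estimators = model.estimators_
    n_tree = len(estimators)
    vi_t = np.zeros((n_tree, D))

    for t, (est, sampled) in enumerate(zip(estimators, model.estimators_samples_)):
        oob = _oob_indices(n, np.asarray(sampled))
        if oob.size == 0:
            warnings.warn(
                f"tree {t} has no out-of-bag samples; it contributes 0 importance",
                stacklevel=2,
            )
            continue
        used = np.unique(est.tree_.feature)
        used = used[used >= 0]
        X_oob = Xa[oob].copy()
        y_oob = ya[oob]
        base_pred = est.predict(X_oob)
        if mode == "regression_mse":
            base = float(np.mean((y_oob - base_pred) ** 2))
        elif mode == "classification_accuracy":
            base = float(np.mean(base_pred == y_oob))
        else:
            raise ValueError(f"unknown importance mode {mode!r}")
        for j in used:
            original = X_oob[:, j].copy()
            X_oob[:, j] = original[rng.permutation(oob.size)]
            perm_pred = est.predict(X_oob)
            X_oob[:, j] = original
            if mode == "regression_mse":
                vi_t[t, j] = float(np.mean((y_oob - perm_pred) ** 2)) - base
            else:
                vi_t[t, j] = base - float(np.mean(perm_pred == y_oob))

    vi = vi_t.mean(axis=0)
    sd = vi_t.std(axis=0, ddof=1) if n_tree > 1 else np.zeros(D)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, vi / (sd / math.sqrt(n_tree)), 0.0)
    order = np.lexsort((np.arange(D), -z))
    table = pd.DataFrame(
        {
            "name": [names[j] for j in order],
            "vi": vi[order],
            "z_score": z[order],
            "rank": np.arange(1, D + 1),
        }
    )
    return ImportanceReport(table=table)


def top_k_feature_names(ranked: ImportanceReport, k: int) -> list[str]:
    """Names of the k highest-z features, in rank order."""
    if not 1 <= k <= ranked.n_features:
        raise ValueError(f"k={k} outside 1..{ranked.n_features}")
    return ranked.ranked_names()[:k]


@dataclass
class BSFSTrace:
    """Log of a binary-search feature selection run."""

    steps: list[tuple[int, int, float]] = field(default_factory=list)  # (step, k, score)
    selected_k: int = 0

    @property
    def visited_k(self) -> list[int]:
        return [k for _, k, _ in self.steps]

    @property
    def selected_score(self) -> float:
        return dict((k, s) for _, k, s in self.steps)[self.selected_k]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "k", "score"])


class OracleError(RuntimeError):
    """Raised when the evaluation oracle fails at some k; carries the trace."""

    def __init__(self, k: int, trace: BSFSTrace, cause: Exception):
        super().__init__(f"evaluation oracle failed at k={k}: {cause}")
        self.k = k
        self.partial_trace = trace


def stub_oracle(table: dict[int, float]) -> EvaluationOracle:
    """An oracle that replays a fixed k -> score table (e.g. published runs)."""

    def oracle(k: int) -> float:
        if k not in table:
            raise KeyError(f"stub oracle has no score for k={k}")
        return table[k]

    return oracle


def bsfs_search(oracle: EvaluationOracle, d: int) -> BSFSTrace:
    """Halving-then-bisection search for the best feature-count threshold.

    Parameters
    ----------
    oracle : callable
        Maps a candidate threshold k (use the top-k ranked features) to a
        scalar score, e.g. a cross-validated Pearson correlation. Must be
        deterministic for a fixed k.
    d : int
        Number of ranked features (the search starts at k = d), >= 2.

    Returns
    -------
    BSFSTrace
        Every evaluated (k, score) in order, plus the selected threshold.
    """
    if d < 2:
        raise ValueError("need at least 2 ranked features")
    trace = BSFSTrace()
    cache: dict[int, float] = {}

    def evaluate(k: int) -> float:
        if k not in cache:
            try:
                cache[k] = float(oracle(k))
            except Exception as exc:
                raise OracleError(k, trace, exc) from exc
            trace.steps.append((len(trace.steps) + 1, k, cache[k]))
        return cache[k]

    # Phase 1: halve while the score does not decrease.
    k = d
    score = evaluate(k)
    best_k, best_score = k, score
    lo = hi = None
    while k // 2 >= 1 and k // 2 != k:
        k_next = k // 2
        s_next = evaluate(k_next)
        if s_next < score:
            lo, hi = k_next, k
            break
        if s_next > best_score:
            best_k, best_score = k_next, s_next
        k, score = k_next, s_next

    # Phase 2: bisect upward inside the bracketing interval.
    if lo is not None and hi is not None:
        while hi - lo > 1:
            mid = lo + (hi - lo) // 2
            s_mid = evaluate(mid)
            if s_mid > best_score:
                best_k, best_score = mid, s_mid
            lo = mid

    trace.selected_k = best_k
    return trace
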