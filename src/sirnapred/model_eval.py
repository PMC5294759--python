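"""Random-Forest regression of siRNA activity and evaluation statistics.

The predictor is an ensemble of regression trees grown on bootstrap samples
with a random subset of ``mtry`` candidate features per split; the ensemble
prediction is the mean over trees. Defaults follow common regression-forest
practice: 500 trees, mtry = floor(D/3), minimum leaf size 5, unlimited
depth. Evaluation uses the Pearson correlation between observed and
predicted activities and, for the binary potent/nonpotent reading at the
0.7 activity cut, ROC analysis (sensitivity vs 1 - specificity over all
distinct score cuts, trapezoid AUC).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold

from .selection import EvaluationOracle, ImportanceReport, top_k_feature_names

__all__ = [
    "ModelConfig",
    "EvaluationResult",
    "fit_forest",
    "pearson",
    "roc_analysis",
    "grid_search",
    "cv_pcc",
    "make_cv_oracle",
    "make_holdout_oracle",
]


@dataclass(frozen=True)
class ModelConfig:
    """Forest hyperparameters.

    n_trees : number of trees N (default 500).
    mtry : candidate features per split; None means floor(D/3), at least 1.
    seed : root seed governing bootstrap and split sampling.
    min_samples_leaf : minimum records per leaf (default 5).
    """

    n_trees: int = 500
    mtry: int | None = None
    seed: int = 0
    min_samples_leaf: int = 5

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


def _resolve_mtry(cfg: ModelConfig, d: int) -> int:
    if cfg.mtry is None:
        return max(1, d // 3)
    if cfg.mtry > d:
        raise ValueError(f"mtry={cfg.mtry} exceeds the {d} available features")
    return cfg.mtry


def fit_forest(X, y, cfg: ModelConfig = ModelConfig()) -> RandomForestRegressor:
    """Fit the activity-regression forest with bootstrap bookkeeping retained."""
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError("X and y disagree on the number of records")
    if np.isnan(Xa).any() or np.isnan(ya).any():
        raise ValueError("missing values are not supported")
    model = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=_resolve_mtry(cfg, Xa.shape[1]),
        min_samples_leaf=cfg.min_samples_leaf,
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(Xa, ya)
    return model


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation, 1/(n-1) sum of paired z-scores.

    Uses sample (ddof=1) standard deviations. Raises on zero variance,
    where the correlation is undefined.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = xa.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sx = xa.std(ddof=1)
    sy = ya.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined: zero variance input")
    zx = (xa - xa.mean()) / sx
    zy = (ya - ya.mean()) / sy
    return float(np.sum(zx * zy) / (n - 1))


@dataclass(frozen=True)
class EvaluationResult:
    """ROC summary of predicted activities against binary potency labels."""

    roc_points: tuple[tuple[float, float], ...]  # (1 - specificity, sensitivity)
    auc: float
    pcc: float | None = None

    def sensitivity_at(self, specificity: float) -> float:
        """Sensitivity at the largest operating point with specificity >= target."""
        eligible = [
            sens for fpr, sens in self.roc_points if 1.0 - fpr >= specificity
        ]
        if not eligible:
            raise ValueError(f"no operating point reaches specificity {specificity}")
        return max(eligible)


def roc_analysis(
    scores: Sequence[float], labels: Sequence[int | bool], pcc: float | None = None
) -> EvaluationResult:
    """ROC curve and trapezoid AUC of scores against binary labels.

    Operating points are taken at every distinct score cut (plus the
    all-negative sentinel); sensitivity = TP/(TP+FN) and specificity =
    TN/(TN+FP) at each cut. Requires both classes present.
    """
    ya = np.asarray(labels).astype(int)
    sa = np.asarray(scores, dtype=float)
    if set(np.unique(ya)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    fpr, tpr, _ = _sk_roc_curve(ya, sa, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return EvaluationResult(
        roc_points=tuple(zip(fpr.tolist(), tpr.tolist())), auc=auc, pcc=pcc
    )


def cv_pcc(
    X: pd.DataFrame,
    y: Sequence[float],
    cfg: ModelConfig,
    folds: int = 5,
) -> float:
    """Mean out-of-fold Pearson correlation over a K-fold split."""
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    pccs = []
    for fold, (tr, te) in enumerate(kf.split(Xa)):
        model = fit_forest(Xa[tr], ya[tr], replace(cfg, seed=cfg.seed + fold))
        pccs.append(pearson(model.predict(Xa[te]), ya[te]))
    return float(np.mean(pccs))


def make_cv_oracle(
    X: pd.DataFrame,
    y: Sequence[float],
    ranked: ImportanceReport,
    cfg: ModelConfig,
    folds: int = 5,
) -> EvaluationOracle:
    """BSFS oracle: k -> K-fold cross-validated PCC of a top-k-feature model."""

    def oracle(k: int) -> float:
        cols = top_k_feature_names(ranked, k)
        return cv_pcc(X[cols], y, cfg, folds=folds)

    return oracle


def make_holdout_oracle(
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    X_eval: pd.DataFrame,
    y_eval: Sequence[float],
    ranked: ImportanceReport,
    cfg: ModelConfig,
) -> EvaluationOracle:
    """BSFS oracle: k -> PCC of a top-k model on a fixed held-out split."""
    y_tr = np.asarray(y_train, dtype=float)
    y_ev = np.asarray(y_eval, dtype=float)

    def oracle(k: int) -> float:
        cols = top_k_feature_names(ranked, k)
        model = fit_forest(X_train[cols], y_tr, cfg)
        return pearson(model.predict(np.asarray(X_eval[cols], dtype=float)), y_ev)

    return oracle


def grid_search(
    X: pd.DataFrame,
    y: Sequence[float],
    n_grid: Iterable[int],
    mtry_grid: Iterable[int],
    oracle: Callable[[ModelConfig], float] | None = None,
    *,
    base: ModelConfig = ModelConfig(),
    folds: int = 5,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Pick (n_trees, mtry) maximizing cross-validated PCC over a grid.

    Ties favor smaller n_trees, then smaller mtry. Returns the winning
    config and the full grid of scores.
    """
    n_values = sorted(set(n_grid))
    m_values = sorted(set(mtry_grid))
    if not n_values or not m_values:
        raise ValueError("grids must be nonempty")
    score_fn = oracle or (lambda cfg: cv_pcc(X, y, cfg, folds=folds))
    rows = []
    best_cfg: ModelConfig | None = None
    best_score = -np.inf
    for n in n_values:
        for m in m_values:
            cfg = replace(base, n_trees=n, mtry=m)
            s = float(score_fn(cfg))
            rows.append((n, m, s))
            if s > best_score:
                best_cfg, best_score = cfg, s
    assert best_cfg is not None
    return best_cfg, pd.DataFrame(rows, columns=["n_trees", "mtry", "pcc"])
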