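"""Feature ranking and the pairwise-classification harness.

Features are ranked per task pair with the two-class Fisher
discriminant criterion J = (mu1 - mu2)^2 / (s1^2 + s2^2); the top-k are
fed to an RBF-kernel SVM whose C and gamma are tuned by cross-validated
grid search on the training portion of each stratified shuffle split.
Performance is Cohen's kappa on the held-out predictions, averaged over
splits.  Ranking and tuning see only training samples, so the harness
is leak-free by construction; a "global ranking" switch exists to mimic
selection on the pooled data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.model_selection import (GridSearchCV, StratifiedKFold,
                                     train_test_split)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


def all_task_pairs(tasks) -> list[tuple[str, str]]:
    """All unordered task pairs, in canonical order (21 for 7 tasks)."""
    return list(combinations(tasks, 2))


def fisher_score(values: np.ndarray, labels: np.ndarray) -> float:
    """Two-class Fisher discriminant criterion for one feature.

    J = (mu1 - mu2)^2 / (s1^2 + s2^2) with unbiased class variances.
    Degenerate cases: both variances zero with equal means -> 0; with
    different means -> +inf (maps to top rank).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs >= 2 samples")
    num = (a.mean() - b.mean()) ** 2
    den = a.var(ddof=1) + b.var(ddof=1)
    if den == 0:
        return 0.0 if num == 0 else float("inf")
    return float(num / den)


def fisher_scores(X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """Vectorized Fisher scores for every column of X (NaN-tolerant).

    Columns that are NaN for any sample are scored on their non-NaN
    samples; all-NaN or single-class-empty columns score 0.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("fisher_scores is a two-class criterion")
    A = X[y == classes[0]].to_numpy(dtype=float)
    B = X[y == classes[1]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_a, mu_b = np.nanmean(A, axis=0), np.nanmean(B, axis=0)
        va = np.nanvar(A, axis=0, ddof=1)
        vb = np.nanvar(B, axis=0, ddof=1)
        num = (mu_a - mu_b) ** 2
        den = va + vb
        J = num / den
    J = np.where(den == 0, np.where(num == 0, 0.0, np.inf), J)
    J = np.where(np.isnan(J), 0.0, J)
    return pd.Series(J, index=X.columns)


def select_top_k(scores: pd.Series, k: int) -> list[str]:
    """Names of the k highest-scoring features; ties break
    lexicographically by name."""
    if k > len(scores):
        raise ValueError(f"k={k} exceeds {len(scores)} scored features")
    order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in order[:k]]


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a square confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e); returns 0 when p_e = 1.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = c.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(c) / total
    p_e = float(np.sum(c.sum(axis=1) * c.sum(axis=0)) / total ** 2)
    if p_e == 1:
        return 0.0
    return float((p_o - p_e) / (1 - p_e))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    c = np.zeros((len(classes), len(classes)))
    for t, p in zip(y_true, y_pred):
        c[idx[t], idx[p]] += 1
    return c


@dataclass
class EvalConfig:
    """Settings for the pairwise classification harness."""

    train_fraction: float = 0.9
    n_splits: int = 100
    top_k: int = 2000
    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple = (1e-4, 1e-3, 1e-2, 1e-1, "scale")
    inner_cv: int = 3
    seed: int = 0
    global_ranking: bool = False   # rank on pooled data (leaky; off)

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class PairResult:
    """Kappa scores of one task pair across splits."""

    pair: tuple[str, str]
    kappas: np.ndarray
    selected: list[list[str]] = field(default_factory=list)

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(self.kappas))


def pairwise_classify(X: pd.DataFrame, y: pd.Series | np.ndarray,
                      pair: tuple[str, str],
                      cfg: EvalConfig) -> PairResult:
    """Evaluate one task pair under repeated stratified shuffle splits.

    Deterministic for fixed (X, y, cfg): every split's partition,
    ranking, and SVM tuning derive from per-split seeds spawned from
    ``cfg.seed``.
    """
    y = np.asarray(y)
    mask = np.isin(y, pair)
    Xp, yp = X[mask].reset_index(drop=True), y[mask]
    for t in pair:
        if (yp == t).sum() < 10:
            raise ValueError(f"task {t!r} has fewer than 10 samples")
    k = min(cfg.top_k, Xp.shape[1])
    split_seeds = np.random.SeedSequence(cfg.seed).generate_state(
        cfg.n_splits) % (2 ** 31)

    global_rank: list[str] | None = None
    if cfg.global_ranking:
        global_rank = select_top_k(fisher_scores(Xp, yp), k)

    kappas = np.empty(cfg.n_splits)
    selected: list[list[str]] = []
    classes = sorted(pair)
    for s in range(cfg.n_splits):
        seed = int(split_seeds[s])
        idx_tr, idx_te = train_test_split(
            np.arange(len(yp)), test_size=1 - cfg.train_fraction,
            stratify=yp, random_state=seed)
        X_tr, y_tr = Xp.iloc[idx_tr], yp[idx_tr]
        X_te, y_te = Xp.iloc[idx_te], yp[idx_te]
        feats = global_rank if global_rank is not None else select_top_k(
            fisher_scores(X_tr, y_tr), k)
        selected.append(feats)
        # degenerate connectivity frames: impute with train medians
        med = X_tr[feats].median()
        A_tr = X_tr[feats].fillna(med).to_numpy(dtype=float)
        A_te = X_te[feats].fillna(med).to_numpy(dtype=float)
        model = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf")),
        ])
        search = GridSearchCV(
            model,
            {"svm__C": list(cfg.C_grid), "svm__gamma": list(cfg.gamma_grid)},
            cv=StratifiedKFold(cfg.inner_cv, shuffle=True, random_state=seed),
            n_jobs=1,
        )
        search.fit(A_tr, y_tr)
        pred = search.predict(A_te)
        kappas[s] = cohen_kappa(_confusion(y_te, pred, classes))
    return PairResult(pair=pair, kappas=kappas, selected=selected)


def compare_feature_sets(res_a: PairResult, res_b: PairResult,
                         alpha: float = 0.05) -> dict:
    """Two-sided Wilcoxon rank-sum test between two kappa distributions.

    Returns a verdict dict with the p-value, significance at ``alpha``,
    and the direction of the mean difference.
    """
    if len(res_a.kappas) != len(res_b.kappas):
        raise ValueError("kappa vectors must have equal length")
    if np.ptp(res_a.kappas) == 0 and np.ptp(res_b.kappas) == 0:
        logger.warning("both kappa distributions are constant; rank-sum "
                       "verdict is degenerate")
    stat, p = spstats.ranksums(res_a.kappas, res_b.kappas)
    diff = res_b.mean_kappa - res_a.mean_kappa
    return {
        "p_value": float(p),
        "significant": bool(p < alpha),
        "direction": "b_greater" if diff > 0 else
                     ("a_greater" if diff < 0 else "equal"),
        "mean_difference": float(diff),
    }
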