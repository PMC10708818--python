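"""Eigenvector prestige ranking of tasks and features.

The 21 pairwise metrics (kappa or Fisher scores) of the 7-task protocol
fill the upper triangle of a symmetric 7x7 interaction matrix with zero
diagonal.  Its leading eigenvector — nonnegative for an irreducible
nonnegative matrix by Perron-Frobenius — ranks the tasks by the latent
influence they exert across all pairings; scaling it by the leading
eigenvalue preserves relative magnitudes when averaging across dataset
folds.  The same machinery, applied to per-feature Fisher matrices,
ranks features and feature groups per task.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TASKS

logger = logging.getLogger(__name__)


@dataclass
class InteractionMatrix:
    """Symmetric pairwise-metric matrix over a fixed label order."""

    M: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        n = len(self.labels)
        if self.M.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.M, self.M.T):
            raise ValueError("interaction matrix must be symmetric")


@dataclass
class PrestigeScore:
    """Leading-eigenvector ranking of an interaction matrix."""

    v: np.ndarray            # unit-norm nonnegative leading eigenvector
    eigenvalue: float
    labels: tuple[str, ...]

    @property
    def scaled(self) -> np.ndarray:
        return self.eigenvalue * self.v

    def as_series(self, scaled: bool = True) -> pd.Series:
        vals = self.scaled if scaled else self.v
        return pd.Series(vals, index=list(self.labels))


def build_interaction_matrix(pair_metrics: dict[tuple[str, str], float],
                             labels=TASKS) -> InteractionMatrix:
    """Assemble the symmetric matrix from unordered-pair metrics.

    Every pair of ``labels`` must be present (either key order).
    Negative values (possible for kappa) are clipped to zero with a
    logged count so the matrix stays nonnegative.
    """
    labels = tuple(labels)
    n = len(labels)
    idx = {t: i for i, t in enumerate(labels)}
    M = np.zeros((n, n))
    n_clipped = 0
    for a, b in ((x, y) for i, x in enumerate(labels)
                 for y in labels[i + 1:]):
        if (a, b) in pair_metrics:
            v = pair_metrics[(a, b)]
        elif (b, a) in pair_metrics:
            v = pair_metrics[(b, a)]
        else:
            raise ValueError(f"missing pair metric for ({a}, {b})")
        if v < 0:
            n_clipped += 1
            v = 0.0
        M[idx[a], idx[b]] = M[idx[b], idx[a]] = v
    if n_clipped:
        logger.warning("clipped %d negative pair metrics to 0", n_clipped)
    return InteractionMatrix(M=M, labels=labels)


def prestige(im: InteractionMatrix) -> PrestigeScore:
    """Leading eigenpair of the interaction matrix.

    The eigenvector of the algebraically largest eigenvalue is
    sign-fixed so its largest-magnitude entry is positive and tiny
    negative entries (|x| < 1e-10) are clipped to zero.  An all-zero
    matrix yields a zero score with a warning.
    """
    M = im.M
    if not (M[~np.eye(len(im.labels), dtype=bool)] >= 0).all():
        raise ValueError("off-diagonal entries must be nonnegative")
    if not M.any():
        logger.warning("all-zero interaction matrix: zero prestige score")
        return PrestigeScore(v=np.zeros(len(im.labels)), eigenvalue=0.0,
                             labels=im.labels)
    w, V = np.linalg.eigh(M)
    lam = float(w[-1])
    v = V[:, -1]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    v = np.where(np.abs(v) < 1e-10, 0.0, v)
    v = v / np.linalg.norm(v)
    return PrestigeScore(v=v, eigenvalue=lam, labels=im.labels)


def amalgamate(scores: list[PrestigeScore]) -> np.ndarray:
    """Elementwise mean of the eigenvalue-scaled vectors across folds."""
    if not scores:
        raise ValueError("no prestige scores to amalgamate")
    labels = scores[0].labels
    for s in scores[1:]:
        if s.labels != labels:
            raise ValueError("label order differs across folds")
    return np.mean([s.scaled for s in scores], axis=0)


def feature_prestige(feature_pair_scores: pd.DataFrame,
                     labels=TASKS) -> pd.DataFrame:
    """Per-feature prestige vectors from per-feature pairwise scores.

    ``feature_pair_scores`` has columns feature_name, task_a, task_b,
    score (21 rows per feature).  Returns one row per feature with the
    eigenvalue and the scaled prestige component per task.
    """
    labels = tuple(labels)
    rows = []
    for fname, grp in feature_pair_scores.groupby("feature_name", sort=True):
        metrics = {(r.task_a, r.task_b): r.score
                   for r in grp.itertuples(index=False)}
        score = prestige(build_interaction_matrix(metrics, labels))
        rows.append({"feature_name": fname, "eigenvalue": score.eigenvalue,
                     **dict(zip(labels, score.scaled))})
    return pd.DataFrame(rows)


def _parse_descriptor(name: str) -> dict[str, str]:
    parts = name.split("__")
    if len(parts) != 3:
        return {"feature_type": name, "channel": "", "band": ""}
    return {"feature_type": parts[0], "channel": parts[1], "band": parts[2]}


def aggregate_prestige(feature_vectors: pd.DataFrame,
                       group_by: str = "feature_type",
                       labels=TASKS) -> pd.DataFrame:
    """Aggregate per-feature prestige vectors by descriptor field.

    ``group_by`` is one of feature_type, channel, band.  Emits both the
    mean and the sum (cumulative score) of the member features' scaled
    components per task.
    """
    if group_by not in ("feature_type", "channel", "band"):
        raise ValueError(f"unknown grouping key {group_by!r}")
    if feature_vectors.empty:
        raise ValueError("no feature vectors to aggregate")
    desc = feature_vectors["feature_name"].map(
        lambda n: _parse_descriptor(n)[group_by])
    cols = list(labels)
    grouped = feature_vectors[cols].groupby(desc)
    mean = grouped.mean().add_suffix("_mean")
    total = grouped.sum().add_suffix("_sum")
    out = pd.concat([mean, total], axis=1)
    out.index.name = group_by
    return out.reset_index()
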