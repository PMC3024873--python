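"""Precision-recall evaluation of database retrieval against group labels.

For every query, candidates retrieved at a distance threshold are compared
with the query's classification group; precision and recall are averaged
over queries at matched thresholds, and the curve is summarized by the area
under precision vs recall. For a random ranking the AUC approaches the
positive-pair fraction of the database (not 0.5, which is the ROC
convention), so skewed databases have small random baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .retrieval import RankedList

__all__ = ["PRCurve", "precision_recall", "pr_auc"]


@dataclass
class PRCurve:
    """Averaged precision and recall per distance threshold."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        self.recall = np.asarray(self.recall, dtype=float)
        if not (len(self.thresholds) == len(self.precision) == len(self.recall)):
            raise ValueError("threshold/precision/recall lengths differ")
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be ascending")
        if np.any(np.diff(self.recall) < -1e-12):
            raise ValueError("recall must be non-decreasing with threshold")


def precision_recall(
    ranked: list[RankedList],
    labels: dict[str, str],
    thresholds: np.ndarray | None = None,
) -> PRCurve:
    """Average precision-recall over queries at shared distance thresholds.

    Precision at a threshold is the same-group fraction of the retrieved
    set (defined as 1 when nothing is retrieved); recall is the retrieved
    same-group count over the query's group size (query excluded). Queries
    whose group has no other member are skipped with a warning.

    ``thresholds`` defaults to the union of all observed distances, which
    yields the exact step curve.
    """
    if not ranked:
        raise ValueError("no ranked lists supplied")
    for rl in ranked:
        for pid in [rl.query_id, *rl.ids()]:
            if pid not in labels:
                raise KeyError(f"no group label for id {pid!r}")

    if thresholds is None:
        all_d = np.concatenate([rl.distances() for rl in ranked if rl.hits])
        thresholds = np.unique(all_d)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be ascending")

    prec_sum = np.zeros(len(thresholds))
    rec_sum = np.zeros(len(thresholds))
    n_queries = 0
    for rl in ranked:
        qgroup = labels[rl.query_id]
        is_pos = np.array([labels[i] == qgroup for i in rl.ids()], dtype=float)
        n_pos = int(is_pos.sum())
        if n_pos == 0:
            warnings.warn(
                f"query {rl.query_id!r} has no other member of group "
                f"{qgroup!r}; skipped",
                stacklevel=2,
            )
            continue
        d = rl.distances()
        # d is ascending, so prefix counts give retrieved/positive totals
        k = np.searchsorted(d, thresholds, side="right")
        pos_prefix = np.concatenate([[0.0], np.cumsum(is_pos)])
        pos_k = pos_prefix[k]
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.where(k > 0, pos_k / np.maximum(k, 1), 1.0)
        prec_sum += prec
        rec_sum += pos_k / n_pos
        n_queries += 1
    if n_queries == 0:
        raise ValueError("no evaluable queries (all groups singletons)")
    return PRCurve(
        thresholds=thresholds,
        precision=prec_sum / n_queries,
        recall=rec_sum / n_queries,
    )


def pr_auc(curve: PRCurve) -> float:
    """Trapezoidal area under precision vs recall.

    The curve is extended horizontally from its smallest achieved recall
    down to recall 0, so the integral always spans [0, max recall].
    """
    if len(curve.recall) < 2:
        raise ValueError("need at least 2 curve points")
    order = np.argsort(curve.recall, kind="stable")
    recall = curve.recall[order]
    precision = curve.precision[order]
    if recall[0] > 0:
        recall = np.concatenate([[0.0], recall])
        precision = np.concatenate([[precision[0]], precision])
    auc = float(np.trapezoid(precision, recall))
    return auc
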