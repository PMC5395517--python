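"""Retrieval evaluation: ROC/AUROC, enrichment factor, BEDROC and the
per-structure deduplicated retrieval protocol.

A query patch is scored against a database of patches; patches from
structures of the same protein are the relevant items. Because a structure
may contribute several patches, only its best-scoring patch counts as the
true positive — its siblings are *ignored* (removed from both numerator and
denominator) rather than punished as negatives. Metrics are AUROC,
enrichment factor in the top fraction (default 5%), and BEDROC (default
alpha = 20), which exponentially weights early recognition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .compare import patch_score
from .patches import Patch

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE, IGNORED = "positive", "negative", "ignored"


class RetrievalError(ValueError):
    pass


@dataclass
class RankedList:
    """Scored items with positive/negative/ignored labels.

    Ignored items are excluded from every metric; they exist so that
    deduplication can drop sibling patches without biasing the denominator.
    """

    item_ids: list[str]
    scores: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        if not (len(self.item_ids) == len(self.scores) == len(self.labels)):
            raise RetrievalError("item_ids, scores and labels must have equal length")
        bad = set(self.labels) - {POSITIVE, NEGATIVE, IGNORED}
        if bad:
            raise RetrievalError(f"unknown labels: {bad}")

    def effective(self) -> tuple[np.ndarray, np.ndarray]:
        """(scores, is_positive) over non-ignored items, input order kept."""
        keep = [k for k, lab in enumerate(self.labels) if lab != IGNORED]
        scores = self.scores[keep]
        y = np.array([self.labels[k] == POSITIVE for k in keep], bool)
        return scores, y

    @classmethod
    def from_binary(cls, scores: Sequence[float], positives: Sequence[bool]) -> "RankedList":
        labels = [POSITIVE if p else NEGATIVE for p in positives]
        return cls(
            item_ids=[str(i) for i in range(len(labels))],
            scores=np.asarray(scores, float),
            labels=labels,
        )


def _check(y: np.ndarray) -> None:
    if not y.any():
        raise RetrievalError("no positives")
    if y.all():
        raise RetrievalError("no negatives")


def roc_points(ranked: RankedList) -> list[tuple[float, float]]:
    """(FPR, TPR) points of the threshold sweep; ties enter together.

    Starts at (0, 0) and ends at (1, 1); both coordinates are monotone
    non-decreasing, with tied scores producing diagonal segments.
    """
    scores, y = ranked.effective()
    _check(y)
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    return [(float(f), float(t)) for f, t in zip(fpr, tpr)]


def auroc(ranked: RankedList) -> float:
    """Area under the ROC curve (ties counted half, Mann-Whitney equivalent)."""
    scores, y = ranked.effective()
    _check(y)
    return float(roc_auc_score(y, scores))


def enrichment_factor(ranked: RankedList, fraction: float = 0.05) -> float:
    """Positive rate in the top ``ceil(fraction * n)`` over the overall rate.

    The cutoff set is taken by descending score with ties at the boundary
    broken by stable input order.
    """
    if not 0 < fraction <= 1:
        raise RetrievalError("fraction must be in (0, 1]")
    scores, y = ranked.effective()
    if not y.any():
        raise RetrievalError("no positives")
    n = len(scores)
    m = math.ceil(fraction * n)
    order = np.argsort(-scores, kind="stable")
    top = order[:m]
    return float((y[top].mean()) / (y.mean()))


def bedroc(ranked: RankedList, alpha: float = 20.0) -> float:
    """Boltzmann-enhanced discrimination of ROC (early-recognition metric).

    The exponentially weighted sum S = sum_i exp(-alpha r_i / N) over positive
    ranks r_i (descending score, stable ties) is normalized to [0, 1] by its
    analytic extremes — all positives first versus all positives last — so a
    perfect ranking scores exactly 1 and a fully inverted one exactly 0.
    """
    if alpha <= 0:
        raise RetrievalError("alpha must be positive")
    scores, y = ranked.effective()
    _check(y)
    n_total = len(scores)
    order = np.argsort(-scores, kind="stable")
    ranks = np.nonzero(y[order])[0] + 1  # 1-based ranks of positives
    n_pos = len(ranks)
    a = alpha / n_total
    s = np.exp(-a * ranks).sum()
    # geometric sums for the best (ranks 1..n) and worst (ranks N-n+1..N) cases
    s_max = math.exp(-a) * (1.0 - math.exp(-a * n_pos)) / (1.0 - math.exp(-a))
    s_min = math.exp(-a * (n_total - n_pos + 1)) * (1.0 - math.exp(-a * n_pos)) / (
        1.0 - math.exp(-a)
    )
    return float((s - s_min) / (s_max - s_min))


def run_retrieval(
    query: Patch,
    database: Sequence[Patch],
    identity_labels: Sequence[str],
    query_identity: Optional[str] = None,
    ef_fraction: float = 0.05,
    bedroc_alpha: float = 20.0,
    **align_kwargs,
) -> tuple[RankedList, dict[str, float]]:
    """Score ``query`` against a patch database and evaluate the ranking.

    ``identity_labels`` gives the protein identity of each database patch;
    ``query_identity`` defaults to the query's structure-derived label. For
    every structure sharing the query's identity, its best-scoring patch is
    the positive and the remaining patches are ignored; patches of other
    proteins are negatives.
    """
    if len(database) != len(identity_labels):
        raise RetrievalError("identity_labels must match database length")
    if any(p.id == query.id for p in database):
        raise RetrievalError("query must not be part of the database")
    qid = query_identity if query_identity is not None else query.structure_id
    if not any(lab == qid for lab in identity_labels):
        raise RetrievalError(f"no database patch shares identity {qid!r}")

    scores = np.array([patch_score(query, p, **align_kwargs) for p in database])
    labels = [NEGATIVE] * len(database)
    by_structure: dict[str, list[int]] = {}
    for k, (p, lab) in enumerate(zip(database, identity_labels)):
        if lab == qid:
            by_structure.setdefault(p.structure_id, []).append(k)
    for members in by_structure.values():
        best = max(members, key=lambda k: (scores[k], -k))
        for k in members:
            labels[k] = POSITIVE if k == best else IGNORED

    ranked = RankedList(
        item_ids=[p.id for p in database], scores=scores, labels=labels
    )
    metrics = {
        "auroc": auroc(ranked),
        "ef": enrichment_factor(ranked, fraction=ef_fraction),
        "bedroc": bedroc(ranked, alpha=bedroc_alpha),
    }
    return ranked, metrics


def metrics_table(rows: Sequence[dict], path=None):
    """Aggregate per-query metrics as mean +/- standard error (over queries).

    ``rows`` are dicts with keys ``target``, ``n``, ``auroc``, ``ef``,
    ``bedroc``. Returns a pandas DataFrame and optionally writes it as TSV.
    """
    import pandas as pd

    df = pd.DataFrame(rows)
    grouped = df.groupby("target").agg(
        n_queries=("auroc", "size"),
        N=("n", "first"),
        auroc_mean=("auroc", "mean"),
        auroc_se=("auroc", "sem"),
        ef_mean=("ef", "mean"),
        ef_se=("ef", "sem"),
        bedroc_mean=("bedroc", "mean"),
        bedroc_se=("bedroc", "sem"),
    )
    if path is not None:
        grouped.to_csv(path, sep="\t")
    return grouped
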