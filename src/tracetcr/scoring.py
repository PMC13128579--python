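"""Checkpoint inference, evaluation metrics and sample-level scores.

Inference featurizes new data exactly as at training time, over the
checkpoint's frozen 500-gene universe (50 model genes plus 450 binning
support genes). Genes absent from the test matrix enter as zero counts;
because binning is rank-based within a unit this degrades gracefully, but
the overlap fraction is always reported.
"""

from __future__ import annotations

import logging
import math
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from ._types import CountMatrix, SampleScore, ScoreTable, ValidationError
from .preprocess import build_features

if TYPE_CHECKING:  # pragma: no cover
    from .trainer import ModelCheckpoint

logger = logging.getLogger(__name__)

__all__ = ["predict", "evaluate", "strace", "expand_to_universe"]


def expand_to_universe(m: CountMatrix, universe: Sequence[str]) -> CountMatrix:
    """Reindex a count matrix onto a frozen gene universe.

    Genes missing from ``m`` become zero-count columns so rank-based
    featurization stays well defined.
    """
    present = set(m.gene_ids)
    counts = np.zeros((m.n_cells, len(universe)), dtype=m.counts.dtype)
    have = [g for g in universe if g in present]
    if have:
        src = m.gene_index(have)
        dst = [i for i, g in enumerate(universe) if g in present]
        counts[:, dst] = m.counts[:, src]
    return CountMatrix(
        unit_ids=list(m.unit_ids),
        gene_ids=list(universe),
        counts=counts,
        sample_of_unit=dict(m.sample_of_unit),
        tissue_of_sample=m.tissue_of_sample,
    )


def predict(
    ckpt: "ModelCheckpoint",
    m: CountMatrix,
    clone_of_cell: Mapping[str, str] | None = None,
    mode: str = "cell",
    threshold: float = 0.5,
) -> ScoreTable:
    """Score cells or clones with a trained checkpoint.

    ``mode='clone'`` requires a cell -> clone assignment; member cells are
    collapsed per the checkpoint's preprocessing before scoring.
    """
    if mode not in ("cell", "clone"):
        raise ValueError(f"mode must be cell or clone, got {mode!r}")
    if mode == "clone" and clone_of_cell is None:
        raise ValidationError("clone mode requires clonotype assignments")
    universe = list(ckpt.model_genes) + list(ckpt.bin_support_genes)
    overlap = sum(g in set(m.gene_ids) for g in universe) / len(universe)
    if overlap < 0.5:
        raise ValidationError(
            f"only {overlap:.0%} of the checkpoint gene universe is present; "
            "harmonize gene symbols before scoring"
        )
    if overlap < 1.0:
        logger.warning("gene universe overlap %.1f%%; missing genes scored as zero", 100 * overlap)
    expanded = expand_to_universe(m, universe)
    features = build_features(
        expanded, clone_of_cell if mode == "clone" else None, ckpt.preprocess
    )
    cols = [features.gene_ids.index(g) for g in ckpt.model_genes]
    X = features.values[:, cols]
    scores = ckpt.predict_proba(X)
    return ScoreTable(
        unit_ids=list(features.unit_ids),
        scores=scores,
        unit_kind=features.unit_kind,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _to_binary(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "SUO":
        return (arr == "TRT").astype(int)
    return arr.astype(int)


def mcc_from_confusion(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def pr_auc_trapezoid(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve by trapezoidal integration."""
    from sklearn.metrics import precision_recall_curve

    precision, recall, _ = precision_recall_curve(y_true, scores)
    # recall is monotone non-increasing in threshold order; integrate along
    # the curve as returned (re-sorting would shuffle same-recall points)
    return float(abs(np.trapezoid(precision, recall)))


def evaluate(
    scores: np.ndarray | ScoreTable,
    truth: Sequence,
    threshold: float = 0.5,
) -> dict[str, float]:
    """Positive-class-aware metric set for binary reactivity calls.

    Threshold-dependent metrics (MCC, F1, precision, recall, accuracy,
    FPR) use ``score >= threshold`` as the TRT call. Threshold-independent
    metrics (PR-AUC, ROC-AUC) are NaN when the truth is single-class.
    """
    if isinstance(scores, ScoreTable):
        scores = scores.scores
    scores = np.asarray(scores, dtype=float)
    y = _to_binary(truth)
    if scores.shape != y.shape:
        raise ValidationError("scores and truth must align")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    out = {
        "mcc": mcc_from_confusion(tp, fp, tn, fn),
        "f1": f1,
        "precision": precision,
        "recall": recall,
        "accuracy": (tp + tn) / len(y) if len(y) else 0.0,
        "fpr": fp / (fp + tn) if fp + tn else 0.0,
    }
    if 0 < y.sum() < len(y):
        from sklearn.metrics import roc_auc_score

        out["pr_auc"] = pr_auc_trapezoid(y, scores)
        out["roc_auc"] = float(roc_auc_score(y, scores))
    else:
        out["pr_auc"] = float("nan")
        out["roc_auc"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# sample-level score
# ---------------------------------------------------------------------------

def strace(
    scores: ScoreTable,
    sample_of_unit: Mapping[str, str],
    threshold: float = 0.5,
    min_cells: int = 10,
) -> list[SampleScore]:
    """Per-sample fraction of cells calling TRT (score >= threshold).

    Samples with fewer than ``min_cells`` scored cells are omitted (their
    ids are logged); the fraction is meaningless on a handful of cells.
    """
    if scores.unit_kind != "cell":
        raise ValidationError("sTRACE requires cell-level scores")
    per_sample: dict[str, list[float]] = {}
    for unit, score in zip(scores.unit_ids, scores.scores):
        sample = sample_of_unit.get(unit)
        if sample is None:
            raise ValidationError(f"cell {unit!r} has no sample tag")
        per_sample.setdefault(sample, []).append(score)
    out, skipped = [], []
    for sample in sorted(per_sample):
        vals = np.asarray(per_sample[sample])
        if vals.size < min_cells:
            skipped.append(sample)
            continue
        out.append(
            SampleScore(
                sample_id=sample,
                strace=float((vals >= threshold).mean()),
                n_cells=int(vals.size),
            )
        )
    if skipped:
        logger.info("sTRACE omitted %d samples with < %d cells: %s", len(skipped), min_cells, skipped)
    return out


def sample_scores_to_frame(samples: Sequence[SampleScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "n_cells": [s.n_cells for s in samples],
            "strace": [s.strace for s in samples],
        }
    )
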