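"""Gene-signature baselines for tumor-reactivity prediction.

Published reactivity signatures are evaluated under a shared protocol:
score each cell with the signature's scoring statistic, aggregate member
cells to one score per clone (max or mean), optionally standardize
against the training distribution, learn the decision threshold on
training clones (Youden's J or accuracy) and call held-out clones. The
three scoring statistics are rank-based analogues of the field's standard
single-sample scorers: a capped Mann-Whitney U (UCell-style), a mean
normalized rank (singscore-style) and a weighted running-sum enrichment
(ssGSEA-style).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from ._types import CountMatrix, LabelTable, ValidationError
from .preprocess import log_normalize
from .scoring import evaluate

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "read_signatures",
    "score_ucell_like",
    "score_rank_mean",
    "score_ssgsea_like",
    "score_cells",
    "aggregate_clone_scores",
    "standardize_scores",
    "learn_threshold",
    "run_benchmark",
]

SCORING_METHODS = ("ssgsea_like", "rank_mean", "ucell_like")
AGGREGATIONS = ("max", "mean")
CRITERIA = ("youden", "accuracy")


@dataclass
class Signature:
    """A reactivity gene signature plus its evaluation protocol."""

    name: str
    up_genes: list[str]
    down_genes: list[str] = field(default_factory=list)
    scoring_method: str = "rank_mean"
    clone_aggregation: str = "max"
    threshold_criterion: str = "youden"
    standardize: bool = False

    def __post_init__(self) -> None:
        if not self.up_genes:
            raise ValidationError(f"signature {self.name!r}: up_genes must be non-empty")
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValidationError(f"signature {self.name!r}: up/down overlap {sorted(overlap)}")
        if self.scoring_method not in SCORING_METHODS:
            raise ValidationError(f"scoring_method must be one of {SCORING_METHODS}")
        if self.clone_aggregation not in AGGREGATIONS:
            raise ValidationError(f"clone_aggregation must be one of {AGGREGATIONS}")
        if self.threshold_criterion not in CRITERIA:
            raise ValidationError(f"threshold_criterion must be one of {CRITERIA}")


def read_signatures(path: str | Path) -> list[Signature]:
    """Read signatures from YAML (list of mappings) or TSV.

    TSV columns: name, up_genes, down_genes (comma-separated),
    scoring_method, clone_aggregation, threshold_criterion, standardize.
    """
    path = Path(path)
    sigs = []
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, list):
            raise ValidationError(f"{path}: expected a YAML list of signatures")
        for i, entry in enumerate(data):
            try:
                sigs.append(Signature(**entry))
            except (TypeError, ValidationError) as exc:
                raise ValidationError(f"{path}: signature #{i + 1}: {exc}") from exc
    else:
        df = pd.read_csv(path, sep="\t")
        if not {"name", "up_genes"} <= set(df.columns):
            raise ValidationError(f"{path}: signature TSV needs name and up_genes columns")
        for i, row in df.iterrows():
            try:
                up_raw = row["up_genes"]
                sigs.append(
                    Signature(
                        name=str(row["name"]),
                        up_genes=(
                            [] if pd.isna(up_raw) else [g for g in str(up_raw).split(",") if g]
                        ),
                        down_genes=(
                            [g for g in str(row["down_genes"]).split(",") if g]
                            if "down_genes" in df.columns and not pd.isna(row.get("down_genes"))
                            else []
                        ),
                        scoring_method=str(row.get("scoring_method", "rank_mean")),
                        clone_aggregation=str(row.get("clone_aggregation", "max")),
                        threshold_criterion=str(row.get("threshold_criterion", "youden")),
                        standardize=bool(row.get("standardize", False)),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {i + 2}: {exc}") from exc
    return sigs


# ---------------------------------------------------------------------------
# per-cell scorers
# ---------------------------------------------------------------------------

def _check_presence(sig_genes: Sequence[str], gene_ids: Sequence[str], name: str) -> list[str]:
    present = [g for g in sig_genes if g in set(gene_ids)]
    if not present:
        logger.warning("signature %s: no gene present in the matrix; score 0", name)
    return present


def score_ucell_like(
    values: np.ndarray,
    gene_ids: Sequence[str],
    signature: Signature,
    max_rank: int = 1500,
) -> float:
    """Capped Mann-Whitney-U statistic on within-cell expression ranks.

    Genes are ranked by descending expression (rank 1 = highest, average
    ranks on ties, absent genes worst); ranks are capped at ``max_rank``
    and the signature's rank-sum U' yields ``1 - U'/(n * max_rank)``,
    clipped to [0, 1]. With down-genes present the analogous down score is
    subtracted.
    """
    idx = {g: i for i, g in enumerate(gene_ids)}
    values = np.asarray(values, dtype=float)
    ranks = rankdata(-values, method="average")
    # unexpressed genes rank past the cap, exactly like absent genes; on
    # transcriptome-scale data this is where UCell's cap puts them anyway
    ranks[values <= 0] = max_rank + 1

    def one_side(genes: Sequence[str]) -> float | None:
        if not genes:
            return None
        r = np.array([ranks[idx[g]] if g in idx else max_rank + 1 for g in genes])
        if all(g not in idx for g in genes):
            return 0.0
        r = np.minimum(r, max_rank + 1)
        n = len(genes)
        u = r.sum() - n * (n + 1) / 2
        return float(np.clip(1.0 - u / (n * max_rank), 0.0, 1.0))

    if not _check_presence(signature.up_genes + signature.down_genes, gene_ids, signature.name):
        return 0.0
    up = one_side(signature.up_genes)
    down = one_side(signature.down_genes)
    return up if down is None else up - down


def score_rank_mean(values: np.ndarray, gene_ids: Sequence[str], signature: Signature) -> float:
    """Mean normalized expression rank of the signature genes.

    Ranks ascend with expression and are scaled to (0, 1) via
    ``(rank - 0.5) / n`` so the exchangeable-null expectation is exactly
    0.5 per gene; the score is centered to 0 under the null, and a
    down-gene term (expected low, so entering with opposite sign) is
    subtracted when present. Absent genes take the worst (lowest) rank.
    """
    if not _check_presence(signature.up_genes + signature.down_genes, gene_ids, signature.name):
        return 0.0
    idx = {g: i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    norm = (rankdata(np.asarray(values, dtype=float), method="average") - 0.5) / n

    def mean_norm(genes: Sequence[str]) -> float:
        vals = [norm[idx[g]] if g in idx else 0.5 / n for g in genes]
        return float(np.mean(vals))

    score = mean_norm(signature.up_genes) - 0.5
    if signature.down_genes:
        score -= mean_norm(signature.down_genes) - 0.5
    return score


def score_ssgsea_like(
    values: np.ndarray,
    gene_ids: Sequence[str],
    signature: Signature,
    exponent: float = 0.75,
) -> float:
    """Weighted running-sum enrichment of the up-gene set.

    Genes are walked in order of descending expression; hits increment the
    running sum proportionally to ``|expression|^exponent``, misses
    decrement uniformly, and the score integrates (sums) the running-sum
    deviations. Exponent 0 reduces to the unweighted statistic. Down-genes,
    when present, contribute an analogous term with opposite sign.
    """
    if not _check_presence(signature.up_genes + signature.down_genes, gene_ids, signature.name):
        return 0.0
    values = np.asarray(values, dtype=float)
    order = np.lexsort((gene_ids, -values))  # descending expression, symbol tie-break

    def one_side(genes: Sequence[str]) -> float:
        inset = np.isin(np.asarray(gene_ids, dtype=object)[order], list(genes))
        n, n_sig = len(gene_ids), int(inset.sum())
        if n_sig == 0 or n_sig == n:
            return 0.0
        w = np.abs(values[order]) ** exponent
        hit = np.where(inset, w, 0.0)
        hit_total = hit.sum()
        if hit_total == 0:  # all signature genes unexpressed: fall back to uniform
            hit = inset.astype(float)
            hit_total = hit.sum()
        running = np.cumsum(hit / hit_total) - np.cumsum(np.where(inset, 0.0, 1.0 / (n - n_sig)))
        return float(running.sum())

    score = one_side([g for g in signature.up_genes if g in set(gene_ids)] or signature.up_genes)
    if signature.down_genes:
        score -= one_side([g for g in signature.down_genes if g in set(gene_ids)] or signature.down_genes)
    return score


_SCORERS = {
    "ucell_like": score_ucell_like,
    "rank_mean": score_rank_mean,
    "ssgsea_like": score_ssgsea_like,
}


def score_cells(m: CountMatrix, signature: Signature, log_transform: bool = True) -> pd.Series:
    """Per-cell signature scores (cells with any counts are log-normalized first).

    The rank-based statistics are invariant to this monotone transform;
    the weighted enrichment uses the log scale so highly expressed genes
    do not dominate through raw magnitude.
    """
    scorer = _SCORERS[signature.scoring_method]
    out = {}
    for i, cell in enumerate(m.unit_ids):
        row = m.counts[i].astype(float)
        if log_transform and row.sum() > 0:
            row = log_normalize(row)
        out[cell] = scorer(row, m.gene_ids, signature)
    return pd.Series(out, name=signature.name)


# ---------------------------------------------------------------------------
# clone aggregation, standardization, thresholding
# ---------------------------------------------------------------------------

def aggregate_clone_scores(
    cell_scores: Mapping[str, float] | pd.Series,
    clone_of_cell: Mapping[str, str],
    method: str = "max",
) -> pd.Series:
    """Collapse cell scores to one score per clone (max or mean)."""
    if method not in AGGREGATIONS:
        raise ValidationError(f"method must be one of {AGGREGATIONS}")
    cell_scores = pd.Series(dict(cell_scores))
    missing = [c for c in cell_scores.index if c not in clone_of_cell]
    if missing:
        raise ValidationError(f"{len(missing)} scored cells lack a clone assignment")
    groups = cell_scores.groupby(cell_scores.index.map(clone_of_cell))
    agg = groups.max() if method == "max" else groups.mean()
    return agg.sort_index()


def standardize_scores(
    train_scores: np.ndarray | pd.Series, test_scores: np.ndarray | pd.Series
):
    """Z-score test scores against the training distribution (sample SD, n-1)."""
    train = np.asarray(train_scores, dtype=float)
    mu = train.mean()
    sd = train.std(ddof=1)
    if not sd > 0:
        raise ValidationError("training scores have zero standard deviation")
    return (test_scores - mu) / sd


def learn_threshold(
    scores: np.ndarray | pd.Series,
    labels: Sequence,
    criterion: str = "youden",
) -> float:
    """Best decision threshold on training scores.

    Candidates are midpoints between adjacent sorted unique scores plus
    -inf and +inf; a unit calls positive when ``score >= threshold``. The
    criterion is Youden's J (sensitivity + specificity - 1) or accuracy;
    ties return the lowest qualifying threshold.
    """
    if criterion not in CRITERIA:
        raise ValidationError(f"criterion must be one of {CRITERIA}")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l in (1, "TRT", True) else 0 for l in labels])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("threshold learning requires both classes")
    uniq = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    best_t, best_val = None, -np.inf
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    for t in candidates:
        pred = scores >= t
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        if criterion == "youden":
            val = tp / n_pos + tn / n_neg - 1.0
        else:
            val = (tp + tn) / len(y)
        if val > best_val:  # strict: ties keep the earlier (lower) threshold
            best_val, best_t = val, float(t)
    return best_t


# ---------------------------------------------------------------------------
# full benchmark protocol
# ---------------------------------------------------------------------------

def run_benchmark(
    m: CountMatrix,
    clone_of_cell: Mapping[str, str],
    labels: LabelTable | Mapping[str, str],
    signatures: Sequence[Signature],
    seeds: Sequence[int],
    holdout_fraction: float = 0.20,
) -> pd.DataFrame:
    """Evaluate each signature over the same clone-level splits as training.

    Per signature and seed: cell scores -> clone aggregation -> optional
    train-set standardization -> threshold learned on training clones ->
    held-out calls and metrics. The original protocol fits a logistic
    regression on the single clone score before thresholding; as that map
    is monotone, thresholding the scores directly yields identical calls.
    One row per (signature, seed).
    """
    from .trainer import _labels_dict, make_outer_split

    lab = _labels_dict(labels)
    covered = set(clone_of_cell.values())
    lab = {c: l for c, l in lab.items() if c in covered}
    rows = []
    for signature in signatures:
        cell_scores = score_cells(m, signature)
        clone_scores = aggregate_clone_scores(cell_scores, clone_of_cell, signature.clone_aggregation)
        clone_scores = clone_scores[[c in lab for c in clone_scores.index]]
        for seed in seeds:
            plan = make_outer_split(lab, holdout_fraction, seed)
            train = [c for c in clone_scores.index if plan.outer_assignment.get(c) == "train"]
            test = [c for c in clone_scores.index if plan.outer_assignment.get(c) == "test"]
            s_train, s_test = clone_scores[train], clone_scores[test]
            if signature.standardize:
                s_test = standardize_scores(s_train, s_test)
                s_train = standardize_scores(s_train, s_train)
            y_train = [lab[c] for c in train]
            y_test = np.array([1 if lab[c] == "TRT" else 0 for c in test])
            thr = learn_threshold(s_train, y_train, signature.threshold_criterion)
            pred = (np.asarray(s_test) >= thr).astype(float)
            metrics = evaluate(pred, y_test, threshold=0.5)
            # threshold-independent metrics from the raw scores, not the calls
            if 0 < y_test.sum() < len(y_test):
                from sklearn.metrics import roc_auc_score

                from .scoring import pr_auc_trapezoid

                metrics["roc_auc"] = float(roc_auc_score(y_test, np.asarray(s_test, dtype=float)))
                metrics["pr_auc"] = pr_auc_trapezoid(y_test, np.asarray(s_test, dtype=float))
            rows.append({"method": signature.name, "seed": seed, "threshold": thr, **metrics})
    cols = [
        "method", "seed", "mcc", "f1", "precision", "recall",
        "pr_auc", "roc_auc", "accuracy", "fpr", "threshold",
    ]
    return pd.DataFrame(rows)[cols]
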