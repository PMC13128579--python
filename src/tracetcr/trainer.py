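"""Clone-level nested cross-validation, tuning and checkpointing.

All data-driven choices — gene filtering, hyperparameter tuning, feature
selection, class balancing and model fitting — are made strictly inside
the outer-training clones of each split, so held-out metrics reflect
genuine generalization at natural class prevalence. A single integer seed
drives the split, the negative subsampling, the search trial sequence and
the booster, making every run exactly reproducible.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
import yaml

from ._types import CountMatrix, LabelTable, ScoreTable, ValidationError
from .preprocess import PreprocessConfig, build_features, filter_genes
from .scoring import evaluate

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "SearchSpace",
    "LeakageAudit",
    "ModelCheckpoint",
    "IncompatibleCheckpointError",
    "make_outer_split",
    "make_inner_folds",
    "balance_training",
    "tune_hyperparameters",
    "select_features",
    "train_model",
    "run_nested_cv",
    "fit_checkpoint",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# split plans
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Clone-level outer holdout plus inner fold assignment."""

    seed: int
    outer_holdout_fraction: float = 0.20
    n_inner_folds: int = 5
    outer_assignment: dict[str, str] = field(default_factory=dict)  # clone -> train|test
    inner_assignment: dict[str, int] = field(default_factory=dict)  # train clone -> fold

    @property
    def train_clones(self) -> list[str]:
        return sorted(c for c, a in self.outer_assignment.items() if a == "train")

    @property
    def test_clones(self) -> list[str]:
        return sorted(c for c, a in self.outer_assignment.items() if a == "test")


def _labels_dict(labels: LabelTable | Mapping[str, str]) -> dict[str, str]:
    if isinstance(labels, LabelTable):
        return labels.labeled_clones()
    return {c: l for c, l in labels.items() if l != "unknown"}


def make_outer_split(
    labels: LabelTable | Mapping[str, str],
    fraction: float = 0.20,
    seed: int = 0,
) -> CVPlan:
    """Stratified clone-level train/test split.

    Per-class test counts use largest-remainder rounding of
    ``fraction * n_class`` and are clamped so both classes appear on both
    sides. Deterministic per seed.
    """
    lab = _labels_dict(labels)
    by_class: dict[str, list[str]] = {}
    for clone in sorted(lab):
        by_class.setdefault(lab[clone], []).append(clone)
    for cls, clones in by_class.items():
        if len(clones) < 2:
            raise ValidationError(f"class {cls!r} has {len(clones)} clone(s); need >= 2 to split")
    # largest-remainder apportionment of the test quota across classes
    total_test = round(fraction * len(lab))
    raw = {cls: fraction * len(c) for cls, c in by_class.items()}
    floors = {cls: int(np.floor(r)) for cls, r in raw.items()}
    remainder = total_test - sum(floors.values())
    order = sorted(by_class, key=lambda cls: (-(raw[cls] - floors[cls]), cls))
    n_test = dict(floors)
    for cls in order[: max(remainder, 0)]:
        n_test[cls] += 1
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for cls in sorted(by_class):
        clones = by_class[cls]
        k = min(max(n_test[cls], 1), len(clones) - 1)
        test_idx = set(rng.choice(len(clones), size=k, replace=False).tolist())
        for i, clone in enumerate(clones):
            assignment[clone] = "test" if i in test_idx else "train"
    return CVPlan(seed=seed, outer_holdout_fraction=fraction, outer_assignment=assignment)


def make_inner_folds(
    clones: Sequence[str],
    labels: LabelTable | Mapping[str, str],
    k: int = 5,
    seed: int = 0,
) -> dict[str, int]:
    """Label-stratified k-fold partition of training clones."""
    from sklearn.model_selection import StratifiedKFold

    clones = sorted(clones)
    if k > len(clones):
        raise ValidationError(f"k={k} exceeds {len(clones)} clones")
    lab = _labels_dict(labels)
    y = [lab[c] for c in clones]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of_clone: dict[str, int] = {}
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(clones)), y)):
        for i in val_idx:
            fold_of_clone[clones[i]] = fold
    return fold_of_clone


def balance_training(
    clones: Sequence[str],
    labels: LabelTable | Mapping[str, str],
    ratio_pos: int = 10,
    ratio_neg: int = 90,
    seed: int = 0,
) -> list[str]:
    """Rebalance a clone set to ratio_pos:ratio_neg by negative subsampling.

    All positives are kept; negatives are drawn without replacement down
    to ``floor(n_pos * ratio_neg / ratio_pos)``. If fewer negatives exist,
    all are kept (with a warning).
    """
    lab = _labels_dict(labels)
    pos = sorted(c for c in clones if lab.get(c) == "TRT")
    neg = sorted(c for c in clones if lab.get(c) == "nonTRT")
    if not pos:
        raise ValidationError("cannot balance with zero positive clones")
    target = int(len(pos) * ratio_neg / ratio_pos)
    if len(neg) <= target:
        if len(neg) < target:
            logger.warning(
                "only %d negatives available for target %d; keeping all", len(neg), target
            )
        chosen = neg
    else:
        rng = np.random.default_rng(seed)
        chosen = sorted(np.asarray(neg, dtype=object)[
            rng.choice(len(neg), size=target, replace=False)
        ].tolist())
    return sorted(pos + list(chosen))


# ---------------------------------------------------------------------------
# leakage instrumentation
# ---------------------------------------------------------------------------

class LeakageAudit:
    """Records which clone ids each training stage touches, per seed."""

    def __init__(self) -> None:
        self.records: list[tuple[str, int, frozenset[str]]] = []

    def record(self, stage: str, seed: int, clones: Sequence[str]) -> None:
        self.records.append((stage, int(seed), frozenset(clones)))

    def touched(self, seed: int, stages: Sequence[str] | None = None) -> set[str]:
        out: set[str] = set()
        for stage, s, clones in self.records:
            if s == seed and (stages is None or stage in stages):
                out |= clones
        return out


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

@dataclass
class SearchSpace:
    """Hyperparameter ranges for the boosted-tree classifier.

    Ranges are inclusive (lo, hi) pairs; ``learning_rate`` and
    ``reg_lambda`` sample log-uniformly. A range with lo == hi pins that
    hyperparameter.
    """

    strategy: str = "random"  # random | bayesian
    n_trials: int = 10
    max_depth: tuple[int, int] = (2, 6)
    learning_rate: tuple[float, float] = (0.03, 0.3)
    n_estimators: tuple[int, int] = (50, 200)
    subsample: tuple[float, float] = (0.6, 1.0)
    # lower bound well below the usual 0.5: with ~10 positive clones many
    # genes separate a balanced subsample perfectly, and without aggressive
    # per-tree feature subsampling greedy boosting concentrates on a few
    # arbitrary separators instead of spreading over the whole program
    colsample_bytree: tuple[float, float] = (0.1, 1.0)
    reg_lambda: tuple[float, float] = (1e-2, 10.0)
    # continuous and allowed below 1: with ~10 positive clones after 10:90
    # balancing, the positive-class hessian budget is < 1 once probabilities
    # approach their targets, and an integer floor of 1 stalls boosting
    # before the model is calibrated against the fixed 0.5 call threshold
    min_child_weight: tuple[float, float] = (0.05, 1.0)

    _LOG = ("learning_rate", "reg_lambda", "min_child_weight")
    _INT = ("max_depth", "n_estimators")
    _PARAMS = (
        "max_depth",
        "learning_rate",
        "n_estimators",
        "subsample",
        "colsample_bytree",
        "reg_lambda",
        "min_child_weight",
    )

    def __post_init__(self) -> None:
        if self.strategy not in ("random", "bayesian"):
            raise ValidationError("strategy must be random or bayesian")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        for name in self._PARAMS:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: empty range ({lo}, {hi})")

    def sample(self, rng: np.random.Generator) -> dict:
        hp = {}
        for name in self._PARAMS:
            lo, hi = getattr(self, name)
            if name in self._LOG:
                val = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            elif name in self._INT:
                val = int(rng.integers(lo, hi + 1))
            else:
                val = float(rng.uniform(lo, hi))
            hp[name] = val
        return hp

    def _encode(self, hp: dict) -> np.ndarray:
        vec = []
        for name in self._PARAMS:
            v = float(hp[name])
            vec.append(np.log(v) if name in self._LOG else v)
        return np.array(vec)


def train_model(X: np.ndarray, y: np.ndarray, hyperparameters: dict, seed: int = 0):
    """Fit the gradient-boosted tree classifier; deterministic per seed."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("training requires both classes")
    clf = xgb.XGBClassifier(
        **{k: v for k, v in hyperparameters.items()},
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
    )
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def _fold_mcc(
    X: pd.DataFrame,
    y: pd.Series,
    fold_of_clone: Mapping[str, int],
    hp: dict,
    seed: int,
    ratio_pos: int,
    ratio_neg: int,
) -> float:
    """Mean validation MCC of one configuration across inner folds."""
    folds = sorted(set(fold_of_clone.values()))
    labels = {c: ("TRT" if y[c] == 1 else "nonTRT") for c in y.index}
    mccs = []
    for f in folds:
        val = [c for c in X.index if fold_of_clone[c] == f]
        train = [c for c in X.index if fold_of_clone[c] != f]
        balanced = balance_training(
            train, labels, ratio_pos, ratio_neg, seed=(seed * 1000003 + f) % (2**31)
        )
        try:
            clf = train_model(X.loc[balanced].to_numpy(), y[balanced].to_numpy(), hp, seed=seed)
        except ValidationError:
            mccs.append(0.0)
            continue
        scores = clf.predict_proba(X.loc[val].to_numpy(dtype=float))[:, 1]
        mccs.append(evaluate(scores, y[val].to_numpy())["mcc"])
    return float(np.mean(mccs))


def _candidate_key(mcc: float, hp: dict) -> tuple:
    # ties go to the more regularized, smaller model
    return (mcc, hp["reg_lambda"], -hp["max_depth"], -hp["n_estimators"])


def tune_hyperparameters(
    X: pd.DataFrame,
    y: pd.Series,
    fold_of_clone: Mapping[str, int],
    space: SearchSpace,
    seed: int = 0,
    ratio_pos: int = 10,
    ratio_neg: int = 90,
) -> dict:
    """Search the space for the configuration with best mean inner-CV MCC.

    ``random`` draws ``n_trials`` independent configurations. ``bayesian``
    seeds with random draws then proposes the remaining trials by expected
    improvement under a Gaussian-process surrogate fit to observed scores.
    Ties break toward stronger regularization and smaller trees.
    """
    rng = np.random.default_rng(seed)
    trials: list[tuple[dict, float]] = []

    def run_trial(hp: dict) -> None:
        mcc = _fold_mcc(X, y, fold_of_clone, hp, seed, ratio_pos, ratio_neg)
        trials.append((hp, mcc))

    n_init = space.n_trials if space.strategy == "random" else max(3, space.n_trials // 3)
    n_init = min(n_init, space.n_trials)
    for _ in range(n_init):
        run_trial(space.sample(rng))
    if space.strategy == "bayesian":
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern, WhiteKernel

        for _ in range(space.n_trials - n_init):
            Xobs = np.vstack([space._encode(hp) for hp, _ in trials])
            yobs = np.array([m for _, m in trials])
            scale = Xobs.std(axis=0)
            scale[scale == 0] = 1.0
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5) + WhiteKernel(1e-3),
                normalize_y=True,
                random_state=0,
            )
            gp.fit((Xobs - Xobs.mean(axis=0)) / scale, yobs)
            pool = [space.sample(rng) for _ in range(64)]
            Xp = np.vstack([space._encode(hp) for hp in pool])
            mu, sd = gp.predict((Xp - Xobs.mean(axis=0)) / scale, return_std=True)
            best = yobs.max()
            from scipy.stats import norm as _norm

            z = np.where(sd > 0, (mu - best) / np.maximum(sd, 1e-12), 0.0)
            ei = (mu - best) * _norm.cdf(z) + sd * _norm.pdf(z)
            run_trial(pool[int(np.argmax(ei))])
    if not trials:
        raise ValidationError("no search trials executed")
    best_hp, _ = max(trials, key=lambda t: _candidate_key(t[1], t[0]))
    logger.info(
        "tuning (%s, %d trials): best mean inner MCC %.3f",
        space.strategy,
        len(trials),
        max(m for _, m in trials),
    )
    return best_hp


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def select_features(
    importances_per_fold: Sequence[Mapping[str, float]],
    gene_universe: Sequence[str],
    k_model: int = 50,
    k_support: int = 450,
) -> tuple[list[str], list[str]]:
    """Rank-aggregate per-fold importances and freeze the gene signature.

    Within each fold genes are ranked descending by importance (rank 1 =
    most important; ties break on gene symbol, so input order is
    irrelevant). The aggregate is the median rank across folds; the top
    ``k_model`` genes become model features and the next ``k_support``
    become binning support.
    """
    genes = sorted(set(gene_universe))
    if len(genes) < k_model + k_support:
        raise ValidationError(
            f"{len(genes)} genes available but {k_model + k_support} required"
        )
    if not importances_per_fold:
        raise ValidationError("no fold importances supplied")
    ranks_per_gene: dict[str, list[int]] = {g: [] for g in genes}
    for imp in importances_per_fold:
        ordered = sorted(genes, key=lambda g: (-imp.get(g, 0.0), g))
        for rank, g in enumerate(ordered, start=1):
            ranks_per_gene[g].append(rank)
    agg = {g: statistics.median(r) for g, r in ranks_per_gene.items()}
    ordered = sorted(genes, key=lambda g: (agg[g], g))
    return ordered[:k_model], ordered[k_model : k_model + k_support]


def _gain_importance(clf, feature_names: Sequence[str]) -> dict[str, float]:
    booster = clf.get_booster().copy()  # leave the live model untouched
    booster.feature_names = list(feature_names)
    return booster.get_score(importance_type="gain")


class BoosterAdapter:
    """Minimal predict_proba facade over a raw xgboost Booster."""

    def __init__(self, booster: xgb.Booster) -> None:
        self.booster = booster

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = self.booster.inplace_predict(np.asarray(X, dtype=float))
        return np.column_stack([1.0 - p, p])

    def get_booster(self) -> xgb.Booster:
        return self.booster


class BalancedEnsemble:
    """Average of boosters trained on independent balanced subsamples.

    A single 10:90 draw discards most negative clones; averaging a few
    draws exposes the model to the full negative diversity and stabilizes
    the probability scale against the fixed 0.5 call threshold.
    """

    def __init__(self, members: Sequence) -> None:
        if not members:
            raise ValidationError("ensemble requires at least one member")
        self.members = list(members)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = np.mean([m.predict_proba(X)[:, 1] for m in self.members], axis=0)
        return np.column_stack([1.0 - p, p])


# ---------------------------------------------------------------------------
# checkpoint
# ---------------------------------------------------------------------------

class IncompatibleCheckpointError(RuntimeError):
    pass


@dataclass
class ModelCheckpoint:
    """Frozen gene sets, preprocessing and trained model for inference."""

    model_genes: list[str]
    bin_support_genes: list[str]
    preprocess: PreprocessConfig
    hyperparameters: dict
    model: xgb.XGBClassifier
    version: str = f"tracetcr-checkpoint-v{CHECKPOINT_FORMAT_VERSION}"
    training_manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.model_genes) & set(self.bin_support_genes)
        if overlap:
            raise ValidationError(
                f"model and bin-support genes overlap: {sorted(overlap)[:5]}..."
                if len(overlap) > 5
                else f"model and bin-support genes overlap: {sorted(overlap)}"
            )
        if not self.model_genes:
            raise ValidationError("model_genes must be non-empty")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X, dtype=float))[:, 1]


def save_checkpoint(ckpt: ModelCheckpoint, path: str | Path) -> None:
    """Write a checkpoint directory: manifest.yaml + model.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": ckpt.version,
        "model_genes": list(ckpt.model_genes),
        "bin_support_genes": list(ckpt.bin_support_genes),
        "preprocess": {k: getattr(ckpt.preprocess, k) for k in PreprocessConfig._YAML_KEYS},
        "hyperparameters": ckpt.hyperparameters,
        "training_manifest": ckpt.training_manifest,
    }
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    if isinstance(ckpt.model, BalancedEnsemble):
        for i, member in enumerate(ckpt.model.members):
            member.get_booster().save_model(str(path / f"model_{i:02d}.json"))
    else:
        ckpt.model.get_booster().save_model(str(path / "model.json"))


def load_checkpoint(path: str | Path) -> ModelCheckpoint:
    path = Path(path)
    try:
        manifest = yaml.safe_load((path / "manifest.yaml").read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"corrupted checkpoint manifest at {path}: {exc}") from exc
    version = str(manifest.get("version", ""))
    expected = f"tracetcr-checkpoint-v{CHECKPOINT_FORMAT_VERSION}"
    if version != expected:
        raise IncompatibleCheckpointError(
            f"checkpoint version {version!r} incompatible with {expected!r}"
        )
    files = sorted(path.glob("model_*.json")) or [path / "model.json"]
    members = []
    try:
        for f in files:
            booster = xgb.Booster()
            booster.load_model(str(f))
            members.append(BoosterAdapter(booster))
    except xgb.core.XGBoostError as exc:
        raise ValidationError(f"corrupted checkpoint model at {path}: {exc}") from exc
    clf = members[0] if len(members) == 1 else BalancedEnsemble(members)
    return ModelCheckpoint(
        model_genes=[str(g) for g in manifest["model_genes"]],
        bin_support_genes=[str(g) for g in manifest["bin_support_genes"]],
        preprocess=PreprocessConfig(**manifest["preprocess"]),
        hyperparameters=dict(manifest["hyperparameters"]),
        model=clf,
        version=version,
        training_manifest=dict(manifest.get("training_manifest", {})),
    )


# ---------------------------------------------------------------------------
# the full training pipeline
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: xgb.XGBClassifier
    model_genes: list[str]
    support_genes: list[str]
    hyperparameters: dict
    universe: list[str]


def _fit_on_clones(
    m_cells: CountMatrix,
    clone_of_cell: Mapping[str, str],
    labels01: Mapping[str, int],
    cfg: PreprocessConfig,
    space: SearchSpace,
    seed: int,
    k_model: int,
    k_support: int,
    n_inner_folds: int,
    ratio_pos: int,
    ratio_neg: int,
    audit: LeakageAudit | None,
    n_importance_boosters: int = 20,
    n_balanced_members: int = 15,
) -> FitResult:
    """Gene filtering, tuning, feature freezing and final fit on one clone set."""
    filtered = filter_genes(m_cells, cfg)

    # Clone-size augmentation of the positive class: expanded clones
    # dominate small labeled cohorts, but a held-out clone can have very
    # few cells, and percentile collapsing looks systematically different
    # at 1-4 cells (weak genes inflate toward their upper order
    # statistics). Pseudo-clones collapsed from random member subsets of
    # each training TRT clone restore that exposure; they are built from
    # training cells only and never leave the training side.
    clones = sorted(c for c in set(clone_of_cell.values()) if c in labels01)
    rng_aug = np.random.default_rng((seed * 1000003 + 7919) % (2**31))
    aug_map = dict(clone_of_cell)
    aug_labels = dict(labels01)
    cells_of: dict[str, list[str]] = {}
    for cell, cl in clone_of_cell.items():
        cells_of.setdefault(cl, []).append(cell)
    aug_names: list[str] = []
    for cl in sorted(c for c in clones if labels01[c] == 1):
        member_cells = sorted(cells_of.get(cl, []))
        for k in (1, 2, 4):
            if len(member_cells) <= k:
                continue
            pseudo = f"{cl}#sub{k}"
            for cell in rng_aug.choice(member_cells, size=k, replace=False):
                aug_map[cell + "#" + pseudo] = pseudo
            aug_labels[pseudo] = 1
            aug_names.append(pseudo)
    if aug_names:
        # duplicate the sampled cells under alias barcodes so the original
        # clone assignment is untouched
        alias_cells = sorted(c for c in aug_map if "#" in c)
        src = [c.split("#", 1)[0] for c in alias_cells]
        idx = {c: i for i, c in enumerate(filtered.unit_ids)}
        m_aug = CountMatrix(
            unit_ids=list(filtered.unit_ids) + alias_cells,
            gene_ids=list(filtered.gene_ids),
            counts=np.vstack([filtered.counts, filtered.counts[[idx[c] for c in src]]]),
            sample_of_unit={
                **filtered.sample_of_unit,
                **{a: filtered.sample_of_unit[s] for a, s in zip(alias_cells, src)},
            },
        )
    else:
        m_aug = filtered

    feats = build_features(m_aug, aug_map, cfg)
    df = feats.to_frame()
    X = df.loc[clones]
    y = pd.Series({c: labels01[c] for c in clones})
    label_names = {c: ("TRT" if labels01[c] == 1 else "nonTRT") for c in clones}
    y_aug = pd.Series({c: aug_labels[c] for c in clones + aug_names})
    label_names_aug = {
        c: ("TRT" if aug_labels[c] == 1 else "nonTRT") for c in clones + aug_names
    }
    parent = {p: p.split("#", 1)[0] for p in aug_names}

    folds = make_inner_folds(clones, label_names, k=n_inner_folds, seed=seed)
    if audit is not None:
        audit.record("tuning", seed, clones)
    hp = tune_hyperparameters(X, y, folds, space, seed=seed, ratio_pos=ratio_pos, ratio_neg=ratio_neg)

    # Per-fold importances come from a feature-bagged ensemble of the tuned
    # configuration: on small balanced clone sets a single booster converges
    # within a few trees and credits only one or two representatives of a
    # redundant program, so gains are summed over several boosters that each
    # sample a small feature fraction per split (stability-selection style).
    importances = []
    for f in sorted(set(folds.values())):
        train = [c for c in clones if folds[c] != f]
        # pseudo-clones follow their parent's fold so no fold-val clone
        # contributes cells to a fold-train pseudo-clone
        train = train + [p for p in aug_names if folds[parent[p]] != f]
        # fixed extraction config, decoupled from the tuned predictor: slow
        # enough not to converge in a handful of trees, feature-subsampled
        # per split so redundant program genes all accumulate gain
        hp_bag = dict(
            max_depth=3,
            learning_rate=0.1,
            n_estimators=150,
            subsample=1.0,
            colsample_bytree=1.0,
            colsample_bynode=0.05,
            reg_lambda=1.0,
            min_child_weight=1.0,
        )
        total: dict[str, float] = {}
        for b in range(n_importance_boosters):
            # fresh negative draw per booster: a spurious gene that only
            # correlates within one particular 10:90 subsample is diluted
            balanced = balance_training(
                train,
                label_names_aug,
                ratio_pos,
                ratio_neg,
                seed=(seed * 1000003 + 1000 + 31 * f + b) % (2**31),
            )
            clf = train_model(
                df.loc[balanced].to_numpy(),
                y_aug[balanced].to_numpy(),
                hp_bag,
                seed=(seed * 1000003 + 101 * f + b) % (2**31),
            )
            for g, v in _gain_importance(clf, X.columns).items():
                total[g] = total.get(g, 0.0) + v
        importances.append(total)
    if audit is not None:
        audit.record("feature_selection", seed, clones)
    model_genes, support_genes = select_features(importances, list(X.columns), k_model, k_support)

    universe = model_genes + support_genes
    feats500 = build_features(m_aug.subset_genes(universe), aug_map, cfg)
    X500 = feats500.to_frame().loc[clones + aug_names, model_genes]
    members = []
    for b in range(n_balanced_members):
        balanced = balance_training(
            clones + aug_names,
            label_names_aug,
            ratio_pos,
            ratio_neg,
            seed=(seed * 1000003 + 99 + 7 * b) % (2**31),
        )
        if audit is not None:
            audit.record("training", seed, balanced)
        # random-subspace bagging: each member also samples features per
        # split so predictions aggregate over the whole frozen program
        # instead of hinging on a few arbitrary perfect separators
        hp_member = dict(hp, colsample_bytree=1.0, colsample_bynode=0.1)
        members.append(
            train_model(
                X500.loc[balanced].to_numpy(),
                y_aug[balanced].to_numpy(),
                hp_member,
                seed=(seed * 1000003 + b) % (2**31),
            )
        )
    model = BalancedEnsemble(members)
    return FitResult(model, model_genes, support_genes, hp, universe)


@dataclass
class SeedResult:
    seed: int
    fit: FitResult
    test_clones: list[str]
    scores: ScoreTable
    truth: dict[str, int]
    metrics: dict[str, float]


def run_nested_cv(
    m: CountMatrix,
    clone_of_cell: Mapping[str, str],
    labels: LabelTable | Mapping[str, str],
    cfg: PreprocessConfig,
    space: SearchSpace,
    seeds: Sequence[int],
    *,
    holdout_fraction: float = 0.20,
    n_inner_folds: int = 5,
    ratio_pos: int = 10,
    ratio_neg: int = 90,
    k_model: int = 50,
    k_support: int = 450,
    audit: LeakageAudit | None = None,
) -> tuple[pd.DataFrame, list[SeedResult]]:
    """Repeat the outer split / tune / freeze / retrain / score loop per seed.

    Returns a per-seed metrics table (MCC, F1, precision, recall, PR-AUC,
    ROC-AUC plus accuracy and FPR) and per-seed artifacts. Held-out clones
    never contribute to filtering, tuning, feature selection or training.
    """
    lab = _labels_dict(labels)
    covered = set(clone_of_cell.values())
    lab = {c: l for c, l in lab.items() if c in covered}
    if not lab:
        raise ValidationError("no labeled clones present in the data")
    rows, results = [], []
    for seed in seeds:
        try:
            plan = make_outer_split(lab, holdout_fraction, seed)
            train_clones = set(plan.train_clones)
            test_clones = plan.test_clones
            if audit is not None:
                audit.record("outer_test", seed, test_clones)
            train_cells = [c for c, cl in clone_of_cell.items() if cl in train_clones]
            m_train = m.subset_cells(sorted(set(train_cells) & set(m.unit_ids)))
            clone_map_train = {c: clone_of_cell[c] for c in m_train.unit_ids}
            labels01 = {c: (1 if lab[c] == "TRT" else 0) for c in train_clones}
            fit = _fit_on_clones(
                m_train,
                clone_map_train,
                labels01,
                cfg,
                space,
                seed,
                k_model,
                k_support,
                n_inner_folds,
                ratio_pos,
                ratio_neg,
                audit,
            )
            # featurize held-out clones over the frozen universe
            from .scoring import expand_to_universe

            test_cells = sorted(
                c for c, cl in clone_of_cell.items() if cl in set(test_clones) and c in set(m.unit_ids)
            )
            m_test = expand_to_universe(m.subset_cells(test_cells), fit.universe)
            clone_map_test = {c: clone_of_cell[c] for c in test_cells}
            feats = build_features(m_test, clone_map_test, cfg)
            X = feats.to_frame().loc[:, fit.model_genes]
            scores = fit.model.predict_proba(X.to_numpy(dtype=float))[:, 1]
            table = ScoreTable(unit_ids=list(X.index), scores=scores, unit_kind="clone")
            truth = {c: (1 if lab[c] == "TRT" else 0) for c in X.index}
            metrics = evaluate(scores, np.array([truth[c] for c in X.index]))
            rows.append({"seed": seed, **metrics})
            results.append(SeedResult(seed, fit, list(test_clones), table, truth, metrics))
        except ValidationError:
            raise
        except Exception as exc:
            raise RuntimeError(f"nested CV failed at seed {seed}: {exc}") from exc
    cols = ["seed", "mcc", "f1", "precision", "recall", "pr_auc", "roc_auc", "accuracy", "fpr"]
    return pd.DataFrame(rows)[cols], results


def fit_checkpoint(
    m: CountMatrix,
    clone_of_cell: Mapping[str, str],
    labels: LabelTable | Mapping[str, str],
    cfg: PreprocessConfig,
    space: SearchSpace,
    seed: int = 0,
    *,
    n_inner_folds: int = 5,
    ratio_pos: int = 10,
    ratio_neg: int = 90,
    k_model: int = 50,
    k_support: int = 450,
    audit: LeakageAudit | None = None,
) -> ModelCheckpoint:
    """Train on all labeled clones and bundle the result for inference.

    The final fit re-runs tuning and feature freezing on the full labeled
    dataset (10:90 balancing included, as during cross-validation) and
    records clone/cell counts in the training manifest.
    """
    lab = _labels_dict(labels)
    covered = set(clone_of_cell.values())
    lab = {c: l for c, l in lab.items() if c in covered}
    cells = sorted(c for c, cl in clone_of_cell.items() if cl in lab and c in set(m.unit_ids))
    m_lab = m.subset_cells(cells)
    clone_map = {c: clone_of_cell[c] for c in cells}
    labels01 = {c: (1 if l == "TRT" else 0) for c, l in lab.items()}
    fit = _fit_on_clones(
        m_lab, clone_map, labels01, cfg, space, seed, k_model, k_support,
        n_inner_folds, ratio_pos, ratio_neg, audit,
    )
    manifest = {
        "seed": int(seed),
        "n_clones": len(lab),
        "n_cells": len(cells),
        "n_trt_clones": int(sum(labels01.values())),
        "balanced_ratio": f"{ratio_pos}:{ratio_neg}",
        "importance_type": "gain",
        "search_strategy": space.strategy,
    }
    return ModelCheckpoint(
        model_genes=fit.model_genes,
        bin_support_genes=fit.support_genes,
        preprocess=cfg,
        hyperparameters=fit.hyperparameters,
        model=fit.model,
        training_manifest=manifest,
    )
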