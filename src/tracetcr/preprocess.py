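"""Gene filtering, expression transforms and clone collapsing.

Two per-unit transforms are supported. *Expression binning* discretizes a
unit's non-zero gene counts into ``n_bins`` equal-frequency bins by rank
(zeros fall in bin 0), which makes features invariant to library size,
sequencing depth and any monotone distortion of counts. *Log
normalization* is the familiar ``log2(1e4 * count / total + 1)``.

When paired clonotypes are available, member-cell raw counts are first
collapsed to one clone-level vector per gene via an interpolated
percentile (default the 75th), and the transform is applied to the
collapsed vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from ._types import CountMatrix, UnitFeatureMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "filter_genes",
    "select_hvg",
    "log_normalize",
    "bin_expression",
    "collapse_clones",
    "build_features",
]

TRANSFORMS = ("expression_binning", "log_normalization")
GENE_SELECTION = ("all", "hvg")
DEFAULT_EXCLUSION = ["MT-", "RPL", "RPS", "LINC", "MALAT1"]


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters.

    Attributes
    ----------
    min_cell_fraction
        Prevalence filter: keep genes expressed (count > 0) in at least
        this fraction of cells (inclusive). Default 0.10.
    n_hvg
        Number of highly variable genes to retain. Default 5000.
    exclusion_patterns
        Gene-symbol prefixes removed after HVG selection (mitochondrial,
        ribosomal, abundant ncRNA).
    n_bins
        Number of non-zero expression bins. Default 20.
    transform
        ``expression_binning`` (default) or ``log_normalization``.
    collapse_percentile
        Per-gene percentile used to collapse member cells to a clone
        vector, in [0, 100]. Default 75.
    gene_selection_method
        ``hvg`` applies the HVG step; ``all`` bypasses it (used when the
        gene universe is frozen in a checkpoint).
    collapse_order
        ``collapse_first`` (default) collapses raw counts then transforms
        the clone vector; ``transform_first`` transforms each cell then
        collapses transformed values.
    """

    min_cell_fraction: float = 0.10
    n_hvg: int = 5000
    exclusion_patterns: list[str] = field(default_factory=lambda: list(DEFAULT_EXCLUSION))
    n_bins: int = 20
    transform: str = "expression_binning"
    collapse_percentile: float = 75.0
    gene_selection_method: str = "hvg"
    collapse_order: str = "collapse_first"

    def __post_init__(self) -> None:
        if not 0 < self.min_cell_fraction <= 1:
            raise ValidationError("min_cell_fraction must be in (0, 1]")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        if not 0 <= self.collapse_percentile <= 100:
            raise ValidationError("collapse_percentile must be in [0, 100]")
        if self.transform not in TRANSFORMS:
            raise ValidationError(f"transform must be one of {TRANSFORMS}")
        if self.gene_selection_method not in GENE_SELECTION:
            raise ValidationError(f"gene_selection_method must be one of {GENE_SELECTION}")
        if self.collapse_order not in ("collapse_first", "transform_first"):
            raise ValidationError("collapse_order must be collapse_first or transform_first")

    # YAML round trip with the exact documented key set -------------------
    _YAML_KEYS = (
        "min_cell_fraction",
        "n_hvg",
        "exclusion_patterns",
        "n_bins",
        "transform",
        "collapse_percentile",
        "gene_selection_method",
    )

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self._YAML_KEYS}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PreprocessConfig":
        data = yaml.safe_load(Path(path).read_text())
        unknown = set(data) - set(cls._YAML_KEYS) - {"collapse_order"}
        if unknown:
            raise ValidationError(f"unknown preprocess config keys {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def single_cell_default(cls) -> "PreprocessConfig":
        """The packaged single-cell scoring configuration."""
        ref = resources.files("tracetcr.data") / "config_preprocess_sc.yaml"
        with resources.as_file(ref) as p:
            return cls.from_yaml(p)


# ---------------------------------------------------------------------------
# gene filtering
# ---------------------------------------------------------------------------

def select_hvg(m: CountMatrix, n_hvg: int) -> list[str]:
    """Rank genes by normalized log-dispersion and return the top ``n_hvg``.

    The statistic is the classic dispersion measure: per-gene
    log((variance/mean) + 1) z-scored within 20 mean-expression bins, so
    highly expressed genes do not dominate purely through their scale.
    Deterministic: ties break on gene symbol.
    """
    if n_hvg < 1:
        raise ValidationError("n_hvg must be >= 1")
    counts = m.counts.astype(float)
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1) if m.n_cells > 1 else np.zeros(m.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    logdisp = np.log1p(disp)
    # z-score dispersion within equal-frequency mean bins (>= 20 genes per
    # bin so the within-bin moments are stable; one global bin when small)
    n_mean_bins = max(1, min(20, m.n_genes // 20))
    order = np.argsort(mean, kind="stable")
    bins = np.empty(m.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(m.n_genes) * n_mean_bins) // max(m.n_genes, 1), n_mean_bins - 1
    )
    norm = np.empty(m.n_genes)
    for b in range(n_mean_bins):
        sel = bins == b
        if not sel.any():
            continue
        mu, sd = logdisp[sel].mean(), logdisp[sel].std()
        norm[sel] = (logdisp[sel] - mu) / sd if sd > 0 else logdisp[sel] - mu
    if n_hvg > m.n_genes:
        logger.warning("n_hvg=%d exceeds gene count %d; keeping all", n_hvg, m.n_genes)
    ranked = sorted(zip(-norm, m.gene_ids))  # descending statistic, symbol tie-break
    return [g for _, g in ranked[: min(n_hvg, m.n_genes)]]


def filter_genes(m: CountMatrix, cfg: PreprocessConfig) -> CountMatrix:
    """Apply prevalence filter, optional HVG selection, then exclusions.

    Gene order of the input is preserved. Labels are never consulted.
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValidationError("cannot filter an empty matrix")
    prevalence = (m.counts > 0).mean(axis=0)
    keep = prevalence >= cfg.min_cell_fraction  # inclusive at the threshold
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    if genes and cfg.gene_selection_method == "hvg" and cfg.n_hvg < len(genes):
        sub = m.subset_genes(genes)
        hvg = set(select_hvg(sub, cfg.n_hvg))
        genes = [g for g in genes if g in hvg]
    if cfg.exclusion_patterns:
        pats = tuple(cfg.exclusion_patterns)
        genes = [g for g in genes if not g.startswith(pats)]
    if not genes:
        raise ValidationError("no genes survive filtering; relax thresholds")
    return m.subset_genes(genes)


# ---------------------------------------------------------------------------
# per-unit transforms
# ---------------------------------------------------------------------------

def log_normalize(v: np.ndarray) -> np.ndarray:
    """``log2(1e4 * count / total + 1)`` for one unit's count vector."""
    v = np.asarray(v, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValidationError("log normalization undefined for an all-zero unit")
    return np.log2(1e4 * v / total + 1.0)


def bin_expression(v: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Equal-frequency binning of one unit's non-zero counts.

    Zero-count genes go to bin 0. Non-zero genes are ranked ascending by
    count and assigned ``bin = ceil(rank / n_nonzero * n_bins)``; tied
    counts share the bin obtained by evaluating that expression at their
    average rank. Output integers lie in ``[0, n_bins]``.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    v = np.asarray(v)
    out = np.zeros(v.shape, dtype=np.int64)
    nz = np.flatnonzero(v > 0)
    if nz.size == 0:
        return out
    ranks = _average_ranks(v[nz].astype(float))
    out[nz] = np.ceil(ranks * n_bins / nz.size).astype(np.int64)
    np.clip(out, 0, n_bins, out=out)
    return out


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Ascending 1-based ranks with ties sharing their average rank."""
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def _bin_matrix(values: np.ndarray, n_bins: int) -> np.ndarray:
    return np.vstack([bin_expression(row, n_bins) for row in values])


# ---------------------------------------------------------------------------
# clone collapsing
# ---------------------------------------------------------------------------

def collapse_clones(
    m: CountMatrix | UnitFeatureMatrix,
    clone_of_cell: Mapping[str, str],
    percentile: float = 75.0,
) -> UnitFeatureMatrix:
    """Summarize member cells to one vector per clone.

    For each clone and gene the collapsed value is the linear-interpolation
    percentile of the member cells' values. Cells without a clone
    assignment are excluded (count logged). Clone ids sort lexicographically
    in the output.
    """
    if not 0 <= percentile <= 100:
        raise ValidationError("percentile must be in [0, 100]")
    values = m.counts if isinstance(m, CountMatrix) else m.values
    cells = m.unit_ids
    idx_of_cell = {c: i for i, c in enumerate(cells)}
    members: dict[str, list[int]] = {}
    unassigned = 0
    for cell in cells:
        clone = clone_of_cell.get(cell)
        if clone is None:
            unassigned += 1
            continue
        members.setdefault(clone, []).append(idx_of_cell[cell])
    if unassigned:
        logger.info("collapse_clones: %d cells without clone assignment excluded", unassigned)
    if not members:
        raise ValidationError("no cells carry a clone assignment")
    clone_ids = sorted(members)
    out = np.empty((len(clone_ids), values.shape[1]), dtype=float)
    for i, clone in enumerate(clone_ids):
        out[i] = np.percentile(values[members[clone]], percentile, axis=0, method="linear")
    return UnitFeatureMatrix(
        unit_ids=clone_ids, gene_ids=list(m.gene_ids), values=out, unit_kind="clone"
    )


# ---------------------------------------------------------------------------
# pipeline entry point
# ---------------------------------------------------------------------------

def build_features(
    m: CountMatrix,
    clone_of_cell: Mapping[str, str] | None,
    cfg: PreprocessConfig,
) -> UnitFeatureMatrix:
    """Produce the unit x gene feature matrix the classifier consumes.

    Clone mode (``clone_of_cell`` given): collapse member-cell raw counts
    at ``cfg.collapse_percentile`` per gene, then apply ``cfg.transform``
    to each clone vector (or the reverse under
    ``collapse_order='transform_first'``). Cell mode (``None``): apply the
    transform directly to each cell.
    """
    if clone_of_cell is None:
        values = m.counts.astype(float)
        if cfg.transform == "expression_binning":
            out = _bin_matrix(values, cfg.n_bins)
        else:
            out = np.vstack([log_normalize(row) for row in values])
        return UnitFeatureMatrix(
            unit_ids=list(m.unit_ids), gene_ids=list(m.gene_ids), values=out, unit_kind="cell"
        )

    if cfg.collapse_order == "transform_first":
        if cfg.transform == "expression_binning":
            cellvals = _bin_matrix(m.counts, cfg.n_bins)
        else:
            cellvals = np.vstack([log_normalize(row) for row in m.counts])
        ufm = UnitFeatureMatrix(
            unit_ids=list(m.unit_ids), gene_ids=list(m.gene_ids), values=cellvals, unit_kind="cell"
        )
        return collapse_clones(ufm, clone_of_cell, cfg.collapse_percentile)

    collapsed = collapse_clones(m, clone_of_cell, cfg.collapse_percentile)
    if cfg.transform == "expression_binning":
        values = _bin_matrix(collapsed.values, cfg.n_bins)
    else:
        values = np.vstack([log_normalize(row) for row in collapsed.values])
    return UnitFeatureMatrix(
        unit_ids=collapsed.unit_ids,
        gene_ids=collapsed.gene_ids,
        values=values,
        unit_kind="clone",
    )
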