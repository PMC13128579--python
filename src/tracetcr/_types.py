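"""Core in-memory containers shared across the pipeline.

Everything downstream operates on two views of the data: a cells x genes
UMI count matrix (:class:`CountMatrix`) and a table of per-cell TCR chains
from which the cell -> clone assignment is derived (:class:`ClonotypeTable`).
Transformed features (bin indices or log-normalized values) live in
:class:`UnitFeatureMatrix`, where a "unit" is either a cell or a clone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ChainRecord",
    "ClonotypeTable",
    "LabelTable",
    "UnitFeatureMatrix",
    "ScoreTable",
    "SampleScore",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class CountMatrix:
    """Cells x genes non-negative integer UMI counts.

    Parameters
    ----------
    unit_ids
        Cell barcodes, unique.
    gene_ids
        Gene symbols, unique (readers disambiguate duplicates by suffixing).
    counts
        Dense ``(n_cells, n_genes)`` integer array, all entries >= 0.
    sample_of_unit
        Maps every cell barcode to a sample identifier.
    tissue_of_sample
        Optional map sample -> one of {"tumor", "normal", "pbmc", "other"}.
    """

    unit_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray
    sample_of_unit: dict[str, str]
    tissue_of_sample: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D cells x genes array")
        if self.counts.shape != (len(self.unit_ids), len(self.gene_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.unit_ids)} cells x {len(self.gene_ids)} genes"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                self.counts == np.floor(self.counts)
            ):
                self.counts = self.counts.astype(np.int64)
            else:
                raise ValidationError("counts must be integers")
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValidationError("cell barcodes must be unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene symbols must be unique")
        missing = [u for u in self.unit_ids if u not in self.sample_of_unit]
        if missing:
            raise ValidationError(
                f"{len(missing)} cells lack a sample tag (e.g. {missing[0]!r})"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.unit_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not present in matrix") from None

    def subset_cells(self, keep: np.ndarray | Sequence[str]) -> "CountMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif len(keep) and isinstance(keep[0], str):
            lookup = {u: i for i, u in enumerate(self.unit_ids)}
            idx = np.array([lookup[u] for u in keep], dtype=int)
        else:
            idx = np.asarray(keep, dtype=int)
        unit_ids = [self.unit_ids[i] for i in idx]
        return replace(
            self,
            unit_ids=unit_ids,
            counts=self.counts[idx],
            sample_of_unit={u: self.sample_of_unit[u] for u in unit_ids},
        )

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = self.gene_index(genes)
        return replace(self, gene_ids=list(genes), counts=self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.unit_ids, columns=self.gene_ids)


@dataclass(frozen=True)
class ChainRecord:
    """One assembled TCR chain for one cell."""

    cell_id: str
    locus: str  # "TRA" or "TRB"
    cdr3_aa: str
    v_gene: str = ""
    j_gene: str = ""
    umis: int = 0
    productive: bool = True

    def __post_init__(self) -> None:
        if self.locus not in ("TRA", "TRB"):
            raise ValidationError(f"locus must be TRA or TRB, got {self.locus!r}")
        if self.productive and not self.cdr3_aa:
            raise ValidationError("productive chain requires a non-empty CDR3")
        if self.umis < 0:
            raise ValidationError("umis must be >= 0")


@dataclass
class ClonotypeTable:
    """Per-cell chains plus the derived cell -> clone assignment."""

    chains: list[ChainRecord]
    clone_of_cell: dict[str, str]
    clone_key_mode: str  # paired_cdr3 | cdr3b_only | vdj_expression

    def __post_init__(self) -> None:
        if self.clone_key_mode not in ("paired_cdr3", "cdr3b_only", "vdj_expression"):
            raise ValidationError(f"unknown clone_key_mode {self.clone_key_mode!r}")

    def cells_of_clone(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cell, clone in self.clone_of_cell.items():
            out.setdefault(clone, []).append(cell)
        return out

    @property
    def clone_ids(self) -> list[str]:
        return sorted(set(self.clone_of_cell.values()))


LABELS = ("TRT", "nonTRT", "unknown")
PROVENANCES = ("experimental", "vdjdb", "pbmc", "expt_coculture")


@dataclass
class LabelTable:
    """Clone-level reactivity labels with provenance."""

    label_of_clone: dict[str, str]
    provenance_of_clone: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.label_of_clone.values()} - set(LABELS)
        if bad:
            raise ValidationError(f"labels outside {LABELS}: {sorted(bad)}")
        badp = set(self.provenance_of_clone.values()) - set(PROVENANCES)
        if badp:
            raise ValidationError(f"provenance outside {PROVENANCES}: {sorted(badp)}")

    def labeled_clones(self) -> dict[str, str]:
        """Clones with a definite TRT / nonTRT label (``unknown`` dropped)."""
        return {c: l for c, l in self.label_of_clone.items() if l != "unknown"}


@dataclass
class UnitFeatureMatrix:
    """Units (cells or clones) x genes after a transform.

    ``values`` holds integer bin indices in ``[0, n_bins]`` for the binning
    transform, or non-negative reals for log normalization.
    """

    unit_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    unit_kind: str  # "cell" | "clone"

    def __post_init__(self) -> None:
        if self.unit_kind not in ("cell", "clone"):
            raise ValidationError(f"unit_kind must be cell or clone, got {self.unit_kind!r}")
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.unit_ids), len(self.gene_ids)):
            raise ValidationError("values shape does not match ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.unit_ids, columns=self.gene_ids)


@dataclass
class ScoreTable:
    """Per-unit reactivity probabilities and calls at a fixed threshold."""

    unit_ids: list[str]
    scores: np.ndarray
    unit_kind: str
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.unit_ids),):
            raise ValidationError("one score per unit required")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValidationError("scores must lie in [0, 1]")

    @property
    def calls(self) -> np.ndarray:
        # inclusive at the threshold: a score of exactly 0.5 is a TRT call
        return np.where(self.scores >= self.threshold, "TRT", "nonTRT")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": self.unit_ids,
                "score": self.scores,
                "call": self.calls,
                "unit_kind": self.unit_kind,
            }
        )


@dataclass(frozen=True)
class SampleScore:
    """Per-sample reactive-cell fraction (sTRACE score)."""

    sample_id: str
    strace: float
    n_cells: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.strace <= 1.0:
            raise ValidationError("strace must lie in [0, 1]")
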