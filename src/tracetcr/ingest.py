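"""Readers, QC filters and clone assignment.

Counts arrive as a 10x MTX directory, a dense CSV (cells x genes) or an
HDF5 container; TCR chains arrive as a 10x ``filtered_contig_annotations``
CSV or an AIRR rearrangement TSV. Cell QC follows the usual droplet
conventions (minimum detected genes, maximum mitochondrial fraction), and
clonotype handling enforces at most one productive alpha and one beta chain
per cell before clones are keyed on CDR3 amino-acid sequences.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._types import (
    ChainRecord,
    ClonotypeTable,
    CountMatrix,
    LabelTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts_csv",
    "write_counts_mtx",
    "read_clonotypes",
    "read_labels",
    "write_labels",
    "qc_filter_cells",
    "enforce_single_chains",
    "assign_clones",
    "infer_clones_from_vdj_expression",
    "match_vdjdb",
    "label_expt_trt",
    "filter_cd8",
    "CorpusManifest",
    "load_corpus_manifest",
]


# ---------------------------------------------------------------------------
# count readers / writers
# ---------------------------------------------------------------------------

def _dedupe(symbols: Iterable[str]) -> list[str]:
    """Disambiguate duplicate gene symbols by suffixing .1, .2 in file order."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dirpath}")


def read_counts(
    path: str | Path,
    format: str,
    sample_of_unit: Mapping[str, str] | None = None,
    default_sample: str = "sample0",
) -> CountMatrix:
    """Read a UMI count matrix.

    ``format`` is one of ``mtx_dir`` (10x-style directory with matrix.mtx,
    features.tsv, barcodes.tsv, optionally gzipped), ``csv`` (dense cells x
    genes with a header row of gene symbols and barcodes in the first
    column) or ``h5`` (datasets /counts, /genes, /barcodes). Cells absent
    from ``sample_of_unit`` are tagged ``default_sample``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            frac = values != np.floor(values)
            if frac.any():
                r, c = np.argwhere(frac)[0]
                raise ValidationError(
                    f"non-integer count {values[r, c]} at cell "
                    f"{df.index[r]!r}, gene {df.columns[c]!r} in {path}"
                )
            values = values.astype(np.int64)
        barcodes = [str(b) for b in df.index]
        genes = _dedupe(str(g) for g in df.columns)
    elif format == "mtx_dir":
        mtx = _find(path, "matrix.mtx")
        try:
            mat = scipy.io.mmread(mtx)
        except Exception as exc:  # noqa: BLE001 - surface the offending file
            raise ValidationError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
        with _open_maybe_gz(_find(path, "features.tsv")) as fh:
            genes = _dedupe(line.rstrip("\n").split("\t")[0] for line in fh if line.strip())
        with _open_maybe_gz(_find(path, "barcodes.tsv")) as fh:
            barcodes = [line.strip() for line in fh if line.strip()]
        dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        if dense.shape == (len(genes), len(barcodes)):
            dense = dense.T  # 10x convention: genes x cells on disk
        if not np.issubdtype(dense.dtype, np.integer):
            if np.any(dense != np.floor(dense)):
                raise ValidationError(f"non-integer values in {mtx}")
            dense = dense.astype(np.int64)
        values = dense
    elif format == "h5":
        import h5py

        with h5py.File(path, "r") as f:
            values = np.asarray(f["/counts"])
            genes = _dedupe(g.decode() if isinstance(g, bytes) else str(g) for g in f["/genes"][:])
            barcodes = [
                b.decode() if isinstance(b, bytes) else str(b) for b in f["/barcodes"][:]
            ]
        if not np.issubdtype(values.dtype, np.integer):
            if np.any(values != np.floor(values)):
                raise ValidationError(f"non-integer values in {path}:/counts")
            values = values.astype(np.int64)
    else:
        raise ValueError(f"unknown counts format {format!r}")

    sm = dict(sample_of_unit or {})
    tags = {b: sm.get(b, default_sample) for b in barcodes}
    return CountMatrix(unit_ids=barcodes, gene_ids=genes, counts=values, sample_of_unit=tags)


def write_counts_csv(m: CountMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path)


def write_counts_mtx(m: CountMatrix, dirpath: str | Path) -> None:
    """Write a 10x-style MTX directory (genes x cells on disk)."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(dirpath / "matrix.mtx", scipy.sparse.coo_matrix(m.counts.T))
    (dirpath / "features.tsv").write_text("".join(f"{g}\t{g}\tGene Expression\n" for g in m.gene_ids))
    (dirpath / "barcodes.tsv").write_text("".join(b + "\n" for b in m.unit_ids))


# ---------------------------------------------------------------------------
# clonotype readers
# ---------------------------------------------------------------------------

_TENX_COLS = {"barcode", "chain", "cdr3", "umis", "productive"}
_AIRR_COLS = {"cell_id", "locus", "junction_aa", "duplicate_count", "productive"}


def _as_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in ("true", "t", "yes", "1")


def read_clonotypes(path: str | Path, format: str = "auto") -> list[ChainRecord]:
    """Read TCR chains from a 10x contig CSV or an AIRR rearrangement TSV."""
    path = Path(path)
    if format == "auto":
        format = "airr" if path.suffix in (".tsv", ".txt") else "tenx"
    if format == "tenx":
        df = pd.read_csv(path)
        missing = _TENX_COLS - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing 10x contig columns {sorted(missing)}")
        cols = dict(cell="barcode", locus="chain", cdr3="cdr3", umis="umis")
    elif format == "airr":
        df = pd.read_csv(path, sep="\t")
        missing = _AIRR_COLS - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing AIRR columns {sorted(missing)}")
        cols = dict(cell="cell_id", locus="locus", cdr3="junction_aa", umis="duplicate_count")
    else:
        raise ValueError(f"unknown clonotype format {format!r}")

    chains = []
    for _, row in df.iterrows():
        locus = str(row[cols["locus"]])
        if locus not in ("TRA", "TRB"):
            continue  # gamma/delta and multi-mapped contigs are ignored
        chains.append(
            ChainRecord(
                cell_id=str(row[cols["cell"]]),
                locus=locus,
                cdr3_aa="" if pd.isna(row[cols["cdr3"]]) else str(row[cols["cdr3"]]),
                v_gene=str(row.get("v_gene", row.get("v_call", "")) or ""),
                j_gene=str(row.get("j_gene", row.get("j_call", "")) or ""),
                umis=int(row[cols["umis"]]),
                productive=_as_bool(row["productive"]),
            )
        )
    return chains


def write_clonotypes_tenx(chains: Sequence[ChainRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "barcode": [c.cell_id for c in chains],
            "chain": [c.locus for c in chains],
            "cdr3": [c.cdr3_aa for c in chains],
            "v_gene": [c.v_gene for c in chains],
            "j_gene": [c.j_gene for c in chains],
            "umis": [c.umis for c in chains],
            "productive": ["True" if c.productive else "False" for c in chains],
        }
    ).to_csv(path, index=False)


def read_labels(path: str | Path) -> LabelTable:
    """Read a clone label TSV with columns clone_id, label, provenance."""
    df = pd.read_csv(path, sep="\t")
    need = {"clone_id", "label"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: label TSV needs columns {sorted(need)}")
    prov = {}
    if "provenance" in df.columns:
        prov = {
            str(r.clone_id): str(r.provenance)
            for r in df.itertuples()
            if not pd.isna(r.provenance)
        }
    return LabelTable(
        label_of_clone={str(r.clone_id): str(r.label) for r in df.itertuples()},
        provenance_of_clone=prov,
    )


def write_labels(labels: LabelTable, path: str | Path) -> None:
    rows = [
        {
            "clone_id": c,
            "label": l,
            "provenance": labels.provenance_of_clone.get(c, ""),
        }
        for c, l in labels.label_of_clone.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC and marker filters
# ---------------------------------------------------------------------------

def qc_filter_cells(
    m: CountMatrix,
    mito_gene_prefix: str = "MT-",
    min_genes: int = 200,
    max_mito_frac: float = 0.25,
) -> CountMatrix:
    """Drop low-complexity and high-mitochondrial cells.

    Keeps cells with at least ``min_genes`` detected genes AND a
    mitochondrial count fraction of at most ``max_mito_frac`` (both
    thresholds inclusive on the keep side).
    """
    detected = (m.counts > 0).sum(axis=1)
    mito_idx = [i for i, g in enumerate(m.gene_ids) if g.startswith(mito_gene_prefix)]
    totals = m.counts.sum(axis=1)
    mito = m.counts[:, mito_idx].sum(axis=1) if mito_idx else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    keep = (detected >= min_genes) & (frac <= max_mito_frac)
    if not keep.any():
        raise ValidationError(
            "QC removed every cell; review min_genes/max_mito_frac thresholds"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("QC removed %d/%d cells", dropped, m.n_cells)
    return m.subset_cells(keep)


def filter_cd8(
    m: CountMatrix,
    cd8_genes: Sequence[str] = ("CD8A", "CD8B"),
    cd4_gene: str = "CD4",
) -> CountMatrix:
    """Keep putative CD8+ cells by a per-cell marker ratio.

    A cell is retained when its summed CD8 marker counts strictly exceed
    its CD4 counts. This is a deliberately simple per-cell rule; it does
    not attempt cluster-level annotation.
    """
    missing = [g for g in (*cd8_genes, cd4_gene) if g not in m.gene_ids]
    if missing:
        raise ValidationError(f"marker genes absent from matrix: {missing}")
    cd8 = m.counts[:, m.gene_index(cd8_genes)].sum(axis=1)
    cd4 = m.counts[:, m.gene_index([cd4_gene])].sum(axis=1)
    return m.subset_cells(cd8 > cd4)


# ---------------------------------------------------------------------------
# chain enforcement and clone assignment
# ---------------------------------------------------------------------------

def enforce_single_chains(chains: Sequence[ChainRecord]) -> list[ChainRecord]:
    """Retain at most one productive chain per (cell, locus).

    The chain with the most UMIs wins; exact ties go to the
    lexicographically smallest CDR3 so the outcome is order-independent.
    Non-productive chains are dropped; cells with no productive chain pass
    through chainless.
    """
    best: dict[tuple[str, str], ChainRecord] = {}
    order: list[tuple[str, str]] = []
    for ch in chains:
        if not ch.productive:
            continue
        key = (ch.cell_id, ch.locus)
        cur = best.get(key)
        if cur is None:
            best[key] = ch
            order.append(key)
        elif (ch.umis, _neg_lex(ch.cdr3_aa)) > (cur.umis, _neg_lex(cur.cdr3_aa)):
            best[key] = ch
    return [best[k] for k in order]


class _neg_lex(str):
    """Inverts lexicographic order so max-comparison prefers smaller CDR3s."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def assign_clones(chains: Sequence[ChainRecord], mode: str = "paired_cdr3") -> ClonotypeTable:
    """Group cells into clones by CDR3 amino-acid identity.

    ``paired_cdr3`` keys a clone on (CDR3alpha, CDR3beta); ``cdr3b_only``
    keys on the beta CDR3 alone, which is how cross-dataset labels keyed
    only by beta chains are transferred. Cells lacking a required chain
    stay unassigned.
    """
    if mode not in ("paired_cdr3", "cdr3b_only"):
        raise ValueError(f"unknown clone mode {mode!r}")
    by_cell: dict[str, dict[str, str]] = {}
    for ch in chains:
        if ch.productive:
            by_cell.setdefault(ch.cell_id, {})[ch.locus] = ch.cdr3_aa
    clone_of_cell: dict[str, str] = {}
    for cell in sorted(by_cell):
        loci = by_cell[cell]
        if mode == "paired_cdr3":
            if "TRA" in loci and "TRB" in loci:
                clone_of_cell[cell] = f"{loci['TRA']}_{loci['TRB']}"
        else:
            if "TRB" in loci:
                clone_of_cell[cell] = loci["TRB"]
    return ClonotypeTable(chains=list(chains), clone_of_cell=clone_of_cell, clone_key_mode=mode)


def infer_clones_from_vdj_expression(
    m: CountMatrix, trav_genes: Sequence[str], trbv_genes: Sequence[str]
) -> ClonotypeTable:
    """Infer clones from V-segment expression when scTCR-seq is missing.

    Each cell's clone key is the (TRAV, TRBV) pair with the most counts;
    ties resolve to the first gene in the provided list order. Cells with
    zero counts across either list are unassigned.
    """
    if not trav_genes or not trbv_genes:
        raise ValidationError("trav_genes and trbv_genes must be non-empty")
    trav_idx = m.gene_index(trav_genes)
    trbv_idx = m.gene_index(trbv_genes)
    trav = m.counts[:, trav_idx]
    trbv = m.counts[:, trbv_idx]
    clone_of_cell = {}
    for i, cell in enumerate(m.unit_ids):
        if trav[i].max() == 0 or trbv[i].max() == 0:
            continue
        a = trav_genes[int(np.argmax(trav[i]))]  # argmax returns first max: list order
        b = trbv_genes[int(np.argmax(trbv[i]))]
        clone_of_cell[cell] = f"{a}_{b}"
    return ClonotypeTable(chains=[], clone_of_cell=clone_of_cell, clone_key_mode="vdj_expression")


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def match_vdjdb(ct: ClonotypeTable, reference: pd.DataFrame) -> LabelTable:
    """Label clones whose beta CDR3 has a known (non-tumor) antigen.

    ``reference`` needs a ``cdr3b`` column (antigen annotations optional).
    Matched clones become nonTRT with provenance ``vdjdb``; everything else
    is ``unknown``.
    """
    if "cdr3b" not in reference.columns:
        raise ValidationError("reference table needs a 'cdr3b' column")
    if reference["cdr3b"].duplicated().any():
        raise ValidationError("reference CDR3b keys must be unique")
    known = set(reference["cdr3b"].astype(str))
    trb_of_cell: dict[str, str] = {}
    for ch in ct.chains:
        if ch.productive and ch.locus == "TRB":
            trb_of_cell[ch.cell_id] = ch.cdr3_aa
    labels, prov = {}, {}
    for clone, cells in ct.cells_of_clone().items():
        cdr3bs = {trb_of_cell[c] for c in cells if c in trb_of_cell}
        if cdr3bs & known:
            labels[clone] = "nonTRT"
            prov[clone] = "vdjdb"
        else:
            labels[clone] = "unknown"
    return LabelTable(label_of_clone=labels, provenance_of_clone=prov)


def label_expt_trt(
    clone_replicate_stats: Mapping[str, Sequence[tuple[int, int]]],
    min_cells: int = 1,
    min_frac: float = 0.05,
) -> LabelTable:
    """Label clones from co-culture activation statistics.

    ``clone_replicate_stats`` maps clone -> [(n_cells, n_high), ...] per
    replicate, where ``n_high`` counts cells in an activation-marker-high
    (TNFRSF9-high) state. A clone is TRT when any replicate has at least
    ``min_cells`` high cells AND a high fraction of at least ``min_frac``.
    """
    labels, prov = {}, {}
    for clone, reps in clone_replicate_stats.items():
        hit = False
        for n_cells, n_high in reps:
            if n_high > n_cells:
                raise ValidationError(f"clone {clone}: n_high {n_high} > n_cells {n_cells}")
            if n_cells > 0 and n_high >= min_cells and n_high / n_cells >= min_frac:
                hit = True
        labels[clone] = "TRT" if hit else "nonTRT"
        prov[clone] = "expt_coculture"
    return LabelTable(label_of_clone=labels, provenance_of_clone=prov)


# ---------------------------------------------------------------------------
# training-corpus bookkeeping
# ---------------------------------------------------------------------------

CORPUS_CATEGORIES = ("trt", "nontrt_expt", "nontrt_vdjdb", "nontrt_pbmc")


@dataclass
class CorpusManifest:
    """Per-dataset clone/cell counts by label category.

    Rows describe the composition of a training corpus (one row per
    dataset and category); ``totals`` aggregates clones and cells per
    category and overall.
    """

    table: pd.DataFrame  # columns: dataset, category, n_clones, n_cells

    def __post_init__(self) -> None:
        need = {"dataset", "category", "n_clones", "n_cells"}
        if not need <= set(self.table.columns):
            raise ValidationError(f"manifest needs columns {sorted(need)}")
        bad = set(self.table["category"]) - set(CORPUS_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown manifest categories {sorted(bad)}")

    def totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cat in CORPUS_CATEGORIES:
            sub = self.table[self.table["category"] == cat]
            out[f"{cat}_clones"] = int(sub["n_clones"].sum())
            out[f"{cat}_cells"] = int(sub["n_cells"].sum())
        out["total_clones"] = int(self.table["n_clones"].sum())
        out["total_cells"] = int(self.table["n_cells"].sum())
        return out


def load_corpus_manifest(path: str | Path | None = None) -> CorpusManifest:
    """Load a corpus manifest TSV; defaults to the packaged published-corpus table."""
    if path is None:
        ref = resources.files("tracetcr.data") / "training_corpus.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return CorpusManifest(table=df)
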