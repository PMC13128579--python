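"""Synthetic scRNA/scTCR datasets with known ground truth.

The generator draws overdispersed UMI counts from a negative-binomial
model (gamma-Poisson) with lognormal per-gene relative abundances and
lognormal library sizes, organizes cells into clones with a skewed
(geometric) clone-size law, and plants a rare tumor-reactive class
(~2% of clones by default) carrying a 36-up / 14-down expression program
applied multiplicatively on the mean scale. A configurable fraction of
the negative clones is tagged as PBMC-derived and carries elevated
naive-program expression (the down-set genes), emulating bystander
diversity. Everything is deterministic per seed and writes the same
on-disk formats the readers consume.
"""

from __future__ import annotations

import string
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._types import ChainRecord, ClonotypeTable, CountMatrix, LabelTable, ValidationError
from .benchmarks import Signature

__all__ = ["SimSpec", "SimulatedDataset", "simulate_dataset", "planted_signature",
           "write_dataset", "read_dataset"]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimSpec:
    """Study conditions for one simulated dataset.

    Defaults describe a modest tumor+blood cohort: 500 clones of which 2%
    are tumor-reactive, TRT clones clonally expanded (mean 35 cells per
    clone vs ~2 for bystanders, matching the composition of published
    training corpora), ~2000 counts per cell, and a strong planted program
    (|log2FC| = 2 over 36 up- and 14 down-regulated genes).
    """

    seed: int = 0
    n_genes: int = 2000
    n_clones: int = 500
    frac_trt: float = 0.02
    clone_size_mean: float = 2.0
    trt_clone_size_mean: float = 35.0
    library_size_mean: float = 2000.0
    library_size_sigma: float = 0.3
    gene_mean_sigma: float = 1.0
    nb_dispersion: float = 0.3
    n_up: int = 36
    n_down: int = 14
    effect_log2fc: float = 2.0
    n_samples: int = 4
    pbmc_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.frac_trt < 1:
            raise ValidationError("frac_trt must be in (0, 1)")
        if self.effect_log2fc < 0:
            raise ValidationError("effect_log2fc must be >= 0")
        if self.n_up + self.n_down > self.n_genes:
            raise ValidationError("n_up + n_down exceeds n_genes")
        if round(self.frac_trt * self.n_clones) < 1:
            raise ValidationError(
                f"frac_trt={self.frac_trt} x n_clones={self.n_clones} yields no TRT clone"
            )
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    clonotypes: ClonotypeTable
    labels: LabelTable
    truth: dict

    @property
    def clone_of_cell(self) -> dict[str, str]:
        return self.clonotypes.clone_of_cell


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draws: mean mu, variance mu + dispersion * mu^2."""
    lam = rng.gamma(shape=1.0 / dispersion, scale=np.maximum(mu, 1e-12) * dispersion)
    return rng.poisson(lam).astype(np.int64)


def _geometric_sizes(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    p = 1.0 / max(mean, 1.0)
    return rng.geometric(p, size=n)


def _cdr3(rng: np.random.Generator, prefix: str, length: int = 8) -> str:
    return prefix + "".join(rng.choice(list(_AA), size=length))


def simulate_dataset(spec: SimSpec) -> SimulatedDataset:
    """Draw a full dataset (counts, clonotypes, labels, truth manifest)."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]

    # planted program
    planted = rng.choice(spec.n_genes, size=spec.n_up + spec.n_down, replace=False)
    up_idx, down_idx = planted[: spec.n_up], planted[spec.n_up :]

    # clone labels, sizes, samples
    n_trt = int(round(spec.frac_trt * spec.n_clones))
    clone_ids = [f"C{i:04d}" for i in range(spec.n_clones)]
    trt_clones = set(clone_ids[:n_trt])  # clone ids are arbitrary; first block is TRT
    neg_clones = clone_ids[n_trt:]
    n_pbmc = int(round(spec.pbmc_fraction * len(neg_clones)))
    pbmc_clones = set(neg_clones[:n_pbmc])

    sizes = np.empty(spec.n_clones, dtype=int)
    sizes[:n_trt] = _geometric_sizes(rng, n_trt, spec.trt_clone_size_mean)
    sizes[n_trt:] = _geometric_sizes(rng, spec.n_clones - n_trt, spec.clone_size_mean)

    n_tumor_samples = max(1, spec.n_samples // 2)
    n_pbmc_samples = max(1, spec.n_samples - n_tumor_samples)
    tumor_samples = [f"tumor{i}" for i in range(n_tumor_samples)]
    pbmc_samples = [f"pbmc{i}" for i in range(n_pbmc_samples)]
    sample_of_clone = {}
    for i, clone in enumerate(clone_ids):
        if clone in pbmc_clones:
            sample_of_clone[clone] = pbmc_samples[i % n_pbmc_samples]
        else:
            sample_of_clone[clone] = tumor_samples[i % n_tumor_samples]
    tissue_of_sample = {**{s: "tumor" for s in tumor_samples}, **{s: "pbmc" for s in pbmc_samples}}

    # per-class expected relative abundances
    base = rng.lognormal(mean=0.0, sigma=spec.gene_mean_sigma, size=spec.n_genes)
    fc = 2.0 ** spec.effect_log2fc
    w_trt = base.copy()
    w_trt[up_idx] *= fc
    w_trt[down_idx] /= fc
    w_pbmc = base.copy()
    w_pbmc[down_idx] *= fc  # naive program high in blood bystanders
    profiles = {
        "trt": w_trt / w_trt.sum(),
        "til_neg": base / base.sum(),
        "pbmc": w_pbmc / w_pbmc.sum(),
    }

    # cells
    cell_rows, cell_clones, cell_classes = [], [], []
    for i, clone in enumerate(clone_ids):
        cls = "trt" if clone in trt_clones else ("pbmc" if clone in pbmc_clones else "til_neg")
        for j in range(sizes[i]):
            cell_rows.append(f"{clone}-{j:03d}")
            cell_clones.append(clone)
            cell_classes.append(cls)
    n_cells = len(cell_rows)
    libs = rng.lognormal(mean=np.log(spec.library_size_mean), sigma=spec.library_size_sigma, size=n_cells)
    counts = np.empty((n_cells, spec.n_genes), dtype=np.int64)
    for cls in ("trt", "til_neg", "pbmc"):
        sel = np.array([c == cls for c in cell_classes])
        if sel.any():
            mu = libs[sel, None] * profiles[cls][None, :]
            counts[sel] = _nb_counts(rng, mu, spec.nb_dispersion)

    sample_of_cell = {c: sample_of_clone[cl] for c, cl in zip(cell_rows, cell_clones)}
    m = CountMatrix(
        unit_ids=cell_rows,
        gene_ids=genes,
        counts=counts,
        sample_of_unit=sample_of_cell,
        tissue_of_sample=tissue_of_sample,
    )

    # clonotypes: unique paired CDR3s per clone
    seen: set[str] = set()
    cdr3a_of_clone, cdr3b_of_clone = {}, {}
    for clone in clone_ids:
        while True:
            b = _cdr3(rng, "CASS")
            if b not in seen:
                seen.add(b)
                break
        cdr3a_of_clone[clone] = _cdr3(rng, "CAV")
        cdr3b_of_clone[clone] = b
    chains = []
    for cell, clone in zip(cell_rows, cell_clones):
        chains.append(ChainRecord(cell, "TRA", cdr3a_of_clone[clone], v_gene="TRAV1-1", j_gene="TRAJ1", umis=3))
        chains.append(ChainRecord(cell, "TRB", cdr3b_of_clone[clone], v_gene="TRBV2", j_gene="TRBJ1-1", umis=5))
    ct = ClonotypeTable(
        chains=chains,
        clone_of_cell=dict(zip(cell_rows, cell_clones)),
        clone_key_mode="paired_cdr3",
    )

    labels = LabelTable(
        label_of_clone={c: ("TRT" if c in trt_clones else "nonTRT") for c in clone_ids},
        provenance_of_clone={
            c: ("experimental" if c in trt_clones else ("pbmc" if c in pbmc_clones else "experimental"))
            for c in clone_ids
        },
    )

    truth = {
        "spec": asdict(spec),
        "up_genes": [genes[i] for i in sorted(up_idx)],
        "down_genes": [genes[i] for i in sorted(down_idx)],
        "trt_clones": sorted(trt_clones),
        "pbmc_clones": sorted(pbmc_clones),
        "clone_sizes": {c: int(s) for c, s in zip(clone_ids, sizes)},
    }
    return SimulatedDataset(counts=m, clonotypes=ct, labels=labels, truth=truth)


def planted_signature(
    spec_or_truth: SimSpec | Mapping,
    scoring_method: str = "rank_mean",
    clone_aggregation: str = "mean",
    threshold_criterion: str = "youden",
) -> Signature:
    """Ground-truth up/down gene sets as a benchmark signature."""
    if isinstance(spec_or_truth, SimSpec):
        truth = simulate_dataset(spec_or_truth).truth
    else:
        truth = spec_or_truth
    return Signature(
        name="planted",
        up_genes=list(truth["up_genes"]),
        down_genes=list(truth["down_genes"]),
        scoring_method=scoring_method,
        clone_aggregation=clone_aggregation,
        threshold_criterion=threshold_criterion,
    )


# ---------------------------------------------------------------------------
# on-disk round trip (exercises the real readers)
# ---------------------------------------------------------------------------

def write_dataset(ds: SimulatedDataset, dirpath: str | Path) -> None:
    """Write MTX directory + 10x contig CSV + label TSV + manifests."""
    from . import ingest

    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    ingest.write_counts_mtx(ds.counts, dirpath / "counts")
    ingest.write_clonotypes_tenx(ds.clonotypes.chains, dirpath / "filtered_contig_annotations.csv")
    ingest.write_labels(ds.labels, dirpath / "labels.tsv")
    samples = pd.DataFrame(
        {
            "barcode": ds.counts.unit_ids,
            "sample": [ds.counts.sample_of_unit[c] for c in ds.counts.unit_ids],
        }
    )
    samples.to_csv(dirpath / "samples.tsv", sep="\t", index=False)
    # clone id <-> paired CDR3 key, so labels stay joinable after re-reading
    trb = {c.cell_id: c.cdr3_aa for c in ds.clonotypes.chains if c.locus == "TRB"}
    tra = {c.cell_id: c.cdr3_aa for c in ds.clonotypes.chains if c.locus == "TRA"}
    rows = {}
    for cell, clone in ds.clonotypes.clone_of_cell.items():
        rows[clone] = {"clone_id": clone, "cdr3a": tra[cell], "cdr3b": trb[cell]}
    pd.DataFrame(sorted(rows.values(), key=lambda r: r["clone_id"])).to_csv(
        dirpath / "clones.tsv", sep="\t", index=False
    )
    (dirpath / "truth.yaml").write_text(yaml.safe_dump(ds.truth, sort_keys=True))


def read_dataset(dirpath: str | Path) -> SimulatedDataset:
    from . import ingest

    dirpath = Path(dirpath)
    samples = pd.read_csv(dirpath / "samples.tsv", sep="\t")
    sample_of_unit = dict(zip(samples["barcode"].astype(str), samples["sample"].astype(str)))
    m = ingest.read_counts(dirpath / "counts", format="mtx_dir", sample_of_unit=sample_of_unit)
    chains = ingest.read_clonotypes(dirpath / "filtered_contig_annotations.csv", format="tenx")
    ct = ingest.assign_clones(ingest.enforce_single_chains(chains), mode="paired_cdr3")
    clones = pd.read_csv(dirpath / "clones.tsv", sep="\t")
    rename = {f"{r.cdr3a}_{r.cdr3b}": str(r.clone_id) for r in clones.itertuples()}
    ct.clone_of_cell = {c: rename.get(k, k) for c, k in ct.clone_of_cell.items()}
    labels = ingest.read_labels(dirpath / "labels.tsv")
    truth = yaml.safe_load((dirpath / "truth.yaml").read_text())
    return SimulatedDataset(counts=m, clonotypes=ct, labels=labels, truth=truth)
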