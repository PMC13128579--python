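"""Readers, QC filters, chain enforcement and clone labeling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tracetcr import ingest
from tracetcr._types import ChainRecord, ValidationError
from tests.conftest import make_counts


# ---------------------------------------------------------------------------
# count readers
# ---------------------------------------------------------------------------

class TestReadCounts:
    def test_csv_identity_roundtrip(self, tmp_path):
        m = make_counts([[1, 0, 2, 3], [0, 0, 1, 5], [4, 2, 0, 0]])
        path = tmp_path / "counts.csv"
        ingest.write_counts_csv(m, path)
        back = ingest.read_counts(path, format="csv")
        assert back.unit_ids == m.unit_ids
        assert back.gene_ids == m.gene_ids
        np.testing.assert_array_equal(back.counts, m.counts)

    def test_mtx_matches_csv(self, tmp_path):
        m = make_counts([[1, 0, 2, 3], [0, 0, 1, 5], [4, 2, 0, 0]])
        ingest.write_counts_csv(m, tmp_path / "c.csv")
        ingest.write_counts_mtx(m, tmp_path / "mtx")
        a = ingest.read_counts(tmp_path / "c.csv", format="csv")
        b = ingest.read_counts(tmp_path / "mtx", format="mtx_dir")
        np.testing.assert_array_equal(a.counts, b.counts)
        assert a.gene_ids == b.gene_ids and a.unit_ids == b.unit_ids

    def test_h5_roundtrip(self, tmp_path):
        import h5py

        m = make_counts([[3, 1], [0, 7]])
        with h5py.File(tmp_path / "c.h5", "w") as f:
            f["/counts"] = m.counts
            f["/genes"] = np.array(m.gene_ids, dtype="S")
            f["/barcodes"] = np.array(m.unit_ids, dtype="S")
        back = ingest.read_counts(tmp_path / "c.h5", format="h5")
        np.testing.assert_array_equal(back.counts, m.counts)
        assert back.gene_ids == m.gene_ids

    def test_non_integer_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("barcode,G1,G2\nc1,1,2.5\n")
        with pytest.raises(ValidationError, match="non-integer"):
            ingest.read_counts(tmp_path / "bad.csv", format="csv")

    def test_duplicate_genes_suffixed(self, tmp_path):
        (tmp_path / "dup.csv").write_text("barcode,G1,G1,G1\nc1,1,2,3\n")
        m = ingest.read_counts(tmp_path / "dup.csv", format="csv")
        assert m.gene_ids == ["G1", "G1.1", "G1.2"]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestQC:
    def _matrix(self):
        # 300 genes; cell0 has 199 detected, cell1 has 250 with clean mito,
        # cell2 has 250 detected but 30% mito, cell3 exactly 25% mito
        genes = [f"G{i}" for i in range(298)] + ["MT-1", "MT-2"]
        counts = np.zeros((4, 300), dtype=int)
        counts[0, :199] = 1
        counts[1, :250] = 1
        counts[2, :249] = 1
        counts[2, 298] = 107  # 107/356 ~ 0.30
        counts[3, :249] = 3
        counts[3, 298] = 249  # 249/996 = 0.25 exactly
        return make_counts(counts, genes=genes)

    def test_thresholds_inclusive_on_keep_side(self):
        kept = ingest.qc_filter_cells(self._matrix())
        assert kept.unit_ids == ["cell1", "cell3"]

    def test_zero_mito_high_genes_kept(self):
        counts = np.ones((1, 500), dtype=int)
        m = make_counts(counts, genes=[f"G{i}" for i in range(500)])
        assert ingest.qc_filter_cells(m).n_cells == 1

    def test_all_removed_raises(self):
        m = make_counts(np.ones((2, 5), dtype=int))
        with pytest.raises(ValidationError, match="threshold"):
            ingest.qc_filter_cells(m, min_genes=200)

    def test_idempotent_and_never_grows(self):
        m = self._matrix()
        once = ingest.qc_filter_cells(m)
        twice = ingest.qc_filter_cells(once)
        assert twice.unit_ids == once.unit_ids
        assert once.n_cells <= m.n_cells


class TestCD8Filter:
    def test_marker_ratio(self):
        counts = np.array([[5, 0, 0], [0, 0, 3], [2, 0, 2], [1, 1, 1]])
        m = make_counts(counts, genes=["CD8A", "CD8B", "CD4"])
        kept = ingest.filter_cd8(m)
        # strict inequality: summed CD8 must exceed CD4
        assert kept.unit_ids == ["cell0", "cell3"]

    def test_missing_marker_raises(self):
        m = make_counts([[1, 2]], genes=["CD8A", "CD4"])
        with pytest.raises(ValidationError, match="CD8B"):
            ingest.filter_cd8(m)


# ---------------------------------------------------------------------------
# chains and clones
# ---------------------------------------------------------------------------

def chain(cell, locus, cdr3, umis=1, productive=True):
    return ChainRecord(cell_id=cell, locus=locus, cdr3_aa=cdr3, umis=umis, productive=productive)


class TestEnforceSingleChains:
    def test_max_umi_wins(self):
        out = ingest.enforce_single_chains(
            [chain("c1", "TRB", "CASSX", 10), chain("c1", "TRB", "CASSY", 3)]
        )
        assert [c.cdr3_aa for c in out] == ["CASSX"]

    def test_tie_breaks_lexicographically(self):
        out = ingest.enforce_single_chains(
            [chain("c1", "TRB", "CASSB", 5), chain("c1", "TRB", "CASSA", 5)]
        )
        assert [c.cdr3_aa for c in out] == ["CASSA"]

    def test_paired_cell_unchanged(self):
        chains = [chain("c1", "TRA", "CAVX"), chain("c1", "TRB", "CASSX")]
        assert ingest.enforce_single_chains(chains) == chains

    def test_nonproductive_dropped(self):
        out = ingest.enforce_single_chains(
            [ChainRecord("c1", "TRB", "", umis=9, productive=False)]
        )
        assert out == []

    @given(st.lists(
        st.tuples(
            st.sampled_from(["c1", "c2", "c3"]),
            st.sampled_from(["TRA", "TRB"]),
            st.text(alphabet="ACDEF", min_size=1, max_size=6),
            st.integers(0, 20),
        ),
        max_size=30,
    ))
    def test_at_most_one_chain_per_cell_locus(self, raw):
        chains = [chain(c, l, s, u) for c, l, s, u in raw]
        out = ingest.enforce_single_chains(chains)
        keys = [(c.cell_id, c.locus) for c in out]
        assert len(keys) == len(set(keys))


class TestAssignClones:
    def test_shared_pair_same_clone(self):
        chains = [
            chain("c1", "TRA", "CAVX"), chain("c1", "TRB", "CASSX"),
            chain("c2", "TRA", "CAVX"), chain("c2", "TRB", "CASSX"),
        ]
        ct = ingest.assign_clones(chains, mode="paired_cdr3")
        assert ct.clone_of_cell["c1"] == ct.clone_of_cell["c2"]

    def test_paired_mode_requires_both_chains(self):
        ct = ingest.assign_clones([chain("c1", "TRB", "CASSX")], mode="paired_cdr3")
        assert "c1" not in ct.clone_of_cell

    def test_cdr3b_only_ignores_alpha(self):
        chains = [
            chain("c1", "TRA", "CAVX"), chain("c1", "TRB", "CASSX"),
            chain("c2", "TRA", "CAVY"), chain("c2", "TRB", "CASSX"),
        ]
        ct = ingest.assign_clones(chains, mode="cdr3b_only")
        assert ct.clone_of_cell["c1"] == ct.clone_of_cell["c2"]

    @given(st.permutations(list(range(8))))
    def test_permutation_invariant(self, perm):
        base = [
            chain("c1", "TRA", "CAVX", 2), chain("c1", "TRB", "CASSX", 3),
            chain("c2", "TRA", "CAVX", 1), chain("c2", "TRB", "CASSX", 4),
            chain("c3", "TRA", "CAVZ", 2), chain("c3", "TRB", "CASSZ", 1),
            chain("c3", "TRB", "CASSW", 1), chain("c4", "TRB", "CASSX", 2),
        ]
        shuffled = [base[i] for i in perm]
        ref = ingest.assign_clones(ingest.enforce_single_chains(base)).clone_of_cell
        got = ingest.assign_clones(ingest.enforce_single_chains(shuffled)).clone_of_cell
        assert got == ref


class TestVdjExpressionClones:
    def test_argmax_pair(self):
        m = make_counts([[5, 2, 7]], genes=["TRAV1", "TRAV2", "TRBV1"])
        ct = ingest.infer_clones_from_vdj_expression(m, ["TRAV1", "TRAV2"], ["TRBV1"])
        assert ct.clone_of_cell["cell0"] == "TRAV1_TRBV1"

    def test_tie_takes_first_in_list(self):
        m = make_counts([[3, 3, 1]], genes=["TRAV1", "TRAV2", "TRBV1"])
        ct = ingest.infer_clones_from_vdj_expression(m, ["TRAV1", "TRAV2"], ["TRBV1"])
        assert ct.clone_of_cell["cell0"] == "TRAV1_TRBV1"
        ct2 = ingest.infer_clones_from_vdj_expression(m, ["TRAV2", "TRAV1"], ["TRBV1"])
        assert ct2.clone_of_cell["cell0"] == "TRAV2_TRBV1"

    def test_zero_counts_unassigned(self):
        m = make_counts([[2, 0]], genes=["TRAV1", "TRBV1"])
        ct = ingest.infer_clones_from_vdj_expression(m, ["TRAV1"], ["TRBV1"])
        assert ct.clone_of_cell == {}

    def test_empty_lists_rejected(self):
        m = make_counts([[1]], genes=["TRAV1"])
        with pytest.raises(ValidationError):
            ingest.infer_clones_from_vdj_expression(m, [], ["TRBV1"])


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

class TestMatchVdjdb:
    def _clonotypes(self):
        chains = [
            chain("c1", "TRB", "CASSKNOWN"), chain("c2", "TRB", "CASSNOVEL"),
        ]
        return ingest.assign_clones(chains, mode="cdr3b_only")

    def test_known_cdr3b_labeled_nontrt(self):
        ref = pd.DataFrame({"cdr3b": ["CASSKNOWN"], "antigen": ["ELAGIGILTV"]})
        labels = ingest.match_vdjdb(self._clonotypes(), ref)
        assert labels.label_of_clone["CASSKNOWN"] == "nonTRT"
        assert labels.provenance_of_clone["CASSKNOWN"] == "vdjdb"
        assert labels.label_of_clone["CASSNOVEL"] == "unknown"

    def test_empty_reference_all_unknown(self):
        ref = pd.DataFrame({"cdr3b": []})
        labels = ingest.match_vdjdb(self._clonotypes(), ref)
        assert set(labels.label_of_clone.values()) == {"unknown"}


class TestExptTrtLabels:
    @pytest.mark.parametrize(
        "reps, expected",
        [
            ([(20, 1)], "TRT"),          # exactly 1 cell and 5%
            ([(30, 1), (30, 1)], "nonTRT"),  # 3.3% everywhere
            ([(10, 0), (40, 0)], "nonTRT"),
            ([(100, 4), (20, 2)], "TRT"),    # second replicate qualifies
        ],
    )
    def test_activation_rule(self, reps, expected):
        labels = ingest.label_expt_trt({"cl": reps})
        assert labels.label_of_clone["cl"] == expected
        assert labels.provenance_of_clone["cl"] == "expt_coculture"

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValidationError):
            ingest.label_expt_trt({"cl": [(5, 6)]})


# ---------------------------------------------------------------------------
# clonotype table readers
# ---------------------------------------------------------------------------

class TestClonotypeReaders:
    def test_tenx_and_airr_agree(self, tmp_path):
        chains = [
            chain("c1", "TRA", "CAVX", 2), chain("c1", "TRB", "CASSX", 4),
        ]
        ingest.write_clonotypes_tenx(chains, tmp_path / "contigs.csv")
        airr = pd.DataFrame(
            {
                "cell_id": ["c1", "c1"],
                "locus": ["TRA", "TRB"],
                "junction_aa": ["CAVX", "CASSX"],
                "v_call": ["TRAV1", "TRBV2"],
                "j_call": ["TRAJ1", "TRBJ1"],
                "duplicate_count": [2, 4],
                "productive": ["T", "T"],
            }
        )
        airr.to_csv(tmp_path / "airr.tsv", sep="\t", index=False)
        a = ingest.read_clonotypes(tmp_path / "contigs.csv")
        b = ingest.read_clonotypes(tmp_path / "airr.tsv")
        assert [(c.cell_id, c.locus, c.cdr3_aa, c.umis) for c in a] == [
            (c.cell_id, c.locus, c.cdr3_aa, c.umis) for c in b
        ]

    def test_missing_columns_named(self, tmp_path):
        (tmp_path / "bad.csv").write_text("barcode,chain\nc1,TRB\n")
        with pytest.raises(ValidationError, match="cdr3"):
            ingest.read_clonotypes(tmp_path / "bad.csv", format="tenx")


class TestCorpusManifest:
    def test_totals_computed_from_rows(self):
        df = pd.DataFrame(
            {
                "dataset": ["a", "a", "b"],
                "category": ["trt", "nontrt_pbmc", "trt"],
                "n_clones": [3, 10, 4],
                "n_cells": [30, 11, 44],
            }
        )
        totals = ingest.CorpusManifest(df).totals()
        assert totals["trt_clones"] == 7 and totals["trt_cells"] == 74
        assert totals["total_clones"] == 17 and totals["total_cells"] == 85

    def test_unknown_category_rejected(self):
        df = pd.DataFrame(
            {"dataset": ["a"], "category": ["bogus"], "n_clones": [1], "n_cells": [1]}
        )
        with pytest.raises(ValidationError):
            ingest.CorpusManifest(df)
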