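import numpy as np
import pandas as pd
import pytest

from pairsplice import (GeneSetCollection, StudyDesign, TranscriptCountMatrix,
                        filter_low_expression, load_counts, read_gmt, write_gmt)


def _write_inputs(tmp_path, counts: pd.DataFrame, t2g: dict, meta: pd.DataFrame,
                  fmt: str = "tsv"):
    t2g_path = tmp_path / "t2g.tsv"
    pd.DataFrame(list(t2g.items())).to_csv(t2g_path, sep="\t", index=False, header=False)
    meta_path = tmp_path / "meta.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    if fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        counts_path = tmp_path / "counts.mtx"
        mmwrite(str(counts_path), csr_matrix(counts.to_numpy()))
        (tmp_path / "counts.rownames.txt").write_text("\n".join(counts.index) + "\n")
        (tmp_path / "counts.colnames.txt").write_text("\n".join(counts.columns) + "\n")
    else:
        sep = "," if fmt == "csv" else "\t"
        counts_path = tmp_path / f"counts.{fmt}"
        counts.to_csv(counts_path, sep=sep)
    return counts_path, t2g_path, meta_path


@pytest.fixture
def demo_tables():
    counts = pd.DataFrame(
        [[10, 12, 30, 28], [20, 22, 18, 21], [5, 7, 6, 4]],
        index=["tA1", "tA2", "tB1"],
        columns=["s1", "s2", "s3", "s4"],
    )
    t2g = {"tA1": "geneA", "tA2": "geneA", "tB1": "geneB"}
    meta = pd.DataFrame({"sample_id": ["s1", "s2", "s3", "s4"],
                         "condition": ["ctrl", "ctrl", "treat", "treat"]})
    return counts, t2g, meta


@pytest.mark.parametrize("fmt", ["tsv", "csv", "mtx"])
def test_load_counts_round_trip_across_formats(tmp_path, demo_tables, fmt):
    """The same data in TSV, CSV or MTX yields the identical count matrix."""
    counts, t2g, meta = demo_tables
    paths = _write_inputs(tmp_path, counts, t2g, meta, fmt=fmt)
    tcm, design = load_counts(*paths)
    assert tcm.counts.shape == (3, 4)
    np.testing.assert_array_equal(tcm.counts, counts.to_numpy())
    assert tcm.transcript_ids == ("tA1", "tA2", "tB1")
    assert tcm.sample_ids == ("s1", "s2", "s3", "s4")
    assert design.baseline == "ctrl" and design.case == "treat"


def test_load_counts_drops_unmapped_transcript_with_warning(tmp_path, demo_tables):
    counts, t2g, meta = demo_tables
    t2g = {k: v for k, v in t2g.items() if k != "tB1"}
    paths = _write_inputs(tmp_path, counts, t2g, meta)
    with pytest.warns(UserWarning, match="tB1"):
        tcm, _ = load_counts(*paths)
    assert tcm.counts.shape == (2, 4)


def test_load_counts_missing_sample_names_the_sample(tmp_path, demo_tables):
    counts, t2g, meta = demo_tables
    meta = pd.concat([meta, pd.DataFrame({"sample_id": ["s9"], "condition": ["treat"]})])
    paths = _write_inputs(tmp_path, counts, t2g, meta)
    with pytest.raises(ValueError, match="s9"):
        load_counts(*paths)


def test_load_counts_negative_count_locates_cell(tmp_path, demo_tables):
    counts, t2g, meta = demo_tables
    counts.loc["tA2", "s3"] = -1
    paths = _write_inputs(tmp_path, counts, t2g, meta)
    with pytest.raises(ValueError, match="tA2.*s3"):
        load_counts(*paths)


def test_load_counts_rounds_fractional_counts_with_warning(tmp_path, demo_tables):
    counts, t2g, meta = demo_tables
    counts = counts.astype(float)
    counts.loc["tA1", "s1"] = 10.4
    paths = _write_inputs(tmp_path, counts, t2g, meta)
    with pytest.warns(UserWarning, match="rounded"):
        tcm, _ = load_counts(*paths)
    assert tcm.counts[0, 0] == 10


def test_load_counts_canonicalizes_sample_order(tmp_path, demo_tables):
    counts, t2g, meta = demo_tables
    meta = meta.iloc[[2, 3, 0, 1]].reset_index(drop=True)
    paths = _write_inputs(tmp_path, counts, t2g, meta)
    tcm, design = load_counts(*paths)
    assert tcm.sample_ids == ("s3", "s4", "s1", "s2")
    np.testing.assert_array_equal(tcm.counts[:, 2], counts["s1"].to_numpy())
    assert design.baseline == "treat"  # first level in metadata order


class TestTranscriptCountMatrix:
    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            TranscriptCountMatrix(np.ones((2, 2)), ("t1", "t1"), ("a", "b"),
                                  {"t1": "g"})

    def test_rejects_non_integer_counts(self):
        with pytest.raises(ValueError, match="non-integer or negative"):
            TranscriptCountMatrix(np.array([[1.5, 2], [0, 1]]), ("t1", "t2"),
                                  ("a", "b"), {"t1": "g", "t2": "g"})

    def test_multi_isoform_genes_recomputed_after_filtering(self, tiny_tcm):
        assert tiny_tcm.multi_isoform_genes() == {"geneA"}
        # drop one geneA transcript via filtering: geneA is no longer multi
        # (means: tA1 = 20, tA2 = 20.25, tB1 = 5.5)
        filtered = filter_low_expression(tiny_tcm, min_mean=20.1)
        assert filtered.multi_isoform_genes() == set()


class TestStudyDesign:
    def test_requires_exactly_two_levels(self):
        with pytest.raises(ValueError, match="two levels"):
            StudyDesign(("a", "b", "c", "d"), ("x", "y", "z", "x"), "x", "y")

    def test_requires_two_samples_per_level(self):
        with pytest.raises(ValueError, match="< 2 samples"):
            StudyDesign(("a", "b", "c"), ("x", "x", "y"), "x", "y")

    def test_design_matrix_layout(self, design_2x2):
        X = design_2x2.design_matrix()
        assert list(X.columns) == ["intercept", "condition[treat]"]
        np.testing.assert_array_equal(X["condition[treat]"], [0, 0, 1, 1])


class TestFilterLowExpression:
    def test_all_zero_transcript_removed(self):
        tcm = TranscriptCountMatrix(
            np.array([[0, 0, 0, 0], [20, 20, 20, 20]]), ("t0", "t1"),
            ("a", "b", "c", "d"), {"t0": "g0", "t1": "g1"})
        out = filter_low_expression(tcm, min_mean=10)
        assert out.transcript_ids == ("t1",)

    def test_boundary_mean_is_kept(self):
        tcm = TranscriptCountMatrix(
            np.array([[10, 10, 10, 10]]), ("t0",), ("a", "b", "c", "d"), {"t0": "g"})
        assert filter_low_expression(tcm, min_mean=10).transcript_ids == ("t0",)

    def test_matches_brute_force_row_check(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(9, size=(60, 5))
        ids = tuple(f"t{i}" for i in range(60))
        tcm = TranscriptCountMatrix(counts, ids, tuple("abcde"),
                                    {t: f"g{i // 2}" for i, t in enumerate(ids)})
        out = filter_low_expression(tcm, min_mean=9)
        expected = [ids[i] for i in range(60) if sum(counts[i]) / 5 >= 9]
        assert list(out.transcript_ids) == expected

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(12, size=(40, 4))
        ids = tuple(f"t{i}" for i in range(40))
        gene_of = {t: f"g{i // 2}" for i, t in enumerate(ids)}
        tcm = TranscriptCountMatrix(counts, ids, tuple("abcd"), gene_of)
        once = filter_low_expression(tcm, min_mean=12)
        twice = filter_low_expression(once, min_mean=12)
        assert once.transcript_ids == twice.transcript_ids
        perm = rng.permutation(40)
        tcm_p = TranscriptCountMatrix(counts[perm], tuple(ids[i] for i in perm),
                                      tuple("abcd"), gene_of)
        out_p = filter_low_expression(tcm_p, min_mean=12)
        assert set(out_p.transcript_ids) == set(once.transcript_ids)

    def test_empty_result_advises_lower_threshold(self, tiny_tcm):
        with pytest.raises(ValueError, match="lower the threshold"):
            filter_low_expression(tiny_tcm, min_mean=1e6)


class TestGmt:
    def test_read_sizes_and_description(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\tdescA\tg1\tg2\tg3\n"
                     "setB\tdescB\tg1\tg4\tg5\tg6\tg7\n")
        coll = read_gmt(p)
        assert len(coll) == 2
        assert len(coll.sets["setA"]) == 3
        assert len(coll.sets["setB"]) == 5
        assert coll.descriptions["setA"] == "descA"

    def test_duplicate_gene_counted_once(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\td\tg1\tg2\tg1\n")
        assert len(read_gmt(p).sets["setA"]) == 2

    def test_short_line_reports_line_number(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\td\tg1\nbad_line\tonly_two_fields\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(p)

    def test_write_read_round_trip_byte_identical(self, tmp_path):
        p1 = tmp_path / "a.gmt"
        p1.write_text("setA\tdescA\tg1\tg2\nsetB\tdescB\tg3\n")
        coll = read_gmt(p1)
        p2 = tmp_path / "b.gmt"
        write_gmt(coll, p2)
        assert p1.read_text() == p2.read_text()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSetCollection(sets={"s": ()})
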