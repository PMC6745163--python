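import numpy as np
import pandas as pd
import pytest

from tscoex import (
    CoexpressionEdge,
    ParseError,
    TissueNetwork,
    TissueRegistry,
    ValidationError,
    filter_pseudogenes,
    load_paper_table,
    load_selection_counts,
    read_edge_list,
    read_expression_matrix,
    write_edge_list,
    write_graphml,
)
from tscoex.expression_io import EM_DASH, read_annotation, read_sample_map

from conftest import make_matrix

EXPR_TSV = (
    "rna_id\ts1\ts2\ts3\ts4\n"
    "g1\t1.0\t2.0\t3.0\t4.0\n"
    "g2\t0.0\t0.0\t5.5\t0.0\n"
    "g3\t7.0\t7.0\t7.0\t7.0\n"
)
SAMPLES_TSV = "sample_id\ttissue\ns1\tliver\ns2\tliver\ns3\tbrain\ns4\tbrain\n"
ANNOT_TSV = (
    "rna_id\tbiotype\tis_pseudogene\n"
    "g1\tmiRNA\tfalse\n"
    "g2\tlncRNA\tfalse\n"
    "g3\tmRNA\ttrue\n"
)


@pytest.fixture
def io_files(tmp_path):
    (tmp_path / "expr.tsv").write_text(EXPR_TSV)
    (tmp_path / "samples.tsv").write_text(SAMPLES_TSV)
    (tmp_path / "annot.tsv").write_text(ANNOT_TSV)
    return tmp_path


class TestReadExpressionMatrix:
    def test_tsv_readback(self, io_files):
        m = read_expression_matrix(
            io_files / "expr.tsv",
            sample_map=io_files / "samples.tsv",
            annotation=io_files / "annot.tsv",
        )
        assert m.n_rnas == 3
        assert m.n_samples == 4
        assert m.tissues == ["liver", "brain"]
        assert m.values.loc["g2", "s3"] == 5.5
        assert m.biotype["g1"] == "miRNA"
        assert bool(m.is_pseudogene["g3"])

    def test_negative_value_rejected(self, io_files):
        (io_files / "bad.tsv").write_text(EXPR_TSV.replace("5.5", "-1.0"))
        with pytest.raises(ValidationError, match="negative.*g2.*s3"):
            read_expression_matrix(
                io_files / "bad.tsv",
                sample_map=io_files / "samples.tsv",
                annotation=io_files / "annot.tsv",
            )

    def test_gct_equals_tsv(self, io_files):
        body = EXPR_TSV.replace("rna_id", "Name\tDescription").replace(
            "g1\t", "g1\tna\t"
        ).replace("g2\t", "g2\tna\t").replace("g3\t", "g3\tna\t")
        (io_files / "expr.gct").write_text("#1.2\n3\t4\n" + body)
        via_tsv = read_expression_matrix(
            io_files / "expr.tsv",
            sample_map=io_files / "samples.tsv",
            annotation=io_files / "annot.tsv",
        )
        via_gct = read_expression_matrix(
            io_files / "expr.gct",
            format="gct",
            sample_map=io_files / "samples.tsv",
            annotation=io_files / "annot.tsv",
        )
        pd.testing.assert_frame_equal(via_tsv.values, via_gct.values)
        pd.testing.assert_series_equal(via_tsv.biotype, via_gct.biotype)

    def test_gct_bad_version_line(self, io_files):
        (io_files / "bad.gct").write_text("#9.9\n3\t4\nName\ts1\ng1\t1\n")
        with pytest.raises(ParseError, match="version"):
            read_expression_matrix(
                io_files / "bad.gct",
                format="gct",
                sample_map=io_files / "samples.tsv",
                annotation=io_files / "annot.tsv",
            )

    def test_gct_dimension_mismatch(self, io_files):
        body = "Name\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\n"
        (io_files / "bad.gct").write_text("#1.2\n3\t4\n" + body)
        with pytest.raises(ParseError, match="dimensions"):
            read_expression_matrix(
                io_files / "bad.gct",
                format="gct",
                sample_map=io_files / "samples.tsv",
                annotation=io_files / "annot.tsv",
            )

    def test_sample_without_tissue(self, io_files):
        (io_files / "short_map.tsv").write_text(
            "sample_id\ttissue\ns1\tliver\ns2\tliver\ns3\tbrain\n"
        )
        with pytest.raises(ValidationError, match="no tissue"):
            read_expression_matrix(
                io_files / "expr.tsv",
                sample_map=io_files / "short_map.tsv",
                annotation=io_files / "annot.tsv",
            )

    def test_missing_value_is_hard_error(self, io_files):
        (io_files / "gap.tsv").write_text(EXPR_TSV.replace("5.5", ""))
        with pytest.raises(ValidationError, match="missing"):
            read_expression_matrix(
                io_files / "gap.tsv",
                sample_map=io_files / "samples.tsv",
                annotation=io_files / "annot.tsv",
            )

    def test_missing_value_zero_coercion(self, io_files):
        (io_files / "gap.tsv").write_text(EXPR_TSV.replace("5.5", ""))
        m = read_expression_matrix(
            io_files / "gap.tsv",
            sample_map=io_files / "samples.tsv",
            annotation=io_files / "annot.tsv",
            missing="zero",
        )
        assert m.values.loc["g2", "s3"] == 0.0

    def test_unknown_biotype_routes(self, io_files):
        (io_files / "annot2.tsv").write_text(
            ANNOT_TSV.replace("g2\tlncRNA", "g2\tsnoRNA")
        )
        with pytest.raises(ValidationError, match="biotype"):
            read_expression_matrix(
                io_files / "expr.tsv",
                sample_map=io_files / "samples.tsv",
                annotation=io_files / "annot2.tsv",
            )
        m = read_expression_matrix(
            io_files / "expr.tsv",
            sample_map=io_files / "samples.tsv",
            annotation=io_files / "annot2.tsv",
            unknown_biotype="drop",
        )
        assert m.rna_ids == ["g1", "g3"]


class TestMatrixInvariants:
    def test_duplicate_rna_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate RNA"):
            make_matrix(
                values=pd.DataFrame(
                    [[1.0, 1.0], [2.0, 2.0]], index=["a", "a"], columns=["s1", "s2"]
                ),
                biotype={"a": "mRNA"},
                tissue_of_sample={"s1": "t1", "s2": "t2"},
            )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError, match="non-finite"):
            make_matrix(
                values={"a": [1.0, np.inf]},
                biotype={"a": "mRNA"},
                tissue_of_sample={"s1": "t1", "s2": "t2"},
            )

    def test_registry_tally_check(self, tiny_matrix):
        reg = TissueRegistry.from_matrix(tiny_matrix)
        assert reg.names == ("tissueA", "tissueB")
        assert reg.sample_counts["tissueA"] == 2
        reg.validate_against(tiny_matrix)
        bad = TissueRegistry(names=("tissueA", "tissueB"), sample_counts={"tissueA": 3, "tissueB": 2})
        with pytest.raises(ValidationError):
            bad.validate_against(tiny_matrix)

    def test_registry_needs_two_tissues(self):
        with pytest.raises(ValidationError):
            TissueRegistry(names=("only",), sample_counts={"only": 1})


class TestFilterPseudogenes:
    def _matrix(self, flags):
        rnas = list(flags)
        return make_matrix(
            values={r: [float(i), float(i + 1)] for i, r in enumerate(rnas)},
            biotype={r: "mRNA" for r in rnas},
            tissue_of_sample={"s1": "t1", "s2": "t2"},
            is_pseudogene=flags,
        )

    def test_removes_flagged(self):
        m = self._matrix({"a": True, "b": False, "c": True, "d": False, "e": False})
        out = filter_pseudogenes(m)
        assert out.rna_ids == ["b", "d", "e"]
        assert m.n_rnas == 5  # input untouched

    def test_zero_flagged_is_identity(self, tiny_matrix):
        out = filter_pseudogenes(tiny_matrix)
        pd.testing.assert_frame_equal(out.values, tiny_matrix.values)

    def test_all_flagged_warns(self, caplog):
        m = self._matrix({"a": True, "b": True})
        with caplog.at_level("WARNING"):
            out = filter_pseudogenes(m)
        assert out.n_rnas == 0
        assert any("all RNAs" in r.message for r in caplog.records)

    def test_surviving_values_unchanged(self):
        m = self._matrix({"a": True, "b": False})
        out = filter_pseudogenes(m)
        assert out.values.loc["b"].tolist() == m.values.loc["b"].tolist()

    def test_mrna_only_scope(self):
        m = make_matrix(
            values={"mi": [1.0, 1.0], "mr": [2.0, 2.0]},
            biotype={"mi": "miRNA", "mr": "mRNA"},
            tissue_of_sample={"s1": "t1", "s2": "t2"},
            is_pseudogene={"mi": True, "mr": True},
        )
        assert filter_pseudogenes(m, only_mrna=True).rna_ids == ["mi"]
        assert filter_pseudogenes(m).rna_ids == []


class TestPaperTables:
    def test_t1_rows(self):
        t1 = load_paper_table("T1")
        assert len(t1.rows) == 30
        assert t1.cell("Testis") == 172
        assert t1.printed_total == 8553

    def test_t3_esophagus(self):
        assert load_paper_table("T3").cell("Esophagus") == 1

    def test_t5_dashes_are_absent_not_zero(self):
        t5 = load_paper_table("T5")
        for tissue in ("Blood vessel", "Esophagus", "Uterus"):
            assert t5.cell(tissue) is None
        assert len(t5.numeric_cells()) == 27

    def test_unknown_table_id(self):
        with pytest.raises(KeyError):
            load_paper_table("T9")

    def test_selection_counts(self):
        sc = load_selection_counts()
        assert sc.loc["mRNA", "retained"] == 19028
        assert sc.loc["miRNA", "initial"] == 1368


def _edges(tissue="liver"):
    return [
        CoexpressionEdge(tissue, "miR-1", "GENE2", "miRNA", "mRNA", 0.912345678901234, 12),
        CoexpressionEdge(tissue, "miR-1", "LNC-9", "miRNA", "lncRNA", -0.75, 12),
        CoexpressionEdge(tissue, "LNC-9", "GENE2", "lncRNA", "mRNA", 1 / 3, 12),
    ]


class TestEdgeLists:
    def test_roundtrip_bit_for_bit(self, tmp_path):
        net = TissueNetwork("liver", tuple(_edges()), {"miRNA": 1, "lncRNA": 1, "mRNA": 1}, 12)
        path = tmp_path / "edges.tsv"
        write_edge_list(net, path)
        back = read_edge_list(path)
        assert set(back) == set(net.edges)  # dataclass equality incl. exact floats

    def test_counting_and_header(self, tmp_path):
        net = TissueNetwork("liver", tuple(_edges()), {}, 12)
        path = tmp_path / "edges.tsv"
        write_edge_list(net, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + 3
        assert lines[0].split("\t") == [
            "tissue", "rna_a", "biotype_a", "rna_b", "biotype_b", "pearson_r", "n_samples",
        ]

    def test_empty_network_header_only(self, tmp_path):
        path = tmp_path / "edges.tsv"
        write_edge_list(TissueNetwork("liver", (), {}, 5), path)
        assert path.read_text().splitlines() == [
            "tissue\trna_a\tbiotype_a\trna_b\tbiotype_b\tpearson_r\tn_samples"
        ]

    def test_canonical_ordering(self, tmp_path):
        path = tmp_path / "edges.tsv"
        write_edge_list(TissueNetwork("liver", tuple(_edges()), {}, 12), path)
        rows = [l.split("\t") for l in path.read_text().splitlines()[1:]]
        # miRNA endpoints come first; rows sorted by endpoint precedence
        assert [r[2] for r in rows] == ["miRNA", "miRNA", "lncRNA"]

    def test_graphml_export(self, tmp_path):
        import networkx as nx

        path = tmp_path / "net.graphml"
        write_graphml(TissueNetwork("liver", tuple(_edges()), {}, 12), path)
        g = nx.read_graphml(path)
        assert g.number_of_edges() == 3
        assert g.nodes["miR-1"]["biotype"] == "miRNA"

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("a\tb\n")
        with pytest.raises(ParseError):
            read_edge_list(path)
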