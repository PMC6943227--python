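"""Container validation and TSV round-trip fidelity."""

import numpy as np
import pandas as pd
import pytest

import fmt_engraft as fe
from fmt_engraft.io_formats import write_edges_tsv


def _abundance(values, taxa=None, samples=None):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"T{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return fe.AbundanceTable(pd.DataFrame(values, index=taxa, columns=samples))


class TestAbundanceTable:
    def test_roundtrip_identity(self, tmp_path):
        table = _abundance([[0.5, 0.2], [0.25, 0.3], [0.25, 0.5]])
        path = tmp_path / "ab.tsv"
        fe.write_abundance_table(table, path)
        again = fe.read_abundance_table(path)
        assert again == table

    def test_roundtrip_full_precision(self, tmp_path):
        vals = np.random.default_rng(1).dirichlet(np.ones(7), size=3).T
        table = _abundance(vals)
        fe.write_abundance_table(table, tmp_path / "ab.tsv")
        again = fe.read_abundance_table(tmp_path / "ab.tsv")
        assert np.array_equal(again.data.to_numpy(), table.data.to_numpy())

    def test_na_cell_is_parse_error_with_coordinates(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("taxon_id\tS1\nTA\t0.5\nTB\tNA\n")
        with pytest.raises(fe.ParseError, match="TB"):
            fe.read_abundance_table(path)

    def test_column_sum_above_one_rejected(self):
        with pytest.raises(fe.ValidationError, match="column sum"):
            _abundance([[0.6], [0.42]])

    def test_negative_value_rejected(self):
        with pytest.raises(fe.ValidationError, match="negative"):
            _abundance([[0.5], [-0.1]])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(fe.ValidationError, match="duplicate taxon"):
            _abundance([[0.4], [0.4]], taxa=["T", "T"])

    def test_columns_orientation(self, tmp_path):
        path = tmp_path / "wide.tsv"
        path.write_text("sample_id\tTA\tTB\nS1\t0.6\t0.4\nS2\t0.1\t0.9\n")
        table = fe.read_abundance_table(path, taxa_orientation="columns")
        assert table.taxon_ids == ["TA", "TB"]
        assert table.sample_ids == ["S1", "S2"]


class TestSNVTable:
    def _write(self, tmp_path, body):
        path = tmp_path / "snv.tsv"
        header = "species_id\tposition\tref_allele\talt_allele\tsA:cov\tsA:freq\tsB:cov\tsB:freq"
        path.write_text(header + "\n" + body)
        return path

    def test_read_counts_records(self, tmp_path):
        body = "\n".join(f"sp1\t{i}\tA\tG\t20\t0.1\t15\t0.9" for i in range(5)) + "\n"
        snv = fe.read_snv_table(self._write(tmp_path, body))
        assert len(snv.loci) == 5
        assert snv.sample_ids == ["sA", "sB"]

    def test_roundtrip(self, tmp_path, small_snv):
        snv, _ = small_snv
        path = tmp_path / "snv.tsv"
        fe.write_snv_table(snv, path)
        assert fe.read_snv_table(path) == snv

    def test_frequency_out_of_range_rejected(self, tmp_path):
        path = self._write(tmp_path, "sp1\t0\tA\tG\t20\t1.3\t15\t0.9\n")
        with pytest.raises(fe.ValidationError, match=r"\[0, 1\]"):
            fe.read_snv_table(path)

    def test_duplicate_position_rejected(self, tmp_path):
        body = "sp1\t0\tA\tG\t20\t0.1\t15\t0.9\nsp1\t0\tA\tC\t20\t0.2\t15\t0.8\n"
        with pytest.raises(fe.ValidationError, match="duplicate"):
            fe.read_snv_table(self._write(tmp_path, body))

    def test_zero_coverage_frequency_coerced_missing(self, tmp_path, caplog):
        path = self._write(tmp_path, "sp1\t0\tA\tG\t0\t0.5\t15\t0.9\n")
        with caplog.at_level("WARNING"):
            snv = fe.read_snv_table(path)
        assert np.isnan(snv.freq.iloc[0]["sA"])
        assert any("coercing" in r.message for r in caplog.records)


class TestManifest:
    def _df(self, rows):
        return pd.DataFrame(
            rows,
            columns=["sample_id", "subject_id", "role", "donor_id", "subtype", "arm", "day"],
        )

    def test_resolving_donor(self):
        mani = fe.CohortManifest(
            self._df(
                [
                    ("D1.don", "D1", "donor", "", "healthy", "none", 0),
                    ("CD-1.d0", "CD-1", "recipient", "D1", "CD", "allogenic", "baseline"),
                    ("CD-1.d3", "CD-1", "recipient", "D1", "CD", "allogenic", "day3"),
                ]
            )
        )
        pair = mani.pairs()[0]
        assert pair.donor_sample == "D1.don"
        assert pair.post_samples == {3: "CD-1.d3"}

    def test_dangling_donor_rejected(self):
        with pytest.raises(fe.ValidationError, match="unknown donor"):
            fe.CohortManifest(
                self._df([("CD-2.d0", "CD-2", "recipient", "DX", "CD", "allogenic", 0)])
            )

    def test_autologous_must_self_reference(self):
        with pytest.raises(fe.ValidationError, match="autologous"):
            fe.CohortManifest(
                self._df([("M-1.d0", "M-1", "recipient", "M-2", "metabolic", "autologous", 0)])
            )

    def test_duplicate_subject_timepoint_rejected(self):
        with pytest.raises(fe.ValidationError, match="duplicate"):
            fe.CohortManifest(
                self._df(
                    [
                        ("D1.don", "D1", "donor", "", "healthy", "none", 0),
                        ("a", "CD-1", "recipient", "D1", "CD", "allogenic", 3),
                        ("b", "CD-1", "recipient", "D1", "CD", "allogenic", "day3"),
                    ]
                )
            )

    def test_roundtrip(self, tmp_path, small_cohort):
        _, manifest, _ = small_cohort
        path = tmp_path / "manifest.tsv"
        fe.write_manifest(manifest, path)
        assert fe.read_manifest(path) == manifest


@pytest.mark.parametrize(
    "raw,expected",
    [("baseline", 0), ("day3", 3), ("day30", 30), ("d7", 7), (14, 14), ("84", 84)],
)
def test_parse_timepoint(raw, expected):
    assert fe.parse_timepoint(raw) == expected


def test_parse_timepoint_rejects_garbage():
    with pytest.raises(fe.ValidationError):
        fe.parse_timepoint("sometime")


class TestNetworkExport:
    def _graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_node("TA", kind="taxon")
        g.add_node("HBI", kind="clinical")
        g.add_edge("TA", "HBI", rho=-0.9, p=1e-5, q=1e-3, sign="negative", weight=0.9)
        return g

    def test_graphml_loads_back(self, tmp_path):
        import networkx as nx

        path = tmp_path / "net.graphml"
        fe.export_network(self._graph(), path, "graphml")
        g = nx.read_graphml(path)
        assert set(g.nodes) == {"TA", "HBI"}
        assert g.edges["TA", "HBI"]["rho"] == pytest.approx(-0.9)

    def test_sif_lines(self, tmp_path):
        path = tmp_path / "net.sif"
        fe.export_network(self._graph(), path, "sif")
        assert path.read_text().strip() == "TA\tnegative\tHBI"

    def test_empty_graph_valid(self, tmp_path):
        import networkx as nx

        path = tmp_path / "empty.graphml"
        fe.export_network(nx.Graph(), path, "graphml")
        assert len(nx.read_graphml(path)) == 0

    def test_unknown_format_is_usage_error(self, tmp_path):
        with pytest.raises(fe.ConfigError, match="unknown network format"):
            fe.export_network(self._graph(), tmp_path / "x", "dot")


def test_clinical_roundtrip(tmp_path):
    clin = fe.ClinicalTable(
        pd.DataFrame(
            {
                "subject_id": ["CD-1", "CD-1", "UC-1"],
                "day": [0, 3, 0],
                "index_name": ["HBI", "HBI", "Mayo"],
                "value": [9.0, 5.0, 7.5],
            }
        )
    )
    path = tmp_path / "clin.tsv"
    fe.write_clinical(clin, path)
    assert fe.read_clinical(path) == clin


def test_edges_tsv_written_empty(tmp_path):
    edges = pd.DataFrame(columns=["taxon_id", "index_name", "rho", "p", "q", "sign"])
    path = tmp_path / "edges.tsv"
    write_edges_tsv(edges, path)
    assert path.read_text().startswith("taxon_id")
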