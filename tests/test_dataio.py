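"""Round-trips, canonicalisation and typed parse errors for the IO layer."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from trinet import dataio
from trinet.dataio import (
    DesignError,
    RegPredictionTables,
    SchemaError,
    canonical_symbol,
    read_expression_matrix,
    read_ppi_edges,
    read_prediction_tables,
    write_expression_study,
    write_network,
    write_ppi_edges,
)
from trinet.regnet import DirectionalCall, MirnaTargetEdge, TFMirnaEdge, TriadNetwork


@pytest.mark.parametrize(
    "raw, kind, expected",
    [
        ("Fosl2", "gene", "fosl2"),
        ("FOSL2", "gene", "fosl2"),
        ("mmu-miR-155", "mirna", "mir-155"),
        ("hsa-miR-21-5p", "mirna", "mir-21-5p"),
        ("miR-146a", "mirna", "mir-146a"),
        ("mir-146a", "mirna", "mir-146a"),
    ],
)
def test_canonical_symbol_joins_mixed_spellings(raw, kind, expected):
    assert canonical_symbol(raw, kind) == expected


def _toy_matrix(tmp_path, rows, samples, design_rows):
    mpath = tmp_path / "m.tsv"
    dpath = tmp_path / "d.tsv"
    with open(mpath, "w") as fh:
        fh.write("feature\t" + "\t".join(samples) + "\n")
        for name, vals in rows:
            fh.write(name + "\t" + "\t".join(map(str, vals)) + "\n")
    pd.DataFrame(design_rows, columns=["sample", "group"]).to_csv(dpath, sep="\t", index=False)
    return mpath, dpath


def test_expression_round_trip(tmp_path):
    mpath, dpath = _toy_matrix(
        tmp_path,
        [("GeneA", [1, 2, 3, 4]), ("GeneB", [5, 6, 7, 8]), ("GeneC", [0, 0, 1, 1])],
        ["s1", "s2", "s3", "s4"],
        [("s1", "case"), ("s2", "case"), ("s3", "control"), ("s4", "control")],
    )
    study = read_expression_matrix(mpath, dpath)
    assert len(study.features) == 3 and len(study.samples) == 4
    out_m, out_d = tmp_path / "out.tsv", tmp_path / "out.design.tsv"
    write_expression_study(study, out_m, out_d)
    again = read_expression_matrix(out_m, out_d, study_id=study.study_id)
    assert again.features == study.features
    assert again.samples == study.samples
    assert again.design == study.design
    np.testing.assert_allclose(again.values, study.values)


def test_sample_missing_from_design_is_an_error(tmp_path):
    mpath, dpath = _toy_matrix(
        tmp_path,
        [("GeneA", [1, 2, 3, 4])],
        ["s1", "s2", "s3", "s4"],
        [("s1", "case"), ("s2", "case"), ("s3", "control")],
    )
    with pytest.raises(DesignError):
        read_expression_matrix(mpath, dpath)


def test_fewer_than_two_per_group_is_an_error(tmp_path):
    mpath, dpath = _toy_matrix(
        tmp_path,
        [("GeneA", [1, 2, 3])],
        ["s1", "s2", "s3"],
        [("s1", "case"), ("s2", "control"), ("s3", "control")],
    )
    with pytest.raises(DesignError):
        read_expression_matrix(mpath, dpath)


def test_duplicate_feature_rows_collapse_to_highest_mean(tmp_path):
    # GeneA appears three times (case-insensitively); the mean-7 row must win.
    mpath, dpath = _toy_matrix(
        tmp_path,
        [
            ("GeneA", [1, 1, 1, 1]),
            ("genea", [7, 7, 7, 7]),
            ("GENEA", [4, 4, 4, 4]),
            ("GeneB", [2, 2, 2, 2]),
        ],
        ["s1", "s2", "s3", "s4"],
        [("s1", "case"), ("s2", "case"), ("s3", "control"), ("s4", "control")],
    )
    study = read_expression_matrix(mpath, dpath)
    assert len(study.features) == 2
    np.testing.assert_allclose(study.row("GeneA"), [7, 7, 7, 7])


def test_non_numeric_matrix_is_a_schema_error(tmp_path):
    mpath, dpath = _toy_matrix(
        tmp_path,
        [("GeneA", [1, "oops", 3, 4])],
        ["s1", "s2", "s3", "s4"],
        [("s1", "case"), ("s2", "case"), ("s3", "control"), ("s4", "control")],
    )
    with pytest.raises(SchemaError):
        read_expression_matrix(mpath, dpath)


def _write_tables(tmp_path, tm_rows, mt_rows):
    tf_path, mt_path = tmp_path / "tm.tsv", tmp_path / "mt.tsv"
    pd.DataFrame(tm_rows, columns=["tf", "mirna", "action", "evidence"]).to_csv(
        tf_path, sep="\t", index=False)
    pd.DataFrame(mt_rows, columns=["mirna", "target", "score"]).to_csv(
        mt_path, sep="\t", index=False)
    return tf_path, mt_path


def test_prediction_tables_parse_and_canonicalize(tmp_path):
    tf_path, mt_path = _write_tables(
        tmp_path,
        [("Fosl2", "mmu-miR-155", "Activation", "chip"),
         ("Fosl2", "miR-146a", "Activation", "chip"),
         ("Mafk", "mir-25", "Activation", "chip"),
         ("Cebpb", "mir-155", "Activation", "chip")],
        [("mir-155", "Fosl2", 73), ("mir-146a", "Fosl2", 51),
         ("mir-25", "Mafk", 71), ("mir-155", "Cebpb", 88)],
    )
    tables = read_prediction_tables(tf_path, mt_path)
    assert len(tables.tf_mirna) == 4
    assert set(tables.tf_mirna["tf"]) == {"Fosl2", "Mafk", "Cebpb"}
    # species prefix and miR/mir capitalisation collapse to one key
    assert set(tables.tf_mirna["mirna_key"]) == {"mir-155", "mir-146a", "mir-25"}


def test_prediction_table_score_out_of_range_is_an_error(tmp_path):
    tf_path, mt_path = _write_tables(
        tmp_path, [("A", "mir-1", "Activation", "")], [("mir-1", "B", 101)])
    with pytest.raises(SchemaError):
        read_prediction_tables(tf_path, mt_path)


def test_prediction_table_missing_column_is_an_error(tmp_path):
    _, mt_path = _write_tables(tmp_path, [("A", "mir-1", "Activation", "")], [("mir-1", "B", 50)])
    tf_path = tmp_path / "tm_bad.tsv"
    pd.DataFrame([("A", "mir-1")], columns=["tf", "mirna"]).to_csv(tf_path, sep="\t", index=False)
    with pytest.raises(SchemaError):
        read_prediction_tables(tf_path, mt_path)


def test_prediction_table_duplicates_dropped():
    tables = RegPredictionTables.from_frames(
        pd.DataFrame([("A", "miR-1", "Activation", ""), ("a", "mmu-mir-1", "Activation", "")],
                     columns=["tf", "mirna", "action", "evidence"]),
        pd.DataFrame([("mir-1", "B", 50.0)], columns=["mirna", "target", "score"]),
    )
    assert len(tables.tf_mirna) == 1


def test_ppi_round_trip_drops_self_loops(tmp_path):
    path = tmp_path / "ppi.tsv"
    pd.DataFrame([("A", "B"), ("B", "C"), ("C", "C")],
                 columns=["protein_a", "protein_b"]).to_csv(path, sep="\t", index=False)
    g = read_ppi_edges(path)
    assert set(g.edges()) == {("a", "b"), ("b", "c")}
    out = tmp_path / "ppi2.tsv"
    write_ppi_edges(g, out)
    assert nx.is_isomorphic(read_ppi_edges(out), g)


def _one_triad_network():
    return TriadNetwork(
        nodes=[DirectionalCall("tf1", "TF", "up"),
               DirectionalCall("mir-9", "miRNA", "up"),
               DirectionalCall("geneb", "target", "down")],
        tf_mirna_edges=[TFMirnaEdge("tf1", "mir-9", "Activation")],
        mirna_target_edges=[MirnaTargetEdge("mir-9", "geneb", 77.0)],
        triads=[("tf1", "mir-9", "geneb")],
    )


def test_empty_network_writes_valid_documents(tmp_path):
    net = TriadNetwork()
    write_network(net, tmp_path / "empty.graphml", format="GraphML")
    write_network(net, tmp_path / "empty.sif", format="SIF")
    assert dataio.read_network_graphml(tmp_path / "empty.graphml").number_of_nodes() == 0


def test_one_triad_network_round_trip(tmp_path):
    net = _one_triad_network()
    write_network(net, tmp_path / "net.graphml", format="GraphML")
    g = dataio.read_network_graphml(tmp_path / "net.graphml")
    assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
    assert g.nodes["mir-9"]["layer"] == "miRNA"
    assert g.edges["tf1", "mir-9"]["interaction"] == "activates"
    assert g.edges["mir-9", "geneb"]["interaction"] == "represses"


def test_graphml_round_trip_is_attribute_isomorphic(tmp_path, small_dataset):
    from trinet.pipeline import run_pipeline

    res = run_pipeline(small_dataset.studies, small_dataset.mirna_study, small_dataset.tables)
    original = dataio.network_to_digraph(res.network)
    write_network(res.network, tmp_path / "net.graphml", format="GraphML")
    reread = dataio.read_network_graphml(tmp_path / "net.graphml")

    def node_eq(a, b):
        return a.get("layer") == b.get("layer") and a.get("direction") == b.get("direction")

    def edge_eq(a, b):
        if a.get("interaction") != b.get("interaction"):
            return False
        sa, sb = a.get("score"), b.get("score")
        return (sa is None) == (sb is None) and (sa is None or abs(sa - sb) < 1e-9)

    assert nx.is_isomorphic(original, reread, node_match=node_eq, edge_match=edge_eq)


def test_sif_uses_relation_tokens_and_sidecar(tmp_path):
    net = _one_triad_network()
    write_network(net, tmp_path / "net.sif", format="SIF")
    lines = (tmp_path / "net.sif").read_text().splitlines()
    assert "tf1\tactivates\tmir-9" in lines
    assert "mir-9\trepresses\tgeneb" in lines
    g = dataio.read_network_sif(tmp_path / "net.sif")
    assert g.nodes["geneb"]["direction"] == "down"


def test_unknown_network_format_rejected(tmp_path):
    with pytest.raises(SchemaError):
        write_network(_one_triad_network(), tmp_path / "x", format="dot")
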