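"""Network parsing, validation, summaries and export."""

import pandas as pd
import pytest

from rnm import (
    EvidenceRecord,
    InteractionRecord,
    NetworkFormatError,
    NetworkValidationError,
    NodeRecord,
    RegulatoryNetwork,
    SignConflictError,
    UnknownNodeError,
    corpus_summary,
    degree_of_connectivity,
    export_network,
    load_graphml,
    load_sif,
    merge_nodes,
    parse_interaction_table,
    remove_nodes,
)
from rnm.network import canonical_name

from conftest import make_net


def write_csv(tmp_path, rows, header="source,target,effect", name="net.csv"):
    path = tmp_path / name
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestParsing:
    def test_three_row_table(self, tmp_path):
        path = write_csv(tmp_path, ["A,B,+1", "B,C,-1", "A,C,+1"])
        net = parse_interaction_table(path)
        assert len(net.nodes) == 3
        assert len(net.interactions) == 3
        assert net.activators_of("C") == ["A"]
        assert net.inhibitors_of("C") == ["B"]

    def test_tsv_dialect(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("source\ttarget\teffect\nA\tB\t1\n")
        net = parse_interaction_table(path, dialect="edge-list-tsv")
        assert [n.name for n in net.nodes] == ["A", "B"]

    def test_effect_word_forms(self, tmp_path):
        path = write_csv(tmp_path, ["A,B,activation", "B,C,inhibits"])
        net = parse_interaction_table(path)
        assert {(i.source, i.target, i.effect) for i in net.interactions} == {
            ("A", "B", 1),
            ("B", "C", -1),
        }

    def test_sign_conflict_names_pair(self, tmp_path):
        path = write_csv(tmp_path, ["X,Y,+1", "X,Y,-1"])
        with pytest.raises(SignConflictError, match="X.*Y"):
            parse_interaction_table(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = write_csv(tmp_path, ["A,B"], header="source,target")
        with pytest.raises(NetworkFormatError, match="effect"):
            parse_interaction_table(path)

    def test_alias_normalisation(self, tmp_path):
        path = write_csv(tmp_path, ["IL-1b,TGF-beta,-1"])
        net = parse_interaction_table(path)
        assert [n.name for n in net.nodes] == ["IL-1β", "TGF-β"]
        assert canonical_name("  IFN-g ") == "IFN-γ"

    def test_unknown_columns_become_annotations(self, tmp_path):
        path = write_csv(
            tmp_path, ["A,B,1,direct"], header="source,target,effect,mechanism"
        )
        net = parse_interaction_table(path)
        assert dict(net.interactions[0].annotations) == {"mechanism": "direct"}

    def test_evidence_columns(self, tmp_path):
        path = write_csv(
            tmp_path,
            ["A,B,1,P1,IVD-NPC,human,3D,normal"],
            header="source,target,effect,reference_id,cell_type,species,culture,pathology",
        )
        net = parse_interaction_table(path)
        ev = net.interactions[0].evidence[0]
        assert (ev.reference_id, ev.cell_type, ev.culture) == ("P1", "IVD-NPC", "3D")


class TestValidation:
    def test_dangling_endpoint(self):
        with pytest.raises(NetworkValidationError, match="endpoint"):
            RegulatoryNetwork(
                nodes=[NodeRecord("A")],
                interactions=[InteractionRecord("A", "B", 1)],
            )

    def test_duplicate_node_names(self):
        with pytest.raises(NetworkValidationError, match="duplicate"):
            RegulatoryNetwork(nodes=[NodeRecord("A"), NodeRecord("A")])

    def test_merged_from_must_not_be_live(self):
        with pytest.raises(NetworkValidationError, match="merged_from"):
            RegulatoryNetwork(
                nodes=[NodeRecord("A"), NodeRecord("B", merged_from=("A",))]
            )

    def test_effect_domain(self):
        with pytest.raises(NetworkValidationError):
            InteractionRecord("A", "B", 2)

    def test_evidence_enum(self):
        with pytest.raises(NetworkValidationError):
            EvidenceRecord(reference_id="P1", cell_type="fibroblast")


class TestDegree:
    def test_star(self):
        net = make_net([("H", f"L{i}", 1) for i in range(5)])
        doc = degree_of_connectivity(net)
        assert doc["H"] == 5
        assert all(doc[f"L{i}"] == 1 for i in range(5))

    def test_self_loop_counts_once(self):
        net = make_net([("A", "A", 1), ("A", "B", 1)])
        assert degree_of_connectivity(net)["A"] == 2

    def test_doc_sum_is_twice_edge_count(self, fixture_net):
        doc = degree_of_connectivity(fixture_net)
        assert sum(doc.values()) == 2 * len(fixture_net.interactions)


class TestMergeRemove:
    def test_merge_collapses_duplicates(self):
        net = make_net([("X", "A1", 1), ("X", "A2", 1)])
        merged = merge_nodes(net, ["A1", "A2"], "A")
        assert {(i.source, i.target, i.effect) for i in merged.interactions} == {
            ("X", "A", 1)
        }
        assert merged.node("A").merged_from == ("A1", "A2")

    def test_merge_sign_conflict(self):
        net = make_net([("X", "A1", 1), ("X", "A2", -1)])
        with pytest.raises(SignConflictError):
            merge_nodes(net, ["A1", "A2"], "A")

    def test_merge_without_incident_edges_is_rename(self):
        net = make_net([("X", "Y", 1)], nodes=["A1", "A2"])
        merged = merge_nodes(net, ["A1", "A2"], "A")
        assert len(merged.interactions) == 1
        assert merged.has_node("A") and not merged.has_node("A1")

    def test_merge_unknown_member(self):
        net = make_net([("X", "Y", 1)])
        with pytest.raises(UnknownNodeError):
            merge_nodes(net, ["X", "Z"], "W")

    @pytest.mark.parametrize(
        "drop, n_nodes, n_edges",
        [(["C"], 2, 1), (["B"], 2, 0)],
    )
    def test_remove_from_chain(self, drop, n_nodes, n_edges):
        net = make_net([("A", "B", 1), ("B", "C", 1)])
        out = remove_nodes(net, drop)
        assert (len(out.nodes), len(out.interactions)) == (n_nodes, n_edges)

    def test_remove_all_nodes_gives_valid_empty_network(self):
        net = make_net([("A", "B", 1)])
        out = remove_nodes(net, ["A", "B"])
        assert out.nodes == [] and out.interactions == []

    def test_remove_unknown_name(self):
        net = make_net([("A", "B", 1)])
        with pytest.raises(UnknownNodeError):
            remove_nodes(net, ["Q"])


class TestCorpusSummary:
    def test_distinct_paper_counting(self):
        ev = EvidenceRecord(
            reference_id="P1", cell_type="IVD-NPC", species="human", culture="2D"
        )
        net = RegulatoryNetwork(
            nodes=[NodeRecord(n) for n in "ABC"],
            interactions=[
                InteractionRecord("A", "B", 1, evidence=(ev,)),
                InteractionRecord("B", "C", 1, evidence=(ev,)),
            ],
        )
        cs = corpus_summary(net)
        assert cs.total_links == 2
        assert cs.total_papers == 1
        assert cs.links("IVD-NPC") == 2

    def test_missing_evidence_counts_under_na(self):
        net = make_net([("A", "B", 1)])
        cs = corpus_summary(net)
        assert cs.total_links == 1
        assert cs.total_papers == 0
        assert cs.by_source.index[0] == ("n/a", "n/a", "n/a")

    def test_cell_totals_sum_to_links(self, fixture_net):
        # every fixture edge carries exactly one evidence record
        cs = corpus_summary(fixture_net)
        assert cs.by_source["n_links"].sum() == len(fixture_net.interactions)
        assert cs.by_pathology["n_links"].sum() == len(fixture_net.interactions)


class TestExport:
    @pytest.mark.parametrize("fmt,ext", [("edge-list-csv", "csv"), ("edge-list-tsv", "tsv")])
    def test_edge_list_round_trip(self, tmp_path, fixture_net, fmt, ext):
        path = tmp_path / f"net.{ext}"
        export_network(fixture_net, path, format=fmt)
        assert parse_interaction_table(path) == fixture_net

    def test_graphml_round_trip(self, tmp_path, fixture_net):
        path = tmp_path / "net.graphml"
        export_network(fixture_net, path, format="graphml")
        assert load_graphml(path) == fixture_net

    def test_sif_round_trip_edges(self, tmp_path):
        net = make_net([("A", "B", 1), ("B", "C", -1), ("A", "C", 1)])
        path = tmp_path / "net.sif"
        export_network(net, path, format="sif")
        lines = path.read_text().splitlines()
        assert "A\tactivates\tB" in lines and "B\tinhibits\tC" in lines
        again = load_sif(path)
        assert {(i.source, i.target, i.effect) for i in again.interactions} == {
            (i.source, i.target, i.effect) for i in net.interactions
        }

    def test_graphml_element_counts(self, tmp_path):
        net = make_net([("A", "B", 1), ("B", "C", -1), ("A", "C", 1)])
        path = tmp_path / "toy.graphml"
        export_network(net, path, format="graphml")
        text = path.read_text()
        assert text.count("<node ") == 3 and text.count("<edge ") == 3

    def test_empty_network_export(self, tmp_path):
        empty = RegulatoryNetwork()
        path = export_network(empty, tmp_path / "empty.csv")
        assert parse_interaction_table(path) == empty

    def test_unsupported_format(self, tmp_path, fixture_net):
        with pytest.raises(NetworkFormatError):
            export_network(fixture_net, tmp_path / "x.bin", format="binary")
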