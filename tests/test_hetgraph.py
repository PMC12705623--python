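"""Graph data model: cleaning filters, construction, merging, round-trips."""

import numpy as np
import pandas as pd
import pytest

from herbgat import hetgraph as hg
from herbgat.augment import SyntheticPrescription
from herbgat.featurize import MoleculeRecord, PrescriptionRecord, TargetRecord


def _label_table(shares, n=400):
    """Binary label matrix whose column means hit the requested shares."""
    mat = np.zeros((n, len(shares)), dtype=int)
    for j, s in enumerate(shares):
        mat[: int(round(s * n)), j] = 1
    return hg.EfficacyLabelTable(mat, [f"eff{j}" for j in range(len(shares))],
                                 [f"P{i}" for i in range(n)])


class TestFilterRareEfficacies:
    def test_nineteen_efficacies_with_twelve_rare_leave_seven(self):
        shares = [0.50, 0.45, 0.40, 0.35, 0.30, 0.25, 0.20] + [0.10] * 12
        labels = _label_table(shares)
        assert len(labels.efficacies) == 19
        assert len(hg.filter_rare_efficacies(labels, 0.15)) == 7

    def test_all_retained_when_all_common(self):
        labels = _label_table([0.3, 0.5, 0.15])
        assert hg.filter_rare_efficacies(labels) == ["eff0", "eff1", "eff2"]

    def test_boundary_share_exactly_at_threshold_is_retained(self):
        labels = _label_table([0.15, 0.1475])  # 60/400 and 59/400
        kept = hg.filter_rare_efficacies(labels, 0.15)
        assert kept == ["eff0"]

    def test_empty_table_rejected(self):
        labels = hg.EfficacyLabelTable(np.zeros((0, 2), dtype=int),
                                       ["a", "b"], [])
        with pytest.raises(ValueError):
            hg.filter_rare_efficacies(labels)


def _toy_graph():
    prescriptions = [
        PrescriptionRecord("P1", ["A", "B"]),
        PrescriptionRecord("P2", ["B"]),
    ]
    features = {
        "prescription": np.ones((2, 3)),
        "herb": np.ones((2, 3)),
        "metabolite": np.arange(10).reshape(5, 2).astype(float),
        "target": np.ones((2, 2)),
    }
    hm = [("A", "M1"), ("A", "M2"), ("B", "M3"), ("B", "M4"), ("B", "M5")]
    mt = [("M1", "T1"), ("M3", "T2"), ("M4", "T1")]
    return hg.build_graph(prescriptions, ["A", "B"], hm, mt, features,
                          metabolite_ids=["M1", "M2", "M3", "M4", "M5"],
                          target_ids=["T1", "T2"])


class TestBuildGraph:
    def test_membership_edge_count(self):
        g = _toy_graph()
        assert g.num_edges("prescription-herb") == 3  # total memberships

    def test_reverse_duals_present_and_consistent(self):
        g = _toy_graph()
        g.validate()
        assert g.num_edges("herb-prescription") == 3

    def test_duplicate_edges_and_herbs_collapse(self):
        p = [PrescriptionRecord("P1", ["A", "A", "B"])]
        feats = {"prescription": np.ones((1, 3)), "herb": np.ones((2, 3)),
                 "metabolite": np.empty((0, 2)), "target": np.empty((0, 2))}
        g = hg.build_graph(p, ["A", "B"], [("A", "M1"), ("A", "M1")], [],
                           feats | {"metabolite": np.ones((1, 2))},
                           metabolite_ids=["M1"], target_ids=[])
        assert g.num_edges("prescription-herb") == 2
        assert g.num_edges("herb-metabolite") == 1

    def test_dangling_id_raises_listing_offender(self):
        p = [PrescriptionRecord("P1", ["A", "ZZZ"])]
        feats = {"prescription": np.ones((1, 3)), "herb": np.ones((1, 3)),
                 "metabolite": np.empty((0, 2)), "target": np.empty((0, 2))}
        with pytest.raises(hg.DanglingIdError, match="ZZZ"):
            hg.build_graph(p, ["A"], [], [], feats,
                           metabolite_ids=[], target_ids=[])

    def test_row_order_permutation_invariance(self):
        g1 = _toy_graph()
        prescriptions = [PrescriptionRecord("P2", ["B"]),
                         PrescriptionRecord("P1", ["B", "A"])]
        # same content, different row order; ids sort canonically
        hm = [("B", "M5"), ("A", "M1"), ("B", "M3"), ("A", "M2"), ("B", "M4")]
        mt = [("M4", "T1"), ("M1", "T1"), ("M3", "T2")]
        feats = {"prescription": np.ones((2, 3)), "herb": np.ones((2, 3)),
                 "metabolite": np.arange(10).reshape(5, 2).astype(float),
                 "target": np.ones((2, 2))}
        g2 = hg.build_graph(prescriptions, ["B", "A"], hm, mt, feats,
                            metabolite_ids=["M1", "M2", "M3", "M4", "M5"],
                            target_ids=["T1", "T2"])
        assert g1.node_ids["herb"] == g2.node_ids["herb"]
        for rel in g1.edges:
            s1, d1 = g1.edges[rel]
            s2, d2 = g2.edges[rel]
            # prescription order differs; compare edge sets by ids
            st, dt = g1.relation_types[rel]
            e1 = {(g1.node_ids[st][a], g1.node_ids[dt][b]) for a, b in zip(s1, d1)}
            e2 = {(g2.node_ids[st][a], g2.node_ids[dt][b]) for a, b in zip(s2, d2)}
            assert e1 == e2

    def test_roundtrip_serialization(self, tmp_path):
        g = _toy_graph()
        g.labels = _label_table([0.5, 0.2], n=2)
        hg.save_graph(g, tmp_path / "g")
        g2 = hg.load_graph(tmp_path / "g")
        assert g.node_ids == g2.node_ids
        for rel in g.edges:
            assert np.array_equal(g.edges[rel][0], g2.edges[rel][0])
            assert np.array_equal(g.edges[rel][1], g2.edges[rel][1])
        for t in g.features:
            assert np.array_equal(g.features[t], g2.features[t])
        assert np.array_equal(g.labels.matrix, g2.labels.matrix)

    def test_graphml_export_parses(self, tmp_path):
        import networkx as nx

        g = _toy_graph()
        hg.to_graphml(g, tmp_path / "g.graphml")
        G = nx.read_graphml(tmp_path / "g.graphml")
        assert G.number_of_nodes() == g.num_nodes()


class TestDropUnsequenced:
    def _molecules(self):
        return [MoleculeRecord(f"M{i}", smiles="CCO", ecfp=np.ones(8))
                for i in (1, 3, 4)] + \
               [MoleculeRecord("M2"), MoleculeRecord("M5")]

    def _targets(self):
        return [TargetRecord("T1", "MKT"), TargetRecord("T2", "MKV")]

    def test_unsequenced_metabolites_removed(self):
        g, report = hg.drop_unsequenced(_toy_graph(), self._molecules(),
                                        self._targets())
        assert g.num_nodes("metabolite") == 3
        assert report["nodes_removed"]["metabolite"] == 2

    def test_edge_counts_match_brute_force_recount(self):
        g0 = _toy_graph()
        g, _ = hg.drop_unsequenced(g0, self._molecules(), self._targets())
        surviving = set(g.node_ids["metabolite"])
        expected = sum(1 for a, b in [("A", "M1"), ("A", "M2"), ("B", "M3"),
                                      ("B", "M4"), ("B", "M5")]
                       if b in surviving)
        assert g.num_edges("herb-metabolite") == expected
        g.validate()

    def test_identity_when_everything_sequenced(self):
        mols = [MoleculeRecord(f"M{i}", smiles="CCO", ecfp=np.ones(8))
                for i in range(1, 6)]
        g, report = hg.drop_unsequenced(_toy_graph(), mols, self._targets())
        assert g.num_nodes("metabolite") == 5
        assert report["nodes_removed"] == {"metabolite": 0, "target": 0}

    def test_idempotent(self):
        g1, _ = hg.drop_unsequenced(_toy_graph(), self._molecules(),
                                    self._targets())
        g2, r2 = hg.drop_unsequenced(g1, self._molecules(), self._targets())
        assert g1.node_ids == g2.node_ids
        assert sum(r2["edges_removed"].values()) == 0


class TestVirtualEcfp:
    def test_one_virtual_node_per_fingerprinted_metabolite(self):
        g = _toy_graph()
        mols = [MoleculeRecord(f"M{i}", smiles="CCO", ecfp=np.ones(8))
                for i in (1, 2, 3)] + [MoleculeRecord("M4"), MoleculeRecord("M5")]
        g2 = hg.attach_virtual_ecfp(g, mols)
        assert g2.num_nodes("ecfp_virtual") == 3
        assert g2.num_edges("metabolite-ecfp") == 3
        assert g2.num_edges("ecfp-metabolite") == 3
        deg = np.zeros(3, dtype=int)
        np.add.at(deg, g2.edges["ecfp-metabolite"][0], 1)
        assert (deg == 1).all()

    def test_no_fingerprints_no_nodes(self):
        g2 = hg.attach_virtual_ecfp(_toy_graph(),
                                    [MoleculeRecord(f"M{i}") for i in range(1, 6)])
        assert g2.num_nodes("ecfp_virtual") == 0


class TestMergeGenerated:
    def _synth(self, herb_sets):
        return [SyntheticPrescription(label=1, feature=np.full(3, 0.5),
                                      soft_adjacency=np.zeros(2),
                                      herb_set=frozenset(s))
                for s in herb_sets]

    def test_empty_merge_is_identity(self):
        g = _toy_graph()
        g2 = hg.merge_generated(g, [], "eff0")
        assert g2.node_ids == g.node_ids

    def test_node_and_edge_arithmetic(self):
        g = _toy_graph()
        g.labels = _label_table([0.5, 0.5], n=2)
        sets = [{0}, {0, 1}, {1}]
        g2 = hg.merge_generated(g, self._synth(sets), "eff0")
        assert g2.num_nodes("prescription") == 2 + 3
        assert g2.num_edges("prescription-herb") == 3 + sum(map(len, sets))
        assert g2.provenance["prescription"][-3:] == ["generated"] * 3
        assert g2.labels.matrix[-3:, 0].tolist() == [1, 1, 1]

    def test_original_subgraph_untouched(self):
        g = _toy_graph()
        g2 = hg.merge_generated(g, self._synth([{0, 1}]), "eff0")
        n = g.num_nodes("prescription")
        s, d = g2.edges["prescription-herb"]
        mask = s < n
        assert np.array_equal(np.sort(s[mask]), np.sort(g.edges["prescription-herb"][0]))
        for t in g.node_ids:
            assert g2.node_ids[t][: len(g.node_ids[t])] == g.node_ids[t]
            assert np.array_equal(g2.features[t][: len(g.node_ids[t])],
                                  g.features[t])
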