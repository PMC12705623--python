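"""Heterogeneous network of prescriptions, herbs, metabolites and targets.

Node types: prescription, herb, metabolite, target, plus one virtual
fingerprint node per fingerprinted metabolite. Relations are stored as
directed typed edge lists; every forward relation has an explicit reverse
dual with its own relation name so message passing can reach prescriptions
from targets. Edges carry no attributes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .featurize import MoleculeRecord, PrescriptionRecord, TargetRecord

NODE_TYPES = ("prescription", "herb", "metabolite", "target", "ecfp_virtual")

# forward relation -> (src_type, dst_type)
FORWARD_RELATIONS = {
    "prescription-herb": ("prescription", "herb"),
    "herb-metabolite": ("herb", "metabolite"),
    "metabolite-target": ("metabolite", "target"),
    "metabolite-ecfp": ("metabolite", "ecfp_virtual"),
}


def reverse_name(relation: str) -> str:
    src, dst = relation.split("-")
    return f"{dst}-{src}"


class DanglingIdError(ValueError):
    """Edge references a node id that does not exist."""


@dataclass
class EfficacyLabelTable:
    """Prescription x efficacy binary matrix with a fixed efficacy order."""

    matrix: np.ndarray  # (n_prescriptions, n_efficacies) in {0,1}
    efficacies: list
    prescription_ids: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("label entries must be 0/1")
        if self.matrix.shape != (len(self.prescription_ids), len(self.efficacies)):
            raise ValueError("label matrix shape mismatch")

    def column(self, efficacy: str) -> np.ndarray:
        return self.matrix[:, self.efficacies.index(efficacy)]

    def positive_share(self, efficacy: str) -> float:
        return float(self.column(efficacy).mean())


def filter_rare_efficacies(labels: EfficacyLabelTable, min_share: float = 0.15) -> list:
    """Efficacies whose positive share is at least ``min_share``.

    Classes strictly below the threshold are dropped; a share exactly at
    the threshold is retained.
    """
    if not (0 < min_share < 1):
        raise ValueError("min_share must be in (0, 1)")
    if len(labels.prescription_ids) == 0:
        raise ValueError("empty label table")
    return [e for e in labels.efficacies if labels.positive_share(e) >= min_share]


@dataclass
class HeteroGraph:
    node_ids: dict = field(default_factory=dict)      # type -> list of ids
    features: dict = field(default_factory=dict)      # type -> (n, d) array
    edges: dict = field(default_factory=dict)         # relation -> (src_idx, dst_idx)
    relation_types: dict = field(default_factory=dict)  # relation -> (src_type, dst_type)
    provenance: dict = field(default_factory=dict)    # type -> list of flags
    labels: EfficacyLabelTable | None = None

    # -- bookkeeping ---------------------------------------------------

    def num_nodes(self, node_type: str | None = None) -> int:
        if node_type is not None:
            return len(self.node_ids.get(node_type, []))
        return sum(len(v) for v in self.node_ids.values())

    def num_edges(self, relation: str | None = None) -> int:
        if relation is not None:
            return len(self.edges[relation][0])
        return sum(len(s) for s, _ in self.edges.values())

    def index_of(self, node_type: str, node_id: str) -> int:
        return self._index_maps()[node_type][node_id]

    def _index_maps(self) -> dict:
        return {t: {nid: i for i, nid in enumerate(ids)}
                for t, ids in self.node_ids.items()}

    def add_nodes(self, node_type: str, ids: list, features: np.ndarray,
                  provenance: str = "original") -> None:
        if node_type not in self.node_ids:
            self.node_ids[node_type] = []
            self.provenance[node_type] = []
        existing = set(self.node_ids[node_type])
        dup = [i for i in ids if i in existing]
        if dup:
            raise ValueError(f"duplicate {node_type} ids: {dup[:5]}")
        self.node_ids[node_type].extend(ids)
        self.provenance[node_type].extend([provenance] * len(ids))
        feats = np.asarray(features, dtype=np.float64)
        if node_type in self.features and self.features[node_type].size:
            self.features[node_type] = np.vstack([self.features[node_type], feats])
        else:
            self.features[node_type] = feats

    def add_edges(self, relation: str, src_type: str, dst_type: str,
                  src_idx: np.ndarray, dst_idx: np.ndarray,
                  add_reverse: bool = True) -> None:
        """Append (deduplicated) directed edges plus their reverse dual."""
        src_idx = np.asarray(src_idx, dtype=np.intp)
        dst_idx = np.asarray(dst_idx, dtype=np.intp)
        if len(src_idx):
            if src_idx.max() >= self.num_nodes(src_type) or dst_idx.max() >= self.num_nodes(dst_type):
                raise DanglingIdError(f"edge endpoint out of range for {relation}")
        pairs = np.unique(np.stack([src_idx, dst_idx], axis=1), axis=0) \
            if len(src_idx) else np.empty((0, 2), dtype=np.intp)
        if relation in self.edges:
            old = np.stack(self.edges[relation], axis=1)
            pairs = np.unique(np.vstack([old, pairs]), axis=0)
        self.edges[relation] = (pairs[:, 0].copy(), pairs[:, 1].copy())
        self.relation_types[relation] = (src_type, dst_type)
        if add_reverse:
            rev = reverse_name(relation)
            self.edges[rev] = (pairs[:, 1].copy(), pairs[:, 0].copy())
            self.relation_types[rev] = (dst_type, src_type)

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        for rel, (src_idx, dst_idx) in self.edges.items():
            st, dt = self.relation_types[rel]
            if len(src_idx) and (src_idx.max() >= self.num_nodes(st)
                                 or dst_idx.max() >= self.num_nodes(dt)):
                raise DanglingIdError(f"dangling endpoint in relation {rel}")
            rev = reverse_name(rel)
            if rev not in self.edges:
                raise ValueError(f"missing reverse dual for {rel}")
            fwd = set(zip(src_idx.tolist(), dst_idx.tolist()))
            bwd = set(zip(*(arr.tolist() for arr in self.edges[rev][::-1])))
            if fwd != bwd:
                raise ValueError(f"reverse dual of {rel} inconsistent")
        if "ecfp_virtual" in self.node_ids and "ecfp-metabolite" in self.edges:
            deg = np.zeros(self.num_nodes("ecfp_virtual"), dtype=int)
            np.add.at(deg, self.edges["ecfp-metabolite"][0], 1)
            if not np.all(deg == 1):
                raise ValueError("ecfp_virtual nodes must have degree exactly 1")
        for t, ids in self.node_ids.items():
            if t in self.features and len(self.features[t]) != len(ids):
                raise ValueError(f"feature matrix length mismatch for {t}")

    def copy(self) -> "HeteroGraph":
        g = HeteroGraph(
            node_ids={t: list(v) for t, v in self.node_ids.items()},
            features={t: v.copy() for t, v in self.features.items()},
            edges={r: (s.copy(), d.copy()) for r, (s, d) in self.edges.items()},
            relation_types=dict(self.relation_types),
            provenance={t: list(v) for t, v in self.provenance.items()},
        )
        if self.labels is not None:
            g.labels = EfficacyLabelTable(self.labels.matrix.copy(),
                                          list(self.labels.efficacies),
                                          list(self.labels.prescription_ids))
        return g

    def remove_nodes(self, node_type: str, drop_local: set) -> dict:
        """Remove nodes (by local index) and all incident edges, in place.

        Returns counts of removed nodes and edges per relation.
        """
        n = self.num_nodes(node_type)
        keep = np.array([i for i in range(n) if i not in drop_local], dtype=np.intp)
        remap = -np.ones(n, dtype=np.intp)
        remap[keep] = np.arange(len(keep))
        report = {"nodes_removed": {node_type: len(drop_local)}, "edges_removed": {}}
        self.node_ids[node_type] = [self.node_ids[node_type][i] for i in keep]
        self.provenance[node_type] = [self.provenance[node_type][i] for i in keep]
        if node_type in self.features and self.features[node_type].size:
            self.features[node_type] = self.features[node_type][keep]
        for rel, (src_idx, dst_idx) in list(self.edges.items()):
            st, dt = self.relation_types[rel]
            mask = np.ones(len(src_idx), dtype=bool)
            if st == node_type:
                mask &= remap[src_idx] >= 0
            if dt == node_type:
                mask &= remap[dst_idx] >= 0
            removed = int((~mask).sum())
            if removed:
                report["edges_removed"][rel] = removed
            s, d = src_idx[mask], dst_idx[mask]
            if st == node_type:
                s = remap[s]
            if dt == node_type:
                d = remap[d]
            self.edges[rel] = (s, d)
        return report


# ---------------------------------------------------------------------------
# Construction and cleaning
# ---------------------------------------------------------------------------


def build_graph(
    prescriptions: list[PrescriptionRecord],
    herb_ids: list,
    herb_metab_edges: list[tuple],
    metab_target_edges: list[tuple],
    features: dict,
    metabolite_ids: list | None = None,
    target_ids: list | None = None,
) -> HeteroGraph:
    """Assemble the heterogeneous graph from cleaned tables.

    ``features`` maps node type to its feature matrix, row order matching
    the (canonically sorted) id lists. Prescription-herb edges come from
    each prescription's (de-duplicated) herb list. Dangling ids raise with
    the offenders listed.
    """
    herb_ids = sorted(set(herb_ids))
    presc_ids = [p.prescription_id for p in prescriptions]
    if len(set(presc_ids)) != len(presc_ids):
        raise ValueError("duplicate prescription ids")
    if metabolite_ids is None:
        metabolite_ids = sorted({m for _, m in herb_metab_edges}
                                | {m for m, _ in metab_target_edges})
    if target_ids is None:
        target_ids = sorted({t for _, t in metab_target_edges})

    hmap = {h: i for i, h in enumerate(herb_ids)}
    mmap = {m: i for i, m in enumerate(metabolite_ids)}
    tmap = {t: i for i, t in enumerate(target_ids)}

    dangling = []
    for p in prescriptions:
        dangling += [h for h in p.herb_ids if h not in hmap]
    dangling += [h for h, m in herb_metab_edges if h not in hmap]
    dangling += [m for h, m in herb_metab_edges if m not in mmap]
    dangling += [m for m, t in metab_target_edges if m not in mmap]
    dangling += [t for m, t in metab_target_edges if t not in tmap]
    if dangling:
        raise DanglingIdError(f"unresolvable ids: {sorted(set(dangling))[:10]}")

    g = HeteroGraph()
    g.add_nodes("prescription", presc_ids, np.asarray(features["prescription"]))
    for i, p in enumerate(prescriptions):
        if p.provenance != "original":
            g.provenance["prescription"][i] = p.provenance
    g.add_nodes("herb", herb_ids, np.asarray(features["herb"]))
    g.add_nodes("metabolite", metabolite_ids, np.asarray(features["metabolite"]))
    g.add_nodes("target", target_ids, np.asarray(features["target"]))

    ph_src, ph_dst = [], []
    for i, p in enumerate(prescriptions):
        for h in sorted(set(p.herb_ids)):
            ph_src.append(i)
            ph_dst.append(hmap[h])
    g.add_edges("prescription-herb", "prescription", "herb",
                np.array(ph_src, dtype=np.intp), np.array(ph_dst, dtype=np.intp))
    g.add_edges("herb-metabolite", "herb", "metabolite",
                np.array([hmap[h] for h, _ in herb_metab_edges], dtype=np.intp),
                np.array([mmap[m] for _, m in herb_metab_edges], dtype=np.intp))
    g.add_edges("metabolite-target", "metabolite", "target",
                np.array([mmap[m] for m, _ in metab_target_edges], dtype=np.intp),
                np.array([tmap[t] for _, t in metab_target_edges], dtype=np.intp))
    g.validate()
    return g


def drop_unsequenced(graph: HeteroGraph, molecules: list[MoleculeRecord],
                     targets: list[TargetRecord]) -> tuple[HeteroGraph, dict]:
    """Remove metabolites without parsable SMILES and targets without a
    sequence, together with all their incident edges.

    Returns the cleaned graph (a copy) and a removal report.
    """
    g = graph.copy()
    seq_m = {m.metabolite_id for m in molecules if m.sequenced}
    seq_t = {t.target_id for t in targets if t.sequenced}
    report = {"nodes_removed": {}, "edges_removed": {}}
    for node_type, keepset in (("metabolite", seq_m), ("target", seq_t)):
        drop = {i for i, nid in enumerate(g.node_ids.get(node_type, []))
                if nid not in keepset}
        r = g.remove_nodes(node_type, drop)
        report["nodes_removed"].update(r["nodes_removed"])
        for rel, c in r["edges_removed"].items():
            report["edges_removed"][rel] = report["edges_removed"].get(rel, 0) + c
    g.validate()
    return g, report


def attach_virtual_ecfp(graph: HeteroGraph,
                        molecules: list[MoleculeRecord]) -> HeteroGraph:
    """One virtual fingerprint node per fingerprinted metabolite.

    The virtual node's feature is the metabolite's ECFP bit vector; it is
    connected to its metabolite by a single edge (plus reverse).
    """
    g = graph.copy()
    by_id = {m.metabolite_id: m for m in molecules}
    ids, feats, src = [], [], []
    for i, mid in enumerate(g.node_ids.get("metabolite", [])):
        m = by_id.get(mid)
        if m is not None and m.ecfp is not None:
            ids.append(f"ecfp::{mid}")
            feats.append(m.ecfp)
            src.append(i)
    if not ids:
        return g
    g.add_nodes("ecfp_virtual", ids, np.stack(feats))
    g.add_edges("metabolite-ecfp", "metabolite", "ecfp_virtual",
                np.array(src, dtype=np.intp),
                np.arange(len(ids), dtype=np.intp))
    g.validate()
    return g


def merge_generated(graph: HeteroGraph, synthetic: list, efficacy: str) -> HeteroGraph:
    """Add GAN-generated prescription nodes and their herb edges.

    Only prescription nodes (flagged ``generated``) and prescription-herb
    edges are added; pre-existing nodes and edges are untouched. The label
    table is extended with the generated labels for ``efficacy`` (other
    efficacies zero).
    """
    g = graph.copy()
    if not synthetic:
        return g
    base = g.num_nodes("prescription")
    ids = [f"gen::{efficacy}::{i}" for i in range(len(synthetic))]
    feats = np.stack([s.feature for s in synthetic])
    g.add_nodes("prescription", ids, feats, provenance="generated")
    src, dst = [], []
    for i, s in enumerate(synthetic):
        for h in sorted(s.herb_set):
            src.append(base + i)
            dst.append(h)
    g.add_edges("prescription-herb", "prescription", "herb",
                np.array(src, dtype=np.intp), np.array(dst, dtype=np.intp))
    if g.labels is not None:
        col = g.labels.efficacies.index(efficacy)
        extra = np.zeros((len(synthetic), len(g.labels.efficacies)), dtype=np.int64)
        extra[:, col] = [s.label for s in synthetic]
        g.labels = EfficacyLabelTable(
            np.vstack([g.labels.matrix, extra]),
            list(g.labels.efficacies),
            list(g.labels.prescription_ids) + ids,
        )
    g.validate()
    return g


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_graph(graph: HeteroGraph, out_dir) -> None:
    """Write nodes/edges as TSV, features as .npz, plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"node_types": [], "relations": []}
    for t, ids in graph.node_ids.items():
        pd.DataFrame({"node_id": ids, "provenance": graph.provenance[t]}).to_csv(
            out / f"nodes_{t}.tsv", sep="\t", index=False)
        manifest["node_types"].append(t)
    np.savez(out / "features.npz",
             **{t: graph.features[t] for t in graph.features})
    for rel, (s, d) in graph.edges.items():
        st, dt = graph.relation_types[rel]
        pd.DataFrame({"src": s, "dst": d}).to_csv(
            out / f"edges_{rel}.tsv", sep="\t", index=False)
        manifest["relations"].append({"name": rel, "src_type": st, "dst_type": dt})
    if graph.labels is not None:
        pd.DataFrame(graph.labels.matrix, columns=graph.labels.efficacies,
                     index=graph.labels.prescription_ids).to_csv(
            out / "labels.csv", index_label="prescription_id")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_graph(in_dir) -> HeteroGraph:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    feats = np.load(src / "features.npz")
    g = HeteroGraph()
    for t in manifest["node_types"]:
        df = pd.read_csv(src / f"nodes_{t}.tsv", sep="\t", dtype=str)
        g.node_ids[t] = df["node_id"].tolist()
        g.provenance[t] = df["provenance"].tolist()
        if t in feats:
            g.features[t] = feats[t]
    for rel in manifest["relations"]:
        df = pd.read_csv(src / f"edges_{rel['name']}.tsv", sep="\t")
        g.edges[rel["name"]] = (df["src"].to_numpy(dtype=np.intp),
                                df["dst"].to_numpy(dtype=np.intp))
        g.relation_types[rel["name"]] = (rel["src_type"], rel["dst_type"])
    labels_path = src / "labels.csv"
    if labels_path.exists():
        df = pd.read_csv(labels_path, index_col="prescription_id")
        g.labels = EfficacyLabelTable(df.to_numpy(), list(df.columns),
                                      [str(i) for i in df.index])
    g.validate()
    return g


def to_graphml(graph: HeteroGraph, path) -> None:
    """Export node/edge structure (no features) for visualization."""
    import networkx as nx

    G = nx.MultiDiGraph()
    for t, ids in graph.node_ids.items():
        for nid in ids:
            G.add_node(f"{t}::{nid}", node_type=t)
    for rel, (s, d) in graph.edges.items():
        st, dt = graph.relation_types[rel]
        for a, b in zip(s, d):
            G.add_edge(f"{st}::{graph.node_ids[st][a]}",
                       f"{dt}::{graph.node_ids[dt][b]}", relation=rel)
    nx.write_graphml(G, path)


def load_forbidden_pairs(path) -> list[tuple]:
    df = pd.read_csv(path, dtype=str)
    return [(a, b) for a, b in zip(df["herb_id_a"], df["herb_id_b"])]
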