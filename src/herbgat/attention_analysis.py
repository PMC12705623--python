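"""Post-training attention extraction on herb-metabolite edges.

After training, each edge of a chosen relation carries per-layer, per-head
attention weights. For interpretation these are reduced (default: mean
over heads at the final layer), binned on [0, 1] in steps of 0.1, and the
top edges of each bin exported as TSV or GraphML.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hetgraph import HeteroGraph
from .rgat import AttentionTrace, GraphTensors


@dataclass(frozen=True)
class WeightedEdge:
    source: str
    destination: str
    relation: str
    weight: float

    def __post_init__(self):
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"weight {self.weight} outside [0, 1]")


def extract_relation_attention(
    trace: AttentionTrace,
    gt: GraphTensors,
    graph: HeteroGraph,
    relation: str = "metabolite-herb",
    reduction: str = "mean",
    layer: int = -1,
    kind: str = "alpha",
) -> list[WeightedEdge]:
    """One weight per edge of ``relation``: head-reduced attention at the
    chosen layer. ``kind`` selects neighborhood attention ("alpha") or
    relation attention ("beta")."""
    if relation not in trace.relation_names:
        raise ValueError(f"relation {relation!r} absent from trace")
    rid = trace.relation_names.index(relation)
    mask = trace.rel == rid
    if not mask.any():
        raise ValueError(f"relation {relation!r} has no edges")
    W = (trace.alpha if kind == "alpha" else trace.beta)[layer][mask]
    if reduction == "mean":
        w = W.mean(axis=1)
    elif reduction == "max":
        w = W.max(axis=1)
    else:
        raise ValueError(f"unknown reduction {reduction!r}")

    ids, types = [], []
    for t in gt.node_types:
        ids += list(graph.node_ids[t])
        types += [t] * graph.num_nodes(t)
    out = []
    for e, weight in zip(np.flatnonzero(mask), w):
        out.append(WeightedEdge(ids[gt.src[e]], ids[gt.dst[e]], relation,
                                float(np.clip(weight, 0.0, 1.0))))
    return out


def bin_top_edges(edges: list[WeightedEdge], bin_width: float = 0.1,
                  top_n: int = 5) -> list[WeightedEdge]:
    """Partition [0,1] into half-open bins of ``bin_width`` (last bin
    closed at 1.0) and keep the ``top_n`` heaviest edges per non-empty
    bin, ties broken by source id order."""
    n_bins = int(round(1.0 / bin_width))
    for e in edges:
        if not (0.0 <= e.weight <= 1.0):
            raise ValueError(f"weight {e.weight} outside [0, 1]")
    selected = []
    for b in range(n_bins):
        lo, hi = b * bin_width, (b + 1) * bin_width
        if b == n_bins - 1:
            members = [e for e in edges if lo <= e.weight <= hi]
        else:
            members = [e for e in edges if lo <= e.weight < hi]
        members.sort(key=lambda e: (-e.weight, e.source, e.destination))
        selected.extend(members[:top_n])
    return selected


def export_attention(edges: list[WeightedEdge], path,
                     format: str = "tsv") -> None:
    """Write edges as TSV (src,dst,relation,weight) or GraphML."""
    path = Path(path)
    if format == "tsv":
        pd.DataFrame(
            [(e.source, e.destination, e.relation, f"{e.weight:.6f}")
             for e in edges],
            columns=["src", "dst", "relation", "weight"],
        ).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        import networkx as nx

        G = nx.DiGraph()
        for e in edges:
            G.add_edge(e.source, e.destination, relation=e.relation,
                       weight=round(e.weight, 6))
        nx.write_graphml(G, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_attention_tsv(path) -> list[WeightedEdge]:
    df = pd.read_csv(path, sep="\t", dtype={"src": str, "dst": str})
    return [WeightedEdge(r["src"], r["dst"], r["relation"], float(r["weight"]))
            for _, r in df.iterrows()]
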