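"""Relational graph attention message passing.

Each layer combines two aggregations over a node's in-neighborhood:

* multi-head scaled dot-product attention over neighbor features
  (per head: alpha = softmax(q_i . k_j / sqrt(d_k)) over j in N(i),
  message = sum_j alpha_ij W_k h_j, heads concatenated), and
* relation attention: each relation type owns a learned embedding r; a
  two-layer transform g = sigmoid(relu(r W1 + b1) W2 + b2) scores every
  edge by its relation, beta = softmax(g) over the neighborhood, and the
  beta-weighted transformed neighbor features are concatenated over M
  relation heads.

The two aggregates are concatenated and passed through a relu-activated
dense projection. Self-loop edges with their own "self" relation are added
so isolated nodes remain defined. Node types enter through per-type linear
input projections to the common hidden width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import (
    Linear,
    Tensor,
    concat,
    gather_rows,
    segment_softmax,
    segment_sum,
)
from .hetgraph import HeteroGraph

SELF_RELATION = "self"


@dataclass
class RgatConfig:
    num_layers: int = 2
    hidden_dim: int = 512
    attention_heads: int = 4
    relation_heads: int = 4
    relation_dim: int = 32
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if self.hidden_dim % self.attention_heads:
            raise ValueError("hidden_dim must be divisible by attention_heads")
        if self.hidden_dim % self.relation_heads:
            raise ValueError("hidden_dim must be divisible by relation_heads")


@dataclass
class GraphTensors:
    """Flattened view of a heterogeneous graph for message passing.

    Nodes of all types share one global index space (grouped by type);
    edges are concatenated with integer relation ids; a self-loop edge with
    its own relation is appended for every node.
    """

    node_types: list
    type_of: np.ndarray          # (N,) type index per node
    type_slices: dict            # type -> slice in global index space
    features: dict               # type -> (n_t, d_t)
    src: np.ndarray              # (E,)
    dst: np.ndarray              # (E,)
    rel: np.ndarray              # (E,) relation ids
    relation_names: list

    @property
    def num_nodes(self) -> int:
        return len(self.type_of)

    @classmethod
    def from_graph(cls, graph: HeteroGraph, drop_relations: tuple = ()) -> "GraphTensors":
        node_types = [t for t in graph.node_ids if graph.num_nodes(t) > 0]
        offsets, off = {}, 0
        type_of = []
        for ti, t in enumerate(node_types):
            n = graph.num_nodes(t)
            offsets[t] = off
            type_of += [ti] * n
            off += n
        relation_names = sorted(r for r in graph.edges if r not in drop_relations)
        src_all, dst_all, rel_all = [], [], []
        for ri, rel in enumerate(relation_names):
            st, dt = graph.relation_types[rel]
            if st not in offsets or dt not in offsets:
                continue
            s, d = graph.edges[rel]
            src_all.append(s + offsets[st])
            dst_all.append(d + offsets[dt])
            rel_all.append(np.full(len(s), ri, dtype=np.intp))
        # self-loops for every node, with a dedicated relation type
        n_total = off
        relation_names = relation_names + [SELF_RELATION]
        src_all.append(np.arange(n_total, dtype=np.intp))
        dst_all.append(np.arange(n_total, dtype=np.intp))
        rel_all.append(np.full(n_total, len(relation_names) - 1, dtype=np.intp))
        return cls(
            node_types=node_types,
            type_of=np.array(type_of, dtype=np.intp),
            type_slices={t: slice(offsets[t], offsets[t] + graph.num_nodes(t))
                         for t in node_types},
            features={t: np.asarray(graph.features[t], dtype=np.float64)
                      for t in node_types},
            src=np.concatenate(src_all),
            dst=np.concatenate(dst_all),
            rel=np.concatenate(rel_all),
            relation_names=relation_names,
        )


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Dense softmax(QK^T / sqrt(d_k)) V."""
    Q, K, V = (np.asarray(x, dtype=np.float64) for x in (Q, K, V))
    d_k = Q.shape[1]
    if d_k == 0:
        raise ValueError("key dimension must be positive")
    S = Q @ K.T / np.sqrt(d_k)
    S = S - S.max(axis=1, keepdims=True)
    W = np.exp(S)
    W /= W.sum(axis=1, keepdims=True)
    return W @ V


class RgatLayer:
    """One round of node attention + relation attention + projection."""

    def __init__(self, hidden: int, K: int, M: int, relation_dim: int,
                 n_relations: int, rng: np.random.Generator):
        self.K, self.M = K, M
        self.hidden = hidden
        d_head, d_rhead = hidden // K, hidden // M
        # heads live in column blocks of fused (hidden -> hidden) transforms:
        # block k of self.q is head k's query projection, etc.
        self.q = Linear(hidden, hidden, rng, bias=False)
        self.k = Linear(hidden, hidden, rng, bias=False)
        self.v = Linear(hidden, hidden, rng, bias=False)
        self.rel_emb = Tensor(rng.normal(0.0, 1.0, size=(n_relations, relation_dim)))
        self.rel_w1 = [Linear(relation_dim, relation_dim, rng) for _ in range(M)]
        self.rel_w2 = [Linear(relation_dim, 1, rng) for _ in range(M)]
        self.rel_v = Linear(hidden, hidden, rng, bias=False)
        self.out = Linear(2 * hidden, hidden, rng)
        self.d_head, self.d_rhead = d_head, d_rhead

    def parameters(self) -> list:
        ps = [self.rel_emb] + self.out.parameters()
        for mod in (self.q, self.k, self.v, self.rel_v):
            ps += mod.parameters()
        for mods in (self.rel_w1, self.rel_w2):
            for m in mods:
                ps += m.parameters()
        return ps

    def node_attention(self, H: Tensor, src, dst, n_nodes):
        """Multi-head neighborhood attention; returns (h_att, alphas).

        Per head k: alpha_ij = softmax_j(q_i . k_j / sqrt(d_head)) over the
        in-neighborhood of i, message = sum_j alpha_ij v_j; head outputs are
        concatenated (adjacent column blocks of the fused transforms).
        """
        E = len(src)
        q = gather_rows(self.q(H), dst)                 # (E, hidden)
        key = gather_rows(self.k(H), src)
        score = (q * key).reshape(E, self.K, self.d_head).sum(axis=2) \
            * (1.0 / np.sqrt(self.d_head))              # (E, K)
        alpha = segment_softmax(score, dst, n_nodes)    # (E, K)
        val = gather_rows(self.v(H), src).reshape(E, self.K, self.d_head)
        msg = val * alpha.reshape(E, self.K, 1)
        agg = segment_sum(msg, dst, n_nodes).reshape(n_nodes, self.hidden)
        return agg, alpha.data.copy()

    def relation_attention(self, H: Tensor, src, dst, rel, n_nodes):
        """Relation-embedding attention; returns (h_rel, betas).

        Per relation head m: g = sigmoid(relu(r W1 + b1) W2 + b2) scores each
        relation type, beta = softmax of g over the neighborhood, and the
        beta-weighted value-transformed neighbors are aggregated.
        """
        E = len(src)
        g_types = concat(
            [self.rel_w2[m](self.rel_w1[m](self.rel_emb).relu()).sigmoid()
             for m in range(self.M)], axis=1)           # (n_relations, M)
        g = gather_rows(g_types, rel)                   # (E, M)
        beta = segment_softmax(g, dst, n_nodes)         # (E, M)
        val = gather_rows(self.rel_v(H), src).reshape(E, self.M, self.d_rhead)
        msg = val * beta.reshape(E, self.M, 1)
        agg = segment_sum(msg, dst, n_nodes).reshape(n_nodes, self.hidden)
        return agg, beta.data.copy()

    def __call__(self, H: Tensor, src, dst, rel, n_nodes):
        h_att, alphas = self.node_attention(H, src, dst, n_nodes)
        h_rel, betas = self.relation_attention(H, src, dst, rel, n_nodes)
        x = concat([h_att, h_rel], axis=1)
        h_new = self.out(x).relu()
        if not np.all(np.isfinite(h_new.data)):
            bad = np.argwhere(~np.isfinite(h_new.data))[:3]
            raise FloatingPointError(f"non-finite layer output at {bad.tolist()}")
        return h_new, alphas, betas


@dataclass
class AttentionTrace:
    """All attention weights of a forward pass, edge-aligned arrays."""

    src: np.ndarray
    dst: np.ndarray
    rel: np.ndarray
    relation_names: list
    alpha: list = field(default_factory=list)   # per layer (E, K)
    beta: list = field(default_factory=list)    # per layer (E, M)


class RgatModel:
    """Per-type input projections + stacked relational attention layers."""

    def __init__(self, config: RgatConfig, input_dims: dict, relation_names: list):
        self.config = config
        self.relation_names = list(relation_names)
        rng = np.random.default_rng(config.seed)
        h = config.hidden_dim
        self.proj = {t: Linear(d, h, rng, bias=False) for t, d in input_dims.items()}
        self.layers = [
            RgatLayer(h, config.attention_heads, config.relation_heads,
                      config.relation_dim, len(relation_names), rng)
            for _ in range(config.num_layers)
        ]

    def parameters(self) -> list:
        ps = []
        for p in self.proj.values():
            ps += p.parameters()
        for layer in self.layers:
            ps += layer.parameters()
        return ps

    def project_inputs(self, gt: GraphTensors) -> Tensor:
        """Per-type linear projection to the common hidden width, assembled
        into one (N, hidden) matrix in global node order."""
        blocks = []
        for t in gt.node_types:
            if t not in self.proj:
                raise KeyError(f"unknown node type: {t}")
            blocks.append(self.proj[t](Tensor(gt.features[t], requires_grad=False)))
        return _vstack(blocks)

    def forward(self, gt: GraphTensors) -> tuple[Tensor, AttentionTrace]:
        """Full message passing; returns final representations and the
        attention trace for later analysis."""
        rel_ids = _remap_relations(gt.relation_names, self.relation_names, gt.rel)
        H = self.project_inputs(gt)
        trace = AttentionTrace(gt.src.copy(), gt.dst.copy(), gt.rel.copy(),
                               list(gt.relation_names))
        for layer in self.layers:
            H, alphas, betas = layer(H, gt.src, gt.dst, rel_ids, gt.num_nodes)
            trace.alpha.append(alphas)
            trace.beta.append(betas)
        return H, trace

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        arrays, meta = {}, {"config": asdict(self.config),
                            "relation_names": self.relation_names,
                            "input_dims": {t: p.W.data.shape[0]
                                           for t, p in self.proj.items()}}
        for name, p in self._named_parameters():
            arrays[name] = p.data
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "RgatModel":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(RgatConfig(**meta["config"]), meta["input_dims"],
                    meta["relation_names"])
        for name, p in model._named_parameters():
            p.data = data[name]
        return model

    def _named_parameters(self):
        for t, p in sorted(self.proj.items()):
            yield f"proj.{t}.W", p.W
        for li, layer in enumerate(self.layers):
            for i, p in enumerate(layer.parameters()):
                yield f"layer{li}.p{i}", p


def _vstack(blocks: list) -> Tensor:
    datas = [b.data for b in blocks]
    out = Tensor(np.vstack(datas), _prev=tuple(blocks))
    sizes = np.cumsum([0] + [d.shape[0] for d in datas])

    def back():
        for b, lo, hi in zip(blocks, sizes[:-1], sizes[1:]):
            b._accum(out.grad[lo:hi])

    out._backward = back
    return out


def _remap_relations(graph_names: list, model_names: list, rel: np.ndarray) -> np.ndarray:
    if graph_names == model_names:
        return rel
    mapping = np.array([model_names.index(n) for n in graph_names], dtype=np.intp)
    return mapping[rel]


def save_attention_tsv(trace: AttentionTrace, gt: GraphTensors,
                       graph: HeteroGraph, path) -> None:
    """Flat TSV of every attention weight: src,dst,relation,layer,head,weight."""
    import pandas as pd

    global_ids, global_types = [], []
    for t in gt.node_types:
        global_ids += list(graph.node_ids[t])
        global_types += [t] * graph.num_nodes(t)
    rows = []
    for li, (alpha, beta) in enumerate(zip(trace.alpha, trace.beta)):
        for kind, W in (("alpha", alpha), ("beta", beta)):
            for h in range(W.shape[1]):
                for e in range(len(trace.src)):
                    rows.append((
                        global_ids[trace.src[e]], global_ids[trace.dst[e]],
                        trace.relation_names[trace.rel[e]], li, kind, h,
                        W[e, h]))
    pd.DataFrame(rows, columns=["src", "dst", "relation", "layer", "kind",
                                "head", "weight"]).to_csv(path, sep="\t",
                                                          index=False)
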