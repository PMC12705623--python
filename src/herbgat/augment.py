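"""GAN-based generation of synthetic prescription nodes.

For an under-represented efficacy stratum, a small generator/discriminator
pair is trained on the real prescriptions of that stratum, each encoded as
the concatenation of its standardized attribute feature and its binary
prescription-herb adjacency row. The trained generator emits (label,
feature, soft adjacency) triples; the soft adjacency row is binarized to a
herb set, and any generated prescription containing a classically
forbidden herb pair (Eighteen Incompatibles / Nineteen Antagonisms style
tables) is pruned before the survivors are merged into the network.

The discriminator maximizes log D(x) + log(1 - D(G(z))); the generator
update uses the standard non-saturating form (maximize log D(G(z))).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Linear, Tensor

_EPS = 1e-7


@dataclass
class GanConfig:
    noise_dim: int = 64
    hidden_dim: int = 128
    lr_discriminator: float = 1e-5
    lr_ratio: float = 30.0
    epochs: int = 400
    batch_size: int = 64
    per_class_counts: dict = field(default_factory=dict)  # efficacy -> count
    # ("topk", None): per-record k drawn from the empirical
    # herbs-per-prescription counts; alternatives ("topk", k) and
    # ("threshold", theta)
    binarization: tuple = ("topk", None)
    seed: int = 0

    def __post_init__(self):
        if self.lr_ratio <= 0:
            raise ValueError("lr_ratio must be > 0")
        if any(c < 0 for c in self.per_class_counts.values()):
            raise ValueError("per-class counts must be >= 0")

    @property
    def lr_generator(self) -> float:
        return self.lr_ratio * self.lr_discriminator

    def count_for(self, efficacy: str, severe: bool = True) -> int:
        """Requested generation count; defaults mirror severe (4000) vs
        mild (2000) imbalance."""
        if efficacy in self.per_class_counts:
            return self.per_class_counts[efficacy]
        return 4000 if severe else 2000


@dataclass
class SyntheticPrescription:
    label: int
    feature: np.ndarray
    soft_adjacency: np.ndarray
    herb_set: frozenset

    def __post_init__(self):
        if len(self.herb_set) == 0:
            raise ValueError("binarized herb set must be non-empty")


@dataclass
class ForbiddenPairTable:
    pairs: list  # unordered (herb_id_a, herb_id_b)


class _Mlp:
    def __init__(self, dims: list, rng, final: str):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.final = final

    def __call__(self, x: Tensor) -> Tensor:
        for lay in self.layers[:-1]:
            x = lay(x).relu()
        x = self.layers[-1](x)
        if self.final == "sigmoid":
            x = x.sigmoid()
        return x

    def parameters(self) -> list:
        return [p for lay in self.layers for p in lay.parameters()]


@dataclass
class GanState:
    generator: _Mlp
    discriminator: _Mlp
    feature_dim: int
    adj_dim: int
    config: GanConfig
    losses: list = field(default_factory=list)  # (d_loss, g_loss) per epoch


def _bce(pred: Tensor, target: float) -> Tensor:
    p = pred.clip(_EPS, 1.0 - _EPS)
    if target == 1.0:
        return -(p.log().mean())
    return -((1.0 - p).log().mean())


def train_gan(features: np.ndarray, adjacency: np.ndarray,
              config: GanConfig) -> GanState:
    """Adversarial training on one stratum's real prescriptions.

    ``features`` is (n, d_f); ``adjacency`` is (n, d_a) with d_a >= 0
    (zero-width adjacency supports plain tabular experiments). The
    generator's feature block has a linear head (standardized features are
    unbounded); the adjacency block passes through a sigmoid into [0, 1].
    Deterministic given ``config.seed``.
    """
    features = np.asarray(features, dtype=np.float64)
    adjacency = np.asarray(adjacency, dtype=np.float64)
    if features.ndim != 2 or len(features) == 0:
        raise ValueError("empty real data")
    if len(adjacency) != len(features):
        raise ValueError("feature/adjacency row mismatch")
    d_f, d_a = features.shape[1], adjacency.shape[1] if adjacency.size else 0
    X = np.hstack([features, adjacency]) if d_a else features

    rng = np.random.default_rng(config.seed)
    gen = _Mlp([config.noise_dim, config.hidden_dim, d_f + d_a], rng, final="linear")
    disc = _Mlp([d_f + d_a, config.hidden_dim, 1], rng, final="sigmoid")
    state = GanState(gen, disc, d_f, d_a, config)
    if config.epochs == 0:
        return state

    opt_d = Adam(disc.parameters(), lr=config.lr_discriminator)
    opt_g = Adam(gen.parameters(), lr=config.lr_generator)
    n = len(X)
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        idx = rng.choice(n, size=bs, replace=False)
        real = Tensor(X[idx], requires_grad=False)
        z = Tensor(rng.standard_normal((bs, config.noise_dim)), requires_grad=False)
        fake = _split_heads(gen(z), d_f, d_a)

        d_loss = _bce(disc(real), 1.0) + _bce(disc(_const(fake)), 0.0)
        opt_d.zero_grad()
        d_loss.backward()
        opt_d.step()

        z2 = Tensor(rng.standard_normal((bs, config.noise_dim)), requires_grad=False)
        fake2 = _split_heads(gen(z2), d_f, d_a)
        g_loss = _bce(disc(fake2), 1.0)
        opt_g.zero_grad()
        g_loss.backward()
        opt_g.step()

        dl, gl = float(d_loss.data), float(g_loss.data)
        if not (np.isfinite(dl) and np.isfinite(gl)):
            raise RuntimeError(
                f"NaN/inf GAN loss at epoch {epoch}: d={dl} g={gl}, "
                f"last batch indices {idx[:8].tolist()}")
        state.losses.append((dl, gl))
    return state


def _split_heads(raw: Tensor, d_f: int, d_a: int) -> Tensor:
    if d_a == 0:
        return raw
    from ._autodiff import concat

    feat = _slice_cols(raw, 0, d_f)
    adj = _slice_cols(raw, d_f, d_f + d_a).sigmoid()
    return concat([feat, adj], axis=1)


def _slice_cols(t: Tensor, lo: int, hi: int) -> Tensor:
    out = Tensor(t.data[:, lo:hi], _prev=(t,))

    def back():
        g = np.zeros_like(t.data)
        g[:, lo:hi] = out.grad
        t._accum(g)

    out._backward = back
    return out


def _const(t: Tensor) -> Tensor:
    return Tensor(t.data.copy(), requires_grad=False)


def sample_gan(state: GanState, count: int, rng: np.random.Generator) -> np.ndarray:
    z = Tensor(rng.standard_normal((count, state.config.noise_dim)),
               requires_grad=False)
    return _split_heads(state.generator(z), state.feature_dim, state.adj_dim).data


def binarize_adjacency(soft_row: np.ndarray, rule: tuple) -> frozenset:
    """Turn a soft adjacency row into a herb index set.

    ``("threshold", theta)`` keeps indices with value > theta;
    ``("topk", k)`` keeps the k largest. An empty result falls back to the
    argmax (first index on ties).
    """
    soft_row = np.asarray(soft_row, dtype=np.float64)
    if soft_row.min() < 0 or soft_row.max() > 1:
        raise ValueError("soft adjacency entries must lie in [0, 1]")
    kind, param = rule
    if kind == "threshold":
        idx = np.flatnonzero(soft_row > param)
    elif kind == "topk":
        k = min(int(param), len(soft_row))
        order = np.argsort(-soft_row, kind="stable")
        idx = order[:k]
    else:
        raise ValueError(f"unknown binarization rule: {kind!r}")
    if len(idx) == 0:
        idx = np.array([int(np.argmax(soft_row))])
    return frozenset(int(i) for i in idx)


def generate_prescriptions(state: GanState, efficacy: str, label: int,
                           count: int, binarization: tuple | None = None,
                           herbs_per_prescription: np.ndarray | None = None,
                           seed: int | None = None) -> list[SyntheticPrescription]:
    """Draw ``count`` synthetic prescriptions from a trained generator.

    With a ``("topk", None)`` rule, per-record k is drawn from the
    empirical herbs-per-prescription counts of the real data
    (``herbs_per_prescription``).
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    rule = binarization if binarization is not None else state.config.binarization
    rng = np.random.default_rng(state.config.seed + 1 if seed is None else seed)
    raw = sample_gan(state, count, rng) if count else np.empty((0, 0))
    out = []
    for i in range(count):
        feat = raw[i, :state.feature_dim]
        soft = raw[i, state.feature_dim:]
        r = rule
        if r[0] == "topk" and r[1] is None:
            if herbs_per_prescription is None:
                raise ValueError("topk rule without k needs empirical counts")
            r = ("topk", int(rng.choice(herbs_per_prescription)))
        herb_set = binarize_adjacency(soft, r)
        out.append(SyntheticPrescription(label=label, feature=feat.copy(),
                                         soft_adjacency=soft.copy(),
                                         herb_set=herb_set))
    return out


def prune_incompatible(items: list[SyntheticPrescription],
                       pairs: ForbiddenPairTable,
                       herb_ids: list) -> tuple[list, int]:
    """Drop generated prescriptions containing any forbidden herb pair.

    Pairs are unordered; a pair naming an unknown herb id is skipped with
    a warning. Returns (kept, removed_count).
    """
    idx_of = {h: i for i, h in enumerate(herb_ids)}
    checked = []
    for a, b in pairs.pairs:
        if a not in idx_of or b not in idx_of:
            warnings.warn(f"forbidden pair ({a}, {b}) references unknown herb; skipped",
                          stacklevel=2)
            continue
        checked.append((idx_of[a], idx_of[b]))
    kept = []
    removed = 0
    for item in items:
        hs = item.herb_set
        if any(a in hs and b in hs for a, b in checked):
            removed += 1
        else:
            kept.append(item)
    return kept, removed


def augment_stratum(features: np.ndarray, adjacency: np.ndarray,
                    efficacy: str, label: int, count: int,
                    config: GanConfig, forbidden: ForbiddenPairTable,
                    herb_ids: list) -> tuple[list, dict]:
    """Train-generate-prune pipeline for one stratum.

    Pruning shortfalls are accepted (not regenerated) and reported.
    """
    state = train_gan(features, adjacency, config)
    hpp = adjacency.sum(axis=1).astype(int) if adjacency.size else None
    items = generate_prescriptions(state, efficacy, label, count,
                                   herbs_per_prescription=hpp)
    kept, removed = prune_incompatible(items, forbidden, herb_ids)
    report = {"requested": count, "pruned": removed, "kept": len(kept),
              "final_d_loss": state.losses[-1][0] if state.losses else None}
    return kept, report
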