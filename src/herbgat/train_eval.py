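"""Training, cross-validated evaluation, and ablation variants.

One binary classifier per efficacy: relational graph attention produces a
representation for every prescription node; the head layer-normalizes it,
maps to two logits and applies softmax; binary cross-entropy on the
positive-class probability is the training loss.

Evaluation follows a rotating 10-fold protocol with an 8:1:1
train/validation/test split: stratified folds, test fold t, validation
fold (t+1) mod folds, the remaining eight folds train. GAN augmentation,
when enabled, is fitted on the training folds only and generated nodes
never enter validation or test metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from ._autodiff import Adam, Linear, Tensor, gather_rows, softmax
from .augment import ForbiddenPairTable, GanConfig, augment_stratum
from .hetgraph import HeteroGraph, merge_generated
from .pipeline import AssembledData
from .rgat import GraphTensors, RgatConfig, RgatModel

_EPS = 1e-7

VARIANTS = ("full", "R", "E", "H", "S")


@dataclass
class TrainConfig:
    efficacy: str
    folds: int = 10
    epochs: int = 150
    lr: float = 1e-3
    patience: int = 20
    seed: int = 0
    augmentation: bool = False
    gan: GanConfig = field(default_factory=GanConfig)
    aug_count: int | None = None     # None: generate up to class balance
    variant: str = "full"
    rgat: RgatConfig = field(default_factory=RgatConfig)
    max_herbs: int = 20              # H-variant concatenation width

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class MetricsReport:
    per_fold: pd.DataFrame          # one row per fold
    efficacy: str
    variant: str = "full"

    METRICS = ("auc", "aupr", "accuracy", "recall", "precision", "f1")

    def mean(self, metric: str) -> float:
        return float(self.per_fold[metric].mean())

    def sd(self, metric: str) -> float:
        return float(self.per_fold[metric].std(ddof=1))

    def summary(self) -> dict:
        return {m: (self.mean(m), self.sd(m)) for m in self.METRICS}

    def to_csv(self, path) -> None:
        """Fold rows plus a summary row formatted as 'mean (sd)'."""
        df = self.per_fold.copy()
        summary = {"fold": "mean (sd)"}
        for m in self.METRICS:
            summary[m] = f"{self.mean(m):.3f} ({self.sd(m):.3f})"
        out = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Head, loss, metrics
# ---------------------------------------------------------------------------


class PredictionHead:
    """LayerNorm -> linear -> softmax over two classes."""

    def __init__(self, hidden: int, rng: np.random.Generator):
        self.gamma = Tensor(np.ones(hidden))
        self.beta = Tensor(np.zeros(hidden))
        self.lin = Linear(hidden, 2, rng)

    def __call__(self, R: Tensor) -> Tensor:
        mu = R.mean(axis=1, keepdims=True)
        d = R - mu
        var = (d * d).mean(axis=1, keepdims=True)
        xn = d / (var + 1e-6).sqrt()
        logits = self.lin(xn * self.gamma + self.beta)
        return softmax(logits, axis=1)

    def parameters(self) -> list:
        return [self.gamma, self.beta] + self.lin.parameters()


def predict_head(R: np.ndarray, head: PredictionHead | None = None,
                 seed: int = 0) -> np.ndarray:
    """Per-prescription class probabilities from representations."""
    if head is None:
        head = PredictionHead(np.asarray(R).shape[1], np.random.default_rng(seed))
    return head(Tensor(np.asarray(R), requires_grad=False)).data


def classify(probs: np.ndarray) -> np.ndarray:
    """Argmax over (negative, positive); exact ties break to negative."""
    probs = np.asarray(probs)
    return (probs[:, 1] > probs[:, 0]).astype(int)


def bce_loss(y, x) -> float:
    """Binary cross-entropy of positive-class probability x against label y,
    clamped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=np.float64)
    x = np.clip(np.asarray(x, dtype=np.float64), _EPS, 1 - _EPS)
    return float(np.mean(-(1 - y) * np.log(1 - x) - y * np.log(x)))


def _bce_t(y: np.ndarray, p_pos: Tensor) -> Tensor:
    p = p_pos.clip(_EPS, 1 - _EPS)
    yt = Tensor(np.asarray(y, dtype=np.float64).reshape(-1, 1), requires_grad=False)
    return -(yt * p.log() + (1.0 - yt) * (1.0 - p).log()).mean()


def evaluate(y_true, scores, threshold: float = 0.5) -> dict:
    """AUC/AUPR from scores; thresholded metrics at 0.5."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    pred = (scores > threshold).astype(int)
    single_class = len(np.unique(y_true)) < 2
    return {
        "auc": 0.5 if single_class else float(roc_auc_score(y_true, scores)),
        "aupr": float(y_true.mean()) if single_class
        else float(average_precision_score(y_true, scores)),
        "accuracy": float(accuracy_score(y_true, pred)),
        "recall": float(recall_score(y_true, pred, zero_division=0)),
        "precision": float(precision_score(y_true, pred, zero_division=0)),
        "f1": float(f1_score(y_true, pred, zero_division=0)),
    }


# ---------------------------------------------------------------------------
# Single training run
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    model: RgatModel
    head: PredictionHead
    scores: np.ndarray       # positive-class probability per prescription
    trace: object            # AttentionTrace of the final forward pass
    history: dict


def fit(graph: HeteroGraph, y: np.ndarray, train_idx, val_idx,
        config: TrainConfig, drop_relations: tuple = ()) -> FitResult:
    """Full-batch training with early stopping on validation AUC."""
    gt = GraphTensors.from_graph(graph, drop_relations=drop_relations)
    input_dims = {t: gt.features[t].shape[1] for t in gt.node_types}
    model = RgatModel(config.rgat, input_dims, gt.relation_names)
    rng = np.random.default_rng(config.seed + 1)
    head = PredictionHead(config.rgat.hidden_dim, rng)
    params = model.parameters() + head.parameters()
    opt = Adam(params, lr=config.lr)

    presc = gt.type_slices["prescription"]
    presc_idx = np.arange(presc.start, presc.stop)
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)

    best_auc, best_state, since_best = -np.inf, None, 0
    history = {"train_loss": [], "val_auc": []}
    for epoch in range(config.epochs):
        opt.zero_grad()
        H, trace = model.forward(gt)
        probs = head(gather_rows(H, presc_idx))
        p_pos = _slice_col(probs, 1)
        loss = _bce_t(y[train_idx], gather_rows(p_pos, train_idx))
        loss.backward()
        opt.step()
        history["train_loss"].append(float(loss.data))

        val_scores = p_pos.data[val_idx, 0]
        val_auc = (roc_auc_score(y[val_idx], val_scores)
                   if len(np.unique(y[val_idx])) > 1 else 0.5)
        history["val_auc"].append(float(val_auc))
        if val_auc > best_auc + 1e-6:
            best_auc, since_best = val_auc, 0
            best_state = [p.data.copy() for p in params]
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        for p, s in zip(params, best_state):
            p.data = s
    H, trace = model.forward(gt)
    probs = head(gather_rows(Tensor(H.data, requires_grad=False), presc_idx))
    return FitResult(model, head, probs.data[:, 1].copy(), trace, history)


def _slice_col(t: Tensor, col: int) -> Tensor:
    out = Tensor(t.data[:, col:col + 1], _prev=(t,))

    def back():
        g = np.zeros_like(t.data)
        g[:, col:col + 1] = out.grad
        t._accum(g)

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def make_folds(y: np.ndarray, folds: int, seed: int) -> list:
    """Stratified fold memberships (list of index arrays)."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def _augmented_training_graph(graph: HeteroGraph, y: np.ndarray,
                              train_idx: np.ndarray, config: TrainConfig,
                              forbidden: ForbiddenPairTable):
    """Fit the GAN on training-fold data only and merge generated nodes."""
    herb_ids = graph.node_ids["herb"]
    n_herbs = len(herb_ids)
    n_presc = graph.num_nodes("prescription")
    adj = np.zeros((n_presc, n_herbs))
    s, d = graph.edges["prescription-herb"]
    adj[s, d] = 1.0
    y_tr = y[train_idx]
    n_pos, n_neg = int(y_tr.sum()), int(len(y_tr) - y_tr.sum())
    minority = 1 if n_pos <= n_neg else 0
    count = config.aug_count
    if count is None:
        count = abs(n_neg - n_pos)
    stratum = train_idx[y_tr == minority]
    feats = graph.features["prescription"][stratum]
    items, report = augment_stratum(
        feats, adj[stratum], config.efficacy, minority, count,
        config.gan, forbidden, herb_ids)
    g_aug = merge_generated(graph, items, config.efficacy)
    gen_idx = np.arange(n_presc, n_presc + len(items))
    y_aug = np.concatenate([y, np.full(len(items), minority, dtype=y.dtype)])
    return g_aug, y_aug, np.concatenate([train_idx, gen_idx]), report


def crossvalidate(graph: HeteroGraph, config: TrainConfig,
                  forbidden: ForbiddenPairTable | None = None,
                  drop_relations: tuple = ()) -> MetricsReport:
    """Rotating stratified k-fold evaluation (8:1:1 at 10 folds).

    Each round tests on fold t, uses fold (t+1) mod k for early stopping,
    and trains on the rest. Augmentation (if on) sees only the training
    folds; generated nodes never contribute to reported metrics.
    """
    if graph.labels is None:
        raise ValueError("graph has no label table")
    y = graph.labels.column(config.efficacy)
    if y.sum() < config.folds or (len(y) - y.sum()) < config.folds:
        raise ValueError("need at least one positive and negative per fold")
    folds = make_folds(y, config.folds, config.seed)
    forbidden = forbidden or ForbiddenPairTable([])
    rows = []
    for t in range(config.folds):
        test_idx = folds[t]
        val_idx = folds[(t + 1) % config.folds]
        train_idx = np.concatenate(
            [folds[i] for i in range(config.folds)
             if i not in (t, (t + 1) % config.folds)])
        g, y_run, tr = graph, y, train_idx
        if config.augmentation:
            gan = replace(config.gan, seed=config.gan.seed + 7919 * t)
            cfg = TrainConfig(**{**config.__dict__, "gan": gan})
            g, y_run, tr, _ = _augmented_training_graph(
                graph, y, train_idx, cfg, forbidden)
        res = fit(g, y_run, tr, val_idx, config, drop_relations=drop_relations)
        m = evaluate(y[test_idx], res.scores[test_idx])
        m["fold"] = t
        rows.append(m)
    per_fold = pd.DataFrame(rows)[["fold", *MetricsReport.METRICS]]
    return MetricsReport(per_fold, config.efficacy, config.variant)


# ---------------------------------------------------------------------------
# Ablation variants
# ---------------------------------------------------------------------------


def _smote(X: np.ndarray, n_new: int, rng: np.random.Generator,
           k: int = 5) -> np.ndarray:
    """Minority oversampling by interpolation toward nearest neighbors."""
    if n_new <= 0 or len(X) == 0:
        return np.empty((0, X.shape[1]))
    k = min(k, len(X) - 1)
    if k < 1:
        return np.repeat(X, int(np.ceil(n_new / len(X))), axis=0)[:n_new]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    base = rng.integers(len(X), size=n_new)
    nbr = idx[base, rng.integers(1, k + 1, size=n_new)]
    lam = rng.random((n_new, 1))
    return X[base] + lam * (X[nbr] - X[base])


def _tabular_baseline(graph: HeteroGraph, config: TrainConfig) -> MetricsReport:
    """S variant: class-balancing oversampling of prescription features
    plus a random-forest classifier; no graph."""
    y = graph.labels.column(config.efficacy)
    X = graph.features["prescription"]
    folds = make_folds(y, config.folds, config.seed)
    rng = np.random.default_rng(config.seed)
    rows = []
    for t in range(config.folds):
        test_idx = folds[t]
        train_idx = np.concatenate(
            [folds[i] for i in range(config.folds)
             if i not in (t, (t + 1) % config.folds)])
        Xt, yt = X[train_idx], y[train_idx]
        n_pos, n_neg = int(yt.sum()), int(len(yt) - yt.sum())
        minority = 1 if n_pos <= n_neg else 0
        Xm = Xt[yt == minority]
        extra = _smote(Xm, abs(n_neg - n_pos), rng)
        Xb = np.vstack([Xt, extra])
        yb = np.concatenate([yt, np.full(len(extra), minority)])
        clf = RandomForestClassifier(n_estimators=200,
                                     random_state=config.seed + t)
        clf.fit(Xb, yb)
        scores = clf.predict_proba(X[test_idx])[:, list(clf.classes_).index(1)]
        m = evaluate(y[test_idx], scores)
        m["fold"] = t
        rows.append(m)
    per_fold = pd.DataFrame(rows)[["fold", *MetricsReport.METRICS]]
    return MetricsReport(per_fold, config.efficacy, "S")


def _concatenated_prescription_features(data: AssembledData,
                                        max_herbs: int) -> np.ndarray:
    """H variant: pad/truncate each prescription's herb features to a fixed
    herb count and concatenate instead of summing."""
    from .featurize import encode_herb

    vocab = data.vocab
    hvec = {h.herb_id: encode_herb(h, vocab) for h in data.herbs}
    n = vocab.n
    out = np.zeros((len(data.prescriptions), max_herbs * n))
    for i, p in enumerate(data.prescriptions):
        for j, hid in enumerate(sorted(set(p.herb_ids))[:max_herbs]):
            out[i, j * n:(j + 1) * n] = hvec[hid]
    return out


def _alternate_encoder_features(data: AssembledData) -> dict:
    from dataclasses import replace

    from .featurize import get_encoder

    spec = replace(data.spec, encoder_id="kmer-hash-alt")
    enc = get_encoder(spec)
    g = data.graph
    feats = {}
    if g.num_nodes("metabolite"):
        by_id = {m.metabolite_id: m for m in data.molecules}
        feats["metabolite"] = enc.encode(
            [by_id[i].smiles for i in g.node_ids["metabolite"]])
    if g.num_nodes("target"):
        by_id = {t.target_id: t for t in data.targets}
        feats["target"] = enc.encode(
            [by_id[i].protein_sequence for i in g.node_ids["target"]])
    return feats


def run_ablation(variant: str, data: AssembledData, config: TrainConfig,
                 forbidden: ForbiddenPairTable | None = None) -> MetricsReport:
    """Evaluate one ablation variant under the shared CV protocol.

    full: the complete model. R: metabolite/target relations dropped.
    E: alternate sequence-encoder backend. H: concatenated (not summed)
    prescription features. S: tabular oversampling + tree ensemble.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    graph = data.graph
    if variant == "S":
        return _tabular_baseline(graph, config)
    drop = ()
    if variant == "R":
        drop = ("herb-metabolite", "metabolite-herb",
                "metabolite-target", "target-metabolite",
                "metabolite-ecfp", "ecfp-metabolite")
        present = tuple(r for r in drop if r in graph.edges)
        if not present:
            drop = ()
        else:
            drop = present
    if variant in ("E", "H"):
        graph = graph.copy()
        if variant == "E":
            for t, F in _alternate_encoder_features(data).items():
                graph.features[t] = F
        else:
            graph.features["prescription"] = \
                _concatenated_prescription_features(data, config.max_herbs)
    report = crossvalidate(graph, config, forbidden=forbidden,
                           drop_relations=drop)
    report.variant = variant
    return report
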