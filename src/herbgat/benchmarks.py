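"""Standard synthetic benchmarks for the pipeline.

Three fixed study conditions, each a planted-signal dataset plus a
training configuration sized for a single CPU:

* signal recovery — the full-scale balanced benchmark (2,000
  prescriptions, 100 herbs, effective set of 10, activation threshold 2,
  5% label noise, dataset seed 7): 10-fold cross-validated AUC of the
  full model, with a label-permutation control;
* augmentation direction — a deliberately hard 1:4-imbalanced corpus
  (500 prescriptions, weak attribute contrast, 10% label noise)
  mirroring the regime where minority recall is poor without
  rebalancing; compares minority recall with and without GAN-generated
  prescription nodes over several seeds;
* ablation direction — a graph-routed corpus (herb attributes all share
  one profile, herb count fixed at ten, so prescription features and
  degrees are uninformative; only metabolite/target structure identifies
  the effective herbs) comparing the full model against the variant
  without metabolite relations.

Dataset seeds are part of the benchmark definition; the ``seed``
arguments drive fold assignment, initialization and GAN training.
"""

from __future__ import annotations

import numpy as np

from .augment import ForbiddenPairTable, GanConfig
from .hetgraph import EfficacyLabelTable
from .pipeline import AssembledData, assemble_dataset
from .rgat import RgatConfig
from .synthetic import SynthConfig, generate_synthetic_dataset
from .train_eval import (
    TrainConfig,
    _augmented_training_graph,
    crossvalidate,
    evaluate,
    fit,
    make_folds,
)

EFFICACY = "planted"

SIGNAL_RECOVERY_DATASET = SynthConfig(seed=7)

IMBALANCED_DATASET = SynthConfig(
    n_prescriptions=500, n_herbs=50, n_metabolites=100, n_targets=80,
    positive_fraction=0.2, label_noise=0.10,
    signal_p_in=0.7, signal_p_out=0.25, seed=21)

GRAPH_SIGNAL_DATASET = SynthConfig(
    n_prescriptions=600, n_herbs=60, n_metabolites=120, n_targets=80,
    signal_routing="graph", profile_pool_size=1,
    herbs_per_prescription_fixed=True, metabolites_per_herb_mean=8.0,
    seed=33)

METABOLITE_RELATIONS = (
    "herb-metabolite", "metabolite-herb",
    "metabolite-target", "target-metabolite",
    "metabolite-ecfp", "ecfp-metabolite",
)


def compact_rgat(seed: int) -> RgatConfig:
    """Model sizing used throughout the benchmarks (single-CPU scale)."""
    return RgatConfig(hidden_dim=32, attention_heads=2, relation_heads=2,
                      relation_dim=16, seed=seed)


def benchmark_gan(seed: int) -> GanConfig:
    """GAN sizing for the desk-scale strata of the benchmarks."""
    return GanConfig(noise_dim=16, hidden_dim=64, lr_discriminator=5e-4,
                     lr_ratio=4.0, epochs=3000, batch_size=64, seed=seed)


def _forbidden(dataset) -> ForbiddenPairTable:
    return ForbiddenPairTable(list(zip(dataset.forbidden_pairs["herb_id_a"],
                                       dataset.forbidden_pairs["herb_id_b"])))


def signal_recovery(seed: int = 7, permuted: bool = False) -> dict:
    """10-fold CV of the full model on the balanced planted-signal corpus.

    With ``permuted=True`` the label column is randomly permuted first,
    destroying the signal; test AUC should then sit at chance.
    """
    ds = generate_synthetic_dataset(SIGNAL_RECOVERY_DATASET)
    data = assemble_dataset(ds)
    graph = data.graph
    if permuted:
        graph = graph.copy()
        perm = np.random.default_rng(seed).permutation(
            len(graph.labels.prescription_ids))
        graph.labels = EfficacyLabelTable(
            graph.labels.matrix[perm], graph.labels.efficacies,
            list(graph.labels.prescription_ids))
    cfg = TrainConfig(efficacy=EFFICACY, epochs=60, patience=12, lr=2e-3,
                      seed=seed, rgat=compact_rgat(seed))
    report = crossvalidate(graph, cfg)
    return {"mean_auc": report.mean("auc"), "mean_aupr": report.mean("aupr"),
            "sd_auc": report.sd("auc"), "report": report,
            "n": len(ds.prescriptions)}


def augmentation_direction(seed: int = 0, n_seeds: int = 5) -> dict:
    """Minority recall with vs without GAN augmentation, per seed.

    One 8:1:1 split per seed; augmentation generates minority
    prescriptions up to class balance from the training folds only.
    """
    ds = generate_synthetic_dataset(IMBALANCED_DATASET)
    data = assemble_dataset(ds)
    y = data.graph.labels.column(EFFICACY)
    forbidden = _forbidden(ds)
    recalls_plain, recalls_aug, kept = [], [], []
    for s in range(seed, seed + n_seeds):
        folds = make_folds(y, 10, s)
        test_idx, val_idx = folds[0], folds[1]
        train_idx = np.concatenate(folds[2:])
        cfg = TrainConfig(efficacy=EFFICACY, epochs=60, patience=12, lr=2e-3,
                          seed=s, rgat=compact_rgat(s), gan=benchmark_gan(s))
        res = fit(data.graph, y, train_idx, val_idx, cfg)
        recalls_plain.append(evaluate(y[test_idx], res.scores[test_idx])["recall"])
        g2, y2, tr2, rep = _augmented_training_graph(
            data.graph, y, train_idx, cfg, forbidden)
        res2 = fit(g2, y2, tr2, val_idx, cfg)
        recalls_aug.append(evaluate(y[test_idx], res2.scores[test_idx])["recall"])
        kept.append(rep["kept"])
    return {
        "median_recall_plain": float(np.median(recalls_plain)),
        "median_recall_augmented": float(np.median(recalls_aug)),
        "recalls_plain": recalls_plain,
        "recalls_augmented": recalls_aug,
        "generated_kept": kept,
        "n": len(ds.prescriptions),
    }


def ablation_direction(seed: int = 0, n_seeds: int = 5) -> dict:
    """Full model vs the no-metabolite-relations variant on graph-routed
    signal; mean test AUC per arm."""
    ds = generate_synthetic_dataset(GRAPH_SIGNAL_DATASET)
    data = assemble_dataset(ds)
    y = data.graph.labels.column(EFFICACY)
    drop = tuple(r for r in METABOLITE_RELATIONS if r in data.graph.edges)
    auc_full, auc_r = [], []
    for s in range(seed, seed + n_seeds):
        folds = make_folds(y, 10, s)
        test_idx, val_idx = folds[0], folds[1]
        train_idx = np.concatenate(folds[2:])
        cfg = TrainConfig(efficacy=EFFICACY, epochs=150, patience=25, lr=1e-3,
                          seed=s, rgat=compact_rgat(s))
        res = fit(data.graph, y, train_idx, val_idx, cfg)
        auc_full.append(evaluate(y[test_idx], res.scores[test_idx])["auc"])
        res_r = fit(data.graph, y, train_idx, val_idx, cfg, drop_relations=drop)
        auc_r.append(evaluate(y[test_idx], res_r.scores[test_idx])["auc"])
    return {
        "mean_auc_full": float(np.mean(auc_full)),
        "mean_auc_no_metabolites": float(np.mean(auc_r)),
        "auc_full": auc_full,
        "auc_no_metabolites": auc_r,
        "n": len(ds.prescriptions),
    }


def end_to_end(seed: int = 0, out_dir=None) -> dict:
    """One compact deterministic pipeline pass: simulate, build, augment,
    cross-validate, extract attention. Returns artifact digests so two
    runs can be compared byte for byte; with ``out_dir`` set, also writes
    the metrics CSV and attention TSV there.
    """
    import hashlib
    import io
    from pathlib import Path

    from .attention_analysis import (bin_top_edges, export_attention,
                                     extract_relation_attention)
    from .rgat import GraphTensors

    cfg_ds = SynthConfig(n_prescriptions=160, n_herbs=40, n_metabolites=60,
                         n_targets=50, positive_fraction=0.35, seed=seed + 11)
    ds = generate_synthetic_dataset(cfg_ds)
    data = assemble_dataset(ds)
    y = data.graph.labels.column(EFFICACY)
    gan = benchmark_gan(seed)
    gan = GanConfig(**{**gan.__dict__, "epochs": 400})
    cfg = TrainConfig(efficacy=EFFICACY, folds=10, epochs=10, patience=10,
                      lr=2e-3, seed=seed, rgat=compact_rgat(seed),
                      augmentation=True, gan=gan)
    report = crossvalidate(data.graph, cfg, forbidden=_forbidden(ds))
    buf = io.StringIO()
    report.to_csv(buf)
    metrics_csv = buf.getvalue()

    folds = make_folds(y, 10, cfg.seed)
    res = fit(data.graph, y, np.concatenate(folds[:-1]), folds[-1], cfg)
    gt = GraphTensors.from_graph(data.graph)
    edges = extract_relation_attention(res.trace, gt, data.graph,
                                       relation="metabolite-herb")
    top = bin_top_edges(edges)
    attention_tsv = "\n".join(
        f"{e.source}\t{e.destination}\t{e.relation}\t{e.weight:.6f}"
        for e in top)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.csv").write_text(metrics_csv)
        export_attention(top, out / "attention.tsv", format="tsv")
    return {
        "mean_auc": report.mean("auc"),
        "metrics_digest": hashlib.sha256(metrics_csv.encode()).hexdigest(),
        "attention_digest": hashlib.sha256(attention_tsv.encode()).hexdigest(),
        "n": cfg_ds.n_prescriptions,
    }
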