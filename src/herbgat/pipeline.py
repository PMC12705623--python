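"""Assembly of raw tables into a featurized heterogeneous graph.

Glue between the table readers, the featurizers and the graph builder:
encode herbs, aggregate prescription features, fingerprint and embed
metabolites, embed targets, drop unsequenced records, and attach the
virtual fingerprint nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import featurize as fz
from . import hetgraph as hg


@dataclass
class AssembledData:
    """A built graph plus everything needed to re-featurize or audit it."""

    graph: hg.HeteroGraph
    vocab: fz.AttributeVocabulary
    herbs: list              # HerbDescriptor, graph herb order
    prescriptions: list      # PrescriptionRecord, graph prescription order
    molecules: list          # MoleculeRecord for surviving metabolites
    targets: list            # TargetRecord for surviving targets
    spec: fz.SequenceEmbeddingSpec
    cleaning_report: dict

    @property
    def herb_ids(self) -> list:
        return self.graph.node_ids["herb"]


def assemble_from_frames(
    herbs_df: pd.DataFrame,
    prescriptions_df: pd.DataFrame,
    metabolites_df: pd.DataFrame,
    targets_df: pd.DataFrame,
    herb_metabolite_df: pd.DataFrame,
    metabolite_target_df: pd.DataFrame,
    spec: fz.SequenceEmbeddingSpec | None = None,
    ecfp_radius: int = 2,
    ecfp_bits: int = 2048,
    min_share: float | None = None,
    vocab: fz.AttributeVocabulary | None = None,
) -> AssembledData:
    """Featurize the tables and build the cleaned heterogeneous graph.

    With ``min_share`` set, efficacies rarer than that share are dropped
    from the label table before it is attached.
    """
    vocab = vocab or fz.AttributeVocabulary()
    spec = spec or fz.SequenceEmbeddingSpec()
    encoder = fz.get_encoder(spec)

    herb_records = _herbs_from_frame(herbs_df, vocab)
    herb_records.sort(key=lambda h: h.herb_id)
    herb_ids = [h.herb_id for h in herb_records]
    herb_feats = fz.herb_feature_matrix(herb_records, vocab)
    hvec = {h.herb_id: v for h, v in zip(herb_records, herb_feats)}

    prescriptions, efficacies = _prescriptions_from_frame(prescriptions_df)
    for p in prescriptions:
        p.feature = fz.aggregate_prescription([hvec[h] for h in set(p.herb_ids)])

    molecules = _molecules_from_frame(metabolites_df, encoder, ecfp_radius, ecfp_bits)
    targets = _targets_from_frame(targets_df, encoder)

    seq_m = [m for m in molecules if m.sequenced]
    seq_t = [t for t in targets if t.sequenced]
    seq_m_ids = {m.metabolite_id for m in seq_m}
    seq_t_ids = {t.target_id for t in seq_t}
    hm = [(h, m) for h, m in zip(herb_metabolite_df["herb_id"],
                                 herb_metabolite_df["metabolite_id"])
          if m in seq_m_ids]
    mt = [(m, t) for m, t in zip(metabolite_target_df["metabolite_id"],
                                 metabolite_target_df["target_id"])
          if m in seq_m_ids and t in seq_t_ids]
    report = {
        "metabolites_dropped": len(molecules) - len(seq_m),
        "targets_dropped": len(targets) - len(seq_t),
        "herb_metabolite_edges_dropped": len(herb_metabolite_df) - len(hm),
        "metabolite_target_edges_dropped": len(metabolite_target_df) - len(mt),
    }

    m_ids = sorted(seq_m_ids)
    t_ids = sorted(seq_t_ids)
    m_by_id = {m.metabolite_id: m for m in seq_m}
    t_by_id = {t.target_id: t for t in seq_t}
    features = {
        "prescription": np.stack([p.feature for p in prescriptions]),
        "herb": herb_feats,
        "metabolite": np.stack([m_by_id[i].seq_embedding for i in m_ids])
        if m_ids else np.zeros((0, spec.dim)),
        "target": np.stack([t_by_id[i].seq_embedding for i in t_ids])
        if t_ids else np.zeros((0, spec.dim)),
    }
    graph = hg.build_graph(prescriptions, herb_ids, hm, mt, features,
                           metabolite_ids=m_ids, target_ids=t_ids)
    graph = hg.attach_virtual_ecfp(graph, seq_m)

    label_matrix = np.array([[p.efficacy_labels.get(e, 0) for e in efficacies]
                             for p in prescriptions], dtype=np.int64)
    labels = hg.EfficacyLabelTable(label_matrix, efficacies,
                                   [p.prescription_id for p in prescriptions])
    if min_share is not None:
        retained = hg.filter_rare_efficacies(labels, min_share)
        keep = [labels.efficacies.index(e) for e in retained]
        labels = hg.EfficacyLabelTable(labels.matrix[:, keep], retained,
                                       list(labels.prescription_ids))
    graph.labels = labels
    graph.validate()
    return AssembledData(graph, vocab, herb_records, prescriptions,
                         seq_m, seq_t, spec, report)


def assemble_graph(data_dir, **kwargs) -> AssembledData:
    """Read the CSV/TSV tables from a directory and assemble the graph."""
    d = Path(data_dir)
    return assemble_from_frames(
        pd.read_csv(d / "herbs.csv", dtype=str).fillna(""),
        pd.read_csv(d / "prescriptions.csv", dtype=str).fillna(""),
        pd.read_csv(d / "metabolites.csv", dtype=str).fillna(""),
        pd.read_csv(d / "targets.csv", dtype=str).fillna(""),
        pd.read_csv(d / "herb_metabolite.tsv", sep="\t", dtype=str),
        pd.read_csv(d / "metabolite_target.tsv", sep="\t", dtype=str),
        **kwargs,
    )


def assemble_dataset(dataset, **kwargs) -> AssembledData:
    """Assemble directly from an in-memory synthetic dataset."""
    return assemble_from_frames(
        dataset.herbs, dataset.prescriptions.astype(str),
        dataset.metabolites.fillna(""), dataset.targets.fillna(""),
        dataset.herb_metabolite, dataset.metabolite_target, **kwargs)


def _herbs_from_frame(df, vocab):
    out = []
    for _, row in df.iterrows():
        attrs = frozenset(t for t in str(row["attributes"]).split("|") if t)
        for t in attrs:
            vocab.index(t)
        out.append(fz.HerbDescriptor(str(row["herb_id"]),
                                     str(row.get("name", "")), attrs))
    return out


def _prescriptions_from_frame(df):
    meta = {"prescription_id", "herb_ids", "provenance"}
    efficacies = [c for c in df.columns if c not in meta]
    out = []
    for _, row in df.iterrows():
        out.append(fz.PrescriptionRecord(
            prescription_id=str(row["prescription_id"]),
            herb_ids=[h for h in str(row["herb_ids"]).split("|") if h],
            efficacy_labels={e: int(row[e]) for e in efficacies},
            provenance=str(row.get("provenance", "") or "original"),
        ))
    return out, efficacies


def _molecules_from_frame(df, encoder, radius, nbits):
    out = []
    for _, row in df.iterrows():
        smiles = str(row["smiles"]) or None
        rec = fz.MoleculeRecord(str(row["metabolite_id"]), smiles=smiles)
        if smiles:
            try:
                rec.ecfp = fz.compute_ecfp(smiles, radius, nbits)
                rec.seq_embedding = encoder.encode([smiles])[0]
            except fz.SmilesParseError:
                rec.smiles = None
        out.append(rec)
    return out


def _targets_from_frame(df, encoder):
    out = []
    for _, row in df.iterrows():
        seq = str(row["sequence"]) or None
        rec = fz.TargetRecord(str(row["target_id"]), protein_sequence=seq)
        if seq:
            rec.seq_embedding = encoder.encode([seq])[0]
        out.append(rec)
    return out
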