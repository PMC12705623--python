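"""Schema-compatible synthetic datasets with a planted efficacy signal.

The generator emulates the statistical shape of a prescription corpus
joined to a herb-metabolite-target knowledge base: a few thousand
prescriptions over a few hundred herbs, roughly ten herbs per
prescription, metabolites carrying SMILES strings, targets carrying
protein sequences, and a tunable fraction of unsequenced records.

The planted ground truth is a herb-motif threshold rule: a hidden
"effective" herb set S is drawn, and a prescription is positive for the
planted efficacy iff it contains at least ``activation_threshold`` herbs
of S (before label noise). Where that signal is observable is routable:

* ``features``: S-herbs get a distinctive attribute profile, so herb and
  prescription feature vectors carry the signal directly;
* ``graph``: herb attributes are drawn from a small shared profile pool
  independent of S (feature vectors are uninformative); instead S-herbs
  connect exclusively to a reserved pool of marker metabolites (with
  their own SMILES vocabulary and marker targets), so only the
  metabolite/target structure identifies S;
* ``both``: both mechanisms.

SMILES come from a fixed bundled list of valid small molecules so
fingerprints are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .featurize import AttributeVocabulary

# fixed vocabulary of 50 valid small-molecule SMILES; the first ten are
# reserved for marker metabolites under graph signal routing
BUNDLED_SMILES = (
    "CCO", "CC(=O)O", "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1",
    "CC(=O)Oc1ccccc1C(=O)O", "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",
    "OCC1OC(O)C(O)C(O)C1O", "NCC(=O)O", "CC(N)C(=O)O",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "CC(=O)Nc1ccc(O)cc1",
    "CN1CCCC1c1cccnc1", "C1CCCCC1", "CCCCCC", "CCN(CC)CC", "CC(C)O",
    "CCOC(C)=O", "O=C(O)c1ccccc1", "Nc1ccccc1", "Clc1ccccc1",
    "Brc1ccccc1", "OCCO", "C=CC=C", "CC#N", "CS(C)=O", "O=C1CCCCC1",
    "c1ccc2ccccc2c1", "c1ccncc1", "c1cc[nH]c1", "c1ccoc1", "c1ccsc1",
    "OC(=O)C(O)C(O)C(=O)O", "OC(=O)CC(O)(CC(=O)O)C(=O)O", "CCC(=O)O",
    "CCCCO", "CC(C)(C)O", "O=CC=O", "CC=O", "C1CCOC1", "C1COCCO1",
    "CNC", "CN(C)C", "OCC(O)CO", "N#Cc1ccccc1", "COc1ccccc1",
    "CC(C)=O", "NC(N)=O", "O=Cc1ccccc1", "OCc1ccccc1",
)

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SynthConfig:
    n_prescriptions: int = 2000
    n_herbs: int = 100
    n_metabolites: int = 300
    n_targets: int = 200
    herbs_per_prescription_mean: float = 10.0
    # fixed herb count per prescription removes the degree-label shortcut
    # (prescription size correlates with the threshold rule's outcome)
    herbs_per_prescription_fixed: bool = False
    metabolites_per_herb_mean: float = 6.0
    targets_per_metabolite_mean: float = 3.0
    frac_unsequenced_metabolites: float = 0.05
    frac_unsequenced_targets: float = 0.05
    effective_set_size: int = 10
    activation_threshold: int = 2
    label_noise: float = 0.05
    signal_routing: str = "features"   # features | graph | both
    positive_fraction: float = 0.5     # 0.2 emulates 1:4 imbalance
    attribute_prob: float = 0.3
    signal_tokens: int = 6
    signal_p_in: float = 0.95
    signal_p_out: float = 0.15
    profile_pool_size: int = 6
    marker_fraction: float = 0.25
    n_forbidden_pairs: int = 5
    efficacy_name: str = "planted"
    seed: int = 7

    def __post_init__(self):
        for name in ("n_prescriptions", "n_herbs", "n_metabolites", "n_targets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.effective_set_size > self.n_herbs:
            raise ValueError("effective set larger than herb universe")
        if self.signal_routing not in ("features", "graph", "both"):
            raise ValueError(f"unknown signal routing {self.signal_routing!r}")


@dataclass
class SynthTruth:
    """Planted ground truth: the rule, its parameters, noiseless labels."""

    effective_herbs: list
    activation_threshold: int
    label_noise: float
    signal_routing: str
    noiseless_labels: dict  # prescription_id -> {0,1}
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "SynthTruth":
        return cls(**json.loads(Path(path).read_text()))


def oracle_label(herb_set, truth: SynthTruth) -> int:
    """Noiseless planted label: 1 iff |herbs intersect S| >= threshold."""
    hits = len(set(herb_set) & set(truth.effective_herbs))
    return int(hits >= truth.activation_threshold)


@dataclass
class SynthDataset:
    herbs: pd.DataFrame
    prescriptions: pd.DataFrame
    metabolites: pd.DataFrame
    targets: pd.DataFrame
    herb_metabolite: pd.DataFrame
    metabolite_target: pd.DataFrame
    forbidden_pairs: pd.DataFrame
    truth: SynthTruth
    config: SynthConfig = field(repr=False, default=None)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.herbs.to_csv(out / "herbs.csv", index=False)
        self.prescriptions.to_csv(out / "prescriptions.csv", index=False)
        self.metabolites.to_csv(out / "metabolites.csv", index=False)
        self.targets.to_csv(out / "targets.csv", index=False)
        self.herb_metabolite.to_csv(out / "herb_metabolite.tsv", sep="\t", index=False)
        self.metabolite_target.to_csv(out / "metabolite_target.tsv", sep="\t", index=False)
        self.forbidden_pairs.to_csv(out / "forbidden_pairs.csv", index=False)
        self.truth.to_json(out / "truth.json")


def _truncated_poisson(rng, mean: float, lo: int, hi: int) -> int:
    for _ in range(1000):
        v = rng.poisson(mean)
        if lo <= v <= hi:
            return int(v)
    return lo


def _attr_string(mask: np.ndarray, vocab: AttributeVocabulary,
                 rng: np.random.Generator) -> str:
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        idx = np.array([rng.integers(vocab.n)])
    return "|".join(vocab.tokens[i] for i in idx)


def generate_synthetic_dataset(config: SynthConfig,
                               vocab: AttributeVocabulary | None = None) -> SynthDataset:
    """Draw a full dataset (tables + planted truth) from the config."""
    vocab = vocab or AttributeVocabulary()
    rng = np.random.default_rng(config.seed)
    c = config

    herb_ids = [f"H{i:04d}" for i in range(c.n_herbs)]
    metab_ids = [f"M{i:05d}" for i in range(c.n_metabolites)]
    target_ids = [f"T{i:05d}" for i in range(c.n_targets)]
    S = sorted(rng.choice(c.n_herbs, size=c.effective_set_size, replace=False).tolist())
    S_ids = [herb_ids[i] for i in S]
    in_S = np.zeros(c.n_herbs, dtype=bool)
    in_S[S] = True

    # --- herb attributes -------------------------------------------------
    n_tok = vocab.n
    if c.signal_routing in ("features", "both"):
        masks = rng.random((c.n_herbs, n_tok)) < c.attribute_prob
        sig = slice(0, c.signal_tokens)
        masks[:, sig] = rng.random((c.n_herbs, c.signal_tokens)) < c.signal_p_out
        masks[in_S, sig] = rng.random((c.effective_set_size, c.signal_tokens)) < c.signal_p_in
    else:  # graph routing: attributes from a small pool, independent of S
        pool = rng.random((c.profile_pool_size, n_tok)) < c.attribute_prob
        assign = rng.integers(c.profile_pool_size, size=c.n_herbs)
        masks = pool[assign]
    herbs = pd.DataFrame({
        "herb_id": herb_ids,
        "name": [f"herb-{i}" for i in range(c.n_herbs)],
        "attributes": [_attr_string(m, vocab, rng) for m in masks],
    })

    # --- prescriptions (quota sampling to the requested class balance) ---
    # quota sampling on clean labels; the clean-positive quota is adjusted
    # so that after independent label flips the OBSERVED positive share
    # matches the requested fraction in expectation
    p = c.label_noise
    clean_frac = (c.positive_fraction - p) / (1 - 2 * p) if p < 0.5 else \
        c.positive_fraction
    clean_frac = min(max(clean_frac, 0.0), 1.0)
    n_pos = int(round(c.n_prescriptions * clean_frac))
    n_neg = c.n_prescriptions - n_pos
    pos, neg = [], []
    max_draws = 400 * c.n_prescriptions
    draws = 0
    while (len(pos) < n_pos or len(neg) < n_neg) and draws < max_draws:
        draws += 1
        if c.herbs_per_prescription_fixed:
            m = min(int(round(c.herbs_per_prescription_mean)), c.n_herbs)
        else:
            m = _truncated_poisson(rng, c.herbs_per_prescription_mean, 1, c.n_herbs)
        hs = rng.choice(c.n_herbs, size=m, replace=False)
        y = int(in_S[hs].sum() >= c.activation_threshold)
        if y and len(pos) < n_pos:
            pos.append(hs)
        elif not y and len(neg) < n_neg:
            neg.append(hs)
    # infeasible quotas: construct records of the needed class directly
    non_S = np.array([i for i in range(c.n_herbs) if not in_S[i]])
    while len(pos) < n_pos:
        k = min(c.activation_threshold, len(S))
        pos.append(rng.choice(np.array(S), size=k, replace=False))
    while len(neg) < n_neg:
        if len(non_S):
            neg.append(rng.choice(non_S, size=min(3, len(non_S)), replace=False))
        else:
            neg.append(np.array([int(rng.integers(c.n_herbs))]))

    herb_sets = pos + neg
    clean = np.array([1] * n_pos + [0] * n_neg)
    order = rng.permutation(c.n_prescriptions)
    herb_sets = [herb_sets[i] for i in order]
    clean = clean[order]
    flips = rng.random(c.n_prescriptions) < c.label_noise
    observed = np.where(flips, 1 - clean, clean)
    presc_ids = [f"P{i:05d}" for i in range(c.n_prescriptions)]
    prescriptions = pd.DataFrame({
        "prescription_id": presc_ids,
        "herb_ids": ["|".join(herb_ids[j] for j in sorted(hs)) for hs in herb_sets],
        c.efficacy_name: observed,
    })

    # --- metabolites and targets -----------------------------------------
    n_marker_m = int(round(c.marker_fraction * c.n_metabolites))
    n_marker_t = int(round(c.marker_fraction * c.n_targets))
    marker_m = np.zeros(c.n_metabolites, dtype=bool)
    marker_m[:n_marker_m] = True
    marker_t = np.zeros(c.n_targets, dtype=bool)
    marker_t[:n_marker_t] = True
    structured = c.signal_routing in ("graph", "both")

    unseq_m = rng.random(c.n_metabolites) < c.frac_unsequenced_metabolites
    smiles = []
    for i in range(c.n_metabolites):
        if unseq_m[i]:
            smiles.append("")
        elif structured and marker_m[i]:
            smiles.append(BUNDLED_SMILES[rng.integers(0, 10)])
        elif structured:
            smiles.append(BUNDLED_SMILES[rng.integers(10, len(BUNDLED_SMILES))])
        else:
            smiles.append(BUNDLED_SMILES[rng.integers(len(BUNDLED_SMILES))])
    metabolites = pd.DataFrame({"metabolite_id": metab_ids, "smiles": smiles})

    unseq_t = rng.random(c.n_targets) < c.frac_unsequenced_targets
    seqs = []
    for i in range(c.n_targets):
        if unseq_t[i]:
            seqs.append("")
        else:
            L = int(rng.integers(60, 180))
            seqs.append("".join(rng.choice(_AMINO_ACIDS, size=L)))
    targets = pd.DataFrame({"target_id": target_ids, "sequence": seqs})

    # --- edges ------------------------------------------------------------
    hm_rows = []
    all_m = np.arange(c.n_metabolites)
    for i in range(c.n_herbs):
        if structured:
            pool = all_m[marker_m] if in_S[i] else all_m[~marker_m]
        else:
            pool = all_m
        k = _truncated_poisson(rng, c.metabolites_per_herb_mean, 1, len(pool))
        for j in rng.choice(pool, size=k, replace=False):
            hm_rows.append((herb_ids[i], metab_ids[j]))
    herb_metabolite = pd.DataFrame(hm_rows, columns=["herb_id", "metabolite_id"])

    mt_rows = []
    all_t = np.arange(c.n_targets)
    for i in range(c.n_metabolites):
        if structured:
            pool = all_t[marker_t] if marker_m[i] else all_t[~marker_t]
        else:
            pool = all_t
        k = _truncated_poisson(rng, c.targets_per_metabolite_mean, 1, len(pool))
        for j in rng.choice(pool, size=k, replace=False):
            mt_rows.append((metab_ids[i], target_ids[j]))
    metabolite_target = pd.DataFrame(mt_rows, columns=["metabolite_id", "target_id"])

    # --- forbidden pairs (for pruning GAN output) -------------------------
    fp_rows = set()
    while len(fp_rows) < min(c.n_forbidden_pairs, c.n_herbs * (c.n_herbs - 1) // 2):
        a, b = rng.choice(c.n_herbs, size=2, replace=False)
        fp_rows.add((herb_ids[min(a, b)], herb_ids[max(a, b)]))
    forbidden = pd.DataFrame(sorted(fp_rows), columns=["herb_id_a", "herb_id_b"])

    truth = SynthTruth(
        effective_herbs=S_ids,
        activation_threshold=c.activation_threshold,
        label_noise=c.label_noise,
        signal_routing=c.signal_routing,
        noiseless_labels={pid: int(y) for pid, y in zip(presc_ids, clean)},
        seed=c.seed,
    )
    return SynthDataset(herbs, prescriptions, metabolites, targets,
                        herb_metabolite, metabolite_target, forbidden,
                        truth, config=c)
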