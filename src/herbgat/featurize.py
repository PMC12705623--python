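"""Node featurization for the prescription-herb-metabolite-target network.

Herbs are encoded as multi-hot vectors over a fixed 22-token vocabulary of
traditional pharmacological attributes (10 properties/flavors + 12 meridian
tropisms). A prescription's feature is the standardized elementwise sum of
its herbs' vectors. Metabolites carry two featurizations: a hashed
extended-connectivity (Morgan) fingerprint of the SMILES, and a sequence
embedding shared with protein targets. The sequence embedding contract is
pluggable; the default backend is a deterministic character k-mer hashing
projector, optionally fine-tuned with the SimCSE contrastive objective
(dropout-perturbed duplicate encodings as positive pairs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from ._autodiff import Adam, Linear, Tensor

logger = logging.getLogger(__name__)

PROPERTIES_FLAVORS = (
    "cold", "hot", "warm", "cool", "neutral",
    "sour", "bitter", "sweet", "pungent", "salty",
)
MERIDIANS = (
    "lung", "pericardium", "heart", "large intestine", "triple energizer",
    "small intestine", "stomach", "gallbladder", "bladder", "spleen",
    "liver", "kidney",
)


class UnknownAttributeError(ValueError):
    """An attribute token absent from the vocabulary."""


class SmilesParseError(ValueError):
    """A SMILES string the chemistry toolkit cannot parse."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparsable SMILES: {smiles!r}")


@dataclass(frozen=True)
class AttributeVocabulary:
    """Fixed, ordered token list for herb attributes."""

    properties_flavors: tuple = PROPERTIES_FLAVORS
    meridians: tuple = MERIDIANS

    def __post_init__(self):
        toks = self.tokens
        if len(set(toks)) != len(toks):
            raise ValueError("vocabulary tokens must be unique")

    @property
    def tokens(self) -> tuple:
        return tuple(self.properties_flavors) + tuple(self.meridians)

    @property
    def n(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            raise UnknownAttributeError(f"unknown attribute token: {token!r}") from None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"properties_flavors": list(self.properties_flavors),
             "meridians": list(self.meridians)}, indent=1))

    @classmethod
    def from_json(cls, path) -> "AttributeVocabulary":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["properties_flavors"]), tuple(d["meridians"]))


@dataclass
class HerbDescriptor:
    herb_id: str
    name: str = ""
    attributes: frozenset = frozenset()


@dataclass
class PrescriptionRecord:
    prescription_id: str
    herb_ids: list
    efficacy_labels: dict = field(default_factory=dict)
    feature: np.ndarray | None = None
    provenance: str = "original"

    def __post_init__(self):
        if len(self.herb_ids) == 0:
            raise ValueError(f"prescription {self.prescription_id} has no herbs")


@dataclass
class SequenceEmbeddingSpec:
    dim: int = 256
    temperature: float = 0.05
    dropout_rate: float = 0.1
    encoder_id: str = "kmer-hash"
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class MoleculeRecord:
    metabolite_id: str
    smiles: str | None = None
    seq_embedding: np.ndarray | None = None
    ecfp: np.ndarray | None = None

    @property
    def sequenced(self) -> bool:
        return self.ecfp is not None


@dataclass
class TargetRecord:
    target_id: str
    protein_sequence: str | None = None
    seq_embedding: np.ndarray | None = None

    @property
    def sequenced(self) -> bool:
        return bool(self.protein_sequence)


# ---------------------------------------------------------------------------
# Herb / prescription features
# ---------------------------------------------------------------------------


def encode_herb(descriptor: HerbDescriptor, vocab: AttributeVocabulary) -> np.ndarray:
    """Multi-hot encoding of a herb's attribute set over the fixed vocabulary.

    Each attribute is one-hot encoded and the union over the herb's
    attributes taken; an empty attribute set yields a zero vector with a
    logged warning.
    """
    y = np.zeros(vocab.n, dtype=np.float64)
    if not descriptor.attributes:
        logger.warning("herb %s has no attributes; zero feature", descriptor.herb_id)
        return y
    for tok in descriptor.attributes:
        y[vocab.index(tok)] = 1.0
    return y


def aggregate_prescription(herb_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Standardized sum of herb attribute vectors.

    The herb vectors are summed elementwise, then the sum is centered and
    scaled by the population standard deviation of its own entries. A
    constant sum (zero sd) yields a zero vector with a warning.
    """
    if len(herb_vectors) == 0:
        raise ValueError("empty herb vector list")
    mat = np.asarray(herb_vectors, dtype=np.float64)
    if mat.ndim != 2:
        raise ValueError("herb vectors must share a common length")
    s = mat.sum(axis=0)
    mu = s.mean()
    sigma = s.std()  # population (1/n) convention
    if sigma == 0:
        warnings.warn("constant prescription sum vector; returning zeros", stacklevel=2)
        return np.zeros_like(s)
    return (s - mu) / sigma


# ---------------------------------------------------------------------------
# Similarity and contrastive objective
# ---------------------------------------------------------------------------


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero-norm input")
    return float(u @ v / (nu * nv))


def _row_normalize(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm row in embedding matrix")
    return M / norms


def simcse_contrastive_loss(H: np.ndarray, H_prime: np.ndarray, tau: float) -> float:
    """In-batch contrastive loss over dropout-perturbed duplicate encodings.

    Row i of ``H`` and ``H_prime`` encode the same input under two dropout
    masks; every other row of ``H_prime`` serves as a negative. The loss is
    the mean cross-entropy of picking the matched row under
    cosine-similarity logits scaled by the temperature ``tau``.
    """
    H = np.asarray(H, dtype=np.float64)
    H_prime = np.asarray(H_prime, dtype=np.float64)
    if H.shape != H_prime.shape:
        raise ValueError(f"shape mismatch: {H.shape} vs {H_prime.shape}")
    if tau <= 0:
        raise ValueError("temperature must be > 0")
    S = _row_normalize(H) @ _row_normalize(H_prime).T / tau  # (N, N)
    S = S - S.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(S).sum(axis=1))
    return float(np.mean(logZ - np.diag(S)))


# ---------------------------------------------------------------------------
# Molecular fingerprints
# ---------------------------------------------------------------------------


def compute_ecfp(smiles: str, radius: int = 2, nbits: int = 2048) -> np.ndarray:
    """Hashed extended-connectivity (Morgan) fingerprint of a SMILES string."""
    if radius < 0 or nbits < 1:
        raise ValueError("radius must be >= 0 and nbits >= 1")
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    return gen.GetFingerprintAsNumPy(mol).astype(np.float64)


# ---------------------------------------------------------------------------
# Sequence embedding
# ---------------------------------------------------------------------------


class SequenceEncoder(Protocol):
    """Contract for pluggable sequence encoders: deterministic given
    (string, seed), fixed output dimension."""

    dim: int

    def encode(self, strings: Sequence[str]) -> np.ndarray: ...


class KmerHashEncoder:
    """Deterministic character k-mer hashing projector.

    Each overlapping k-mer is hashed (blake2b keyed by the seed) to a
    coordinate and a sign; the signed counts are L2-normalized. Sequences
    shorter than k fall back to single-character tokens.
    """

    def __init__(self, dim: int = 256, k: int = 3, seed: int = 0):
        self.dim = dim
        self.k = k
        self.seed = seed
        self._key = str(seed).encode()

    def _hash(self, kmer: str) -> tuple[int, int]:
        h = hashlib.blake2b(kmer.encode(), key=self._key, digest_size=8).digest()
        val = int.from_bytes(h, "little")
        return val % self.dim, 1 if (val >> 63) & 1 else -1

    def encode(self, strings: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(strings), self.dim), dtype=np.float64)
        for i, s in enumerate(strings):
            if not s:
                raise ValueError(f"empty sequence at position {i}")
            kmers = [s[j:j + self.k] for j in range(len(s) - self.k + 1)] or list(s)
            for km in kmers:
                idx, sign = self._hash(km)
                out[i, idx] += sign
            n = np.linalg.norm(out[i])
            if n > 0:
                out[i] /= n
        return out


def get_encoder(spec: SequenceEmbeddingSpec) -> SequenceEncoder:
    """Resolve the encoder backend named by ``spec.encoder_id``."""
    if spec.encoder_id == "kmer-hash":
        return KmerHashEncoder(dim=spec.dim, k=3, seed=spec.seed)
    if spec.encoder_id == "kmer-hash-alt":
        # alternate backend: different k-mer width and hash key
        return KmerHashEncoder(dim=spec.dim, k=2, seed=spec.seed + 104729)
    raise ValueError(f"unknown encoder backend: {spec.encoder_id!r}")


def embed_sequences(
    strings: Sequence[str],
    spec: SequenceEmbeddingSpec,
    encoder: SequenceEncoder | None = None,
) -> np.ndarray:
    """One embedding row per string via the configured encoder backend."""
    if encoder is None:
        encoder = get_encoder(spec)
    M = encoder.encode(list(strings))
    if M.shape != (len(strings), spec.dim):
        raise ValueError(
            f"encoder produced shape {M.shape}, expected {(len(strings), spec.dim)}")
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite entries in embedding matrix")
    return M


class ContrastiveProjector:
    """Encoder wrapper with a learned projection fine-tuned contrastively.

    Wraps a base encoder with a square linear projection trained by the
    SimCSE objective: two dropout masks applied to each base encoding form
    a positive pair, all other batch members are negatives.
    """

    def __init__(self, base: SequenceEncoder, spec: SequenceEmbeddingSpec):
        self.base = base
        self.spec = spec
        self.dim = spec.dim
        rng = np.random.default_rng(spec.seed)
        self.proj = Linear(spec.dim, spec.dim, rng, bias=False)
        # start at identity so an untrained projector equals the base encoder
        self.proj.W.data = np.eye(spec.dim)
        self._rng = rng

    def encode(self, strings: Sequence[str]) -> np.ndarray:
        base = self.base.encode(strings)
        return base @ self.proj.W.data

    def _loss(self, base: np.ndarray) -> Tensor:
        p = self.spec.dropout_rate
        keep = 1.0 - p
        m1 = (self._rng.random(base.shape) >= p) / keep
        m2 = (self._rng.random(base.shape) >= p) / keep
        H = Tensor(base * m1, requires_grad=False) @ self.proj.W
        Hp = Tensor(base * m2, requires_grad=False) @ self.proj.W
        eps = 1e-12
        nH = ((H * H).sum(axis=1, keepdims=True) + eps).sqrt()
        nHp = ((Hp * Hp).sum(axis=1, keepdims=True) + eps).sqrt()
        # cosine-similarity logits (N, N)
        Hn, Hpn = H / nH, Hp / nHp
        logits = Hn.matmul(_transpose(Hpn)) * (1.0 / self.spec.temperature)
        mx = Tensor(logits.data.max(axis=1, keepdims=True), requires_grad=False)
        shifted = logits - mx
        logZ = shifted.exp().sum(axis=1, keepdims=True).log()
        diag = (shifted * Tensor(np.eye(base.shape[0]), requires_grad=False)).sum(
            axis=1, keepdims=True)
        return (logZ - diag).mean()

    def finetune(self, strings: Sequence[str], epochs: int = 50, lr: float = 1e-2) -> list:
        """Contrastive fine-tuning pass; returns the per-epoch loss trace."""
        base = self.base.encode(list(strings))
        opt = Adam([self.proj.W], lr=lr)
        trace = []
        for _ in range(epochs):
            opt.zero_grad()
            loss = self._loss(base)
            loss.backward()
            opt.step()
            trace.append(float(loss.data))
        return trace


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, _prev=(t,))
    out._backward = lambda: t._accum(out.grad.T)
    return out


# ---------------------------------------------------------------------------
# Table readers (CSV schemas)
# ---------------------------------------------------------------------------


def read_herbs(path, vocab: AttributeVocabulary) -> list[HerbDescriptor]:
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        attrs = frozenset(t for t in row["attributes"].split("|") if t)
        for t in attrs:
            vocab.index(t)  # validate early, names the offender
        out.append(HerbDescriptor(row["herb_id"], row.get("name", ""), attrs))
    return out


def read_prescriptions(path) -> tuple[list[PrescriptionRecord], list[str]]:
    df = pd.read_csv(path, dtype=str).fillna("")
    meta_cols = {"prescription_id", "herb_ids", "provenance"}
    efficacies = [c for c in df.columns if c not in meta_cols]
    out = []
    for _, row in df.iterrows():
        labels = {e: int(row[e]) for e in efficacies}
        out.append(PrescriptionRecord(
            prescription_id=row["prescription_id"],
            herb_ids=[h for h in row["herb_ids"].split("|") if h],
            efficacy_labels=labels,
            provenance=row.get("provenance", "original") or "original",
        ))
    return out, efficacies


def read_metabolites(path, radius: int = 2, nbits: int = 2048,
                     spec: SequenceEmbeddingSpec | None = None) -> list[MoleculeRecord]:
    spec = spec or SequenceEmbeddingSpec()
    encoder = get_encoder(spec)
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        smiles = row["smiles"] or None
        rec = MoleculeRecord(row["metabolite_id"], smiles=smiles)
        if smiles:
            try:
                rec.ecfp = compute_ecfp(smiles, radius, nbits)
                rec.seq_embedding = encoder.encode([smiles])[0]
            except SmilesParseError:
                rec.smiles = None
        out.append(rec)
    return out


def read_targets(path, spec: SequenceEmbeddingSpec | None = None) -> list[TargetRecord]:
    spec = spec or SequenceEmbeddingSpec()
    encoder = get_encoder(spec)
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        seq = row["sequence"] or None
        rec = TargetRecord(row["target_id"], protein_sequence=seq)
        if seq:
            rec.seq_embedding = encoder.encode([seq])[0]
        out.append(rec)
    return out


def herb_feature_matrix(herbs: Iterable[HerbDescriptor],
                        vocab: AttributeVocabulary) -> np.ndarray:
    return np.stack([encode_herb(h, vocab) for h in herbs])
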