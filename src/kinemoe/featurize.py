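"""Featurization: pluggable embedders, RBF covariate encoding, fusion.

An entry is characterized by three blocks that are concatenated into the
model input: an enzyme-sequence embedding (default 1024-d), a substrate
embedding from its canonical SMILES (default 300-d), and an auxiliary block
(default 300-d) summing three projections — pH and temperature, each expanded
over a grid of Gaussian radial basis functions and mapped linearly to the
auxiliary dimension, and an organism embedding looked up from a table.

The RBF expansion of a scalar x over centers {mu_m} is

    e_m(x) = exp(-gamma * (x - mu_m)^2),   gamma = 10 by default,

with centers laid out from the minimum to the maximum of the training values
at a stride of 0.1.  Values outside the span simply fall on the Gaussian
tails; they are never an error.

Embedders are a contract (name, dim, deterministic ``embed``); the shipped
defaults are the deterministic hash embedders from :mod:`kinemoe.synthetic`,
so the whole pipeline runs offline.  Adapters for pretrained protein or
molecule language models can be plugged in behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Protocol, Sequence, Tuple

import numpy as np

from .records import CuratedEntry

__all__ = [
    "Embedder",
    "AuxEncoderSpec",
    "AuxParams",
    "ModelInput",
    "FeatureSet",
    "build_rbf_centers",
    "rbf_expand",
    "encode_organism",
    "encode_aux",
    "mean_pool",
    "assemble_input",
    "fit_aux_spec",
    "featurize_entries",
    "UNKNOWN_ORGANISM",
]

UNKNOWN_ORGANISM = -1  # sentinel index; maps to the reserved last table row


class Embedder(Protocol):
    """Deterministic text -> fixed-length vector contract."""

    name: str
    dim: int

    def embed(self, text: str) -> np.ndarray: ...


def build_rbf_centers(values: Sequence[float], stride: float = 0.1) -> np.ndarray:
    """Centers from min(values) to >= max(values) in steps of ``stride``."""
    if len(values) == 0:
        raise ValueError("cannot build RBF centers from an empty value list")
    if stride <= 0:
        raise ValueError("stride must be positive")
    lo, hi = float(min(values)), float(max(values))
    n = int(np.ceil((hi - lo) / stride - 1e-12)) + 1
    centers = lo + stride * np.arange(n)
    if centers[-1] < hi - 1e-12:
        centers = np.append(centers, lo + stride * n)
    return centers


def rbf_expand(x: float, centers: np.ndarray, gamma: float = 10.0) -> np.ndarray:
    """Gaussian kernel responses exp(-gamma * (x - mu)^2) at each center."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise ValueError("centers must be nonempty")
    return np.exp(-gamma * (x - centers) ** 2)


def mean_pool(matrix: np.ndarray) -> np.ndarray:
    """Column means of an n x m matrix (the per-token -> per-item pooling)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("mean_pool requires a nonempty 2-D matrix")
    return matrix.mean(axis=0)


@dataclass
class AuxEncoderSpec:
    """Frozen description of the auxiliary encoder, fit on training data."""

    ph_centers: np.ndarray
    temp_centers: np.ndarray
    organism_vocab: Tuple[str, ...]
    gamma: float = 10.0
    stride: float = 0.1
    aux_dim: int = 300

    @property
    def n_ph(self) -> int:
        return len(self.ph_centers)

    @property
    def n_temp(self) -> int:
        return len(self.temp_centers)

    def organism_index(self, name: Optional[str]) -> int:
        """Vocab index, or the reserved unknown row for out-of-vocab names."""
        if name is None:
            return UNKNOWN_ORGANISM
        try:
            return self.organism_vocab.index(name)
        except ValueError:
            return len(self.organism_vocab)  # reserved unknown row

    def to_dict(self) -> dict:
        return {
            "ph_centers": self.ph_centers.tolist(),
            "temp_centers": self.temp_centers.tolist(),
            "organism_vocab": list(self.organism_vocab),
            "gamma": self.gamma,
            "stride": self.stride,
            "aux_dim": self.aux_dim,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AuxEncoderSpec":
        return cls(
            ph_centers=np.asarray(d["ph_centers"], dtype=float),
            temp_centers=np.asarray(d["temp_centers"], dtype=float),
            organism_vocab=tuple(d["organism_vocab"]),
            gamma=d["gamma"],
            stride=d["stride"],
            aux_dim=d["aux_dim"],
        )


@dataclass
class AuxParams:
    """Trainable parameters of the auxiliary encoder.

    ``w_ph``/``w_temp`` linearly map the RBF vectors to the auxiliary
    dimension; ``organism_table`` has one row per vocab entry plus a reserved
    unknown row.  A missing covariate contributes the zero vector, so the
    linear maps carry no bias.
    """

    w_ph: np.ndarray  # (n_ph, aux_dim)
    w_temp: np.ndarray  # (n_temp, aux_dim)
    organism_table: np.ndarray  # (len(vocab) + 1, aux_dim)

    @classmethod
    def init(cls, spec: AuxEncoderSpec, rng: np.random.Generator) -> "AuxParams":
        def u(fan_in: int, shape: tuple) -> np.ndarray:
            b = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-b, b, size=shape)

        return cls(
            w_ph=u(spec.n_ph, (spec.n_ph, spec.aux_dim)),
            w_temp=u(spec.n_temp, (spec.n_temp, spec.aux_dim)),
            organism_table=u(
                spec.aux_dim, (len(spec.organism_vocab) + 1, spec.aux_dim)
            ),
        )


def encode_organism(
    name: Optional[str], spec: AuxEncoderSpec, params: AuxParams
) -> np.ndarray:
    """One-hot lookup into the organism embedding table (unknowns reserved)."""
    idx = spec.organism_index(name)
    if idx == UNKNOWN_ORGANISM:
        return np.zeros(spec.aux_dim)
    return params.organism_table[idx].copy()


def encode_aux(
    ph: Optional[float],
    temperature: Optional[float],
    organism: Optional[str],
    spec: AuxEncoderSpec,
    params: AuxParams,
) -> np.ndarray:
    """Sum of the three auxiliary projections; missing components are zero."""
    aux = np.zeros(spec.aux_dim)
    if ph is not None:
        aux += rbf_expand(ph, spec.ph_centers, spec.gamma) @ params.w_ph
    if temperature is not None:
        aux += rbf_expand(temperature, spec.temp_centers, spec.gamma) @ params.w_temp
    aux += encode_organism(organism, spec, params)
    return aux


@dataclass
class ModelInput:
    """The fused per-entry feature vector consumed by the multitask core."""

    enzyme_vec: np.ndarray
    substrate_vec: np.ndarray
    aux_vec: np.ndarray

    @property
    def fused(self) -> np.ndarray:
        return np.concatenate([self.enzyme_vec, self.substrate_vec, self.aux_vec])


def assemble_input(
    entry: CuratedEntry,
    enzyme_embedder: Embedder,
    substrate_embedder: Embedder,
    spec: AuxEncoderSpec,
    params: AuxParams,
) -> ModelInput:
    """Embed one curated entry into its fused feature vector."""
    try:
        e = np.asarray(enzyme_embedder.embed(entry.sequence), dtype=float)
        s = np.asarray(substrate_embedder.embed(entry.canonical_smiles), dtype=float)
    except Exception as exc:  # annotate with the entry key, re-raise
        raise RuntimeError(f"embedding failed for entry {entry.key}") from exc
    if e.shape != (enzyme_embedder.dim,) or s.shape != (substrate_embedder.dim,):
        raise ValueError("embedder returned a vector of the wrong length")
    a = encode_aux(entry.ph, entry.temperature, entry.organism, spec, params)
    return ModelInput(e, s, a)


def fit_aux_spec(
    entries: Iterable[CuratedEntry],
    gamma: float = 10.0,
    stride: float = 0.1,
    aux_dim: int = 300,
) -> AuxEncoderSpec:
    """Build the auxiliary spec (RBF centers + organism vocab) from training data."""
    entries = list(entries)
    if not entries:
        raise ValueError("cannot fit an auxiliary spec on an empty training set")
    phs = [e.ph for e in entries if e.ph is not None]
    temps = [e.temperature for e in entries if e.temperature is not None]
    vocab = tuple(sorted({e.organism for e in entries if e.organism is not None}))
    return AuxEncoderSpec(
        ph_centers=build_rbf_centers(phs, stride),
        temp_centers=build_rbf_centers(temps, stride),
        organism_vocab=vocab,
        gamma=gamma,
        stride=stride,
        aux_dim=aux_dim,
    )


@dataclass
class FeatureSet:
    """Dense arrays for a batch of entries, ready for training.

    The auxiliary block is kept in ingredient form (RBF responses + organism
    index) because its projections are trainable model parameters; the model
    assembles the fused input on the fly.
    """

    enzyme: np.ndarray  # (n, d_e)
    substrate: np.ndarray  # (n, d_s)
    rbf_ph: np.ndarray  # (n, n_ph); zero rows where pH missing
    rbf_temp: np.ndarray  # (n, n_temp)
    organism_idx: np.ndarray  # (n,), int; table row, or len(vocab) for unknown
    labels: np.ndarray  # (n, 2): log10 kcat, log10 Km (0 where masked)
    label_mask: np.ndarray  # (n, 2) bool
    keys: List[tuple] = field(default_factory=list)
    enzyme_types: List[str] = field(default_factory=list)
    spec: Optional[AuxEncoderSpec] = None

    def __len__(self) -> int:
        return self.enzyme.shape[0]

    @property
    def input_dim(self) -> int:
        return self.enzyme.shape[1] + self.substrate.shape[1] + self.spec.aux_dim

    def subset(self, idx: np.ndarray) -> "FeatureSet":
        return FeatureSet(
            enzyme=self.enzyme[idx],
            substrate=self.substrate[idx],
            rbf_ph=self.rbf_ph[idx],
            rbf_temp=self.rbf_temp[idx],
            organism_idx=self.organism_idx[idx],
            labels=self.labels[idx],
            label_mask=self.label_mask[idx],
            keys=[self.keys[i] for i in np.atleast_1d(idx)],
            enzyme_types=[self.enzyme_types[i] for i in np.atleast_1d(idx)],
            spec=self.spec,
        )


def featurize_entries(
    entries: Sequence[CuratedEntry],
    enzyme_embedder: Embedder,
    substrate_embedder: Embedder,
    spec: AuxEncoderSpec,
) -> FeatureSet:
    """Vectorize a list of curated entries against a fitted auxiliary spec."""
    n = len(entries)
    E = np.zeros((n, enzyme_embedder.dim))
    S = np.zeros((n, substrate_embedder.dim))
    Rp = np.zeros((n, spec.n_ph))
    Rt = np.zeros((n, spec.n_temp))
    org = np.zeros(n, dtype=int)
    y = np.zeros((n, 2))
    m = np.zeros((n, 2), dtype=bool)
    keys, etypes = [], []
    seq_cache: Dict[str, np.ndarray] = {}
    smi_cache: Dict[str, np.ndarray] = {}
    for i, e in enumerate(entries):
        if e.sequence not in seq_cache:
            seq_cache[e.sequence] = np.asarray(
                enzyme_embedder.embed(e.sequence), dtype=float
            )
        if e.canonical_smiles not in smi_cache:
            smi_cache[e.canonical_smiles] = np.asarray(
                substrate_embedder.embed(e.canonical_smiles), dtype=float
            )
        E[i] = seq_cache[e.sequence]
        S[i] = smi_cache[e.canonical_smiles]
        if e.ph is not None:
            Rp[i] = rbf_expand(e.ph, spec.ph_centers, spec.gamma)
        if e.temperature is not None:
            Rt[i] = rbf_expand(e.temperature, spec.temp_centers, spec.gamma)
        idx = spec.organism_index(e.organism)
        org[i] = len(spec.organism_vocab) if idx == UNKNOWN_ORGANISM else idx
        if e.log10_kcat is not None:
            y[i, 0] = e.log10_kcat
            m[i, 0] = True
        if e.log10_km is not None:
            y[i, 1] = e.log10_km
            m[i, 1] = True
        keys.append(e.key)
        etypes.append(e.enzyme_type.value)
    return FeatureSet(E, S, Rp, Rt, org, y, m, keys, etypes, spec)
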