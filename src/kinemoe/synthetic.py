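"""Synthetic data: deterministic embedder stand-ins and a generative model.

Two distinct jobs live here.

* :class:`HashEmbedder` is a deterministic stand-in for a pretrained
  sequence or molecule embedder: a stable hash of (salt, text) seeds a
  pseudo-random map to an L2-normalized vector, so equal strings always get
  equal vectors and a single residue substitution changes the whole vector.

* :func:`gen_dataset` emits schema-complete raw kinetic records with known
  ground truth.  Labels are linear in the fused feature vector: with a
  shared latent u = a.x and task-specific latents v_t = b_t.x (standardized
  across the dataset),

      label_t = center_t + rho*u + (1-rho)*v_t + eps_t,
      eps_t ~ Normal(0, noise_sd^2),

  so the shared-signal fraction rho controls how correlated the two tasks
  are and the Bayes-optimal R^2 is known in closed form:
  R^2 = s2/(s2 + noise_sd^2) with s2 = rho^2 + (1-rho)^2.  The generator
  also plants unit variety, duplicate groups, mutant rows (wild sequence +
  substitution codes) and per-filter violations in requested counts, so the
  curation pipeline is exercised end to end.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .curation import apply_mutations, canonicalize_smiles
from .featurize import AuxEncoderSpec, AuxParams, build_rbf_centers, encode_aux
from .records import EnzymeType, KineticRecord, ParamKind, Source

__all__ = [
    "AMINO_ACIDS",
    "HashEmbedder",
    "hash_embedder",
    "gen_sequences",
    "gen_substrates",
    "SynthSpec",
    "GroundTruth",
    "gen_labels",
    "gen_dataset",
    "gen_casestudy",
    "noise_sd_for_bayes_r2",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def hash_embedder(text: str, dim: int, salt: int = 0) -> np.ndarray:
    """Deterministic unit-norm vector derived from a stable hash of the text."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    digest = hashlib.blake2b(
        f"{salt}|{text}".encode(), digest_size=8
    ).digest()
    seed = int.from_bytes(digest, "little")
    rng = np.random.Generator(np.random.PCG64(seed))
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


@dataclass
class HashEmbedder:
    """Embedder-contract wrapper around :func:`hash_embedder`."""

    name: str
    dim: int
    salt: int = 0

    def embed(self, text: str) -> np.ndarray:
        return hash_embedder(text, self.dim, self.salt)


def gen_sequences(
    n: int, length_range: Tuple[int, int], seed: int
) -> List[str]:
    """Uniform random amino-acid sequences over the 20-letter alphabet."""
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append("".join(rng.choice(list(AMINO_ACIDS), size=length)))
    return out


def gen_substrates(
    n: int,
    seed: int,
    heavy_atom_range: Tuple[int, int] = (3, 20),
    violator: Optional[str] = None,
) -> List[str]:
    """Valid toy SMILES: linear/branched C/N/O chains of controlled size.

    ``violator`` switches to rule-breaking output: ``"small"`` (<= 2 heavy
    atoms), ``"large"`` (> 128 heavy atoms), ``"fragment"`` (dotted SMILES).
    """
    rng = np.random.default_rng(seed)
    if violator == "small":
        return [rng.choice(["O", "CC", "C", "N"]) for _ in range(n)]
    if violator == "large":
        return ["C" * int(rng.integers(129, 140)) for _ in range(n)]
    if violator == "fragment":
        return [rng.choice(["CCO.O", "CC.CC", "CCN.O"]) for _ in range(n)]
    if violator is not None:
        raise ValueError(f"unknown violator mode {violator!r}")
    out = []
    for _ in range(n):
        target = int(rng.integers(heavy_atom_range[0], heavy_atom_range[1] + 1))
        atoms: List[str] = ["C"]  # start on carbon so branching is legal
        while len(atoms) < target:
            # interior heteroatoms are valence-safe in a single chain
            atoms.append(str(rng.choice(["C", "C", "C", "N", "O"])))
        smi = []
        for i, a in enumerate(atoms):
            smi.append(a)
            # occasional methyl branch on carbon (counts toward heavy atoms)
            if (
                a == "C"
                and 0 < i < len(atoms) - 1
                and len(atoms) < target
                and rng.random() < 0.15
            ):
                smi.append("(C)")
        out.append("".join(smi))
    return out


def noise_sd_for_bayes_r2(rho: float, target_r2: float) -> float:
    """Noise level giving a Bayes-optimal R^2 of ``target_r2``.

    With standardized, near-uncorrelated latents the signal variance is
    s2 = rho^2 + (1-rho)^2, and R^2_bayes = s2/(s2 + sd^2).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target R^2 must be in (0, 1)")
    s2 = rho**2 + (1.0 - rho) ** 2
    return float(np.sqrt(s2 * (1.0 - target_r2) / target_r2))


@dataclass
class SynthSpec:
    """Generator conditions for one synthetic dataset.

    ``missing_props`` defaults to the label-pattern mix of the curated joint
    kinetic dataset the method was developed on (about 50.4% entries with
    both labels, 12.9% kcat-only, 36.6% Km-only).  ``shared_signal_fraction``
    (rho) sets the latent correlation between the two tasks; ``noise_sd``
    defaults to the level at which the Bayes-optimal R^2 is 0.8 at rho=0.9.
    """

    n_entries: int = 1000
    seq_length_range: Tuple[int, int] = (30, 60)
    missing_props: Tuple[float, float, float] = (
        14237 / 28241,
        3656 / 28241,
        10348 / 28241,
    )
    shared_signal_fraction: float = 0.9
    noise_sd: float = field(default_factory=lambda: noise_sd_for_bayes_r2(0.9, 0.8))
    n_organisms: int = 10
    mutant_fraction: float = 0.3
    n_wild_sequences: int = 0  # 0: one wild sequence per ~4 entries
    n_substrates: int = 0  # 0: one substrate per ~5 entries
    enzyme_dim: int = 32
    substrate_dim: int = 16
    aux_dim: int = 16
    n_duplicate_groups: int = 0
    planted_violations: Dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.missing_props) - 1.0) > 1e-9:
            raise ValueError("missing_props must sum to 1")
        if not 0 <= self.shared_signal_fraction <= 1:
            raise ValueError("shared_signal_fraction must lie in [0, 1]")


VIOLATION_KINDS = (
    "incomplete",
    "small_substrate",
    "large_substrate",
    "fragment",
    "nonpositive",
    "unknown_unit",
    "bad_mutation",
)

LABEL_CENTER = {ParamKind.KCAT: 0.9, ParamKind.KM: -0.9}

_KCAT_UNIT_CHOICES = (("s^-1", 1.0), ("min^-1", 60.0), ("h^-1", 3600.0))
_KM_UNIT_CHOICES = (("mM", 1.0), ("uM", 1000.0), ("M", 0.001), ("nM", 1e6))


@dataclass
class GroundTruth:
    """Latents, noiseless labels and generative coefficients per entry key."""

    rho: float
    noise_sd: float
    coefficients: Dict[str, np.ndarray]
    aux_spec: AuxEncoderSpec
    aux_params: AuxParams
    per_entry: Dict[tuple, dict] = field(default_factory=dict)

    def noiseless(self, key: tuple, task: ParamKind) -> float:
        return self.per_entry[key][f"true_{task.value}"]


def gen_labels(
    x_fused: np.ndarray,
    rho: float,
    noise_sd: float,
    coefficients: Dict[str, np.ndarray],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Labels for a batch of fused feature vectors, plus the latents.

    Projections u and v_t are standardized across the batch so the signal
    variance, and hence the Bayes R^2, is known.
    """
    def _std(z: np.ndarray) -> np.ndarray:
        s = z.std()
        return (z - z.mean()) / s if s > 0 else z - z.mean()

    u = _std(x_fused @ coefficients["a"])
    v_kcat = _std(x_fused @ coefficients["b_kcat"])
    v_km = _std(x_fused @ coefficients["b_km"])
    signal_kcat = rho * u + (1 - rho) * v_kcat
    signal_km = rho * u + (1 - rho) * v_km
    y_kcat = (
        LABEL_CENTER[ParamKind.KCAT]
        + signal_kcat
        + rng.normal(0, noise_sd, size=u.shape)
    )
    y_km = (
        LABEL_CENTER[ParamKind.KM]
        + signal_km
        + rng.normal(0, noise_sd, size=u.shape)
    )
    latents = {
        "u": u,
        "v_kcat": v_kcat,
        "v_km": v_km,
        "true_kcat": LABEL_CENTER[ParamKind.KCAT] + signal_kcat,
        "true_km": LABEL_CENTER[ParamKind.KM] + signal_km,
    }
    return y_kcat, y_km, latents


def _make_record(
    i: int,
    suffix: str,
    kind: ParamKind,
    seq: str,
    codes: Tuple[str, ...],
    etype: EnzymeType,
    smiles: str,
    organism: str,
    ph: float,
    temp: float,
    value: float,
    unit: str,
    ec: str,
) -> KineticRecord:
    return KineticRecord(
        record_id=f"syn-{i:06d}{suffix}",
        ec_number=ec,
        enzyme_type=etype,
        mutation_codes=codes,
        sequence=seq,
        substrate_name=f"substrate-{zlib.crc32(smiles.encode()) % 10_000:04d}",
        substrate_smiles=smiles,
        organism=organism,
        ph=ph,
        temperature=temp,
        param_kind=kind,
        value=value,
        unit=unit,
        source=Source.SYNTHETIC,
    )


def gen_dataset(spec: SynthSpec) -> Tuple[List[KineticRecord], GroundTruth]:
    """Schema-complete raw records with retained generative ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_entries
    n_wild = spec.n_wild_sequences or max(1, n // 4)
    n_subs = spec.n_substrates or max(1, n // 5)

    wild_seqs = gen_sequences(n_wild, spec.seq_length_range, spec.seed + 1)
    substrates = [
        canonicalize_smiles(s)
        for s in gen_substrates(n_subs, spec.seed + 2)
    ]
    organisms = [f"Organism_{i:02d}" for i in range(spec.n_organisms)]

    # fixed auxiliary encoder used only to build the generative features
    ph_grid = np.round(np.arange(5.0, 9.01, 0.1), 1)
    temp_grid = np.round(np.arange(20.0, 45.01, 0.5), 1)
    aux_spec = AuxEncoderSpec(
        ph_centers=build_rbf_centers([5.0, 9.0], 0.1),
        temp_centers=build_rbf_centers([20.0, 45.0], 0.1),
        organism_vocab=tuple(organisms),
        aux_dim=spec.aux_dim,
    )
    aux_rng = np.random.default_rng(spec.seed + 3)
    aux_params = AuxParams.init(aux_spec, aux_rng)

    enz = HashEmbedder("hash-enzyme", spec.enzyme_dim, salt=1)
    sub = HashEmbedder("hash-substrate", spec.substrate_dim, salt=2)

    d = spec.enzyme_dim + spec.substrate_dim + spec.aux_dim
    coef_rng = np.random.default_rng(spec.seed + 4)
    coefficients = {
        "a": coef_rng.standard_normal(d),
        "b_kcat": coef_rng.standard_normal(d),
        "b_km": coef_rng.standard_normal(d),
    }

    # draw the per-entry context
    rows = []
    for i in range(n):
        wild = wild_seqs[int(rng.integers(n_wild))]
        is_mut = rng.random() < spec.mutant_fraction
        codes: Tuple[str, ...] = ()
        seq = wild
        if is_mut:
            n_mut = int(rng.integers(1, 3))
            positions = rng.choice(len(wild), size=min(n_mut, len(wild)), replace=False)
            code_list = []
            for pos in sorted(positions):
                ref = wild[pos]
                new = rng.choice([a for a in AMINO_ACIDS if a != ref])
                code_list.append(f"{ref}{pos + 1}{new}")
            codes = tuple(code_list)
            seq = apply_mutations(wild, codes)
        smiles = substrates[int(rng.integers(n_subs))]
        org = organisms[int(rng.integers(spec.n_organisms))]
        ph = float(rng.choice(ph_grid))
        temp = float(rng.choice(temp_grid))
        ec = f"{rng.integers(1, 7)}.{rng.integers(1, 20)}.{rng.integers(1, 20)}.{rng.integers(1, 99)}"
        rows.append((wild, codes, seq, smiles, org, ph, temp, ec))

    # fused generative features and labels
    X = np.zeros((n, d))
    for i, (_, _, seq, smiles, org, ph, temp, _) in enumerate(rows):
        aux = encode_aux(ph, temp, org, aux_spec, aux_params)
        X[i] = np.concatenate([enz.embed(seq), sub.embed(smiles), aux])
    label_rng = np.random.default_rng(spec.seed + 5)
    y_kcat, y_km, latents = gen_labels(
        X, spec.shared_signal_fraction, spec.noise_sd, coefficients, label_rng
    )

    patterns = rng.choice(
        ["both", "kcat_only", "km_only"], size=n, p=list(spec.missing_props)
    )

    truth = GroundTruth(
        rho=spec.shared_signal_fraction,
        noise_sd=spec.noise_sd,
        coefficients=coefficients,
        aux_spec=aux_spec,
        aux_params=aux_params,
    )
    records: List[KineticRecord] = []
    for i, (wild, codes, seq, smiles, org, ph, temp, ec) in enumerate(rows):
        etype = EnzymeType.MUTANT if codes else EnzymeType.WILD_TYPE
        key = (smiles, seq, ph, temp, org)
        truth.per_entry[key] = {
            "u": float(latents["u"][i]),
            "v_kcat": float(latents["v_kcat"][i]),
            "v_km": float(latents["v_km"][i]),
            "true_kcat": float(latents["true_kcat"][i]),
            "true_km": float(latents["true_km"][i]),
            "label_kcat": float(y_kcat[i]),
            "label_km": float(y_km[i]),
            "pattern": str(patterns[i]),
        }
        dup_group = i < spec.n_duplicate_groups
        if patterns[i] in ("both", "kcat_only"):
            value = 10.0 ** y_kcat[i]
            unit, scale = _KCAT_UNIT_CHOICES[int(rng.integers(3))]
            records.append(
                _make_record(i, "k", ParamKind.KCAT, wild, codes, etype,
                             smiles, org, ph, temp, value * scale, unit, ec)
            )
            if dup_group:
                # decoy duplicate with a smaller kcat: aggregation keeps the max
                records.append(
                    _make_record(i, "kd", ParamKind.KCAT, wild, codes, etype,
                                 smiles, org, ph, temp, value * 0.5, "s^-1", ec)
                )
        if patterns[i] in ("both", "km_only"):
            value = 10.0 ** y_km[i]
            unit, scale = _KM_UNIT_CHOICES[int(rng.integers(4))]
            records.append(
                _make_record(i, "m", ParamKind.KM, wild, codes, etype,
                             smiles, org, ph, temp, value * scale, unit, ec)
            )
            if dup_group:
                # decoy duplicate with a larger Km: aggregation keeps the min
                records.append(
                    _make_record(i, "md", ParamKind.KM, wild, codes, etype,
                                 smiles, org, ph, temp, value * 2.0, "mM", ec)
                )

    records.extend(_planted_violations(spec, rng, organisms))
    return records, truth


def _planted_violations(
    spec: SynthSpec, rng: np.random.Generator, organisms: Sequence[str]
) -> List[KineticRecord]:
    out: List[KineticRecord] = []
    counter = 0
    base_seq = gen_sequences(1, spec.seq_length_range, spec.seed + 6)[0]

    def base(kind: str, **over) -> KineticRecord:
        nonlocal counter
        counter += 1
        fields = dict(
            record_id=f"bad-{kind}-{counter:04d}",
            ec_number="1.1.1.1",
            enzyme_type=EnzymeType.WILD_TYPE,
            mutation_codes=(),
            sequence=base_seq,
            substrate_name="planted",
            substrate_smiles="CCCO",
            organism=organisms[0],
            ph=7.0,
            temperature=30.0,
            param_kind=ParamKind.KCAT,
            value=1.0,
            unit="s^-1",
            source=Source.SYNTHETIC,
        )
        fields.update(over)
        return KineticRecord(**fields)

    for kind, count in spec.planted_violations.items():
        if kind not in VIOLATION_KINDS:
            raise ValueError(f"unknown violation kind {kind!r}")
        for j in range(count):
            if kind == "incomplete":
                out.append(base(kind, ph=None))
            elif kind == "small_substrate":
                out.append(
                    base(kind, substrate_smiles=gen_substrates(
                        1, spec.seed + 7 + j, violator="small")[0])
                )
            elif kind == "large_substrate":
                out.append(
                    base(kind, substrate_smiles=gen_substrates(
                        1, spec.seed + 7 + j, violator="large")[0])
                )
            elif kind == "fragment":
                out.append(
                    base(kind, substrate_smiles=gen_substrates(
                        1, spec.seed + 7 + j, violator="fragment")[0])
                )
            elif kind == "nonpositive":
                out.append(base(kind, value=float(rng.choice([-1.0, 0.0]))))
            elif kind == "unknown_unit":
                out.append(base(kind, unit="kat"))
            elif kind == "bad_mutation":
                ref = base_seq[0]
                wrong = next(a for a in AMINO_ACIDS if a != ref)
                out.append(
                    base(
                        kind,
                        enzyme_type=EnzymeType.MUTANT,
                        mutation_codes=(f"{wrong}1{ref}",),
                    )
                )
    return out


def gen_casestudy(
    n_variants: int, n_correct: int, seed: int = 0
) -> Tuple[Tuple[float, float], List[Tuple[str, float, float]]]:
    """Reference and variant efficiencies with a planted direction-match count.

    Returns (reference, variants) in the shape :func:`kinemoe.evalsplit.hit_ratio`
    consumes: the reference is (experimental, predicted) log10 efficiency and
    each variant is (id, experimental, predicted).  Exactly ``n_correct`` of
    the variants have a predicted change whose sign matches the experimental
    change.
    """
    if not 0 <= n_correct <= n_variants:
        raise ValueError("n_correct must lie in [0, n_variants]")
    rng = np.random.default_rng(seed)
    reference = (1.0, 0.8)
    correct = np.zeros(n_variants, dtype=bool)
    correct[:n_correct] = True
    rng.shuffle(correct)
    variants = []
    for i in range(n_variants):
        d_exp = float(rng.uniform(0.2, 1.5)) * (1 if rng.random() < 0.5 else -1)
        d_pred = float(rng.uniform(0.1, 1.2))
        d_pred *= np.sign(d_exp) if correct[i] else -np.sign(d_exp)
        variants.append(
            (f"variant-{i + 1}", reference[0] + d_exp, reference[1] + d_pred)
        )
    return reference, variants
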