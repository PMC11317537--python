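"""Data-curation pipeline for kinetic-parameter records.

Cleaning stages, applied in order:

1. completeness filter (every required field present),
2. unit normalization to s^-1 / mM (unknown units rejected),
3. mutation application (mutant rows supplied as wild-type sequence +
   substitution codes such as ``A123V``),
4. SMILES canonicalization (RDKit),
5. structural filter (2 < heavy atoms <= 128, no multi-fragment "." SMILES),
6. value filter (kinetic value strictly positive),
7. per-key duplicate aggregation (max kcat, min Km before the log transform),
8. log10 transform,
9. outer join of the kcat and Km tables into joint multitask entries.

Per-record failures are logged with a reason code; the batch never aborts.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit import RDLogger

from .records import (
    CuratedEntry,
    EntryKey,
    EnzymeType,
    KineticRecord,
    ParamKind,
    UnknownUnitError,
    log_transform,
    normalize_unit,
)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CurationReport",
    "MutationError",
    "drop_incomplete",
    "filter_structure",
    "filter_values",
    "canonicalize_smiles",
    "heavy_atom_count",
    "apply_mutations",
    "dedup_and_aggregate",
    "merge_tasks",
    "curate_pipeline",
]

# reason codes written to the report's reason log
R_INCOMPLETE = "incomplete"
R_UNKNOWN_UNIT = "unknown_unit"
R_MUTATION = "mutation_error"
R_SMILES_PARSE = "smiles_parse_error"
R_HEAVY_ATOMS = "heavy_atom_count"
R_FRAGMENT = "fragment_smiles"
R_NONPOSITIVE = "nonpositive_value"
R_DUPLICATE = "exact_duplicate"


@dataclass
class CurationReport:
    """Per-stage bookkeeping for one curation run."""

    n_input: int = 0
    n_dropped_incomplete: int = 0
    n_dropped_unknown_unit: int = 0
    n_dropped_mutation_error: int = 0
    n_dropped_smiles_parse: int = 0
    n_dropped_heavy_atoms: int = 0
    n_dropped_fragment_or_nonpositive: int = 0
    n_dropped_duplicate: int = 0
    n_aggregated: int = 0
    n_output: int = 0
    reasons: List[Tuple[str, str]] = field(default_factory=list)

    def log(self, record_id: str, reason: str) -> None:
        self.reasons.append((record_id, reason))

    @property
    def n_dropped_total(self) -> int:
        return (
            self.n_dropped_incomplete
            + self.n_dropped_unknown_unit
            + self.n_dropped_mutation_error
            + self.n_dropped_smiles_parse
            + self.n_dropped_heavy_atoms
            + self.n_dropped_fragment_or_nonpositive
            + self.n_dropped_duplicate
        )

    def check_balance(self) -> None:
        """Input = drops + merged-away + per-parameter outputs folded by the join."""
        kept = self.n_input - self.n_dropped_total - self.n_aggregated
        if kept != self._n_kept_rows:
            raise AssertionError(
                f"curation bookkeeping out of balance: {kept} != {self._n_kept_rows}"
            )

    # populated by curate_pipeline: rows surviving to the per-parameter tables
    _n_kept_rows: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_dropped_incomplete": self.n_dropped_incomplete,
            "n_dropped_unknown_unit": self.n_dropped_unknown_unit,
            "n_dropped_mutation_error": self.n_dropped_mutation_error,
            "n_dropped_smiles_parse": self.n_dropped_smiles_parse,
            "n_dropped_heavy_atoms": self.n_dropped_heavy_atoms,
            "n_dropped_fragment_or_nonpositive": self.n_dropped_fragment_or_nonpositive,
            "n_dropped_duplicate": self.n_dropped_duplicate,
            "n_aggregated": self.n_aggregated,
            "n_output": self.n_output,
            "reason_counts": dict(Counter(r for _, r in self.reasons)),
        }


REQUIRED_FIELDS = (
    "ec_number",
    "enzyme_type",
    "sequence",
    "substrate_smiles",
    "ph",
    "temperature",
    "organism",
    "value",
    "unit",
)


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    if isinstance(v, float) and v != v:  # NaN
        return True
    return False


def drop_incomplete(
    records: Iterable[KineticRecord],
) -> Tuple[List[KineticRecord], List[KineticRecord]]:
    """Split records into (kept, dropped) by presence of every required field."""
    kept, dropped = [], []
    for r in records:
        if any(_is_missing(getattr(r, f)) for f in REQUIRED_FIELDS):
            dropped.append(r)
        else:
            kept.append(r)
    return kept, dropped


def canonicalize_smiles(smiles: str) -> str:
    """Deterministic canonical SMILES via RDKit; raises on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms in the molecule encoded by ``smiles``."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol.GetNumHeavyAtoms()


def filter_structure(
    records: Iterable[KineticRecord],
) -> Tuple[List[KineticRecord], List[KineticRecord], List[str]]:
    """Keep substrates with 2 < heavy atoms <= 128 and no "." fragment separator.

    Returns (kept, dropped, reasons) with one reason per dropped record.
    """
    kept, dropped, reasons = [], [], []
    for r in records:
        smi = r.substrate_smiles or ""
        if "." in smi:
            dropped.append(r)
            reasons.append(R_FRAGMENT)
            continue
        try:
            h = heavy_atom_count(smi)
        except ValueError:
            dropped.append(r)
            reasons.append(R_SMILES_PARSE)
            continue
        if h <= 2 or h > 128:
            dropped.append(r)
            reasons.append(R_HEAVY_ATOMS)
        else:
            kept.append(r)
    return kept, dropped, reasons


def filter_values(
    records: Iterable[KineticRecord],
) -> Tuple[List[KineticRecord], List[KineticRecord]]:
    """Keep records whose kinetic value is strictly positive."""
    kept, dropped = [], []
    for r in records:
        (kept if (r.value is not None and r.value > 0) else dropped).append(r)
    return kept, dropped


MUTATION_CODE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class MutationError(ValueError):
    """A substitution code that cannot be applied to the wild-type sequence."""


def apply_mutations(wild_sequence: str, codes: Sequence[str]) -> str:
    """Apply substitution codes like ``K2A`` (1-based) to a wild-type sequence.

    Only substitutions are supported; the reference residue in each code must
    match the wild-type sequence at that position.
    """
    seq = list(wild_sequence)
    for code in codes:
        m = MUTATION_CODE.match(code.strip())
        if m is None:
            raise MutationError(f"malformed substitution code {code!r}")
        ref, pos, new = m.group(1), int(m.group(2)), m.group(3)
        if not 1 <= pos <= len(seq):
            raise MutationError(
                f"position {pos} out of range for sequence of length {len(seq)}"
            )
        if wild_sequence[pos - 1] != ref:
            raise MutationError(
                f"reference mismatch at position {pos}: "
                f"code says {ref}, sequence has {wild_sequence[pos - 1]}"
            )
        seq[pos - 1] = new
    return "".join(seq)


def _record_key(r: KineticRecord) -> EntryKey:
    return (r.substrate_smiles, r.sequence, r.ph, r.temperature, r.organism)


def dedup_and_aggregate(
    records: Iterable[KineticRecord],
) -> Tuple[List[KineticRecord], int, int]:
    """Collapse same-key groups: keep max kcat / min Km, on the linear scale.

    Byte-identical measurements (same key and value) collapse silently; groups
    with differing values are resolved by the extremum rule.  Records must
    already be unit-normalized and SMILES-canonicalized.  Returns
    (one record per key per parameter, n_exact_duplicates, n_merged_away).
    """
    groups: Dict[Tuple[EntryKey, ParamKind], List[KineticRecord]] = {}
    order: List[Tuple[EntryKey, ParamKind]] = []
    for r in records:
        k = (_record_key(r), r.param_kind)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(r)

    out: List[KineticRecord] = []
    n_exact = 0
    n_merged = 0
    for k in order:
        grp = groups[k]
        values = [g.value for g in grp]
        uniq = len(set(values))
        n_exact += len(values) - uniq
        n_merged += uniq - 1
        pick = max if k[1] == ParamKind.KCAT else min
        best = pick(grp, key=lambda g: g.value)
        out.append(best)
    return out, n_exact, n_merged


def merge_tasks(
    kcat_entries: Dict[EntryKey, KineticRecord],
    km_entries: Dict[EntryKey, KineticRecord],
) -> List[CuratedEntry]:
    """Outer-join the deduplicated kcat and Km tables on the shared key."""
    keys = list(kcat_entries)
    keys += [k for k in km_entries if k not in kcat_entries]
    out = []
    for key in keys:
        rk = kcat_entries.get(key)
        rm = km_entries.get(key)
        ref = rk or rm
        out.append(
            CuratedEntry(
                key=key,
                ec_number=ref.ec_number,
                enzyme_type=ref.enzyme_type,
                mutation_codes=tuple(ref.mutation_codes),
                log10_kcat=log_transform(rk.value) if rk is not None else None,
                log10_km=log_transform(rm.value) if rm is not None else None,
            )
        )
    return out


def curate_pipeline(
    records: Sequence[KineticRecord],
) -> Tuple[List[CuratedEntry], CurationReport]:
    """Run the full cleaning pipeline; per-record failures go to the reason log."""
    report = CurationReport(n_input=len(records))

    kept, dropped = drop_incomplete(records)
    report.n_dropped_incomplete = len(dropped)
    for r in dropped:
        report.log(r.record_id, R_INCOMPLETE)

    # unit normalization
    normalized: List[KineticRecord] = []
    for r in kept:
        try:
            v = normalize_unit(r.value, r.unit, r.param_kind)
        except UnknownUnitError:
            report.n_dropped_unknown_unit += 1
            report.log(r.record_id, R_UNKNOWN_UNIT)
            continue
        normalized.append(
            replace(r, value=v, unit="s^-1" if r.param_kind == ParamKind.KCAT else "mM")
        )

    # mutation application for mutant rows given as wild sequence + codes
    mutated: List[KineticRecord] = []
    for r in normalized:
        if r.enzyme_type == EnzymeType.MUTANT and r.mutation_codes:
            try:
                mutant_seq = apply_mutations(r.sequence, r.mutation_codes)
            except MutationError:
                report.n_dropped_mutation_error += 1
                report.log(r.record_id, R_MUTATION)
                continue
            r = replace(r, sequence=mutant_seq)
        mutated.append(r)

    # canonicalization
    canonical: List[KineticRecord] = []
    for r in mutated:
        if "." in r.substrate_smiles:
            # fragment check precedes parsing so dotted SMILES keep their reason
            canonical.append(r)
            continue
        try:
            smi = canonicalize_smiles(r.substrate_smiles)
        except ValueError:
            report.n_dropped_smiles_parse += 1
            report.log(r.record_id, R_SMILES_PARSE)
            continue
        canonical.append(replace(r, substrate_smiles=smi))

    kept2, dropped2, reasons2 = filter_structure(canonical)
    for r, why in zip(dropped2, reasons2):
        report.log(r.record_id, why)
        if why == R_HEAVY_ATOMS:
            report.n_dropped_heavy_atoms += 1
        elif why == R_SMILES_PARSE:
            report.n_dropped_smiles_parse += 1
        else:
            report.n_dropped_fragment_or_nonpositive += 1

    kept3, dropped3 = filter_values(kept2)
    report.n_dropped_fragment_or_nonpositive += len(dropped3)
    for r in dropped3:
        report.log(r.record_id, R_NONPOSITIVE)

    deduped, n_exact, n_merged = dedup_and_aggregate(kept3)
    report.n_dropped_duplicate = n_exact
    report.n_aggregated = n_merged
    report._n_kept_rows = len(deduped)

    kcat_tab = {
        _record_key(r): r for r in deduped if r.param_kind == ParamKind.KCAT
    }
    km_tab = {_record_key(r): r for r in deduped if r.param_kind == ParamKind.KM}
    entries = merge_tasks(kcat_tab, km_tab)
    report.n_output = len(entries)
    report.check_balance()
    return entries, report
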