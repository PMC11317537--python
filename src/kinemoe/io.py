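"""Reading and writing the tabular interchange formats.

Raw records travel as CSV/TSV with one kinetic value per row; the column
schema mirrors a typical kinetic-database export:

    record_id, ec_number, enzyme_type, mutation_codes, sequence,
    substrate_name, substrate_smiles, organism, ph, temperature,
    param_kind, value, unit, source

``mutation_codes`` is a semicolon-joined list (empty for wild-type).
Sequences may instead be supplied via a FASTA file whose record IDs match
the ``record_id`` column.  Curated entries round-trip through a flat CSV
with the key columns plus optional ``log10_kcat`` / ``log10_km``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .records import CuratedEntry, EnzymeType, KineticRecord, ParamKind, Source

__all__ = [
    "read_records_csv",
    "write_records_csv",
    "read_fasta_sequences",
    "write_entries_csv",
    "read_entries_csv",
]

RECORD_COLUMNS = [
    "record_id",
    "ec_number",
    "enzyme_type",
    "mutation_codes",
    "sequence",
    "substrate_name",
    "substrate_smiles",
    "organism",
    "ph",
    "temperature",
    "param_kind",
    "value",
    "unit",
    "source",
]


def _opt_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    return s or None


def _opt_float(v) -> Optional[float]:
    if v is None or v == "":
        return None
    f = float(v)
    return None if math.isnan(f) else f


def read_fasta_sequences(path: Union[str, Path]) -> Dict[str, str]:
    """FASTA file -> {record id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_records_csv(
    path: Union[str, Path], fasta: Optional[Union[str, Path]] = None
) -> List[KineticRecord]:
    """Load raw kinetic records from CSV/TSV (delimiter sniffed by suffix).

    When ``fasta`` is given, sequences are looked up there by record ID and
    override any inline ``sequence`` column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    seqs = read_fasta_sequences(fasta) if fasta else {}
    records = []
    for _, row in df.iterrows():
        rid = row.get("record_id", "")
        etype = _opt_str(row.get("enzyme_type"))
        codes = tuple(
            c.strip() for c in (row.get("mutation_codes") or "").split(";") if c.strip()
        )
        records.append(
            KineticRecord(
                record_id=rid,
                ec_number=_opt_str(row.get("ec_number")),
                enzyme_type=EnzymeType(etype) if etype else None,
                mutation_codes=codes,
                sequence=seqs.get(rid) or _opt_str(row.get("sequence")),
                substrate_name=_opt_str(row.get("substrate_name")),
                substrate_smiles=_opt_str(row.get("substrate_smiles")),
                organism=_opt_str(row.get("organism")),
                ph=_opt_float(row.get("ph")),
                temperature=_opt_float(row.get("temperature")),
                param_kind=ParamKind(row["param_kind"]),
                value=_opt_float(row.get("value")),
                unit=_opt_str(row.get("unit")),
                source=Source(_opt_str(row.get("source")) or "synthetic"),
            )
        )
    return records


def write_records_csv(
    records: Sequence[KineticRecord], path: Union[str, Path]
) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "ec_number": r.ec_number,
                "enzyme_type": r.enzyme_type.value if r.enzyme_type else None,
                "mutation_codes": ";".join(r.mutation_codes),
                "sequence": r.sequence,
                "substrate_name": r.substrate_name,
                "substrate_smiles": r.substrate_smiles,
                "organism": r.organism,
                "ph": r.ph,
                "temperature": r.temperature,
                "param_kind": r.param_kind.value,
                "value": r.value,
                "unit": r.unit,
                "source": r.source.value,
            }
        )
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


ENTRY_COLUMNS = [
    "canonical_smiles",
    "sequence",
    "ph",
    "temperature",
    "organism",
    "ec_number",
    "enzyme_type",
    "mutation_codes",
    "log10_kcat",
    "log10_km",
]


def write_entries_csv(
    entries: Sequence[CuratedEntry], path: Union[str, Path]
) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "canonical_smiles": e.canonical_smiles,
                "sequence": e.sequence,
                "ph": e.ph,
                "temperature": e.temperature,
                "organism": e.organism,
                "ec_number": e.ec_number,
                "enzyme_type": e.enzyme_type.value,
                "mutation_codes": ";".join(e.mutation_codes),
                "log10_kcat": e.log10_kcat,
                "log10_km": e.log10_km,
            }
        )
    pd.DataFrame(rows, columns=ENTRY_COLUMNS).to_csv(path, index=False)


def read_entries_csv(path: Union[str, Path]) -> List[CuratedEntry]:
    df = pd.read_csv(path)
    entries = []
    for _, row in df.iterrows():
        # stored sequences are post-mutation: codes are provenance only
        entries.append(
            CuratedEntry(
                key=(
                    str(row["canonical_smiles"]),
                    str(row["sequence"]),
                    float(row["ph"]),
                    float(row["temperature"]),
                    str(row["organism"]),
                ),
                ec_number=str(row["ec_number"]),
                enzyme_type=EnzymeType(row["enzyme_type"]),
                mutation_codes=tuple(
                    c
                    for c in str(row.get("mutation_codes") or "").split(";")
                    if c and c != "nan"
                ),
                log10_kcat=_opt_float(row.get("log10_kcat")),
                log10_km=_opt_float(row.get("log10_km")),
            )
        )
    return entries
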