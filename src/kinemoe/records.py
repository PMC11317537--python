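"""Domain types and unit handling for enzyme kinetic-parameter records.

A raw record is one database row reporting a single kinetic value (a turnover
number kcat or a Michaelis constant Km) for an enzyme/substrate pair under
stated assay conditions.  Curated entries are keyed on
(canonical SMILES, sequence, pH, temperature, organism) and carry log10-scale
labels in canonical units: s^-1 for kcat and mM for Km.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Optional, Sequence, Tuple

__all__ = [
    "ParamKind",
    "EnzymeType",
    "Source",
    "KineticRecord",
    "CuratedEntry",
    "DatasetAccounting",
    "UnknownUnitError",
    "normalize_unit",
    "denormalize_unit",
    "log_transform",
    "accounting",
    "KCAT_UNIT_SCALE",
    "KM_UNIT_SCALE",
]


class ParamKind(str, Enum):
    KCAT = "kcat"
    KM = "km"


class EnzymeType(str, Enum):
    WILD_TYPE = "wild_type"
    MUTANT = "mutant"


class Source(str, Enum):
    BRENDA = "brenda"
    SABIO_RK = "sabio_rk"
    SYNTHETIC = "synthetic"


#: Exact rational scale factors to the canonical unit (s^-1 for kcat, mM for Km).
#: The table is closed: a unit outside it rejects the record rather than guessing.
KCAT_UNIT_SCALE: dict[str, Fraction] = {
    "s^-1": Fraction(1),
    "1/s": Fraction(1),
    "s-1": Fraction(1),
    "min^-1": Fraction(1, 60),
    "1/min": Fraction(1, 60),
    "min-1": Fraction(1, 60),
    "h^-1": Fraction(1, 3600),
    "1/h": Fraction(1, 3600),
    "h-1": Fraction(1, 3600),
}

KM_UNIT_SCALE: dict[str, Fraction] = {
    "M": Fraction(1000),
    "mM": Fraction(1),
    "uM": Fraction(1, 1000),
    "µM": Fraction(1, 1000),
    "nM": Fraction(1, 1_000_000),
}

CANONICAL_UNIT = {ParamKind.KCAT: "s^-1", ParamKind.KM: "mM"}


class UnknownUnitError(ValueError):
    """Raised when a unit string is outside the closed conversion table."""


def _scale(unit: str, param_kind: ParamKind) -> Fraction:
    table = KCAT_UNIT_SCALE if param_kind == ParamKind.KCAT else KM_UNIT_SCALE
    try:
        return table[unit]
    except KeyError:
        raise UnknownUnitError(
            f"unknown {param_kind.value} unit {unit!r}; "
            f"known units: {sorted(table)}"
        ) from None


def normalize_unit(value: float, unit: str, param_kind: ParamKind) -> float:
    """Convert ``value`` in ``unit`` to the canonical unit (s^-1 or mM).

    Conversion is an exact rational scaling; unknown units raise
    :class:`UnknownUnitError` so callers can reject the record with a reason.
    """
    return float(value * _scale(unit, param_kind))


def denormalize_unit(value: float, unit: str, param_kind: ParamKind) -> float:
    """Inverse of :func:`normalize_unit` (canonical unit back to ``unit``)."""
    return float(value / _scale(unit, param_kind))


def log_transform(value: float) -> float:
    """log10 of a strictly positive kinetic value.

    Non-positive values must have been filtered upstream; they raise here.
    """
    if value <= 0:
        raise ValueError(f"log10 requires a strictly positive value, got {value}")
    return math.log10(value)


@dataclass
class KineticRecord:
    """One raw database row: a single kinetic value with its context."""

    record_id: str
    ec_number: Optional[str]
    enzyme_type: Optional[EnzymeType]
    mutation_codes: Tuple[str, ...]
    sequence: Optional[str]
    substrate_name: Optional[str]
    substrate_smiles: Optional[str]
    organism: Optional[str]
    ph: Optional[float]
    temperature: Optional[float]
    param_kind: ParamKind
    value: Optional[float]
    unit: Optional[str]
    source: Source = Source.SYNTHETIC

    def __post_init__(self) -> None:
        if self.enzyme_type == EnzymeType.WILD_TYPE and self.mutation_codes:
            raise ValueError(
                f"record {self.record_id}: wild-type records carry no mutation codes"
            )


EntryKey = Tuple[str, str, float, float, str]


@dataclass
class CuratedEntry:
    """One cleaned, unit-normalized entry with log10-scale label(s).

    ``key`` is (canonical_smiles, sequence, ph, temperature, organism); at
    least one of the two labels is present.
    """

    key: EntryKey
    ec_number: str
    enzyme_type: EnzymeType
    mutation_codes: Tuple[str, ...] = ()
    log10_kcat: Optional[float] = None
    log10_km: Optional[float] = None

    def __post_init__(self) -> None:
        if self.log10_kcat is None and self.log10_km is None:
            raise ValueError(f"entry {self.key}: at least one label is required")

    @property
    def canonical_smiles(self) -> str:
        return self.key[0]

    @property
    def sequence(self) -> str:
        return self.key[1]

    @property
    def ph(self) -> float:
        return self.key[2]

    @property
    def temperature(self) -> float:
        return self.key[3]

    @property
    def organism(self) -> str:
        return self.key[4]

    @property
    def label_pattern(self) -> str:
        """'both', 'kcat_only' or 'km_only' depending on which labels exist."""
        if self.log10_kcat is not None and self.log10_km is not None:
            return "both"
        return "kcat_only" if self.log10_kcat is not None else "km_only"


@dataclass(frozen=True)
class DatasetAccounting:
    """Label-pattern bookkeeping for a joint kcat/Km dataset."""

    n_both: int
    n_kcat_only: int
    n_km_only: int
    n_kcat_total: int = field(init=False)
    n_km_total: int = field(init=False)
    n_union: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_kcat_total", self.n_both + self.n_kcat_only)
        object.__setattr__(self, "n_km_total", self.n_both + self.n_km_only)
        object.__setattr__(
            self, "n_union", self.n_both + self.n_kcat_only + self.n_km_only
        )


def accounting(entries: Iterable[CuratedEntry]) -> DatasetAccounting:
    """Count entries by label pattern; the totals partition the union."""
    n_both = n_kcat_only = n_km_only = 0
    for e in entries:
        p = e.label_pattern
        if p == "both":
            n_both += 1
        elif p == "kcat_only":
            n_kcat_only += 1
        else:
            n_km_only += 1
    return DatasetAccounting(n_both, n_kcat_only, n_km_only)


def accounting_from_counts(
    n_both: int, n_kcat_only: int, n_km_only: int
) -> DatasetAccounting:
    """Accounting identities applied to pre-counted label-pattern sizes."""
    return DatasetAccounting(n_both, n_kcat_only, n_km_only)
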