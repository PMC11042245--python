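"""Bioactivity curation: raw assay tables to pChEMBL-labelled compounds.

A raw bioactivity export (one row per assay measurement) is parsed into
:class:`BioactivityRecord` objects, each measurement convertible to a molar
concentration is transformed to a pChEMBL value

    pChEMBL = -log10(effective concentration in mol/L)

and measurements of the same molecule (identified by canonical SMILES) are
aggregated by an unweighted mean on the pChEMBL scale.  Averaging on the log
scale keeps mixed endpoint types (IC50, Ki, ...) commensurable and is the
standard convention for pChEMBL-like quantities.

Non-concentration endpoints (Emax, Fc, percentages) have no defined pChEMBL
and are rejected with a reason; censored qualifiers ("<", ">") are rejected
by default because censored labels bias a regression target.  Nothing is
silently dropped: every input row is accounted for either in a compound or in
the rejects log.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

ENDPOINT_TYPES = {"IC50", "EC50", "AC50", "Ki", "Kd", "Fc", "Emax", "other"}
QUALIFIERS = {"=", "<", ">", "<=", ">=", "missing"}

#: unit token -> multiplier to mol/L; Greek-mu spellings alias to uM
_UNIT_TO_MOLAR = {
    "nm": 1e-9,
    "um": 1e-6,
    "µm": 1e-6,  # micro sign
    "μm": 1e-6,  # greek mu
    "mm": 1e-3,
    "m": 1.0,
}

_QUALIFIER_ALIASES = {
    "=": "=",
    "<": "<",
    ">": ">",
    "<=": "<=",
    ">=": ">=",
    "≤": "<=",
    "≥": ">=",
    "": "missing",
    "missing": "missing",
}

#: preset column map matching a ChEMBL activity export
CHEMBL_COLUMN_MAP = {
    "compound_id": "Molecule ChEMBL ID",
    "smiles": "Smiles",
    "endpoint_type": "Standard Type",
    "qualifier": "Standard Relation",
    "value": "Standard Value",
    "unit": "Standard Units",
}

DEFAULT_COLUMN_MAP = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "endpoint_type": "endpoint_type",
    "qualifier": "qualifier",
    "value": "value",
    "unit": "unit",
}


class NotConvertibleError(ValueError):
    """Raised when a value/unit pair has no molar interpretation."""


class CurationError(RuntimeError):
    """Raised when curation cannot produce any compound."""


@dataclass(frozen=True)
class BioactivityRecord:
    """One raw assay measurement."""

    compound_id: str
    smiles: str
    endpoint_type: str
    qualifier: str
    value: float | None
    unit: str | None


@dataclass(frozen=True)
class CuratedCompound:
    """A deduplicated molecule with aggregated pChEMBL and activity label."""

    structure_key: str
    pchembl: float
    n_source_records: int
    active: bool


@dataclass
class CurationConfig:
    """Rules governing which records contribute and how they are labelled.

    activity_threshold is in pChEMBL units; a compound is active when its
    aggregated pChEMBL is >= the threshold (inclusive, so 7.00 at threshold 7
    counts as active).
    """

    activity_threshold: float = 7.0
    keep_qualifiers: frozenset[str] = frozenset({"="})
    accepted_endpoints: frozenset[str] = frozenset(
        {"IC50", "EC50", "AC50", "Ki", "Kd"}
    )

    def __post_init__(self) -> None:
        if not math.isfinite(self.activity_threshold):
            raise ValueError("activity_threshold must be finite")
        if not self.accepted_endpoints:
            raise ValueError("accepted_endpoints must be non-empty")


@dataclass
class CurationLog:
    """Row-level accounting of a curation run."""

    n_records: int = 0
    n_contributing: int = 0
    n_compounds: int = 0
    rejects: list[tuple[BioactivityRecord, str]] = field(default_factory=list)

    def reject_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in self.rejects:
            counts[reason] = counts.get(reason, 0) + 1
        return counts

    def summary(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_contributing": self.n_contributing,
            "n_rejected": len(self.rejects),
            "n_compounds": self.n_compounds,
            "reject_reasons": self.reject_counts(),
        }


def normalize_unit(unit: str | None) -> str | None:
    """Map a raw unit token to its vocabulary form, or None if unknown."""
    if unit is None:
        return None
    token = unit.strip().lower()
    canonical = {"nm": "nM", "um": "uM", "µm": "uM", "μm": "uM", "mm": "mM", "m": "M"}
    return canonical.get(token)


def to_molar(value: float, unit: str) -> float:
    """Convert a concentration to mol/L.

    Raises :class:`NotConvertibleError` for non-concentration units (e.g. "%")
    and ValueError for non-positive values.
    """
    if value is None or not math.isfinite(value) or value <= 0:
        raise ValueError(f"concentration must be positive, got {value!r}")
    token = (unit or "").strip().lower()
    if token not in _UNIT_TO_MOLAR:
        raise NotConvertibleError(f"unit {unit!r} is not a concentration unit")
    return value * _UNIT_TO_MOLAR[token]


def pchembl_from_molar(value_molar: float) -> float:
    """pChEMBL = -log10(concentration in mol/L); 100 nM maps to 7.0."""
    if value_molar is None or not math.isfinite(value_molar) or value_molar <= 0:
        raise ValueError(f"molar value must be positive, got {value_molar!r}")
    return -math.log10(value_molar)


def label_active(pchembl: float, threshold: float = 7.0) -> bool:
    """Inclusive activity rule: active iff pchembl >= threshold."""
    if not (math.isfinite(pchembl) and math.isfinite(threshold)):
        raise ValueError("pchembl and threshold must be finite")
    return pchembl >= threshold


def canonical_key(smiles: str) -> str:
    """Canonical SMILES used as the deduplication key.

    Delegates to RDKit's canonicalisation so that any two SMILES encodings of
    the same molecule map to the same key.
    """
    if not smiles or not smiles.strip():
        raise ValueError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def parse_activity_table(
    source: TextIO | str,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> tuple[list[BioactivityRecord], list[tuple[dict, str]]]:
    """Parse a CSV/TSV activity table into records plus a rejects list.

    ``column_map`` maps the logical field names (compound_id, smiles,
    endpoint_type, qualifier, value, unit) to header names in the file.
    Unparseable rows are returned with a reason, never dropped.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    if isinstance(source, str):
        source = io.StringIO(source)
    text = source.read()
    if not text.strip():
        raise ValueError("empty activity table")
    if delimiter is None:
        delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    header = reader.fieldnames or []
    missing = [v for v in column_map.values() if v not in header]
    if missing:
        raise ValueError(f"mapped columns missing from header: {missing}")

    records: list[BioactivityRecord] = []
    rejects: list[tuple[dict, str]] = []
    for row in reader:
        smiles = (row[column_map["smiles"]] or "").strip()
        if not smiles:
            rejects.append((row, "missing structure"))
            continue
        raw_value = (row[column_map["value"]] or "").strip()
        try:
            value = float(raw_value) if raw_value else None
        except ValueError:
            rejects.append((row, "non-numeric value"))
            continue
        if value is not None and value <= 0:
            rejects.append((row, "non-positive value"))
            continue
        endpoint = (row[column_map["endpoint_type"]] or "").strip() or "other"
        if endpoint not in ENDPOINT_TYPES:
            endpoint = "other"
        qualifier = _QUALIFIER_ALIASES.get(
            (row[column_map["qualifier"]] or "").strip().strip("'\""), "missing"
        )
        unit = (row[column_map["unit"]] or "").strip() or None
        records.append(
            BioactivityRecord(
                compound_id=(row[column_map["compound_id"]] or "").strip(),
                smiles=smiles,
                endpoint_type=endpoint,
                qualifier=qualifier,
                value=value,
                unit=unit,
            )
        )
    return records, rejects


def record_pchembl(record: BioactivityRecord) -> float:
    """pChEMBL of a single record (raises if not convertible)."""
    if record.value is None:
        raise NotConvertibleError("missing value")
    return pchembl_from_molar(to_molar(record.value, record.unit or ""))


def curate(
    records: Iterable[BioactivityRecord],
    config: CurationConfig | None = None,
) -> tuple[list[CuratedCompound], CurationLog]:
    """Deduplicate and aggregate records into pChEMBL-labelled compounds.

    Each admissible record is converted to pChEMBL first; a compound's label
    is the unweighted mean over its records (permutation-invariant).  The log
    accounts for every input row.
    """
    config = config or CurationConfig()
    log = CurationLog()
    by_key: dict[str, list[float]] = {}
    order: list[str] = []

    for record in records:
        log.n_records += 1
        if record.qualifier not in config.keep_qualifiers:
            log.rejects.append((record, f"qualifier {record.qualifier!r} excluded"))
            continue
        if record.endpoint_type not in config.accepted_endpoints:
            log.rejects.append((record, "endpoint not convertible"))
            continue
        if normalize_unit(record.unit) is None:
            log.rejects.append((record, "unknown unit"))
            continue
        try:
            key = canonical_key(record.smiles)
        except ValueError:
            log.rejects.append((record, "unparseable structure"))
            continue
        try:
            p = record_pchembl(record)
        except (NotConvertibleError, ValueError):
            log.rejects.append((record, "value not convertible"))
            continue
        if key not in by_key:
            by_key[key] = []
            order.append(key)
        by_key[key].append(p)
        log.n_contributing += 1

    if not by_key:
        raise CurationError(
            f"no convertible records; rejections: {log.reject_counts()}"
        )

    compounds = [
        CuratedCompound(
            structure_key=key,
            pchembl=sum(by_key[key]) / len(by_key[key]),
            n_source_records=len(by_key[key]),
            active=label_active(
                sum(by_key[key]) / len(by_key[key]), config.activity_threshold
            ),
        )
        for key in order
    ]
    log.n_compounds = len(compounds)
    return compounds, log


def compounds_to_rows(compounds: Iterable[CuratedCompound]) -> list[dict]:
    """Rows for the curated-dataset CSV (pChEMBL at full precision)."""
    return [
        {
            "structure_key": c.structure_key,
            "pchembl": c.pchembl,
            "n_source_records": c.n_source_records,
            "active": c.active,
        }
        for c in compounds
    ]
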