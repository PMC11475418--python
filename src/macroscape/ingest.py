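"""Target lists and bioactivity record ingestion.

Reads a target table (CSV/XLSX with a ``UniProt Accession ID`` column),
assigns solute-carrier family codes from gene symbols, and loads activity
records through a pluggable backend: a live ChEMBL API client, a local
dump directory (JSON-lines or CSV in the ChEMBL activity field dialect),
or an in-memory fixtures backend. The full pipeline and test suite run
against local backends; no network is ever required.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence

import pandas as pd

from .chem_core import Compound, standardize

logger = logging.getLogger(__name__)

DEFAULT_ID_COLUMN = "UniProt Accession ID"

#: ChEMBL activity dump field names (the on-disk dialect).
DUMP_FIELDS = [
    "molecule_chembl_id",
    "canonical_smiles",
    "standard_type",
    "standard_relation",
    "standard_value",
    "standard_units",
    "pchembl_value",
    "target_chembl_id",
    "assay_chembl_id",
    "document_chembl_id",
]


class SchemaError(ValueError):
    """A required column or field is missing from an input table."""


@dataclass(frozen=True)
class TargetEntry:
    uniprot_id: str
    chembl_target_id: Optional[str] = None
    gene_symbol: Optional[str] = None
    family_code: Optional[str] = None


@dataclass(frozen=True)
class ActivityRecord:
    """One bioactivity measurement tied to a structure and a target."""

    compound: Compound
    compound_id: str
    target: TargetEntry
    standard_type: str
    standard_relation: Optional[str]
    standard_value: Optional[float]
    standard_units: Optional[str]
    pchembl_value: Optional[float]
    assay_id: str
    document_id: str


@dataclass
class FetchResult:
    records: list[ActivityRecord]
    provenance: dict
    n_malformed: int = 0
    failed_targets: list[str] = field(default_factory=list)


def read_target_list(path: str | Path, id_column: str = DEFAULT_ID_COLUMN) -> list[TargetEntry]:
    """Read a target table; one entry per non-empty row, duplicates collapsed.

    Accepts CSV or XLSX (chosen by suffix). Optional columns
    ``ChEMBL ID`` and ``Gene Symbol`` populate the corresponding fields;
    family codes are filled by :func:`assign_family` when a symbol exists.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if id_column not in df.columns:
        raise SchemaError(
            f"column {id_column!r} not found; available columns: {list(df.columns)}"
        )
    entries: list[TargetEntry] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        acc = row[id_column]
        if pd.isna(acc) or not str(acc).strip():
            continue
        acc = str(acc).strip()
        if acc in seen:
            logger.warning("duplicate accession %s collapsed", acc)
            continue
        seen.add(acc)
        entry = TargetEntry(
            uniprot_id=acc,
            chembl_target_id=_opt_str(row.get("ChEMBL ID")),
            gene_symbol=_opt_str(row.get("Gene Symbol")),
        )
        if entry.gene_symbol:
            entry = assign_family(entry)
        entries.append(entry)
    return entries


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


_SLC_NUM = re.compile(r"^SLC(\d+)", re.IGNORECASE)
_SLCO = re.compile(r"^SLCO", re.IGNORECASE)


def assign_family(entry: TargetEntry) -> TargetEntry:
    """Parse the transporter family code out of a gene symbol.

    ``SLC6A2`` -> ``SLC6``; ``SLCO1B1`` -> ``SLCO``; the legacy ``SLC21``
    naming also maps to ``SLCO``. Anything else is ``other``.
    """
    symbol = entry.gene_symbol or ""
    if _SLCO.match(symbol):
        code = "SLCO"
    else:
        m = _SLC_NUM.match(symbol)
        if m:
            num = m.group(1)
            code = "SLCO" if num == "21" else f"SLC{num}"
        else:
            code = "other"
    return replace(entry, family_code=code)


class ActivityBackend(Protocol):
    """Source of raw activity dicts (dump dialect) for one target."""

    version: str

    def fetch(self, target: TargetEntry) -> list[dict]: ...


class DumpBackend:
    """Reads per-run activity dumps: one JSON-lines or CSV file.

    Records are matched to targets by ``target_chembl_id`` or UniProt
    accession. ``version`` is read from a ``VERSION`` sidecar when present
    (the database release the dump was taken from, e.g. ``ChEMBL30``).
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        version_file = self.path / "VERSION" if self.path.is_dir() else self.path.with_suffix(".version")
        self.version = (
            version_file.read_text().strip() if version_file.exists() else "unknown"
        )
        self._records = self._load()

    def _load(self) -> list[dict]:
        files: list[Path]
        if self.path.is_dir():
            files = sorted(
                p for p in self.path.iterdir() if p.suffix in (".jsonl", ".csv", ".json")
            )
        else:
            files = [self.path]
        out: list[dict] = []
        for f in files:
            if f.suffix in (".jsonl", ".json"):
                with open(f) as fh:
                    for line in fh:
                        line = line.strip()
                        if line:
                            out.append(json.loads(line))
            else:
                df = pd.read_csv(f)
                out.extend(
                    {k: (None if pd.isna(v) else v) for k, v in row.items()}
                    for row in df.to_dict("records")
                )
        return out

    def fetch(self, target: TargetEntry) -> list[dict]:
        keys = {target.chembl_target_id, target.uniprot_id} - {None}
        return [
            r
            for r in self._records
            if r.get("target_chembl_id") in keys or r.get("uniprot_id") in keys
        ]


class FixtureBackend:
    """In-memory backend over pre-built raw dicts, for tests and demos."""

    version = "fixtures"

    def __init__(self, records_by_target: dict[str, list[dict]]):
        self._by_target = records_by_target

    def fetch(self, target: TargetEntry) -> list[dict]:
        out = list(self._by_target.get(target.uniprot_id, []))
        if target.chembl_target_id:
            out.extend(self._by_target.get(target.chembl_target_id, []))
        return out


class ChemblApiBackend:
    """Live ChEMBL web-service backend (requires chembl_webresource_client)."""

    def __init__(self):
        try:
            from chembl_webresource_client.new_client import new_client
        except ImportError as exc:  # pragma: no cover - needs the client package
            raise ImportError(
                "chembl_webresource_client is required for the live backend; "
                "use a dump or fixtures backend offline"
            ) from exc
        self._client = new_client
        self.version = "ChEMBL-live"

    def fetch(self, target: TargetEntry) -> list[dict]:  # pragma: no cover
        acts = self._client.activity.filter(
            target_chembl_id=target.chembl_target_id
        ).only(DUMP_FIELDS)
        return list(acts)


def _to_float(value) -> Optional[float]:
    if value is None or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def normalize_record(raw: dict, target: TargetEntry) -> ActivityRecord:
    """Map one raw dump dict onto the internal schema.

    Salts and mixtures are kept as delivered (no desalting by default).
    Raises ``SchemaError`` when the structure or type field is missing.
    """
    smiles = raw.get("canonical_smiles")
    if not smiles:
        raise SchemaError("record lacks canonical_smiles")
    stype = raw.get("standard_type")
    if not stype:
        raise SchemaError("record lacks standard_type")
    value = _to_float(raw.get("standard_value"))
    if value is not None and value < 0:
        raise SchemaError("negative standard_value")
    return ActivityRecord(
        compound=standardize(smiles),
        compound_id=str(raw.get("molecule_chembl_id") or ""),
        target=target,
        standard_type=str(stype),
        standard_relation=_opt_str(raw.get("standard_relation")),
        standard_value=value,
        standard_units=_opt_str(raw.get("standard_units")),
        pchembl_value=_to_float(raw.get("pchembl_value")),
        assay_id=str(raw.get("assay_chembl_id") or ""),
        document_id=str(raw.get("document_chembl_id") or ""),
    )


def fetch_activities(
    targets: Sequence[TargetEntry],
    backend: ActivityBackend,
    retries: int = 2,
) -> FetchResult:
    """Fetch and normalize activity records for every target.

    Per-target failures are retried; targets that still fail are collected
    and reported in one hard error. Malformed records are skipped with a
    counter, never silently.
    """
    records: list[ActivityRecord] = []
    n_malformed = 0
    failed: list[str] = []
    for target in targets:
        raw_list = None
        for _ in range(retries + 1):
            try:
                raw_list = backend.fetch(target)
                break
            except Exception as exc:  # backend/network errors
                logger.warning("fetch failed for %s: %s", target.uniprot_id, exc)
        if raw_list is None:
            failed.append(target.uniprot_id)
            continue
        for raw in raw_list:
            try:
                records.append(normalize_record(raw, target))
            except SchemaError as exc:
                n_malformed += 1
                logger.warning("skipping malformed record: %s", exc)
    if failed:
        raise RuntimeError(f"backend failed for targets: {', '.join(failed)}")
    provenance = {"backend": type(backend).__name__, "db_version": backend.version}
    return FetchResult(records=records, provenance=provenance, n_malformed=n_malformed)


def record_to_raw(record: ActivityRecord) -> dict:
    """Serialize one record back to the dump dialect (lossless round trip)."""
    return {
        "molecule_chembl_id": record.compound_id,
        "canonical_smiles": record.compound.raw_smiles,
        "standard_type": record.standard_type,
        "standard_relation": record.standard_relation,
        "standard_value": record.standard_value,
        "standard_units": record.standard_units,
        "pchembl_value": record.pchembl_value,
        "target_chembl_id": record.target.chembl_target_id or record.target.uniprot_id,
        "assay_chembl_id": record.assay_id,
        "document_chembl_id": record.document_id,
    }


def write_dump(records: Iterable[ActivityRecord], path: str | Path, fmt: str = "jsonl") -> Path:
    """Write records as a JSON-lines or CSV dump readable by DumpBackend."""
    path = Path(path)
    rows = [record_to_raw(r) for r in records]
    if fmt == "jsonl":
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    elif fmt == "csv":
        pd.DataFrame(rows, columns=DUMP_FIELDS).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dump format: {fmt}")
    return path
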