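"""Embedded relational store for reagent and request records.

A single-file SQLite database realizes the reagent schema: one table
per record class, junction tables for the many-to-many links
(co-transfected constructs, multi-supe batches), and a persistent
per-prefix id counter so serials are never reused after deletion.

The store enforces:

* role-gated mutation (``record_admin`` for reagent records,
  ``request_admin`` for requests),
* link validation on every create/update (all violations reported),
* refusal-based deletion — a record referenced downstream cannot be
  deleted, so referential integrity can never be broken from the API,
* recomputation of derived fields (sequence properties, batch mass) on
  every write, never storing them stale.

Construct-map files and QC images live outside the database; only the
filename plus an existence flag is stored, and the existence check
refuses path components that escape the configured map directory.
"""

from __future__ import annotations

import csv
import json
import sqlite3
from dataclasses import dataclass, field
from importlib import resources
from datetime import datetime
from pathlib import Path
from typing import Any, Iterator, Optional

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import seqcalc
from .errors import (
    IOFailure,
    NotFound,
    PermissionDenied,
    ReferencedRecord,
    UnknownField,
    ValidationFailed,
)
from .model import (
    CellLine,
    CellType,
    DNAConstruct,
    ProteinBatch,
    RecordID,
    Request,
    RequestKind,
    RequestStatus,
    Role,
    Supe,
    effective_constructs,
    validate_links,
)
from .seqcalc import MassRecord, SequenceProperties

__all__ = [
    "StoreConfig",
    "Page",
    "SearchQuery",
    "Store",
    "check_map_file",
    "flatten_record",
    "TYPE_TO_PREFIX",
]

# canonical short type names used by the CLI and search API
TYPE_TO_PREFIX = {
    "dna": "DNA",
    "cellline": "CL",
    "supe": "SUP",
    "batch": "PB",
    "request": "REQ",
}
PREFIX_TO_TABLE = {
    "DNA": "dna_construct",
    "CL": "cell_line",
    "SUP": "supe",
    "PB": "protein_batch",
    "REQ": "request",
}


def _prefix_for(record_type: str) -> str:
    if record_type in PREFIX_TO_TABLE:
        return record_type
    try:
        return TYPE_TO_PREFIX[record_type.lower()]
    except KeyError:
        raise UnknownField(f"unknown record type {record_type!r}") from None


@dataclass
class StoreConfig:
    """Configuration for a store instance.

    ``construct_map_dir`` is the directory holding externally produced
    construct-map files; only file *references* are stored. The
    notification sink is one of ``log`` (JSON-lines file), ``memory``
    or ``smtp-stub``.
    """

    database_path: str = "proteintracker.db"
    construct_map_dir: str = "."
    notification_sink: str = "log"
    notification_log_path: Optional[str] = None
    page_size_default: int = 20
    request_group: list[str] = field(default_factory=lambda: ["request-management"])

    def __post_init__(self):
        if self.page_size_default < 1:
            raise ValueError("page_size_default must be >= 1")
        if self.notification_log_path is None:
            self.notification_log_path = str(
                Path(self.database_path).with_suffix(".notifications.log")
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StoreConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "database_path": self.database_path,
            "construct_map_dir": self.construct_map_dir,
            "notification_sink": self.notification_sink,
            "notification_log_path": self.notification_log_path,
            "page_size_default": self.page_size_default,
            "request_group": list(self.request_group),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class Page:
    """One page of a sorted record listing."""

    items: list
    page_number: int      # 1-based
    page_size: int
    total_count: int
    sort_key: str
    sort_dir: str         # asc | desc


@dataclass
class SearchQuery:
    """Conjunctive field filters plus sort/pagination.

    Operators: ``equals`` (exact, numeric-aware), ``contains``
    (case-insensitive substring), ``range`` (inclusive ``(lo, hi)``).
    """

    record_type: str
    filters: list[tuple[str, str, Any]] = field(default_factory=list)
    sort_key: str = "id"
    sort_dir: str = "asc"
    page: int = 1
    page_size: Optional[int] = None


def check_map_file(filename: Optional[str], config: StoreConfig) -> bool:
    """True iff ``filename`` exists inside the configured map directory.

    A missing file is a warning carried on the record, never a
    rejection. Path components escaping the map directory (e.g.
    ``../x``) are treated as not found: the original deployment assumed
    a trusted network share, a library cannot.
    """
    if not filename:
        return False
    base = Path(config.construct_map_dir).resolve()
    try:
        target = (base / filename).resolve()
    except OSError:
        return False
    if not target.is_relative_to(base):
        return False
    return target.is_file()


# ---------------------------------------------------------------------------
# field registries: flattening for search / sort / export / reports
# ---------------------------------------------------------------------------

NUMERIC_FIELDS = {
    "molecular_weight", "extinction_reduced", "extinction_oxidized",
    "absorbance_0_1pct", "n_glyc_sites", "concentration", "aliquot_count",
    "original_aliquots", "current_aliquots", "volume", "total_mass",
    "remaining_mass", "priority_rank", "volume_ml", "flask_count",
    "map_file_found",
}


def flatten_record(record) -> dict[str, Any]:
    """A record as an ordered field-name -> scalar mapping.

    Lists render as ';'-joined strings, ids and enums as their text
    form. This single registry backs search, sorting, CSV export and
    the report renderer, so every stored field has exactly one public
    name.
    """
    def ids(lst):
        return ";".join(str(x) for x in lst)

    if isinstance(record, DNAConstruct):
        p = record.properties
        return {
            "id": str(record.id),
            "construct_name": record.construct_name,
            "project": record.project,
            "vector": record.vector,
            "tag": record.tag,
            "insert_name": record.insert_name,
            "notebook_ref": record.notebook_ref,
            "mature_sequence": record.mature_sequence,
            "construct_map_filename": record.construct_map_filename,
            "map_file_found": record.map_file_found,
            "molecular_weight": p.molecular_weight if p else None,
            "extinction_reduced": p.extinction_reduced if p else None,
            "extinction_oxidized": p.extinction_oxidized if p else None,
            "absorbance_0_1pct": p.absorbance_0_1pct if p else None,
            "n_glyc_sites": p.n_glyc_sites if p else None,
            "created_at": record.created_at,
        }
    if isinstance(record, CellLine):
        return {
            "id": str(record.id),
            "name": record.name,
            "cell_type": record.cell_type.value,
            "construct_ids": ids(record.construct_ids),
            "origin": record.origin,
            "freezer_location": record.freezer_location,
            "mycoplasma_result": record.mycoplasma_result,
            "annotations": record.annotations,
            "bank_date": record.bank_date,
            "culture_time": record.culture_time,
            "created_at": record.created_at,
        }
    if isinstance(record, Supe):
        return {
            "id": str(record.id),
            "cell_line_id": str(record.cell_line_id),
            "transfection_construct_ids": ids(record.transfection_construct_ids),
            "expression_level": record.expression_level,
            "quality": record.quality,
            "western_blot_link": record.western_blot_link,
            "endotoxin_result": record.endotoxin_result,
            "harvest_info": record.harvest_info,
            "location": record.location,
            "culture_media": record.culture_media,
            "notebook_ref": record.notebook_ref,
            "qc_file_link": record.qc_file_link,
            "concentration": record.concentration,
            "remaining_quantity": record.remaining_quantity,
            "aliquot_count": record.aliquot_count,
            "created_at": record.created_at,
        }
    if isinstance(record, ProteinBatch):
        p = record.readonly_props
        m = record.mass
        return {
            "id": str(record.id),
            "supe_ids": ids(record.supe_ids),
            "purification_steps": ";".join(record.purification_steps),
            "original_aliquots": record.original_aliquots,
            "current_aliquots": record.current_aliquots,
            "formulation_buffer": record.formulation_buffer,
            "concentration": record.concentration,
            "volume": record.volume,
            "endotoxin_result": record.endotoxin_result,
            "qc_notes": record.qc_notes,
            "gel_qc_link": record.gel_qc_link,
            "total_mass": m.total_mass if m else None,
            "remaining_mass": m.remaining_mass if m else None,
            "molecular_weight": p.molecular_weight if p else None,
            "extinction_reduced": p.extinction_reduced if p else None,
            "extinction_oxidized": p.extinction_oxidized if p else None,
            "absorbance_0_1pct": p.absorbance_0_1pct if p else None,
            "n_glyc_sites": p.n_glyc_sites if p else None,
            "created_at": record.created_at,
        }
    if isinstance(record, Request):
        return {
            "id": str(record.id),
            "kind": record.kind.value,
            "status": record.status.value,
            "requestor_email": record.requestor_email,
            "priority_rank": record.priority_rank,
            "subject_record_id": (
                str(record.subject_record_id) if record.subject_record_id else None
            ),
            "parent_request_id": (
                str(record.parent_request_id) if record.parent_request_id else None
            ),
            "secondary_request_ids": ids(record.secondary_request_ids),
            "volume_ml": record.volume_ml,
            "flask_count": record.flask_count,
            "created_at": record.created_at,
        }
    raise TypeError(f"not a record: {record!r}")


_FIELD_NAMES: dict[str, list[str]] = {}


def field_names(prefix: str) -> list[str]:
    """Public field names of a record type, in export column order."""
    if prefix not in _FIELD_NAMES:
        probe = {
            "DNA": DNAConstruct(id=RecordID("DNA", 1), mature_sequence="G"),
            "CL": CellLine(id=RecordID("CL", 1)),
            "SUP": Supe(id=RecordID("SUP", 1), cell_line_id=RecordID("CL", 1)),
            "PB": ProteinBatch(id=RecordID("PB", 1)),
            "REQ": Request(id=RecordID("REQ", 1)),
        }[prefix]
        _FIELD_NAMES[prefix] = list(flatten_record(probe).keys())
    return _FIELD_NAMES[prefix]


# fields that map straight onto a table column (usable for SQL-side sort)
_SQL_SORT: dict[str, dict[str, str]] = {
    "DNA": {f: f for f in (
        "construct_name", "project", "vector", "tag", "insert_name",
        "notebook_ref", "mature_sequence", "construct_map_filename",
        "map_file_found", "molecular_weight", "extinction_reduced",
        "extinction_oxidized", "absorbance_0_1pct", "n_glyc_sites",
        "created_at")} | {"id": "serial"},
    "CL": {f: f for f in (
        "name", "cell_type", "origin", "freezer_location",
        "mycoplasma_result", "annotations", "bank_date", "culture_time",
        "created_at")} | {"id": "serial"},
    "SUP": {f: f for f in (
        "expression_level", "quality", "western_blot_link",
        "endotoxin_result", "harvest_info", "location", "culture_media",
        "notebook_ref", "qc_file_link", "concentration",
        "remaining_quantity", "aliquot_count", "created_at")}
        | {"id": "serial", "cell_line_id": "cell_line_serial"},
    "PB": {f: f for f in (
        "original_aliquots", "current_aliquots", "formulation_buffer",
        "concentration", "volume", "endotoxin_result", "qc_notes",
        "gel_qc_link", "total_mass", "remaining_mass", "created_at")}
        | {"id": "serial"},
    "REQ": {f: f for f in (
        "kind", "status", "requestor_email", "priority_rank",
        "subject_record_id", "volume_ml", "flask_count", "created_at")}
        | {"id": "serial"},
}

# fields a caller may set through create/update (everything else derived)
_WRITABLE: dict[str, set[str]] = {
    "DNA": {"construct_name", "project", "vector", "tag", "insert_name",
            "notebook_ref", "mature_sequence", "construct_map_filename",
            "created_at"},
    "CL": {"name", "cell_type", "construct_ids", "origin",
           "freezer_location", "mycoplasma_result", "annotations",
           "bank_date", "culture_time", "created_at"},
    "SUP": {"cell_line_id", "transfection_construct_ids",
            "expression_level", "quality", "western_blot_link",
            "endotoxin_result", "harvest_info", "location",
            "culture_media", "notebook_ref", "qc_file_link",
            "concentration", "remaining_quantity", "aliquot_count",
            "created_at"},
    "PB": {"supe_ids", "purification_steps", "original_aliquots",
           "current_aliquots", "formulation_buffer", "concentration",
           "volume", "endotoxin_result", "qc_notes", "gel_qc_link",
           "created_at"},
    "REQ": {"requestor_email", "volume_ml", "flask_count",
            "subject_record_id"},
}


def _now() -> str:
    return datetime.now().isoformat(timespec="seconds")


class Store:
    """The embedded store. Open it, mutate through role-gated methods,
    close it; records survive reopen field-for-field."""

    def __init__(self, config: StoreConfig):
        self.config = config
        Path(config.database_path).parent.mkdir(parents=True, exist_ok=True)
        self._conn = sqlite3.connect(config.database_path)
        self._conn.row_factory = sqlite3.Row
        self._conn.execute("PRAGMA foreign_keys = ON")
        schema = resources.files("proteintracker").joinpath("schema.sql").read_text()
        self._conn.executescript(schema)
        self._conn.commit()

    # -- lifecycle ----------------------------------------------------------

    def close(self) -> None:
        self._conn.commit()
        self._conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- identifiers --------------------------------------------------------

    def next_id(self, prefix: str) -> RecordID:
        """Allocate the next serial for a prefix; the counter is
        persistent, so serials are never reused after a deletion."""
        prefix = _prefix_for(prefix)
        row = self._conn.execute(
            "INSERT INTO id_counter (prefix, last_serial) VALUES (?, 1) "
            "ON CONFLICT(prefix) DO UPDATE SET last_serial = last_serial + 1 "
            "RETURNING last_serial",
            (prefix,),
        ).fetchone()
        self._conn.commit()
        return RecordID(prefix, row[0])

    # -- role checks ---------------------------------------------------------

    @staticmethod
    def _require(role: Role, needed: Role, action: str) -> None:
        if role != needed:
            raise PermissionDenied(
                f"role {Role(role).value!r} may not {action} "
                f"(requires {needed.value!r})"
            )

    # -- CRUD ----------------------------------------------------------------

    def create_record(self, record, role: Role) -> RecordID:
        """Validate, derive, assign an id and persist a reagent record."""
        if isinstance(record, Request):
            raise TypeError("requests are created through the workflow module")
        self._require(role, Role.record_admin, "create records")
        self._derive(record)
        violations = validate_links(record, self)
        if violations:
            raise ValidationFailed(violations)
        prefix = {DNAConstruct: "DNA", CellLine: "CL",
                  Supe: "SUP", ProteinBatch: "PB"}[type(record)]
        record.id = self.next_id(prefix)
        if not record.created_at:
            record.created_at = _now()
        self._insert(record)
        self._conn.commit()
        return record.id

    def get_record(self, record_id: RecordID | str):
        rec = self.try_get(record_id)
        if rec is None:
            raise NotFound(f"no record {record_id}")
        return rec

    def try_get(self, record_id: RecordID | str):
        if isinstance(record_id, str):
            try:
                record_id = RecordID.parse(record_id)
            except ValueError:
                return None
        table = PREFIX_TO_TABLE[record_id.prefix]
        row = self._conn.execute(
            f"SELECT * FROM {table} WHERE serial = ?", (record_id.serial,)
        ).fetchone()
        if row is None:
            return None
        return self._hydrate(record_id.prefix, row)

    def update_record(self, record_id: RecordID | str, changes: dict, role: Role):
        """Apply field changes, recompute derived fields, re-validate."""
        record = self.get_record(record_id)
        prefix = record.id.prefix
        needed = Role.request_admin if prefix == "REQ" else Role.record_admin
        self._require(role, needed, f"update {prefix} records")
        writable = _WRITABLE[prefix]
        for name, value in changes.items():
            if name not in writable:
                raise UnknownField(
                    f"field {name!r} is not writable on {prefix} records"
                )
            setattr(record, name, _coerce(name, value))
        self._derive(record)
        violations = validate_links(record, self)
        if violations:
            raise ValidationFailed(violations)
        if isinstance(record, Request):
            self._save_request(record)
        else:
            self._delete_row(record.id)
            self._insert(record)
        self._conn.commit()
        return record

    def delete_record(self, record_id: RecordID | str, role: Role) -> None:
        """Delete a reagent record; refused while anything downstream
        (including a request) still references it."""
        record = self.get_record(record_id)
        if isinstance(record, Request):
            raise TypeError("requests are deleted through the workflow module")
        self._require(role, Role.record_admin, "delete records")
        refs = self._referencing(record.id)
        if refs:
            raise ReferencedRecord(
                f"{record.id} is referenced by {', '.join(str(r) for r in refs)}"
            )
        self._delete_row(record.id)
        self._conn.commit()

    def _referencing(self, rid: RecordID) -> list[RecordID]:
        q = self._conn.execute
        refs: list[RecordID] = []
        if rid.prefix == "DNA":
            for row in q("SELECT cellline_serial FROM cellline_construct "
                         "WHERE construct_serial = ?", (rid.serial,)):
                refs.append(RecordID("CL", row[0]))
            for row in q("SELECT supe_serial FROM supe_construct "
                         "WHERE construct_serial = ?", (rid.serial,)):
                refs.append(RecordID("SUP", row[0]))
        elif rid.prefix == "CL":
            for row in q("SELECT serial FROM supe WHERE cell_line_serial = ?",
                         (rid.serial,)):
                refs.append(RecordID("SUP", row[0]))
        elif rid.prefix == "SUP":
            for row in q("SELECT batch_serial FROM batch_supe "
                         "WHERE supe_serial = ?", (rid.serial,)):
                refs.append(RecordID("PB", row[0]))
        for row in q("SELECT serial FROM request WHERE subject_record_id = ?",
                     (str(rid),)):
            refs.append(RecordID("REQ", row[0]))
        return sorted(set(refs))

    # -- derived fields ------------------------------------------------------

    def _derive(self, record) -> None:
        """Recompute every derived field before a write."""
        if isinstance(record, DNAConstruct):
            record.mature_sequence = seqcalc.normalize_sequence(
                record.mature_sequence
            )
            record.properties = seqcalc.sequence_properties(record.mature_sequence)
            record.map_file_found = check_map_file(
                record.construct_map_filename, self.config
            )
        elif isinstance(record, ProteinBatch):
            if (record.concentration >= 0 and record.volume >= 0
                    and 1 <= record.original_aliquots
                    and 0 <= record.current_aliquots <= record.original_aliquots):
                record.mass = seqcalc.mass_record(
                    record.concentration, record.volume,
                    record.original_aliquots, record.current_aliquots,
                )
            else:
                record.mass = None  # validation will report the violation
            record.readonly_props = self._batch_props(record)

    def _batch_props(self, record: ProteinBatch) -> Optional[SequenceProperties]:
        try:
            constructs = effective_constructs(record, self)
        except Exception:
            return None
        # co-transfection: a scalar field must pick one construct; the
        # first in id order is used, reports list them all
        return constructs[0].properties if constructs else None

    # -- row <-> record ------------------------------------------------------

    def _insert(self, record) -> None:
        c = self._conn
        if isinstance(record, DNAConstruct):
            p = record.properties
            c.execute(
                "INSERT INTO dna_construct VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                (record.id.serial, record.construct_name, record.project,
                 record.vector, record.tag, record.insert_name,
                 record.notebook_ref, record.mature_sequence,
                 record.construct_map_filename, int(record.map_file_found),
                 p.molecular_weight, p.extinction_reduced,
                 p.extinction_oxidized, p.absorbance_0_1pct, p.n_glyc_sites,
                 record.created_at),
            )
        elif isinstance(record, CellLine):
            c.execute(
                "INSERT INTO cell_line VALUES (?,?,?,?,?,?,?,?,?,?)",
                (record.id.serial, record.name, record.cell_type.value,
                 record.origin, record.freezer_location,
                 record.mycoplasma_result, record.annotations,
                 record.bank_date, record.culture_time, record.created_at),
            )
            c.executemany(
                "INSERT INTO cellline_construct VALUES (?,?)",
                [(record.id.serial, rid.serial) for rid in record.construct_ids],
            )
        elif isinstance(record, Supe):
            c.execute(
                "INSERT INTO supe VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                (record.id.serial, record.cell_line_id.serial,
                 record.expression_level, record.quality,
                 record.western_blot_link, record.endotoxin_result,
                 record.harvest_info, record.location, record.culture_media,
                 record.notebook_ref, record.qc_file_link,
                 record.concentration, record.remaining_quantity,
                 record.aliquot_count, record.created_at),
            )
            c.executemany(
                "INSERT INTO supe_construct VALUES (?,?)",
                [(record.id.serial, rid.serial)
                 for rid in record.transfection_construct_ids],
            )
        elif isinstance(record, ProteinBatch):
            m = record.mass
            c.execute(
                "INSERT INTO protein_batch VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?)",
                (record.id.serial, json.dumps(record.purification_steps),
                 record.original_aliquots, record.current_aliquots,
                 record.formulation_buffer, record.concentration,
                 record.volume, record.endotoxin_result, record.qc_notes,
                 record.gel_qc_link, m.total_mass, m.remaining_mass,
                 record.created_at),
            )
            c.executemany(
                "INSERT INTO batch_supe VALUES (?,?)",
                [(record.id.serial, rid.serial) for rid in record.supe_ids],
            )
        elif isinstance(record, Request):
            c.execute(
                "INSERT INTO request VALUES (?,?,?,?,?,?,?,?,?,?)",
                (record.id.serial, record.kind.value, record.status.value,
                 record.requestor_email, record.priority_rank,
                 str(record.subject_record_id)
                 if record.subject_record_id else None,
                 record.parent_request_id.serial
                 if record.parent_request_id else None,
                 record.volume_ml, record.flask_count, record.created_at),
            )
        else:
            raise TypeError(f"not a record: {record!r}")

    def _delete_row(self, rid: RecordID) -> None:
        c = self._conn
        if rid.prefix == "CL":
            c.execute("DELETE FROM cellline_construct WHERE cellline_serial = ?",
                      (rid.serial,))
        elif rid.prefix == "SUP":
            c.execute("DELETE FROM supe_construct WHERE supe_serial = ?",
                      (rid.serial,))
        elif rid.prefix == "PB":
            c.execute("DELETE FROM batch_supe WHERE batch_serial = ?",
                      (rid.serial,))
        c.execute(
            f"DELETE FROM {PREFIX_TO_TABLE[rid.prefix]} WHERE serial = ?",
            (rid.serial,),
        )

    def _hydrate(self, prefix: str, row: sqlite3.Row):
        q = self._conn.execute
        if prefix == "DNA":
            return DNAConstruct(
                id=RecordID("DNA", row["serial"]),
                construct_name=row["construct_name"],
                project=row["project"],
                vector=row["vector"],
                tag=row["tag"],
                insert_name=row["insert_name"],
                notebook_ref=row["notebook_ref"],
                mature_sequence=row["mature_sequence"],
                construct_map_filename=row["construct_map_filename"],
                map_file_found=bool(row["map_file_found"]),
                properties=SequenceProperties(
                    molecular_weight=row["molecular_weight"],
                    extinction_reduced=row["extinction_reduced"],
                    extinction_oxidized=row["extinction_oxidized"],
                    absorbance_0_1pct=row["absorbance_0_1pct"],
                    n_glyc_sites=row["n_glyc_sites"],
                ),
                created_at=row["created_at"],
            )
        if prefix == "CL":
            links = [RecordID("DNA", r[0]) for r in q(
                "SELECT construct_serial FROM cellline_construct "
                "WHERE cellline_serial = ? ORDER BY construct_serial",
                (row["serial"],))]
            return CellLine(
                id=RecordID("CL", row["serial"]),
                name=row["name"],
                cell_type=CellType(row["cell_type"]),
                construct_ids=links,
                origin=row["origin"],
                freezer_location=row["freezer_location"],
                mycoplasma_result=row["mycoplasma_result"],
                annotations=row["annotations"],
                bank_date=row["bank_date"],
                culture_time=row["culture_time"],
                created_at=row["created_at"],
            )
        if prefix == "SUP":
            links = [RecordID("DNA", r[0]) for r in q(
                "SELECT construct_serial FROM supe_construct "
                "WHERE supe_serial = ? ORDER BY construct_serial",
                (row["serial"],))]
            return Supe(
                id=RecordID("SUP", row["serial"]),
                cell_line_id=RecordID("CL", row["cell_line_serial"]),
                transfection_construct_ids=links,
                expression_level=row["expression_level"],
                quality=row["quality"],
                western_blot_link=row["western_blot_link"],
                endotoxin_result=row["endotoxin_result"],
                harvest_info=row["harvest_info"],
                location=row["location"],
                culture_media=row["culture_media"],
                notebook_ref=row["notebook_ref"],
                qc_file_link=row["qc_file_link"],
                concentration=row["concentration"],
                remaining_quantity=row["remaining_quantity"],
                aliquot_count=row["aliquot_count"],
                created_at=row["created_at"],
            )
        if prefix == "PB":
            supes = [RecordID("SUP", r[0]) for r in q(
                "SELECT supe_serial FROM batch_supe "
                "WHERE batch_serial = ? ORDER BY supe_serial",
                (row["serial"],))]
            batch = ProteinBatch(
                id=RecordID("PB", row["serial"]),
                supe_ids=supes,
                purification_steps=json.loads(row["purification_steps"]),
                original_aliquots=row["original_aliquots"],
                current_aliquots=row["current_aliquots"],
                formulation_buffer=row["formulation_buffer"],
                concentration=row["concentration"],
                volume=row["volume"],
                endotoxin_result=row["endotoxin_result"],
                qc_notes=row["qc_notes"],
                gel_qc_link=row["gel_qc_link"],
                mass=MassRecord(
                    total_mass=row["total_mass"],
                    remaining_mass=row["remaining_mass"],
                    concentration=row["concentration"],
                    volume=row["volume"],
                    original_aliquots=row["original_aliquots"],
                    current_aliquots=row["current_aliquots"],
                ),
                created_at=row["created_at"],
            )
            batch.readonly_props = self._batch_props(batch)
            return batch
        if prefix == "REQ":
            secondaries = [RecordID("REQ", r[0]) for r in q(
                "SELECT serial FROM request WHERE parent_request_serial = ? "
                "ORDER BY serial", (row["serial"],))]
            return Request(
                id=RecordID("REQ", row["serial"]),
                kind=RequestKind(row["kind"]),
                status=RequestStatus(row["status"]),
                requestor_email=row["requestor_email"],
                priority_rank=row["priority_rank"],
                subject_record_id=(
                    RecordID.parse(row["subject_record_id"])
                    if row["subject_record_id"] else None
                ),
                parent_request_id=(
                    RecordID("REQ", row["parent_request_serial"])
                    if row["parent_request_serial"] else None
                ),
                secondary_request_ids=secondaries,
                volume_ml=row["volume_ml"],
                flask_count=row["flask_count"],
                created_at=row["created_at"],
            )
        raise UnknownField(f"unknown prefix {prefix!r}")

    # -- listing, search, export ---------------------------------------------

    def count(self, record_type: str) -> int:
        table = PREFIX_TO_TABLE[_prefix_for(record_type)]
        return self._conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]

    def counts(self) -> dict[str, int]:
        return {name: self.count(name) for name in TYPE_TO_PREFIX}

    def iter_records(self, record_type: str) -> Iterator:
        prefix = _prefix_for(record_type)
        table = PREFIX_TO_TABLE[prefix]
        rows = self._conn.execute(
            f"SELECT * FROM {table} ORDER BY serial"
        ).fetchall()
        for row in rows:
            yield self._hydrate(prefix, row)

    def list_records(
        self,
        record_type: str,
        sort_key: str = "id",
        sort_dir: str = "asc",
        page: int = 1,
        page_size: Optional[int] = None,
    ) -> Page:
        """Deterministically ordered page: sort key, then id tiebreak."""
        prefix = _prefix_for(record_type)
        if sort_key not in field_names(prefix):
            raise UnknownField(f"{prefix} has no field {sort_key!r}")
        if sort_dir not in ("asc", "desc"):
            raise UnknownField(f"bad sort direction {sort_dir!r}")
        page_size = page_size or self.config.page_size_default
        if page < 1 or page_size < 1:
            raise UnknownField("page and page_size must be >= 1")
        total = self.count(prefix)
        col = _SQL_SORT[prefix].get(sort_key)
        if col is not None:
            table = PREFIX_TO_TABLE[prefix]
            rows = self._conn.execute(
                f"SELECT * FROM {table} "
                f"ORDER BY ({col} IS NULL), {col} {sort_dir.upper()}, serial ASC "
                "LIMIT ? OFFSET ?",
                (page_size, (page - 1) * page_size),
            ).fetchall()
            items = [self._hydrate(prefix, r) for r in rows]
        else:  # junction-backed field: sort hydrated records in memory
            items = self._sorted_records(prefix, sort_key, sort_dir)
            items = items[(page - 1) * page_size: page * page_size]
        return Page(items, page, page_size, total, sort_key, sort_dir)

    def _sorted_records(self, prefix: str, sort_key: str, sort_dir: str) -> list:
        records = list(self.iter_records(prefix))
        _sort_in_place(records, sort_key, sort_dir)
        return records

    def search(self, query: SearchQuery) -> Page:
        """Conjunctive filters over any public field of a record type."""
        prefix = _prefix_for(query.record_type)
        names = field_names(prefix)
        for fname, op, _ in query.filters:
            if fname not in names:
                raise UnknownField(f"{prefix} has no field {fname!r}")
            if op not in ("equals", "contains", "range"):
                raise UnknownField(f"unknown operator {op!r}")
        if query.sort_key not in names:
            raise UnknownField(f"{prefix} has no field {query.sort_key!r}")
        matches = [
            rec for rec in self.iter_records(prefix)
            if all(
                _matches(flatten_record(rec).get(fname), op, needle)
                for fname, op, needle in query.filters
            )
        ]
        _sort_in_place(matches, query.sort_key, query.sort_dir)
        page_size = query.page_size or self.config.page_size_default
        items = matches[(query.page - 1) * page_size: query.page * page_size]
        return Page(items, query.page, page_size, len(matches),
                    query.sort_key, query.sort_dir)

    def export_csv(self, record_type: str, path: str | Path) -> int:
        """Write all records of a type as UTF-8 CSV with a header row;
        returns the number of data rows."""
        prefix = _prefix_for(record_type)
        names = field_names(prefix)
        try:
            with open(path, "w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow(names)
                n = 0
                for rec in self.iter_records(prefix):
                    flat = flatten_record(rec)
                    writer.writerow(
                        ["" if flat[k] is None else flat[k] for k in names]
                    )
                    n += 1
        except OSError as exc:
            raise IOFailure(str(exc)) from exc
        return n

    def export_fasta(self, path: str | Path) -> int:
        """Write every construct's mature sequence as FASTA,
        ``>RecordID construct_name``; returns the record count."""
        seqrecords = [
            SeqRecord(Seq(rec.mature_sequence), id=str(rec.id),
                      description=rec.construct_name)
            for rec in self.iter_records("dna")
        ]
        try:
            SeqIO.write(seqrecords, str(path), "fasta")
        except OSError as exc:
            raise IOFailure(str(exc)) from exc
        return len(seqrecords)

    def import_fasta(self, path: str | Path, role: Role) -> list[RecordID]:
        """Create one construct per FASTA record (batch import)."""
        created = []
        for frec in seqcalc.read_fasta(path):
            construct = DNAConstruct(
                construct_name=frec.name,
                mature_sequence=frec.sequence,
            )
            created.append(self.create_record(construct, role))
        return created

    # -- whole-store validation ----------------------------------------------

    def validate_all(self) -> list[tuple[RecordID, str]]:
        """Re-validate every record against the live store."""
        out: list[tuple[RecordID, str]] = []
        for name in TYPE_TO_PREFIX:
            for rec in self.iter_records(name):
                for violation in validate_links(rec, self):
                    out.append((rec.id, violation))
        return out

    # -- request persistence (used by the workflow module) --------------------

    def _insert_request(self, req: Request) -> RecordID:
        req.id = self.next_id("REQ")
        if not req.created_at:
            req.created_at = _now()
        self._insert(req)
        self._conn.commit()
        return req.id

    def _save_request(self, req: Request) -> None:
        self._conn.execute(
            "UPDATE request SET kind=?, status=?, requestor_email=?, "
            "priority_rank=?, subject_record_id=?, parent_request_serial=?, "
            "volume_ml=?, flask_count=?, created_at=? WHERE serial=?",
            (req.kind.value, req.status.value, req.requestor_email,
             req.priority_rank,
             str(req.subject_record_id) if req.subject_record_id else None,
             req.parent_request_id.serial if req.parent_request_id else None,
             req.volume_ml, req.flask_count, req.created_at, req.id.serial),
        )
        self._conn.commit()

    def _delete_request_row(self, rid: RecordID) -> None:
        self._conn.execute(
            "UPDATE request SET parent_request_serial = NULL "
            "WHERE parent_request_serial = ?", (rid.serial,))
        self._delete_row(rid)
        self._conn.commit()

    def requests_of_kind(self, kind: RequestKind) -> list[Request]:
        rows = self._conn.execute(
            "SELECT * FROM request WHERE kind = ? ORDER BY serial",
            (kind.value,),
        ).fetchall()
        return [self._hydrate("REQ", r) for r in rows]


def _coerce(name: str, value: Any) -> Any:
    """Coerce CLI/string inputs into typed field values."""
    if value is None:
        return None
    if name == "cell_type" and not isinstance(value, CellType):
        return CellType(value)
    if name in ("construct_ids", "transfection_construct_ids", "supe_ids"):
        return [v if isinstance(v, RecordID) else RecordID.parse(v) for v in value]
    if name in ("cell_line_id", "subject_record_id") and isinstance(value, str):
        return RecordID.parse(value)
    if name in NUMERIC_FIELDS and isinstance(value, str):
        return float(value) if "." in value else int(value)
    return value


def _sort_token(value: Any) -> tuple:
    """Total order over mixed (non-None) field values."""
    if value is None:
        return (0, "", 0.0)
    if isinstance(value, (bool, int, float)):
        return (1, "", float(value))
    return (0, str(value), 0.0)


def _sort_in_place(records: list, sort_key: str, sort_dir: str) -> None:
    """Deterministic order: sort key (None always last), id tiebreak.

    Three stable passes mirror the SQL-side ``ORDER BY (col IS NULL),
    col, serial`` used for plain column sorts.
    """
    records.sort(key=lambda r: r.id.serial)
    records.sort(
        key=lambda r: _sort_token(flatten_record(r).get(sort_key)),
        reverse=(sort_dir == "desc"),
    )
    records.sort(key=lambda r: flatten_record(r).get(sort_key) is None)


def _matches(value: Any, op: str, needle: Any) -> bool:
    if op == "equals":
        if value is None:
            return needle is None or needle == ""
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            try:
                return float(value) == float(needle)
            except (TypeError, ValueError):
                return False
        return str(value) == str(needle)
    if op == "contains":
        if value is None:
            return False
        return str(needle).lower() in str(value).lower()
    if op == "range":
        lo, hi = needle
        if value is None:
            return False
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            try:
                return float(lo) <= float(value) <= float(hi)
            except (TypeError, ValueError):
                return False
        return str(lo) <= str(value) <= str(hi)
    raise UnknownField(f"unknown operator {op!r}")
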