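"""Record types, identifiers, roles and link rules of the reagent schema.

Four reagent record classes form a directed acyclic lineage::

    DNAConstruct  <-  CellLine (stable)  <-  Supe  <-  ProteinBatch
                  <-------- Supe (transient transfection)

plus a :class:`Request` work item. Links only ever point from a later
record class to an earlier one, so the lineage graph is acyclic by
construction.

Record identifiers are ``PREFIX-NNNNN`` with a per-prefix serial that is
never reused after deletion; zero padding makes them sort
lexicographically in creation order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Protocol

from .errors import BrokenLineage
from .seqcalc import MassRecord, SequenceProperties

__all__ = [
    "RecordID",
    "Role",
    "CellType",
    "RequestKind",
    "RequestStatus",
    "DNAConstruct",
    "CellLine",
    "Supe",
    "ProteinBatch",
    "Request",
    "PREFIXES",
    "RecordResolver",
    "validate_links",
    "effective_constructs",
]

PREFIXES = ("DNA", "CL", "SUP", "PB", "REQ")

_ID_RE = re.compile(r"^(DNA|CL|SUP|PB|REQ)-(\d{5,})$")


@dataclass(frozen=True, order=True)
class RecordID:
    """Typed unique identifier, rendered as ``<prefix>-<5-digit serial>``."""

    prefix: str
    serial: int

    def __post_init__(self):
        if self.prefix not in PREFIXES:
            raise ValueError(f"unknown prefix {self.prefix!r}")
        if self.serial < 1:
            raise ValueError(f"serial must be positive, got {self.serial}")

    def __str__(self) -> str:
        return f"{self.prefix}-{self.serial:05d}"

    @classmethod
    def parse(cls, text: str) -> "RecordID":
        m = _ID_RE.match(text.strip())
        if not m:
            raise ValueError(f"not a record id: {text!r}")
        return cls(m.group(1), int(m.group(2)))


class Role(str, Enum):
    """Mutation scopes. ``reader`` may never mutate; ``record_admin``
    mutates reagent records; ``request_admin`` mutates and prioritizes
    requests."""

    reader = "reader"
    record_admin = "record_admin"
    request_admin = "request_admin"


class CellType(str, Enum):
    parental = "parental"
    stable = "stable"
    hybridoma = "hybridoma"


class RequestKind(str, Enum):
    transfection = "transfection"
    stable_supe = "stable_supe"
    dna = "dna"
    purification = "purification"
    aliquot = "aliquot"


class RequestStatus(str, Enum):
    pending = "Pending"
    started = "Started"
    fulfilled = "Fulfilled"


# ---------------------------------------------------------------------------
# reagent records
# ---------------------------------------------------------------------------

@dataclass
class DNAConstruct:
    """Expression plasmid record; the source of all derived properties.

    ``properties`` is recomputed from ``mature_sequence`` on every create
    and update, never stored stale. ``map_file_found`` records whether the
    construct-map file reference resolved under the configured map
    directory at last write (a warning flag, never a rejection).
    """

    id: Optional[RecordID] = None
    construct_name: str = ""
    project: str = ""
    vector: str = ""
    tag: str = ""
    insert_name: str = ""
    notebook_ref: str = ""
    mature_sequence: str = ""
    construct_map_filename: Optional[str] = None
    map_file_found: bool = False
    properties: Optional[SequenceProperties] = None
    created_at: str = ""


@dataclass
class CellLine:
    """Expression cell line: parental, stable (with integrated
    construct(s); more than one means a co-transfection) or hybridoma."""

    id: Optional[RecordID] = None
    name: str = ""
    cell_type: CellType = CellType.parental
    construct_ids: list[RecordID] = field(default_factory=list)
    origin: str = ""
    freezer_location: str = ""
    mycoplasma_result: str = ""
    annotations: str = ""
    bank_date: str = ""
    culture_time: str = ""
    created_at: str = ""


@dataclass
class Supe:
    """Conditioned-media record: harvested culture supernatant.

    A transient supe names a parental cell line plus the transfected
    construct(s); a stable-line supe names only the stable line, whose
    constructs are the effective ones.
    """

    id: Optional[RecordID] = None
    cell_line_id: Optional[RecordID] = None
    transfection_construct_ids: list[RecordID] = field(default_factory=list)
    expression_level: str = ""
    quality: str = ""
    western_blot_link: str = ""
    endotoxin_result: str = ""
    harvest_info: str = ""
    location: str = ""
    culture_media: str = ""
    notebook_ref: str = ""
    qc_file_link: str = ""
    concentration: float = 0.0          # mg/mL
    remaining_quantity: str = ""        # free text, e.g. "250 mL"
    aliquot_count: int = 0
    created_at: str = ""


@dataclass
class ProteinBatch:
    """One purification run from one or more supes.

    ``mass`` is recomputed whenever concentration, volume or aliquot
    counts change. ``readonly_props`` mirror the first effective
    construct's sequence properties and are derived on read, never
    entered by hand.
    """

    id: Optional[RecordID] = None
    supe_ids: list[RecordID] = field(default_factory=list)
    purification_steps: list[str] = field(default_factory=list)
    original_aliquots: int = 1
    current_aliquots: int = 1
    formulation_buffer: str = ""
    concentration: float = 0.0          # mg/mL
    volume: float = 0.0                 # mL
    endotoxin_result: str = ""
    qc_notes: str = ""
    gel_qc_link: str = ""
    mass: Optional[MassRecord] = None
    readonly_props: Optional[SequenceProperties] = None
    created_at: str = ""


@dataclass
class Request:
    """A typed work item with a forward-only status lifecycle.

    ``priority_rank`` is defined only while Pending and forms, within
    each kind, a contiguous 1..n permutation (rank 1 = highest
    priority). Transfection requests carry either a culture volume
    (suspension) or a flask count (adherent). Secondary requests are
    bidirectionally linked to their parent.
    """

    id: Optional[RecordID] = None
    kind: RequestKind = RequestKind.dna
    status: RequestStatus = RequestStatus.pending
    requestor_email: Optional[str] = None
    priority_rank: Optional[int] = None
    subject_record_id: Optional[RecordID] = None
    parent_request_id: Optional[RecordID] = None
    secondary_request_ids: list[RecordID] = field(default_factory=list)
    volume_ml: Optional[float] = None
    flask_count: Optional[int] = None
    created_at: str = ""


RECORD_TYPES = {
    "DNA": DNAConstruct,
    "CL": CellLine,
    "SUP": Supe,
    "PB": ProteinBatch,
    "REQ": Request,
}


def prefix_of(record) -> str:
    for prefix, cls in RECORD_TYPES.items():
        if isinstance(record, cls):
            return prefix
    raise TypeError(f"not a record: {record!r}")


class RecordResolver(Protocol):
    """Anything that can look records up by id (the store implements it)."""

    def try_get(self, record_id: RecordID): ...


# ---------------------------------------------------------------------------
# link validation
# ---------------------------------------------------------------------------

def _exists(resolver: RecordResolver, rid: RecordID, expected_prefix: str) -> bool:
    if rid.prefix != expected_prefix:
        return False
    return resolver.try_get(rid) is not None


def validate_links(record, resolver: RecordResolver) -> list[str]:
    """Check every per-type link invariant; return all violations.

    Violations are data, not exceptions: an empty list means the record
    is consistent with the store it is being validated against.
    """
    v: list[str] = []
    if isinstance(record, DNAConstruct):
        if not record.mature_sequence:
            v.append("construct requires a mature sequence")
    elif isinstance(record, CellLine):
        if record.cell_type == CellType.stable and not record.construct_ids:
            v.append("stable cell line requires >=1 construct")
        if record.cell_type != CellType.stable and record.construct_ids:
            v.append(f"{record.cell_type.value} cell line must not link constructs")
        for rid in record.construct_ids:
            if not _exists(resolver, rid, "DNA"):
                v.append(f"construct link {rid} does not resolve")
    elif isinstance(record, Supe):
        if record.cell_line_id is None:
            v.append("supe requires a cell line")
            return v
        line = (
            resolver.try_get(record.cell_line_id)
            if record.cell_line_id.prefix == "CL"
            else None
        )
        if line is None:
            v.append(f"cell line link {record.cell_line_id} does not resolve")
        else:
            if line.cell_type == CellType.parental and not record.transfection_construct_ids:
                v.append("transient supe on a parental line requires >=1 transfected construct")
            if line.cell_type != CellType.parental and record.transfection_construct_ids:
                v.append(
                    f"supe on a {line.cell_type.value} line must not list "
                    "transfection constructs"
                )
        for rid in record.transfection_construct_ids:
            if not _exists(resolver, rid, "DNA"):
                v.append(f"construct link {rid} does not resolve")
    elif isinstance(record, ProteinBatch):
        if not record.supe_ids:
            v.append("batch requires >=1 supe")
        for rid in record.supe_ids:
            if not _exists(resolver, rid, "SUP"):
                v.append(f"supe link {rid} does not resolve")
        if record.original_aliquots < 1:
            v.append("original_aliquots must be >= 1")
        if not 0 <= record.current_aliquots <= record.original_aliquots:
            v.append("current_aliquots outside [0, original_aliquots]")
        if record.concentration < 0 or record.volume < 0:
            v.append("concentration and volume must be >= 0")
        # every supe of the batch must trace to at least one construct
        for rid in record.supe_ids:
            supe = resolver.try_get(rid) if rid.prefix == "SUP" else None
            if supe is not None:
                try:
                    if not effective_constructs(supe, resolver):
                        v.append(f"supe {rid} has no lineage to any construct")
                except BrokenLineage as exc:
                    v.append(str(exc))
    elif isinstance(record, Request):
        if record.kind == RequestKind.transfection:
            if record.volume_ml is None and record.flask_count is None:
                v.append("transfection request requires a volume or flask count")
        if record.subject_record_id is not None:
            rid = record.subject_record_id
            if resolver.try_get(rid) is None:
                v.append(f"subject record {rid} does not resolve")
    else:
        raise TypeError(f"not a record: {record!r}")
    return v


def effective_constructs(record, resolver: RecordResolver) -> list[DNAConstruct]:
    """The DNA constructs a supe or batch ultimately derives from.

    Transient supe: its transfection constructs. Stable-line supe: the
    cell line's constructs. Batch: the union over its supes. Hybridoma
    supes have none. Always deduplicated and in id order; a dangling
    link raises :class:`BrokenLineage`.
    """

    def _get(rid: RecordID):
        rec = resolver.try_get(rid)
        if rec is None:
            raise BrokenLineage(f"lineage link {rid} does not resolve")
        return rec

    ids: set[RecordID] = set()
    if isinstance(record, Supe):
        if record.cell_line_id is None:
            raise BrokenLineage("supe has no cell line")
        line = _get(record.cell_line_id)
        if line.cell_type == CellType.stable:
            ids.update(line.construct_ids)
        else:
            ids.update(record.transfection_construct_ids)
    elif isinstance(record, ProteinBatch):
        for rid in record.supe_ids:
            supe = _get(rid)
            ids.update(c.id for c in effective_constructs(supe, resolver))
    else:
        raise TypeError("effective_constructs applies to Supe or ProteinBatch")
    return [_get(rid) for rid in sorted(ids)]
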