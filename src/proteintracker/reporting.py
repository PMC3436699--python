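"""Chain-of-custody traversal, printable reports, and external links.

The lineage of a purified batch runs batch -> supe(s) -> cell line ->
construct(s); a transient supe's transfected constructs are shown under
its parental line so every leaf of the tree is a DNA construct. Shared
ancestors (two supes of the same line, co-purified constructs) appear
once.

Reports are deterministic UTF-8 text: identical store state renders to
identical bytes, so a report can be diffed, archived or attached to a
collaborator shipment. Every stored field of a record appears in its
report under its public field name; supe and batch reports append the
full upstream lineage sections.

External links use the ``proteintracker://<RECORD-ID>`` scheme:
self-describing, store-relocatable, and an exact inverse pair
(``resolve_link(external_link(x)) == x``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MalformedLink, NotFound
from .model import (
    CellLine,
    CellType,
    DNAConstruct,
    ProteinBatch,
    RecordID,
    Request,
    RequestStatus,
    Supe,
)

__all__ = [
    "LINK_SCHEME",
    "LineageNode",
    "chain_of_custody",
    "record_report",
    "request_report",
    "external_link",
    "resolve_link",
]

LINK_SCHEME = "proteintracker://"

_KIND_LABEL = {
    "DNA": "DNA construct",
    "CL": "cell line",
    "SUP": "supe",
    "PB": "protein batch",
    "REQ": "request",
}


@dataclass
class LineageNode:
    """One node of a chain-of-custody tree."""

    record_id: RecordID
    kind: str                      # DNA | CL | SUP | PB
    summary: str                   # one-line human label
    children: list["LineageNode"] = field(default_factory=list)
    is_ref: bool = False           # back-reference to a node shown elsewhere

    def walk(self):
        """Depth-first iteration over the tree, root first."""
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> list["LineageNode"]:
        """Terminal lineage nodes; back-references to already-expanded
        ancestors are not leaves of the custody chain."""
        return [n for n in self.walk() if not n.children and not n.is_ref]


def _summary(record) -> str:
    if isinstance(record, DNAConstruct):
        return f"{record.construct_name} ({record.properties.molecular_weight} Da)"
    if isinstance(record, CellLine):
        return f"{record.name} [{record.cell_type.value}]"
    if isinstance(record, Supe):
        return f"supe from {record.cell_line_id}"
    if isinstance(record, ProteinBatch):
        return f"batch of {len(record.supe_ids)} supe(s)"
    return str(record.id)


def chain_of_custody(store, record_id: RecordID | str) -> LineageNode:
    """Full upstream lineage of a record as a deduplicated tree.

    A construct is its own single-node tree. A node already emitted
    elsewhere in the tree is added as a bare reference without being
    re-expanded, so every record appears (with children) exactly once
    and traversal terminates on any store.
    """
    record = store.get_record(record_id)  # raises NotFound
    seen: set[RecordID] = set()

    def node_for(rec) -> LineageNode:
        if rec.id in seen:
            # shared ancestor: bare back-reference, not re-expanded
            return LineageNode(rec.id, rec.id.prefix, _summary(rec), is_ref=True)
        seen.add(rec.id)
        node = LineageNode(rec.id, rec.id.prefix, _summary(rec))
        if isinstance(rec, ProteinBatch):
            for sid in rec.supe_ids:
                node.children.append(node_for(store.get_record(sid)))
        elif isinstance(rec, Supe):
            line = store.get_record(rec.cell_line_id)
            line_node = node_for(line)
            if line.cell_type == CellType.parental:
                # transfected constructs displayed under the parental line
                for cid in rec.transfection_construct_ids:
                    line_node.children.append(node_for(store.get_record(cid)))
            node.children.append(line_node)
        elif isinstance(rec, CellLine):
            for cid in rec.construct_ids:
                node.children.append(node_for(store.get_record(cid)))
        return node

    return node_for(record)


def _render_tree(node: LineageNode, indent: int = 0) -> list[str]:
    lines = [f"{'  ' * indent}- {node.record_id} "
             f"({_KIND_LABEL[node.kind]}): {node.summary}"]
    for child in node.children:
        lines.extend(_render_tree(child, indent + 1))
    return lines


def _field_section(record) -> list[str]:
    from .store import flatten_record  # local import to avoid a cycle

    flat = flatten_record(record)
    width = max(len(k) for k in flat)
    return [f"  {k.ljust(width)} : {'' if v is None else v}"
            for k, v in flat.items()]


def record_report(store, record_id: RecordID | str) -> str:
    """Printable report of a reagent record.

    Supe and batch reports append the related upstream records (cell
    lines and constructs) in full, plus the lineage tree, so a single
    printout documents how the reagent was made. Output is
    deterministic for a fixed store.
    """
    record = store.get_record(record_id)
    rid = record.id
    lines = [
        f"=== {_KIND_LABEL[rid.prefix].upper()} REPORT: {rid} ===",
        f"link: {external_link(rid)}",
        "",
        "[record]",
        *_field_section(record),
    ]
    if isinstance(record, (Supe, ProteinBatch)):
        tree = chain_of_custody(store, rid)
        lines += ["", "[chain of custody]"]
        lines += _render_tree(tree)
        related = [n.record_id for n in tree.walk() if n.record_id != rid]
        seen: set[RecordID] = set()
        for rel_id in related:
            if rel_id in seen:
                continue
            seen.add(rel_id)
            rel = store.get_record(rel_id)
            lines += ["", f"[related {_KIND_LABEL[rel_id.prefix]}: {rel_id}]"]
            lines += _field_section(rel)
        if isinstance(record, ProteinBatch):
            line_ids = {
                store.get_record(sid).cell_line_id for sid in record.supe_ids
            }
            if len(line_ids) > 1:
                lines += ["", f"NOTE: batch spans supes from {len(line_ids)} "
                              "different cell lines"]
    return "\n".join(lines) + "\n"


def request_report(store, request_id: RecordID | str) -> str:
    """Printable report of a request: status, queue rank while Pending,
    linked secondary requests and the external link."""
    req = store.get_record(request_id)
    if not isinstance(req, Request):
        raise NotFound(f"{request_id} is not a request")
    lines = [
        f"=== REQUEST REPORT: {req.id} ===",
        f"link: {external_link(req.id)}",
        "",
        f"kind       : {req.kind.value}",
        f"status     : {req.status.value}",
    ]
    if req.status == RequestStatus.pending:
        lines.append(f"queue rank : {req.priority_rank}")
    if req.requestor_email:
        lines.append(f"requestor  : {req.requestor_email}")
    if req.subject_record_id:
        lines.append(f"subject    : {req.subject_record_id} "
                     f"({external_link(req.subject_record_id)})")
    if req.volume_ml is not None:
        lines.append(f"volume     : {req.volume_ml} mL (suspension)")
    if req.flask_count is not None:
        lines.append(f"flasks     : {req.flask_count} (adherent)")
    if req.parent_request_id:
        lines.append(f"parent     : {req.parent_request_id}")
    if req.secondary_request_ids:
        lines.append(
            "secondary  : "
            + ", ".join(str(s) for s in req.secondary_request_ids)
        )
    lines.append(f"created    : {req.created_at}")
    return "\n".join(lines) + "\n"


def external_link(record_id: RecordID | str) -> str:
    """Render the stable external link for a record or request id."""
    if isinstance(record_id, str):
        record_id = RecordID.parse(record_id)
    return f"{LINK_SCHEME}{record_id}"


def resolve_link(text: str) -> RecordID:
    """Parse an external link back to its RecordID (inverse of
    :func:`external_link`); anything else raises MalformedLink."""
    if not isinstance(text, str) or not text.startswith(LINK_SCHEME):
        raise MalformedLink(f"not a {LINK_SCHEME} link: {text!r}")
    try:
        return RecordID.parse(text[len(LINK_SCHEME):])
    except ValueError as exc:
        raise MalformedLink(str(exc)) from exc
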