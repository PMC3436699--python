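"""Request lifecycle: submission, status transitions, prioritization.

Requests move forward-only through ``Pending -> Started -> Fulfilled``;
skipping a stage or moving backward is rejected. Within each request
kind the Pending requests form a priority queue whose ranks are always
a contiguous ``1..n`` permutation: submission appends at the end, an
admin swaps a request with its neighbour to re-prioritize, and leaving
the Pending state (or deletion) compacts the remaining ranks.

Every submission emits one notification to the request-management
group, and every status change emits one notification to the
requestor's email when it was given. Delivery is a pluggable sink (a
JSON-lines log file by default; SMTP is a stub interface) so the whole
workflow is testable offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Callable, Optional, Protocol

from .errors import (
    IllegalTransition,
    MissingQuantity,
    NotFound,
    NotPending,
    PermissionDenied,
)
from .model import RecordID, Request, RequestKind, RequestStatus, Role
from .reporting import external_link
from .store import Store

__all__ = [
    "NotificationEvent",
    "NotificationSink",
    "MemorySink",
    "LogFileSink",
    "SmtpStubSink",
    "make_sink",
    "RequestQueue",
    "RequestManager",
]

_FORWARD = {
    RequestStatus.pending: RequestStatus.started,
    RequestStatus.started: RequestStatus.fulfilled,
}


@dataclass(frozen=True)
class NotificationEvent:
    """One outbound message with an embedded link to its request."""

    recipient: str            # email address or group name
    subject: str
    body: str
    embedded_link: str        # proteintracker://REQ-xxxxx
    timestamp: str


class NotificationSink(Protocol):
    def emit(self, event: NotificationEvent) -> None: ...


class MemorySink:
    """Collects events in memory; the default for tests."""

    def __init__(self):
        self.events: list[NotificationEvent] = []

    def emit(self, event: NotificationEvent) -> None:
        self.events.append(event)


class LogFileSink:
    """Appends one JSON line per event to a log file."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def emit(self, event: NotificationEvent) -> None:
        line = json.dumps(
            {
                "timestamp": event.timestamp,
                "recipient": event.recipient,
                "subject": event.subject,
                "body": event.body,
                "link": event.embedded_link,
            }
        )
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(line + "\n")


class SmtpStubSink:
    """Stand-in for an SMTP transport: records what *would* be sent.

    Real delivery is intentionally out of scope; implement ``emit`` on
    a subclass against your mail relay to enable it.
    """

    def __init__(self, host: str = "localhost", port: int = 25):
        self.host = host
        self.port = port
        self.outbox: list[NotificationEvent] = []

    def emit(self, event: NotificationEvent) -> None:
        self.outbox.append(event)


def make_sink(config) -> NotificationSink:
    """Build the sink named by a :class:`~proteintracker.store.StoreConfig`."""
    kind = config.notification_sink
    if kind == "log":
        return LogFileSink(config.notification_log_path)
    if kind == "memory":
        return MemorySink()
    if kind == "smtp-stub":
        return SmtpStubSink()
    raise ValueError(f"unknown notification sink {kind!r}")


@dataclass
class RequestQueue:
    """Pending requests of one kind, rank 1 = highest priority."""

    kind: RequestKind
    request_ids: list[RecordID] = field(default_factory=list)


def _now() -> str:
    return datetime.now().isoformat(timespec="seconds")


class RequestManager:
    """The public surface for everything request-related.

    Submission is open to any user (requestors are the customers of
    the production group); status updates, prioritization and deletion
    require the ``request_admin`` role.
    """

    def __init__(
        self,
        store: Store,
        sink: Optional[NotificationSink] = None,
        request_group: Optional[list[str]] = None,
        clock: Optional[Callable[[], str]] = None,
    ):
        self.store = store
        self.sink = sink if sink is not None else make_sink(store.config)
        self.request_group = (
            list(request_group)
            if request_group is not None
            else list(store.config.request_group)
        )
        self._clock = clock or _now

    # -- submission -----------------------------------------------------------

    def submit_request(
        self,
        kind: RequestKind | str,
        subject_record_id: Optional[RecordID | str] = None,
        requestor_email: Optional[str] = None,
        volume_ml: Optional[float] = None,
        flask_count: Optional[int] = None,
        parent_request_id: Optional[RecordID] = None,
    ) -> Request:
        """Create a Pending request at the end of its kind's queue."""
        kind = RequestKind(kind)
        if isinstance(subject_record_id, str):
            subject_record_id = RecordID.parse(subject_record_id)
        if subject_record_id is not None:
            if self.store.try_get(subject_record_id) is None:
                raise NotFound(f"no record {subject_record_id}")
        if kind == RequestKind.transfection:
            if volume_ml is None and flask_count is None:
                raise MissingQuantity(
                    "transfection requests need a culture volume (suspension) "
                    "or a flask count (adherent)"
                )
        req = Request(
            kind=kind,
            status=RequestStatus.pending,
            requestor_email=requestor_email,
            priority_rank=len(self.queue(kind).request_ids) + 1,
            subject_record_id=subject_record_id,
            parent_request_id=parent_request_id,
            volume_ml=volume_ml,
            flask_count=flask_count,
            created_at=self._clock(),
        )
        self.store._insert_request(req)
        self._notify_group(req, f"New {kind.value} request {req.id}")
        return req

    def submit_transfection_request(
        self,
        construct_id: RecordID | str,
        cell_type: str = "suspension",
        volume_ml: Optional[float] = None,
        flask_count: Optional[int] = None,
        want_dna: bool = False,
        want_purification: bool = False,
        requestor_email: Optional[str] = None,
    ) -> tuple[Request, list[Request]]:
        """Submit a transfection request, optionally fanning out
        auto-generated, bidirectionally linked DNA and purification
        secondary requests (each Pending in its own kind's queue)."""
        primary = self.submit_request(
            RequestKind.transfection,
            subject_record_id=construct_id,
            requestor_email=requestor_email,
            volume_ml=volume_ml,
            flask_count=flask_count,
        )
        secondaries: list[Request] = []
        if want_dna:
            secondaries.append(
                self.submit_request(
                    RequestKind.dna,
                    subject_record_id=construct_id,
                    requestor_email=requestor_email,
                    parent_request_id=primary.id,
                )
            )
        if want_purification:
            secondaries.append(
                self.submit_request(
                    RequestKind.purification,
                    subject_record_id=construct_id,
                    requestor_email=requestor_email,
                    parent_request_id=primary.id,
                )
            )
        primary.secondary_request_ids = [s.id for s in secondaries]
        return self.store.get_record(primary.id), secondaries

    # -- lifecycle ------------------------------------------------------------

    def update_status(
        self,
        request_id: RecordID | str,
        new_status: RequestStatus | str,
        role: Role,
    ) -> Request:
        """Advance a request one step forward, compacting the Pending
        queue when the request leaves it, and notifying the requestor."""
        self._require_admin(role, "update request status")
        req = self._get_request(request_id)
        new_status = RequestStatus(new_status)
        if _FORWARD.get(req.status) != new_status:
            raise IllegalTransition(
                f"{req.id}: {req.status.value} -> {new_status.value} "
                "(allowed: Pending -> Started -> Fulfilled, one step at a time)"
            )
        leaving_pending = req.status == RequestStatus.pending
        old_rank = req.priority_rank
        req.status = new_status
        if leaving_pending:
            req.priority_rank = None
        self.store._save_request(req)
        if leaving_pending and old_rank is not None:
            self._compact(req.kind, old_rank)
        if req.requestor_email:
            self._emit(
                req.requestor_email,
                f"Request {req.id} is now {new_status.value}",
                req,
            )
        return req

    def prioritize(
        self,
        kind: RequestKind | str,
        request_id: RecordID | str,
        direction: str,
        role: Role,
    ) -> RequestQueue:
        """Swap a Pending request with its neighbour (up = toward rank 1).
        Boundary moves are no-ops; all other ranks are untouched."""
        self._require_admin(role, "prioritize requests")
        kind = RequestKind(kind)
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        req = self._get_request(request_id)
        if req.status != RequestStatus.pending or req.kind != kind:
            raise NotPending(
                f"{req.id} is not a Pending {kind.value} request; only queued "
                "work (not yet begun) can be prioritized"
            )
        rank = req.priority_rank
        target = rank - 1 if direction == "up" else rank + 1
        pending = self._pending(kind)
        if 1 <= target <= len(pending):
            other = next(r for r in pending if r.priority_rank == target)
            req.priority_rank, other.priority_rank = target, rank
            self.store._save_request(req)
            self.store._save_request(other)
        return self.queue(kind)

    def delete_request(self, request_id: RecordID | str, role: Role) -> None:
        """Delete a Pending request and compact the queue behind it."""
        self._require_admin(role, "delete requests")
        req = self._get_request(request_id)
        if req.status != RequestStatus.pending:
            raise NotPending(f"{req.id} is {req.status.value}; only Pending "
                             "requests may be deleted")
        rank = req.priority_rank
        self.store._delete_request_row(req.id)
        self._compact(req.kind, rank)

    # -- views ----------------------------------------------------------------

    def queue(self, kind: RequestKind | str) -> RequestQueue:
        kind = RequestKind(kind)
        pending = self._pending(kind)
        pending.sort(key=lambda r: r.priority_rank)
        return RequestQueue(kind, [r.id for r in pending])

    def list_requests(self, kind: RequestKind | str) -> dict[str, list[Request]]:
        """All requests of a kind, partitioned by status: Pending in
        rank order, Started and Fulfilled in creation order."""
        kind = RequestKind(kind)
        groups: dict[str, list[Request]] = {
            "Pending": [], "Started": [], "Fulfilled": []
        }
        for req in self.store.requests_of_kind(kind):
            groups[req.status.value].append(req)
        groups["Pending"].sort(key=lambda r: r.priority_rank)
        for key in ("Started", "Fulfilled"):
            groups[key].sort(key=lambda r: (r.created_at, r.id.serial))
        return groups

    # -- internals ------------------------------------------------------------

    @staticmethod
    def _require_admin(role: Role, action: str) -> None:
        if role != Role.request_admin:
            raise PermissionDenied(f"role {Role(role).value!r} may not {action} "
                                   "(requires 'request_admin')")

    def _get_request(self, request_id: RecordID | str) -> Request:
        req = self.store.try_get(request_id)
        if req is None or not isinstance(req, Request):
            raise NotFound(f"no request {request_id}")
        return req

    def _pending(self, kind: RequestKind) -> list[Request]:
        return [
            r for r in self.store.requests_of_kind(kind)
            if r.status == RequestStatus.pending
        ]

    def _compact(self, kind: RequestKind, removed_rank: Optional[int]) -> None:
        if removed_rank is None:
            return
        for other in self._pending(kind):
            if other.priority_rank > removed_rank:
                other.priority_rank -= 1
                self.store._save_request(other)

    def _notify_group(self, req: Request, subject: str) -> None:
        for recipient in self.request_group:
            self._emit(recipient, subject, req)

    def _emit(self, recipient: str, subject: str, req: Request) -> None:
        link = external_link(req.id)
        self.sink.emit(
            NotificationEvent(
                recipient=recipient,
                subject=subject,
                body=(
                    f"{subject}. Kind: {req.kind.value}. "
                    f"Status: {req.status.value}. Open: {link}"
                ),
                embedded_link=link,
                timestamp=self._clock(),
            )
        )
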