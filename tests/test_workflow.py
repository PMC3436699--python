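"""Request lifecycle: queues, transitions, notifications, fan-out."""

import itertools
import random

import pytest

from proteintracker import RequestKind, RequestStatus, Role
from proteintracker.errors import (
    IllegalTransition,
    MissingQuantity,
    NotFound,
    NotPending,
    PermissionDenied,
)
from proteintracker.workflow import LogFileSink, RequestManager

ADMIN = Role.request_admin


@pytest.fixture
def dna_id(store, chain):
    return chain["construct"].id


# --- submission ---------------------------------------------------------------

def test_submission_defaults_pending_at_end_of_queue(manager, dna_id):
    r1 = manager.submit_request("dna", subject_record_id=dna_id)
    r2 = manager.submit_request("dna", subject_record_id=dna_id)
    assert (r1.status, r2.status) == (RequestStatus.pending,) * 2
    assert (r1.priority_rank, r2.priority_rank) == (1, 2)
    assert [str(x) for x in manager.queue("dna").request_ids] \
        == [str(r1.id), str(r2.id)]


def test_submission_notifies_request_group(manager, sink, dna_id):
    manager.submit_request("dna", subject_record_id=dna_id)
    assert [e.recipient for e in sink.events] == ["prot-group"]
    assert sink.events[0].embedded_link.startswith("proteintracker://REQ-")


def test_submission_with_dangling_subject_rejected(manager):
    with pytest.raises(NotFound):
        manager.submit_request("aliquot", subject_record_id="PB-00099")


def test_transfection_requires_quantity(manager, dna_id):
    with pytest.raises(MissingQuantity):
        manager.submit_request("transfection", subject_record_id=dna_id)
    ok = manager.submit_request("transfection", subject_record_id=dna_id,
                                flask_count=4)
    assert ok.flask_count == 4


def test_transfection_fanout_creates_linked_secondaries(manager, dna_id):
    primary, secondaries = manager.submit_transfection_request(
        dna_id, volume_ml=500.0, want_dna=True, want_purification=True,
    )
    assert len(secondaries) == 2
    assert {s.kind for s in secondaries} \
        == {RequestKind.dna, RequestKind.purification}
    assert primary.secondary_request_ids == [s.id for s in secondaries]
    for sec in secondaries:
        assert sec.parent_request_id == primary.id
        assert sec.status == RequestStatus.pending
    # secondaries live in their own kind's queue, not the transfection queue
    assert manager.queue("transfection").request_ids == [primary.id]
    assert secondaries[0].id in manager.queue("dna").request_ids


def test_transfection_fanout_flags_off_yields_single_request(manager, dna_id):
    primary, secondaries = manager.submit_transfection_request(
        dna_id, flask_count=2,
    )
    assert secondaries == []
    assert primary.secondary_request_ids == []


def test_secondary_link_symmetry(manager, store, dna_id):
    primary, secondaries = manager.submit_transfection_request(
        dna_id, volume_ml=100.0, want_dna=True,
    )
    fresh_primary = store.get_record(primary.id)
    for sid in fresh_primary.secondary_request_ids:
        assert store.get_record(sid).parent_request_id == primary.id
    for sec in secondaries:
        assert sec.id in fresh_primary.secondary_request_ids


# --- status machine -----------------------------------------------------------

ALL_STATUSES = list(RequestStatus)


def _request_in_state(manager, dna_id, state):
    req = manager.submit_request("dna", subject_record_id=dna_id,
                                 requestor_email="u@example.org")
    if state in (RequestStatus.started, RequestStatus.fulfilled):
        manager.update_status(req.id, RequestStatus.started, ADMIN)
    if state == RequestStatus.fulfilled:
        manager.update_status(req.id, RequestStatus.fulfilled, ADMIN)
    return req


@pytest.mark.parametrize(
    "src, dst", list(itertools.product(ALL_STATUSES, ALL_STATUSES))
)
def test_exhaustive_transition_pairs(manager, dna_id, src, dst):
    """Only Pending->Started and Started->Fulfilled are legal; every
    backward, skipping or self transition is rejected."""
    req = _request_in_state(manager, dna_id, src)
    legal = (src, dst) in {
        (RequestStatus.pending, RequestStatus.started),
        (RequestStatus.started, RequestStatus.fulfilled),
    }
    if legal:
        assert manager.update_status(req.id, dst, ADMIN).status == dst
    else:
        with pytest.raises(IllegalTransition):
            manager.update_status(req.id, dst, ADMIN)


def test_status_updates_require_request_admin(manager, dna_id):
    req = manager.submit_request("dna", subject_record_id=dna_id)
    for role in (Role.reader, Role.record_admin):
        with pytest.raises(PermissionDenied):
            manager.update_status(req.id, RequestStatus.started, role)


def test_notification_count_equals_status_changes(manager, sink, dna_id):
    req = manager.submit_request("dna", subject_record_id=dna_id,
                                 requestor_email="u@example.org")
    manager.update_status(req.id, RequestStatus.started, ADMIN)
    manager.update_status(req.id, RequestStatus.fulfilled, ADMIN)
    to_requestor = [e for e in sink.events if e.recipient == "u@example.org"]
    assert len(to_requestor) == 2
    assert [e.subject for e in to_requestor] == [
        f"Request {req.id} is now Started",
        f"Request {req.id} is now Fulfilled",
    ]


def test_no_requestor_email_no_requestor_notification(manager, sink, dna_id):
    req = manager.submit_request("dna", subject_record_id=dna_id)
    manager.update_status(req.id, RequestStatus.started, ADMIN)
    assert all(e.recipient == "prot-group" for e in sink.events)


def test_log_sink_writes_json_lines(store, tmp_path, dna_id):
    import json
    log = tmp_path / "notify.log"
    manager = RequestManager(store, sink=LogFileSink(log),
                             request_group=["grp"])
    req = manager.submit_request("dna", subject_record_id=dna_id,
                                 requestor_email="u@x.org")
    manager.update_status(req.id, RequestStatus.started, ADMIN)
    lines = [json.loads(l) for l in log.read_text().splitlines()]
    assert len(lines) == 2
    assert lines[1]["recipient"] == "u@x.org"
    assert lines[1]["link"] == f"proteintracker://{req.id}"


# --- prioritization -----------------------------------------------------------

def test_prioritize_swaps_with_neighbor(manager, dna_id):
    reqs = [manager.submit_request("dna", subject_record_id=dna_id)
            for _ in range(3)]
    queue = manager.prioritize("dna", reqs[2].id, "up", ADMIN)
    assert queue.request_ids == [reqs[0].id, reqs[2].id, reqs[1].id]


def test_prioritize_boundary_is_noop(manager, dna_id):
    reqs = [manager.submit_request("dna", subject_record_id=dna_id)
            for _ in range(3)]
    assert manager.prioritize("dna", reqs[0].id, "up", ADMIN).request_ids \
        == [r.id for r in reqs]
    assert manager.prioritize("dna", reqs[2].id, "down", ADMIN).request_ids \
        == [r.id for r in reqs]


def test_prioritize_rejects_started_requests(manager, dna_id):
    req = manager.submit_request("dna", subject_record_id=dna_id)
    manager.update_status(req.id, RequestStatus.started, ADMIN)
    with pytest.raises(NotPending):
        manager.prioritize("dna", req.id, "up", ADMIN)


def test_prioritize_requires_request_admin(manager, dna_id):
    req = manager.submit_request("dna", subject_record_id=dna_id)
    with pytest.raises(PermissionDenied):
        manager.prioritize("dna", req.id, "up", Role.reader)


def test_leaving_pending_compacts_ranks(manager, store, dna_id):
    reqs = [manager.submit_request("dna", subject_record_id=dna_id)
            for _ in range(4)]
    manager.update_status(reqs[1].id, RequestStatus.started, ADMIN)
    queue = manager.queue("dna")
    assert queue.request_ids == [reqs[0].id, reqs[2].id, reqs[3].id]
    ranks = [store.get_record(rid).priority_rank for rid in queue.request_ids]
    assert ranks == [1, 2, 3]


def test_delete_request_pending_only_and_compacts(manager, store, dna_id):
    reqs = [manager.submit_request("dna", subject_record_id=dna_id)
            for _ in range(3)]
    manager.delete_request(reqs[0].id, ADMIN)
    queue = manager.queue("dna")
    assert queue.request_ids == [reqs[1].id, reqs[2].id]
    assert [store.get_record(r).priority_rank for r in queue.request_ids] \
        == [1, 2]
    manager.update_status(reqs[1].id, RequestStatus.started, ADMIN)
    with pytest.raises(NotPending):
        manager.delete_request(reqs[1].id, ADMIN)


def test_list_requests_partitions_by_status(manager, dna_id):
    reqs = [manager.submit_request("dna", subject_record_id=dna_id)
            for _ in range(3)]
    manager.update_status(reqs[1].id, RequestStatus.started, ADMIN)
    manager.update_status(reqs[1].id, RequestStatus.fulfilled, ADMIN)
    groups = manager.list_requests("dna")
    sizes = {k: len(v) for k, v in groups.items()}
    assert sizes == {"Pending": 2, "Started": 0, "Fulfilled": 1}
    assert [r.id for r in groups["Pending"]] \
        == manager.queue("dna").request_ids


def test_list_requests_empty_kind(manager):
    groups = manager.list_requests("aliquot")
    assert all(v == [] for v in groups.values())


# --- model-based queue check ----------------------------------------------------

def test_queue_permutation_against_list_model(manager, store, dna_id):
    """Replay random submissions, transitions, moves and deletions
    against plain per-kind lists; queues must match at every step."""
    rng = random.Random(2024)
    kinds = list(RequestKind)
    model = {k: [] for k in kinds}          # pending ids in rank order
    startable = []                          # pending ids eligible to start
    started = []

    for step in range(400):
        op = rng.choice(["submit", "start", "fulfil", "move", "delete"])
        if op == "submit":
            kind = rng.choice(kinds)
            req = manager.submit_request(
                kind, subject_record_id=dna_id,
                volume_ml=100.0 if kind == RequestKind.transfection else None,
            )
            model[kind].append(req.id)
        elif op == "start" and any(model.values()):
            kind = rng.choice([k for k in kinds if model[k]])
            rid = rng.choice(model[kind])
            manager.update_status(rid, RequestStatus.started, ADMIN)
            model[kind].remove(rid)
            started.append(rid)
        elif op == "fulfil" and started:
            rid = started.pop(rng.randrange(len(started)))
            manager.update_status(rid, RequestStatus.fulfilled, ADMIN)
        elif op == "move" and any(model.values()):
            kind = rng.choice([k for k in kinds if model[k]])
            rid = rng.choice(model[kind])
            direction = rng.choice(["up", "down"])
            manager.prioritize(kind, rid, direction, ADMIN)
            i = model[kind].index(rid)
            j = i - 1 if direction == "up" else i + 1
            if 0 <= j < len(model[kind]):
                model[kind][i], model[kind][j] = model[kind][j], model[kind][i]
        elif op == "delete" and any(model.values()):
            kind = rng.choice([k for k in kinds if model[k]])
            rid = rng.choice(model[kind])
            manager.delete_request(rid, ADMIN)
            model[kind].remove(rid)

        for kind in kinds:
            queue = manager.queue(kind)
            assert queue.request_ids == model[kind], f"step {step}, {kind}"
            ranks = [store.get_record(r).priority_rank
                     for r in queue.request_ids]
            assert ranks == list(range(1, len(ranks) + 1))
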