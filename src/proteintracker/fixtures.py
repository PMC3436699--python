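"""Deterministic synthetic stores: linked reagent chains plus requests.

The generator emulates the shape of a production tracking database —
constructs feeding stable and parental cell lines, transient and
stable supes, multi-supe purification batches, and a request book
spread across kinds and statuses — at any scale, up to the ~9,000
records a busy protein-production group accumulates over a few years.

Sequences are uniform over the 20-letter alphabet: the properties under
test are combinatorial (masses, chromophore counts, sequon scans, link
topology), not biological, so no composition realism is attempted.
Timestamps come from a synthetic monotone clock so two runs with the
same spec produce field-identical stores.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta

from .errors import StoreNotEmpty
from .model import (
    CellLine,
    CellType,
    DNAConstruct,
    ProteinBatch,
    RequestKind,
    RequestStatus,
    Role,
    Supe,
)
from .seqcalc import AMINO_ACIDS
from .store import Store
from .workflow import MemorySink, RequestManager

__all__ = ["FixtureSpec", "random_sequence", "populate", "demo_spec", "SyntheticClock"]


@dataclass
class FixtureSpec:
    """Counts and proportions for one synthetic store.

    The same seed and spec always produce field-identical stores. The
    default proportions — about half the supes transient, requests
    roughly half Pending with the rest split between Started and
    Fulfilled — mirror a production queue where most submitted work is
    still open.
    """

    seed: int = 0
    n_constructs: int = 10
    n_cell_lines: int = 5
    n_supes: int = 8
    n_batches: int = 4
    n_requests: int = 6
    seq_len_range: tuple[int, int] = (30, 300)
    fraction_transient: float = 0.5
    status_fractions: dict[str, float] = field(
        default_factory=lambda: {"Pending": 0.5, "Started": 0.3, "Fulfilled": 0.2}
    )

    @property
    def total(self) -> int:
        return (self.n_constructs + self.n_cell_lines + self.n_supes
                + self.n_batches + self.n_requests)


def demo_spec(scale: str = "small", seed: int = 0) -> FixtureSpec:
    """Canned specs: ``small`` for demos, ``production`` at the ~9,000
    record scale of a mature installation."""
    if scale == "small":
        return FixtureSpec(seed=seed)
    if scale == "production":
        return FixtureSpec(
            seed=seed,
            n_constructs=4200,
            n_cell_lines=1400,
            n_supes=2100,
            n_batches=700,
            n_requests=600,
        )
    raise ValueError(f"unknown scale {scale!r} (small | production)")


class SyntheticClock:
    """Monotone ISO timestamps, one second apart, from a fixed epoch."""

    def __init__(self, start: datetime = datetime(2026, 1, 1)):
        self._t = start

    def __call__(self) -> str:
        self._t += timedelta(seconds=1)
        return self._t.isoformat(timespec="seconds")


def random_sequence(length: int, rng: random.Random) -> str:
    """Uniform random amino-acid sequence of the given length."""
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


_PROJECTS = ["P1", "P2", "P3", "ONC-7", "CTRL"]
_VECTORS = ["pTT5", "pcDNA3.1", "pET28a", "pFUSE"]
_TAGS = ["His6", "FLAG", "Fc", "StrepII", ""]
_BUFFERS = ["PBS pH 7.4", "20 mM Tris 150 mM NaCl", "10 mM HEPES 5% sucrose"]
_STEPS = ["Protein A", "IMAC", "SEC", "IEX", "dialysis"]
_HOSTS = ["HEK293", "CHO-K1", "Expi293", "NS0"]


def populate(
    store: Store,
    spec: FixtureSpec,
    manager: RequestManager | None = None,
) -> dict[str, int]:
    """Fill an empty store with a coherent linked fixture; returns the
    exact per-type counts created.

    Every link invariant holds on the result (``validate_all`` is
    clean); requests are distributed over kinds and statuses per the
    spec's fractions, with a few deterministic priority shuffles so
    queues are not trivially FIFO.
    """
    if sum(store.counts().values()) > 0:
        raise StoreNotEmpty("fixture population requires an empty store")
    rng = random.Random(spec.seed)
    clock = SyntheticClock()
    role = Role.record_admin
    if manager is None:
        manager = RequestManager(store, sink=MemorySink(), clock=clock)
    else:
        manager._clock = clock

    lo, hi = spec.seq_len_range
    constructs = []
    for i in range(spec.n_constructs):
        rec = DNAConstruct(
            construct_name=f"construct-{i + 1:05d}",
            project=rng.choice(_PROJECTS),
            vector=rng.choice(_VECTORS),
            tag=rng.choice(_TAGS),
            insert_name=f"insert-{i + 1}",
            notebook_ref=f"NB{rng.randint(1, 40):03d}-p{rng.randint(1, 200)}",
            mature_sequence=random_sequence(rng.randint(lo, hi), rng),
            construct_map_filename=f"construct-{i + 1:05d}.map",
            created_at=clock(),
        )
        store.create_record(rec, role)
        constructs.append(rec)

    # cell line mix: parental hosts first (supes need them), then stable
    # lines on existing constructs, a few hybridomas
    n_parental = max(1, spec.n_cell_lines // 3)
    n_hybridoma = spec.n_cell_lines // 10
    n_stable = spec.n_cell_lines - n_parental - n_hybridoma
    lines = []
    for i in range(spec.n_cell_lines):
        if i < n_parental:
            ctype, linked = CellType.parental, []
        elif i < n_parental + n_stable and constructs:
            ctype = CellType.stable
            k = 2 if rng.random() < 0.15 else 1  # occasional co-transfection
            linked = [c.id for c in rng.sample(constructs, min(k, len(constructs)))]
        else:
            ctype, linked = CellType.hybridoma, []
        rec = CellLine(
            name=f"{rng.choice(_HOSTS)}-{i + 1:04d}",
            cell_type=ctype,
            construct_ids=linked,
            origin=rng.choice(_HOSTS),
            freezer_location=f"LN2-rack{rng.randint(1, 12)}",
            mycoplasma_result=rng.choice(["negative", "negative", "pending"]),
            bank_date=f"2025-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}",
            culture_time=f"{rng.randint(3, 21)} d",
            created_at=clock(),
        )
        store.create_record(rec, role)
        lines.append(rec)

    parental = [l for l in lines if l.cell_type == CellType.parental]
    stable = [l for l in lines if l.cell_type == CellType.stable]
    supes = []
    for i in range(spec.n_supes):
        transient = stable == [] or rng.random() < spec.fraction_transient
        if transient and parental:
            line = rng.choice(parental)
            k = 2 if rng.random() < 0.1 else 1
            tcons = sorted(
                c.id for c in rng.sample(constructs, min(k, len(constructs)))
            )
        else:
            line = rng.choice(stable)
            tcons = []
        rec = Supe(
            cell_line_id=line.id,
            transfection_construct_ids=tcons,
            expression_level=rng.choice(["low", "medium", "high"]),
            quality=rng.choice(["ok", "good", "excellent"]),
            endotoxin_result=f"{rng.randint(1, 50) / 10:.1f} EU/mL",
            harvest_info=f"day {rng.randint(3, 10)}",
            location=f"-80C-shelf{rng.randint(1, 6)}",
            culture_media=rng.choice(["FreeStyle", "ExpiCHO", "DMEM+10%FBS"]),
            notebook_ref=f"NB{rng.randint(1, 40):03d}-p{rng.randint(1, 200)}",
            concentration=round(rng.uniform(0.05, 2.0), 2),
            remaining_quantity=f"{rng.randint(10, 900)} mL",
            aliquot_count=rng.randint(1, 20),
            created_at=clock(),
        )
        store.create_record(rec, role)
        supes.append(rec)

    batches = []
    for i in range(spec.n_batches):
        k = 2 if rng.random() < 0.2 and len(supes) >= 2 else 1
        chosen = sorted((s.id for s in rng.sample(supes, k)))
        original = rng.randint(1, 20)
        rec = ProteinBatch(
            supe_ids=list(chosen),
            purification_steps=rng.sample(_STEPS, rng.randint(1, 3)),
            original_aliquots=original,
            current_aliquots=rng.randint(0, original),
            formulation_buffer=rng.choice(_BUFFERS),
            concentration=round(rng.uniform(0.1, 10.0), 2),
            volume=round(rng.uniform(0.5, 50.0), 1),
            endotoxin_result=f"{rng.randint(1, 20) / 10:.1f} EU/mg",
            qc_notes=rng.choice(["SEC >95% monomer", "minor aggregate", ""]),
            gel_qc_link=f"gels/batch-{i + 1:05d}.png",
            created_at=clock(),
        )
        store.create_record(rec, role)
        batches.append(rec)

    kinds = list(RequestKind)
    requests = []
    for i in range(spec.n_requests):
        kind = rng.choice(kinds)
        email = (
            f"user{rng.randint(1, 9)}@example.org" if rng.random() < 0.7 else None
        )
        if kind == RequestKind.transfection and constructs:
            suspension = rng.random() < 0.6
            req, _ = manager.submit_transfection_request(
                rng.choice(constructs).id,
                volume_ml=round(rng.uniform(30, 1000), 0) if suspension else None,
                flask_count=None if suspension else rng.randint(1, 12),
                want_dna=rng.random() < 0.3,
                want_purification=rng.random() < 0.3,
                requestor_email=email,
            )
        else:
            subject = None
            if kind in (RequestKind.dna, RequestKind.stable_supe) and constructs:
                subject = rng.choice(constructs).id
            elif kind == RequestKind.aliquot and batches:
                subject = rng.choice(batches).id
            elif kind == RequestKind.purification and supes:
                subject = rng.choice(supes).id
            req = manager.submit_request(
                kind, subject_record_id=subject, requestor_email=email
            )
        requests.append(req)

    # advance statuses per the spec's fractions
    p_started = spec.status_fractions.get("Started", 0.0)
    p_fulfilled = spec.status_fractions.get("Fulfilled", 0.0)
    for req in requests:
        u = rng.random()
        if u < p_fulfilled:
            manager.update_status(req.id, RequestStatus.started, Role.request_admin)
            manager.update_status(req.id, RequestStatus.fulfilled, Role.request_admin)
        elif u < p_fulfilled + p_started:
            manager.update_status(req.id, RequestStatus.started, Role.request_admin)

    # a few deterministic priority shuffles so ranks differ from FIFO
    for kind in kinds:
        queue = manager.queue(kind).request_ids
        for _ in range(min(len(queue), 3)):
            rid = rng.choice(queue)
            manager.prioritize(
                kind, rid, rng.choice(["up", "down"]), Role.request_admin
            )

    counts = store.counts()
    return counts
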