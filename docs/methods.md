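# Methods

This note records the model behind the tracker, the conventions and
defaults it adopts where more than one defensible choice existed, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Domain model

Four reagent record classes form a directed acyclic lineage:

```
DNAConstruct  <──  CellLine (stable)  <──  Supe  <──  ProteinBatch
          ^───────────────────────────────  Supe (transient)
```

Links only point from later record classes to earlier ones, so the
lineage graph is acyclic by construction; a DNA construct has no
outgoing links at all. Cell lines are `parental` (untransfected host,
no construct links), `stable` (one or more integrated constructs; more
than one is a co-transfection) or `hybridoma` (antibody secretors,
tracked without construct links). A supe on a parental line must list
the transfected construct(s); a supe on a stable line must not — its
*effective* constructs are the line's. A batch purifies one or more
supes; its effective constructs are the deduplicated union over its
supes, in id order.

Where a single scalar display field (molecular weight, tag, insert) must
be populated from a co-transfection's several constructs, the first
effective construct in id order is used; reports always list all of
them, so no information is lost — only the headline scalar is a choice.

Identifiers are `PREFIX-NNNNN` with per-prefix persistent counters;
serials are never reused after deletion, so an id seen on a shipped
tube or in an old report can never silently mean a different record.
Zero-padding makes ids sort lexicographically in creation order up to
99 999 records per type (longer serials simply widen the field).

## Sequence calculations

* **Molecular weight** is the average-isotopic mass of the condensed
  chain: the sum of a 20-entry average residue-mass table (4-decimal
  precision, e.g. Gly 57.0519 Da) plus one water, 18.0153 Da.
  Monoisotopic mass is out of scope — A280 normalization and mass
  bookkeeping at the bench use average masses.
* **Extinction at 280 nm** uses the Gill & von Hippel / Pace
  coefficients: Trp 5500, Tyr 1490, cystine 125 M⁻¹·cm⁻¹. Both
  conventions are exposed: `extinction_reduced` assumes all cysteines
  free; `extinction_oxidized` adds 125 per cystine pair,
  `⌊nCys/2⌋` pairs. The reduced value feeds the default A280 — for a
  protein of unknown disulfide state it is the conservative choice,
  and the oxidized value is one field away.
* **A280(0.1 %)** = `ε_reduced / MW` in mL·mg⁻¹·cm⁻¹; zero is a legal
  value for chromophore-free sequences.
* **Sequons**: `N-X-S/T` with `X ≠ P`, scanned at every position;
  overlapping sequons each count (e.g. `NNTT` has two). No further
  context rules (such as a proline after the S/T) are applied: the
  count is the standard motif census, not an occupancy prediction.
* **Input hygiene**: whitespace, digits and `*` are stripped and case
  is folded before validation. Ambiguity codes (B, J, O, U, X, Z) are
  rejected with the offending position rather than assigned zero mass,
  because a silently wrong MW would propagate into A280 and every
  downstream mass field.
* **Rounding**: masses and A280 are reported to 2 decimals (round half
  to even), extinction coefficients are exact integers; all internal
  arithmetic is full double precision.

## Mass bookkeeping

A batch's total mass is `concentration × volume`. The record tracks
only aliquot *counts* (original and current), not per-aliquot volumes,
so remaining mass is proportional: `total × current / original`.
Aliquot counts outside `[0, original]` are rejected, and both masses
are recomputed on every mutation of concentration, volume or counts —
derived fields are never stored stale.

## Storage

The store is a single-file SQLite database whose schema
(`schema.sql`) mirrors the relational design: one table per record
class, junction tables (`cellline_construct`, `supe_construct`,
`batch_supe`) for the many-to-many links, a separate request table,
and a persistent id-counter table. Construct-map files and QC images
stay on the file system; the database stores only the reference string
plus a found/not-found flag. The map-file check refuses path
components that escape the configured map directory — the existence
check must not become a directory-probing primitive.

Deletion is refusal-based, not cascading: a record referenced by any
downstream record (or by a request) cannot be deleted. Combined with
create/update validation this makes referential integrity an invariant
of the API rather than a property to be repaired.

Search filters are conjunctive; `equals` is exact (numeric-aware),
`contains` is case-insensitive substring, `range` is inclusive.
Listing order is always deterministic: the sort key, with NULLs last
and the record serial as tiebreak, so concatenating pages partitions
the full listing for any page size. Plain-column sorts run in SQL;
junction-backed fields (e.g. a cell line's construct list) sort in
memory by the same rule.

## Requests

The status machine is strictly `Pending → Started → Fulfilled`, one
step at a time: no skip (`Pending → Fulfilled`) and no reversal —
reopening finished work would silently falsify the notification
history, and nothing in the workflow requires it. Per kind, the
Pending requests carry ranks forming a contiguous `1..n` permutation:
submission appends at rank `n+1`, prioritization swaps adjacent ranks
(boundary moves are no-ops), and leaving Pending (start or deletion)
compacts the ranks behind. Only Pending requests — work not yet begun
— may be prioritized or deleted, and only by a `request_admin`.

Submission is open to any user (requestors are the production group's
customers); it emits one notification to each member of the configured
request-management group. Every status change emits exactly one
notification to the requestor when an email was supplied. Delivery is
a sink interface — JSON-lines log file by default, in-memory for
tests, and an SMTP stub recording what would be sent — so the
invariant "notifications to a requestor = status changes of their
requests" is countable in any environment.

A transfection request may fan out auto-generated DNA and/or
purification requests, created Pending in their own kinds' queues and
bidirectionally linked to the primary. Secondaries remain independent
work items: fulfilling the parent does not advance them.

## Roles

Three scopes: `reader` (never mutates), `record_admin` (reagent
records), `request_admin` (request lifecycle and queues). The two
admin scopes match the system's two activity classes and are disjoint;
authentication is out of scope — the role is a parameter to mutating
operations, to be bound by whatever surrounds the library.

## Reports, lineage and links

`chain_of_custody` walks upstream only (batch → supes → cell lines →
constructs); a transient supe's transfected constructs are displayed
under its parental line so every leaf of the tree is a construct. A
record reached a second time (shared line, co-purified construct) is
emitted as a back-reference and not re-expanded: each record is
visited once and the leaf set of a batch's tree equals its effective
constructs. Downstream (reverse) lineage is intentionally omitted from
reports.

Reports are deterministic labeled text (identical store ⇒ identical
bytes) built from the same field registry used by search and CSV
export, so every stored field appears under its public name; PDF would
be a renderer over the same section model and is not shipped. External
links are `proteintracker://<RECORD-ID>` — a self-describing scheme +
id pair that survives store relocation; render and parse are exact
inverses.

## Synthetic data

The fixture generator builds coherent linked stores at any scale from
a seed: about a third of cell lines parental and a tenth hybridoma,
roughly half the supes transient, occasional co-transfections (15 % of
stable lines, 10 % of transient supes) and multi-supe batches (20 %),
and a request book roughly half Pending, 30 % Started, 20 % Fulfilled
— a production queue where most submitted work is open. Sequences are
uniform over the 20-letter alphabet and lengths uniform on 30–300
residues: the properties under test (masses, chromophore counts,
sequon scans, link topology, queue mechanics) are combinatorial, so no
compositional realism is attempted. Consequently the fixtures say
nothing about biological plausibility of the values — only about the
correctness of the bookkeeping over arbitrary valid inputs.
Timestamps come from a synthetic one-second-tick clock so two runs
with the same spec are field-identical (the SQLite file itself is not
guaranteed byte-identical; equality is asserted record-by-record).
The `production` scale (4200 constructs, 1400 lines, 2100 supes, 700
batches, 600+ requests; ≥ 9000 records total) models a mature
installation.

## Verification sizes

The test suite checks the calculations against independent
brute-force oracles (character-by-character summation; regex and
sliding-window sequon counts) on 10,000 seeded random sequences of
length 1–500 plus hypothesis property tests; the queue against a
plain-list replay model over 1,000 random operations; durability and
delete-refusal integrity over 20 seeded stores; and the scale
properties on one production-scale store (pagination partition at page
sizes 1, 3, 10 and 1000). `scripts/acceptance.py` recomputes the same
quantities from scratch (oracle gaps at 2,000 sequences, 10 durability
stores) and writes them as JSON.

## Known limitations

* Single-process access; no migrations. The schema is plain SQL, so a
  client–server PostgreSQL port is mechanical.
* No authentication or sessions; roles are caller-supplied.
* `remaining_quantity` on supes is free text, as at the bench
  ("~250 mL"); it is not arithmetic-checked.
* A batch may span supes from different cell lines; reports flag this
  rather than forbidding it.
* pI, instability index, monoisotopic mass and signal-peptide
  detection are out of scope.
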