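"""CRUD, integrity, search, pagination, export and the map-file check."""

import random

import pytest

from proteintracker import (
    CellLine,
    CellType,
    DNAConstruct,
    RecordID,
    Role,
    Store,
    check_map_file,
)
from proteintracker.errors import (
    NotFound,
    PermissionDenied,
    ReferencedRecord,
    UnknownField,
    ValidationFailed,
)
from proteintracker.fixtures import FixtureSpec, populate
from proteintracker.store import SearchQuery, flatten_record

ADMIN = Role.record_admin


def make_dna(store, name="c", seq="NGT", **kw):
    rec = DNAConstruct(construct_name=name, mature_sequence=seq, **kw)
    store.create_record(rec, ADMIN)
    return rec


# --- identifiers ---------------------------------------------------------------

def test_first_ids_and_per_prefix_independence(store):
    assert str(store.next_id("DNA")) == "DNA-00001"
    assert str(store.next_id("DNA")) == "DNA-00002"
    assert str(store.next_id("CL")) == "CL-00001"


def test_serials_not_reused_after_delete(store):
    for i in range(3):
        make_dna(store, name=f"c{i}")
    store.delete_record("DNA-00003", ADMIN)
    rec = make_dna(store, name="c3")
    assert str(rec.id) == "DNA-00004"


# --- CRUD ------------------------------------------------------------------------

def test_create_wires_sequence_properties(store):
    rec = make_dna(store, seq="NGT")
    got = store.get_record(rec.id)
    assert got.properties.n_glyc_sites == 1
    assert got.mature_sequence == "NGT"


def test_create_normalizes_sequence_input(store):
    rec = make_dna(store, seq=" n g t 1*")
    assert store.get_record(rec.id).mature_sequence == "NGT"


def test_reader_and_request_admin_cannot_mutate_records(store):
    for role in (Role.reader, Role.request_admin):
        with pytest.raises(PermissionDenied):
            store.create_record(
                DNAConstruct(construct_name="x", mature_sequence="G"), role
            )


def test_stable_line_before_constructs_fails_validation(store):
    line = CellLine(name="L", cell_type=CellType.stable,
                    construct_ids=[RecordID("DNA", 1)])
    with pytest.raises(ValidationFailed):
        store.create_record(line, ADMIN)


def test_get_roundtrip_field_for_field(store, chain):
    for rec in chain.values():
        assert flatten_record(store.get_record(rec.id)) == flatten_record(rec)


def test_get_missing_raises(store):
    with pytest.raises(NotFound):
        store.get_record("DNA-00042")


def test_update_recomputes_derived_properties(store):
    rec = make_dna(store, seq="G")
    updated = store.update_record(rec.id, {"mature_sequence": "NGT"}, ADMIN)
    assert updated.properties.n_glyc_sites == 1
    assert store.get_record(rec.id).properties.n_glyc_sites == 1


def test_update_batch_aliquots_recomputes_remaining_mass(store, chain):
    batch = chain["batch"]
    assert batch.mass.total_mass == 10.0
    updated = store.update_record(batch.id, {"current_aliquots": 4}, ADMIN)
    assert updated.mass.remaining_mass == 4.0


def test_update_unknown_or_derived_field_rejected(store):
    rec = make_dna(store)
    with pytest.raises(UnknownField):
        store.update_record(rec.id, {"no_such_field": 1}, ADMIN)
    with pytest.raises(UnknownField):
        store.update_record(rec.id, {"molecular_weight": 1.0}, ADMIN)


def test_delete_referenced_construct_refused(store, chain):
    with pytest.raises(ReferencedRecord):
        store.delete_record(chain["construct"].id, ADMIN)
    with pytest.raises(ReferencedRecord):
        store.delete_record(chain["supe"].id, ADMIN)
    # top of the chain deletes fine, then the next level frees up
    store.delete_record(chain["batch"].id, ADMIN)
    store.delete_record(chain["supe"].id, ADMIN)


def test_batch_readonly_props_follow_first_effective_construct(store, chain):
    batch = store.get_record(chain["batch"].id)
    construct = store.get_record(chain["construct"].id)
    assert batch.readonly_props == construct.properties


# --- durability --------------------------------------------------------------------

def test_records_survive_close_and_reopen(config):
    store = Store(config)
    populate(store, FixtureSpec(seed=7))
    before = {
        str(r.id): flatten_record(r)
        for t in ("dna", "cellline", "supe", "batch", "request")
        for r in store.iter_records(t)
    }
    store.close()
    reopened = Store(config)
    after = {
        str(r.id): flatten_record(r)
        for t in ("dna", "cellline", "supe", "batch", "request")
        for r in reopened.iter_records(t)
    }
    reopened.close()
    assert before == after


# --- pagination -----------------------------------------------------------------------

def test_pagination_arithmetic(store):
    for i in range(25):
        make_dna(store, name=f"c{i:02d}")
    page = store.list_records("dna", page=3, page_size=10)
    assert len(page.items) == 5
    assert page.total_count == 25


def test_sort_asc_desc_are_reverses_when_unique(store):
    for name in ("b", "a", "c"):
        make_dna(store, name=name)
    asc = [r.construct_name for r in
           store.list_records("dna", sort_key="construct_name").items]
    desc = [r.construct_name for r in
            store.list_records("dna", sort_key="construct_name",
                               sort_dir="desc").items]
    assert asc == ["a", "b", "c"]
    assert desc == asc[::-1]


def test_empty_store_empty_page(store):
    page = store.list_records("dna")
    assert page.items == [] and page.total_count == 0


def test_pagination_partition_property(store):
    rng = random.Random(5)
    for i in range(23):
        make_dna(store, name=f"c{rng.randint(0, 9)}", project=f"P{i % 3}")
    full = [str(r.id) for r in
            store.list_records("dna", sort_key="construct_name",
                               page_size=1000).items]
    for page_size in (1, 3, 10, 1000):
        seen = []
        page_no = 1
        while True:
            page = store.list_records("dna", sort_key="construct_name",
                                      page=page_no, page_size=page_size)
            if not page.items:
                break
            seen.extend(str(r.id) for r in page.items)
            page_no += 1
        assert seen == full


def test_unknown_sort_field_rejected(store):
    with pytest.raises(UnknownField):
        store.list_records("dna", sort_key="bogus")


# --- search -----------------------------------------------------------------------------

@pytest.fixture
def search_store(store):
    specs = [("alpha", "P1", "His6"), ("beta", "P1", "FLAG"),
             ("gamma", "P1", ""), ("delta", "P2", "His6"),
             ("epsilon", "P2", ""), ("zeta", "P3", "his-tag"),
             ("eta", "P3", ""), ("theta", "P3", "Fc"),
             ("iota", "P3", ""), ("kappa", "P3", "HIS6")]
    for name, project, tag in specs:
        make_dna(store, name=name, project=project, tag=tag)
    return store


def test_search_equals_matches_brute_force(search_store):
    result = search_store.search(
        SearchQuery("dna", filters=[("project", "equals", "P1")])
    )
    brute = [r for r in search_store.iter_records("dna") if r.project == "P1"]
    assert result.total_count == len(brute) == 3
    assert {str(r.id) for r in result.items} == {str(r.id) for r in brute}


def test_search_contains_is_case_insensitive(search_store):
    result = search_store.search(
        SearchQuery("dna", filters=[("tag", "contains", "his")])
    )
    assert {r.construct_name for r in result.items} \
        == {"alpha", "delta", "zeta", "kappa"}


def test_search_range_on_numeric_field(search_store):
    result = search_store.search(
        SearchQuery("dna", filters=[("molecular_weight", "range", (0, 1e9))])
    )
    assert result.total_count == 10


def test_search_filters_are_conjunctive(search_store):
    result = search_store.search(
        SearchQuery("dna", filters=[("project", "equals", "P3"),
                                    ("tag", "contains", "his")])
    )
    assert {r.construct_name for r in result.items} == {"zeta", "kappa"}


def test_empty_filter_list_equals_listing(search_store):
    listed = [str(r.id) for r in
              search_store.list_records("dna", page_size=100).items]
    searched = [str(r.id) for r in
                search_store.search(SearchQuery("dna", page_size=100)).items]
    assert listed == searched


def test_search_unknown_field_rejected(search_store):
    with pytest.raises(UnknownField):
        search_store.search(SearchQuery("dna", filters=[("nope", "equals", 1)]))


# --- map file check ----------------------------------------------------------------------

def test_map_file_found_and_not_found(store, config, tmp_path):
    (tmp_path / "maps" / "present.map").write_text("x")
    assert check_map_file("present.map", config) is True
    assert check_map_file("absent.map", config) is False
    assert check_map_file(None, config) is False


def test_map_file_traversal_rejected(config, tmp_path):
    outside = tmp_path / "secret.map"
    outside.write_text("x")
    assert check_map_file("../secret.map", config) is False


def test_missing_map_file_is_warning_not_rejection(store):
    rec = make_dna(store, construct_map_filename="nope.map")
    got = store.get_record(rec.id)
    assert got.map_file_found is False  # record was still created


# --- export -------------------------------------------------------------------------------

def test_csv_export_cardinality_and_header(store, tmp_path):
    for i in range(3):
        make_dna(store, name=f"c{i}")
    path = tmp_path / "dna.csv"
    assert store.export_csv("dna", path) == 3
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 4
    assert lines[0].startswith("id,construct_name,")


def test_csv_export_empty_store_header_only(store, tmp_path):
    path = tmp_path / "empty.csv"
    store.export_csv("dna", path)
    assert len(path.read_text().strip().splitlines()) == 1


def test_fasta_roundtrip(store, tmp_path):
    seqs = {"a": "MNGTW", "b": "GGCC", "c": "WYWY"}
    for name, seq in seqs.items():
        make_dna(store, name=name, seq=seq)
    path = tmp_path / "out.fasta"
    assert store.export_fasta(path) == 3

    other = Store(type(store.config)(
        database_path=str(tmp_path / "other.db"),
        construct_map_dir=str(tmp_path),
    ))
    other.import_fasta(path, ADMIN)
    assert [r.mature_sequence for r in other.iter_records("dna")] \
        == list(seqs.values())
    other.close()


# --- whole-store validation ------------------------------------------------------------------

def test_validate_all_clean_on_fixture_and_detects_nothing_after_deletes(config):
    store = Store(config)
    populate(store, FixtureSpec(seed=3))
    assert store.validate_all() == []
    rng = random.Random(3)
    ids = [r.id for t in ("dna", "cellline", "supe", "batch")
           for r in store.iter_records(t)]
    deleted = 0
    for rid in rng.sample(ids, len(ids)):
        try:
            store.delete_record(rid, ADMIN)
            deleted += 1
        except ReferencedRecord:
            pass
    assert deleted > 0
    assert store.validate_all() == []
    store.close()
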