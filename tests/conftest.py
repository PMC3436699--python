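import pytest

from proteintracker import (
    CellLine,
    CellType,
    DNAConstruct,
    ProteinBatch,
    Role,
    Store,
    StoreConfig,
    Supe,
)
from proteintracker.workflow import MemorySink, RequestManager


@pytest.fixture
def config(tmp_path):
    map_dir = tmp_path / "maps"
    map_dir.mkdir()
    return StoreConfig(
        database_path=str(tmp_path / "store.db"),
        construct_map_dir=str(map_dir),
        notification_sink="memory",
        page_size_default=10,
    )


@pytest.fixture
def store(config):
    s = Store(config)
    yield s
    s.close()


@pytest.fixture
def sink():
    return MemorySink()


@pytest.fixture
def manager(store, sink):
    return RequestManager(store, sink=sink, request_group=["prot-group"])


@pytest.fixture
def chain(store):
    """A minimal linked lineage: construct -> stable line -> supe -> batch."""
    admin = Role.record_admin
    construct = DNAConstruct(construct_name="c1", project="P1",
                             mature_sequence="MNGTWCC")
    store.create_record(construct, admin)
    line = CellLine(name="CHO-1", cell_type=CellType.stable,
                    construct_ids=[construct.id])
    store.create_record(line, admin)
    supe = Supe(cell_line_id=line.id, concentration=0.5, aliquot_count=4)
    store.create_record(supe, admin)
    batch = ProteinBatch(supe_ids=[supe.id], purification_steps=["IMAC"],
                         original_aliquots=10, current_aliquots=10,
                         concentration=2.0, volume=5.0)
    store.create_record(batch, admin)
    return {"construct": construct, "line": line, "supe": supe, "batch": batch}
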