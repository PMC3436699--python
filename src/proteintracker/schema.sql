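-- Relational schema for the proteintracker embedded store (SQLite).
-- Junction tables (cellline_construct, supe_construct, batch_supe) carry
-- the many-to-many links: co-transfections and multi-supe batches.
-- Request tables are kept separate from the core reagent tables.

CREATE TABLE IF NOT EXISTS id_counter (
    prefix      TEXT PRIMARY KEY,
    last_serial INTEGER NOT NULL
);

CREATE TABLE IF NOT EXISTS dna_construct (
    serial                 INTEGER PRIMARY KEY,
    construct_name         TEXT NOT NULL DEFAULT '',
    project                TEXT NOT NULL DEFAULT '',
    vector                 TEXT NOT NULL DEFAULT '',
    tag                    TEXT NOT NULL DEFAULT '',
    insert_name            TEXT NOT NULL DEFAULT '',
    notebook_ref           TEXT NOT NULL DEFAULT '',
    mature_sequence        TEXT NOT NULL,
    construct_map_filename TEXT,
    map_file_found         INTEGER NOT NULL DEFAULT 0,
    molecular_weight       REAL NOT NULL,
    extinction_reduced     INTEGER NOT NULL,
    extinction_oxidized    INTEGER NOT NULL,
    absorbance_0_1pct      REAL NOT NULL,
    n_glyc_sites           INTEGER NOT NULL,
    created_at             TEXT NOT NULL DEFAULT ''
);

CREATE TABLE IF NOT EXISTS cell_line (
    serial            INTEGER PRIMARY KEY,
    name              TEXT NOT NULL DEFAULT '',
    cell_type         TEXT NOT NULL,
    origin            TEXT NOT NULL DEFAULT '',
    freezer_location  TEXT NOT NULL DEFAULT '',
    mycoplasma_result TEXT NOT NULL DEFAULT '',
    annotations       TEXT NOT NULL DEFAULT '',
    bank_date         TEXT NOT NULL DEFAULT '',
    culture_time      TEXT NOT NULL DEFAULT '',
    created_at        TEXT NOT NULL DEFAULT ''
);

CREATE TABLE IF NOT EXISTS cellline_construct (
    cellline_serial  INTEGER NOT NULL REFERENCES cell_line(serial),
    construct_serial INTEGER NOT NULL REFERENCES dna_construct(serial),
    PRIMARY KEY (cellline_serial, construct_serial)
);

CREATE TABLE IF NOT EXISTS supe (
    serial             INTEGER PRIMARY KEY,
    cell_line_serial   INTEGER NOT NULL REFERENCES cell_line(serial),
    expression_level   TEXT NOT NULL DEFAULT '',
    quality            TEXT NOT NULL DEFAULT '',
    western_blot_link  TEXT NOT NULL DEFAULT '',
    endotoxin_result   TEXT NOT NULL DEFAULT '',
    harvest_info       TEXT NOT NULL DEFAULT '',
    location           TEXT NOT NULL DEFAULT '',
    culture_media      TEXT NOT NULL DEFAULT '',
    notebook_ref       TEXT NOT NULL DEFAULT '',
    qc_file_link       TEXT NOT NULL DEFAULT '',
    concentration      REAL NOT NULL DEFAULT 0,
    remaining_quantity TEXT NOT NULL DEFAULT '',
    aliquot_count      INTEGER NOT NULL DEFAULT 0,
    created_at         TEXT NOT NULL DEFAULT ''
);

CREATE TABLE IF NOT EXISTS supe_construct (
    supe_serial      INTEGER NOT NULL REFERENCES supe(serial),
    construct_serial INTEGER NOT NULL REFERENCES dna_construct(serial),
    PRIMARY KEY (supe_serial, construct_serial)
);

CREATE TABLE IF NOT EXISTS protein_batch (
    serial             INTEGER PRIMARY KEY,
    purification_steps TEXT NOT NULL DEFAULT '[]',   -- JSON array, ordered
    original_aliquots  INTEGER NOT NULL,
    current_aliquots   INTEGER NOT NULL,
    formulation_buffer TEXT NOT NULL DEFAULT '',
    concentration      REAL NOT NULL DEFAULT 0,
    volume             REAL NOT NULL DEFAULT 0,
    endotoxin_result   TEXT NOT NULL DEFAULT '',
    qc_notes           TEXT NOT NULL DEFAULT '',
    gel_qc_link        TEXT NOT NULL DEFAULT '',
    total_mass         REAL NOT NULL DEFAULT 0,
    remaining_mass     REAL NOT NULL DEFAULT 0,
    created_at         TEXT NOT NULL DEFAULT ''
);

CREATE TABLE IF NOT EXISTS batch_supe (
    batch_serial INTEGER NOT NULL REFERENCES protein_batch(serial),
    supe_serial  INTEGER NOT NULL REFERENCES supe(serial),
    PRIMARY KEY (batch_serial, supe_serial)
);

CREATE TABLE IF NOT EXISTS request (
    serial                INTEGER PRIMARY KEY,
    kind                  TEXT NOT NULL,
    status                TEXT NOT NULL,
    requestor_email       TEXT,
    priority_rank         INTEGER,          -- NULL unless Pending
    subject_record_id     TEXT,
    parent_request_serial INTEGER REFERENCES request(serial),
    volume_ml             REAL,
    flask_count           INTEGER,
    created_at            TEXT NOT NULL DEFAULT ''
);

CREATE INDEX IF NOT EXISTS idx_request_kind_status ON request(kind, status);
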