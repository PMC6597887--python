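"""Relational persistence on an embedded SQLite file.

Natural compound keys are used as primary keys wherever the domain provides
them (accession = institute + number, experiment = project + institute +
code + date, plot = experiment + lane + plot, ...); only pictures and
uploads, which have no natural identity, get surrogate ids. Foreign keys are
enforced, so an observation can never reference an absent plot or
measurement. Deletes cascade only into picture link tables, never into
observations.

The observation table is queried attribute-centrically through the trait
metadata hierarchy: trait group > trait > methodology, behaving
set-theoretically (a group query is the union of its member-trait queries).
"""

from __future__ import annotations

import csv
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from . import core
from .core import (
    Accession,
    AggregatedObservation,
    FieldExperiment,
    FieldTreatment,
    Infestation,
    Intervention,
    InvariantError,
    MappingEntry,
    MappingProtocol,
    Measurement,
    Method,
    Methodology,
    Picture,
    PictureFile,
    Plot,
    RawObservation,
    ScoreClass,
    ScoringKey,
    SeedStock,
    Site,
    TraitDescriptor,
    Upload,
)
from .design import FieldPlan, PlanPlot

__all__ = [
    "SCHEMA_VERSION",
    "StoreIntegrityError",
    "SchemaVersionError",
    "ObservationQuery",
    "PhenoStore",
    "init_schema",
    "CSV_KINDS",
]

SCHEMA_VERSION = "1"


class StoreIntegrityError(ValueError):
    """Key conflict or referential-integrity violation."""


class SchemaVersionError(ValueError):
    """Existing file does not carry a compatible schema."""


_DDL = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);

CREATE TABLE IF NOT EXISTS accession (
  holding_institute_code TEXT NOT NULL,
  accession_number TEXT NOT NULL,
  genus TEXT NOT NULL,
  accession_name TEXT,
  species TEXT,
  biological_status TEXT,
  PRIMARY KEY (holding_institute_code, accession_number)
);

CREATE TABLE IF NOT EXISTS seed_stock (
  holding_institute_code TEXT NOT NULL,
  accession_number TEXT NOT NULL,
  stock_id TEXT NOT NULL,
  quantity_grams REAL,
  germination_rate REAL,
  harvest_year INTEGER,
  PRIMARY KEY (holding_institute_code, accession_number, stock_id),
  FOREIGN KEY (holding_institute_code, accession_number)
    REFERENCES accession (holding_institute_code, accession_number)
);

CREATE TABLE IF NOT EXISTS trait (
  trait_id TEXT PRIMARY KEY,
  name TEXT NOT NULL,
  trait_group TEXT NOT NULL,
  plant_part TEXT,
  source_list TEXT
);

CREATE TABLE IF NOT EXISTS scoring_key (
  key_id TEXT PRIMARY KEY,
  direction TEXT NOT NULL,
  classes TEXT NOT NULL -- JSON [[code, label, ordinal], ...]
);

CREATE TABLE IF NOT EXISTS method (
  method_id TEXT PRIMARY KEY,
  name TEXT NOT NULL,
  method_type TEXT NOT NULL,
  unit TEXT,
  scoring_key_id TEXT REFERENCES scoring_key (key_id),
  protocol_ref TEXT,
  parent_method_id TEXT,
  denominator_method_id TEXT
);

CREATE TABLE IF NOT EXISTS methodology (
  methodology_id TEXT PRIMARY KEY,
  trait_id TEXT NOT NULL REFERENCES trait (trait_id),
  method_id TEXT NOT NULL REFERENCES method (method_id),
  recommended_stage TEXT,
  UNIQUE (trait_id, method_id)
);

CREATE TABLE IF NOT EXISTS site (
  site_id TEXT PRIMARY KEY,
  country TEXT NOT NULL,
  latitude REAL NOT NULL,
  longitude REAL NOT NULL,
  municipality TEXT,
  elevation_m REAL,
  external_env_ref TEXT
);

CREATE TABLE IF NOT EXISTS experiment (
  project_code TEXT NOT NULL,
  institute_code TEXT NOT NULL,
  experiment_code TEXT NOT NULL,
  initiation_date TEXT NOT NULL,
  design_type TEXT NOT NULL,
  replications INTEGER NOT NULL,
  plots_per_lane INTEGER NOT NULL,
  site_id TEXT REFERENCES site (site_id),
  season_year INTEGER,
  PRIMARY KEY (project_code, institute_code, experiment_code, initiation_date)
);

CREATE TABLE IF NOT EXISTS infestation (
  infestation_id TEXT PRIMARY KEY,
  agent_name TEXT NOT NULL,
  agent_strain TEXT,
  inoculation_method TEXT,
  dose TEXT,
  date TEXT
);

CREATE TABLE IF NOT EXISTS treatment (
  project_code TEXT NOT NULL,
  institute_code TEXT NOT NULL,
  experiment_code TEXT NOT NULL,
  initiation_date TEXT NOT NULL,
  treatment_id TEXT NOT NULL,
  planting TEXT, cultivation TEXT, pre_crop TEXT, irrigation TEXT,
  fertilization TEXT, plant_protection TEXT,
  infestation_id TEXT REFERENCES infestation (infestation_id),
  PRIMARY KEY (project_code, institute_code, experiment_code, initiation_date, treatment_id),
  FOREIGN KEY (project_code, institute_code, experiment_code, initiation_date)
    REFERENCES experiment (project_code, institute_code, experiment_code, initiation_date)
);

CREATE TABLE IF NOT EXISTS intervention (
  project_code TEXT NOT NULL,
  institute_code TEXT NOT NULL,
  experiment_code TEXT NOT NULL,
  initiation_date TEXT NOT NULL,
  factor TEXT NOT NULL,
  date TEXT NOT NULL DEFAULT '',
  level TEXT NOT NULL,
  PRIMARY KEY (project_code, institute_code, experiment_code, initiation_date, factor, date),
  FOREIGN KEY (project_code, institute_code, experiment_code, initiation_date)
    REFERENCES experiment (project_code, institute_code, experiment_code, initiation_date)
);

CREATE TABLE IF NOT EXISTS plot (
  project_code TEXT NOT NULL,
  institute_code TEXT NOT NULL,
  experiment_code TEXT NOT NULL,
  initiation_date TEXT NOT NULL,
  lane INTEGER NOT NULL,
  plot INTEGER NOT NULL,
  block INTEGER NOT NULL,
  plot_role TEXT NOT NULL,
  holding_institute_code TEXT,
  accession_number TEXT,
  treatment_id TEXT,
  fill_index INTEGER,
  PRIMARY KEY (project_code, institute_code, experiment_code, initiation_date, lane, plot),
  FOREIGN KEY (project_code, institute_code, experiment_code, initiation_date)
    REFERENCES experiment (project_code, institute_code, experiment_code, initiation_date),
  FOREIGN KEY (holding_institute_code, accession_number)
    REFERENCES accession (holding_institute_code, accession_number)
);

CREATE TABLE IF NOT EXISTS measurement (
  project_code TEXT NOT NULL,
  institute_code TEXT NOT NULL,
  experiment_code TEXT NOT NULL,
  initiation_date TEXT NOT NULL,
  methodology_id TEXT NOT NULL REFERENCES methodology (methodology_id),
  observation_date TEXT NOT NULL,
  stage_observed TEXT,
  PRIMARY KEY (project_code, institute_code, experiment_code, initiation_date,
               methodology_id, observation_date),
  FOREIGN KEY (project_code, institute_code, experiment_code, initiation_date)
    REFERENCES experiment (project_code, institute_code, experiment_code, initiation_date)
);

CREATE TABLE IF NOT EXISTS mapping_protocol (
  protocol_id TEXT PRIMARY KEY,
  registry_version TEXT NOT NULL,
  entries TEXT NOT NULL -- JSON list of entry objects
);

CREATE TABLE IF NOT EXISTS upload (
  upload_id INTEGER PRIMARY KEY AUTOINCREMENT,
  file_name TEXT NOT NULL,
  sha256 TEXT NOT NULL,
  uploaded_at TEXT NOT NULL,
  project_code TEXT NOT NULL,
  institute_code TEXT NOT NULL,
  experiment_code TEXT NOT NULL,
  initiation_date TEXT NOT NULL,
  protocol_id TEXT REFERENCES mapping_protocol (protocol_id),
  status TEXT NOT NULL DEFAULT 'active',
  FOREIGN KEY (project_code, institute_code, experiment_code, initiation_date)
    REFERENCES experiment (project_code, institute_code, experiment_code, initiation_date)
);
CREATE UNIQUE INDEX IF NOT EXISTS upload_active_unique
  ON upload (sha256, project_code, institute_code, experiment_code, initiation_date)
  WHERE status = 'active';

CREATE TABLE IF NOT EXISTS raw_observation (
  project_code TEXT NOT NULL,
  institute_code TEXT NOT NULL,
  experiment_code TEXT NOT NULL,
  initiation_date TEXT NOT NULL,
  methodology_id TEXT NOT NULL,
  observation_date TEXT NOT NULL,
  lane INTEGER NOT NULL,
  plot INTEGER NOT NULL,
  value_absolute REAL,
  value_percent REAL,
  value_count INTEGER,
  value_score_numeric REAL,
  value_score_text TEXT,
  homogeneity_code TEXT,
  data_owner TEXT NOT NULL,
  availability TEXT NOT NULL,
  upload_id INTEGER REFERENCES upload (upload_id),
  PRIMARY KEY (project_code, institute_code, experiment_code, initiation_date,
               methodology_id, observation_date, lane, plot),
  FOREIGN KEY (project_code, institute_code, experiment_code, initiation_date,
               methodology_id, observation_date)
    REFERENCES measurement (project_code, institute_code, experiment_code, initiation_date,
                            methodology_id, observation_date),
  FOREIGN KEY (project_code, institute_code, experiment_code, initiation_date, lane, plot)
    REFERENCES plot (project_code, institute_code, experiment_code, initiation_date, lane, plot)
);

CREATE TABLE IF NOT EXISTS aggregated_observation (
  project_code TEXT NOT NULL,
  institute_code TEXT NOT NULL,
  experiment_code TEXT NOT NULL,
  initiation_date TEXT NOT NULL,
  holding_institute_code TEXT NOT NULL,
  accession_number TEXT NOT NULL,
  methodology_id TEXT NOT NULL REFERENCES methodology (methodology_id),
  observation_date TEXT NOT NULL,
  n_replications INTEGER NOT NULL,
  mean REAL, median REAL, sd REAL, se REAL, min REAL, max REAL,
  skewness REAL, kurtosis REAL,
  n_plants INTEGER,
  harmonized_score INTEGER,
  modal_score_text TEXT,
  stale INTEGER NOT NULL DEFAULT 0,
  PRIMARY KEY (project_code, institute_code, experiment_code, initiation_date,
               holding_institute_code, accession_number, methodology_id, observation_date),
  FOREIGN KEY (holding_institute_code, accession_number)
    REFERENCES accession (holding_institute_code, accession_number)
);

CREATE TABLE IF NOT EXISTS picture (
  picture_id TEXT PRIMARY KEY,
  description TEXT,
  camera_make TEXT,
  camera_model TEXT,
  exposure TEXT,
  taken_at TEXT
);

CREATE TABLE IF NOT EXISTS picture_file (
  picture_id TEXT NOT NULL REFERENCES picture (picture_id),
  locator TEXT NOT NULL UNIQUE,
  file_type TEXT NOT NULL,
  size_bytes INTEGER,
  PRIMARY KEY (picture_id, locator)
);

CREATE TABLE IF NOT EXISTS plot_picture (
  picture_id TEXT NOT NULL REFERENCES picture (picture_id),
  project_code TEXT NOT NULL,
  institute_code TEXT NOT NULL,
  experiment_code TEXT NOT NULL,
  initiation_date TEXT NOT NULL,
  lane INTEGER NOT NULL,
  plot INTEGER NOT NULL,
  PRIMARY KEY (picture_id, project_code, institute_code, experiment_code,
               initiation_date, lane, plot),
  FOREIGN KEY (project_code, institute_code, experiment_code, initiation_date, lane, plot)
    REFERENCES plot (project_code, institute_code, experiment_code, initiation_date, lane, plot)
    ON DELETE CASCADE
);

CREATE TABLE IF NOT EXISTS accession_picture (
  picture_id TEXT NOT NULL REFERENCES picture (picture_id),
  holding_institute_code TEXT NOT NULL,
  accession_number TEXT NOT NULL,
  PRIMARY KEY (picture_id, holding_institute_code, accession_number),
  FOREIGN KEY (holding_institute_code, accession_number)
    REFERENCES accession (holding_institute_code, accession_number)
    ON DELETE CASCADE
);
"""

_EXP_COLS = ("project_code", "institute_code", "experiment_code", "initiation_date")


def _exp_dict(key) -> dict:
    return dict(zip(_EXP_COLS, map(str, key)))


@dataclass
class _Table:
    name: str
    key_cols: tuple[str, ...]
    cols: tuple[str, ...]
    to_row: callable
    from_row: callable


def _acc_to_row(a: Accession) -> dict:
    return {
        "holding_institute_code": a.holding_institute_code,
        "accession_number": a.accession_number,
        "genus": a.genus,
        "accession_name": a.accession_name,
        "species": a.species,
        "biological_status": a.biological_status,
    }


def _acc_from_row(r) -> Accession:
    return Accession(
        holding_institute_code=r["holding_institute_code"],
        accession_number=r["accession_number"],
        genus=r["genus"],
        accession_name=r["accession_name"],
        species=r["species"],
        biological_status=r["biological_status"],
    )


def _trait_to_row(t: TraitDescriptor) -> dict:
    return {
        "trait_id": t.trait_id,
        "name": t.name,
        "trait_group": t.trait_group,
        "plant_part": t.plant_part,
        "source_list": t.source_list,
    }


def _trait_from_row(r) -> TraitDescriptor:
    return TraitDescriptor(r["trait_id"], r["name"], r["trait_group"], r["plant_part"], r["source_list"])


def _key_to_row(k: ScoringKey) -> dict:
    return {
        "key_id": k.key_id,
        "direction": k.direction,
        "classes": json.dumps([[c.code, c.label, c.ordinal] for c in k.classes]),
    }


def _key_from_row(r) -> ScoringKey:
    classes = tuple(ScoreClass(c, l, o) for c, l, o in json.loads(r["classes"]))
    return ScoringKey(key_id=r["key_id"], classes=classes, direction=r["direction"])


def _method_to_row(m: Method) -> dict:
    return {
        "method_id": m.method_id,
        "name": m.name,
        "method_type": m.method_type,
        "unit": m.unit,
        "scoring_key_id": m.scoring_key.key_id if m.scoring_key else None,
        "protocol_ref": m.protocol_ref,
        "parent_method_id": m.parent_method_id,
        "denominator_method_id": m.denominator_method_id,
    }


def _site_to_row(s: Site) -> dict:
    return {
        "site_id": s.site_id,
        "country": s.country,
        "latitude": s.latitude,
        "longitude": s.longitude,
        "municipality": s.municipality,
        "elevation_m": s.elevation_m,
        "external_env_ref": s.external_env_ref,
    }


def _site_from_row(r) -> Site:
    return Site(
        site_id=r["site_id"],
        country=r["country"],
        latitude=r["latitude"],
        longitude=r["longitude"],
        municipality=r["municipality"],
        elevation_m=r["elevation_m"],
        external_env_ref=r["external_env_ref"],
    )


def _exp_to_row(e: FieldExperiment) -> dict:
    row = _exp_dict(e.key)
    row.update(
        design_type=e.design_type,
        replications=e.replications,
        plots_per_lane=e.plots_per_lane,
        site_id=e.site_id,
        season_year=e.season_year,
    )
    return row


def _exp_from_row(r) -> FieldExperiment:
    return FieldExperiment(
        project_code=r["project_code"],
        institute_code=r["institute_code"],
        experiment_code=r["experiment_code"],
        initiation_date=r["initiation_date"],
        design_type=r["design_type"],
        replications=r["replications"],
        plots_per_lane=r["plots_per_lane"],
        site_id=r["site_id"],
        season_year=r["season_year"],
    )


def _plot_to_row(p: Plot) -> dict:
    row = _exp_dict(p.experiment_key)
    row.update(
        lane=p.lane,
        plot=p.plot,
        block=p.block,
        plot_role=p.plot_role,
        holding_institute_code=p.accession_key[0] if p.accession_key else None,
        accession_number=p.accession_key[1] if p.accession_key else None,
        treatment_id=p.treatment_id,
        fill_index=None,
    )
    return row


def _plot_from_row(r) -> Plot:
    acc = None
    if r["holding_institute_code"] is not None:
        acc = (r["holding_institute_code"], r["accession_number"])
    return Plot(
        experiment_key=tuple(r[c] for c in _EXP_COLS),
        lane=r["lane"],
        plot=r["plot"],
        block=r["block"],
        plot_role=r["plot_role"],
        accession_key=acc,
        treatment_id=r["treatment_id"],
    )


def _meas_to_row(m: Measurement) -> dict:
    row = _exp_dict(m.experiment_key)
    row.update(
        methodology_id=m.methodology_id,
        observation_date=str(m.observation_date),
        stage_observed=m.stage_observed,
    )
    return row


def _raw_to_row(o: RawObservation) -> dict:
    exp = o.measurement_key[:4]
    row = _exp_dict(exp)
    row.update(
        methodology_id=o.measurement_key[4],
        observation_date=str(o.measurement_key[5]),
        lane=o.plot_key[4],
        plot=o.plot_key[5],
        value_absolute=o.value_absolute,
        value_percent=o.value_percent,
        value_count=o.value_count,
        value_score_numeric=o.value_score_numeric,
        value_score_text=o.value_score_text,
        homogeneity_code=o.homogeneity_code,
        data_owner=o.data_owner,
        availability=o.availability,
        upload_id=o.upload_id,
    )
    return row


def _raw_from_row(r) -> RawObservation:
    exp = tuple(r[c] for c in _EXP_COLS)
    return RawObservation(
        measurement_key=exp + (r["methodology_id"], r["observation_date"]),
        plot_key=exp + (r["lane"], r["plot"]),
        value_absolute=r["value_absolute"],
        value_percent=r["value_percent"],
        value_count=r["value_count"],
        value_score_numeric=r["value_score_numeric"],
        value_score_text=r["value_score_text"],
        homogeneity_code=r["homogeneity_code"],
        data_owner=r["data_owner"],
        availability=r["availability"],
        upload_id=r["upload_id"],
    )


def _agg_to_row(a: AggregatedObservation) -> dict:
    row = _exp_dict(a.experiment_key)
    row.update(
        holding_institute_code=a.accession_key[0],
        accession_number=a.accession_key[1],
        methodology_id=a.methodology_id,
        observation_date=str(a.observation_date),
        n_replications=a.n_replications,
        mean=a.mean,
        median=a.median,
        sd=a.sd,
        se=a.se,
        min=a.min,
        max=a.max,
        skewness=a.skewness,
        kurtosis=a.kurtosis,
        n_plants=a.n_plants,
        harmonized_score=a.harmonized_score,
        modal_score_text=a.modal_score_text,
        stale=0,
    )
    return row


def _treat_to_row(t: FieldTreatment) -> dict:
    row = _exp_dict(t.experiment_key)
    row.update(
        treatment_id=t.treatment_id,
        planting=t.planting,
        cultivation=t.cultivation,
        pre_crop=t.pre_crop,
        irrigation=t.irrigation,
        fertilization=t.fertilization,
        plant_protection=t.plant_protection,
        infestation_id=t.infestation_id,
    )
    return row


def _inf_to_row(i: Infestation) -> dict:
    return {
        "infestation_id": i.infestation_id,
        "agent_name": i.agent_name,
        "agent_strain": i.agent_strain,
        "inoculation_method": i.inoculation_method,
        "dose": i.dose,
        "date": i.date,
    }


def _interv_to_row(i: Intervention) -> dict:
    row = _exp_dict(i.experiment_key)
    row.update(factor=i.factor, date=i.date or "", level=i.level)
    return row


def _stock_to_row(s: SeedStock) -> dict:
    return {
        "holding_institute_code": s.holding_institute_code,
        "accession_number": s.accession_number,
        "stock_id": s.stock_id,
        "quantity_grams": s.quantity_grams,
        "germination_rate": s.germination_rate,
        "harvest_year": s.harvest_year,
    }


def _pic_to_row(p: Picture) -> dict:
    return {
        "picture_id": p.picture_id,
        "description": p.description,
        "camera_make": p.camera_make,
        "camera_model": p.camera_model,
        "exposure": p.exposure,
        "taken_at": p.taken_at,
    }


def _picfile_to_row(f: PictureFile) -> dict:
    return {
        "picture_id": f.picture_id,
        "locator": f.locator,
        "file_type": f.file_type,
        "size_bytes": f.size_bytes,
    }


_TABLES: dict[type, _Table] = {}


def _register(cls, name, key_cols, to_row, from_row=None):
    _TABLES[cls] = _Table(name=name, key_cols=key_cols, cols=(), to_row=to_row, from_row=from_row)


_register(Accession, "accession", ("holding_institute_code", "accession_number"), _acc_to_row, _acc_from_row)
_register(SeedStock, "seed_stock", ("holding_institute_code", "accession_number", "stock_id"), _stock_to_row)
_register(TraitDescriptor, "trait", ("trait_id",), _trait_to_row, _trait_from_row)
_register(ScoringKey, "scoring_key", ("key_id",), _key_to_row, _key_from_row)
_register(Method, "method", ("method_id",), _method_to_row)
_register(Site, "site", ("site_id",), _site_to_row, _site_from_row)
_register(FieldExperiment, "experiment", _EXP_COLS, _exp_to_row, _exp_from_row)
_register(Infestation, "infestation", ("infestation_id",), _inf_to_row)
_register(FieldTreatment, "treatment", _EXP_COLS + ("treatment_id",), _treat_to_row)
_register(Intervention, "intervention", _EXP_COLS + ("factor", "date"), _interv_to_row)
_register(Plot, "plot", _EXP_COLS + ("lane", "plot"), _plot_to_row, _plot_from_row)
_register(Measurement, "measurement", _EXP_COLS + ("methodology_id", "observation_date"), _meas_to_row)
_register(
    RawObservation,
    "raw_observation",
    _EXP_COLS + ("methodology_id", "observation_date", "lane", "plot"),
    _raw_to_row,
    _raw_from_row,
)
_register(
    AggregatedObservation,
    "aggregated_observation",
    _EXP_COLS
    + ("holding_institute_code", "accession_number", "methodology_id", "observation_date"),
    _agg_to_row,
)
_register(Picture, "picture", ("picture_id",), _pic_to_row)
_register(PictureFile, "picture_file", ("picture_id", "locator"), _picfile_to_row)

#: entity kinds supported by CSV import/export
CSV_KINDS = ("accession", "trait", "scoring_key", "method", "methodology", "site")

_KIND_TO_CLS = {
    "accession": Accession,
    "trait": TraitDescriptor,
    "scoring_key": ScoringKey,
    "method": Method,
    "site": Site,
}


@dataclass(frozen=True)
class ObservationQuery:
    """Attribute-centric filter over the observation tables.

    Hierarchical trait filters: ``trait_group`` selects all traits of the
    group, ``trait_id`` all methodologies of the trait, ``methodology_id``
    one variable. ``value_range`` maps a typed value field to (lo, hi).
    """

    trait_group: Optional[str] = None
    trait_id: Optional[str] = None
    method_id: Optional[str] = None
    methodology_id: Optional[str] = None
    experiment_key: Optional[tuple] = None
    accession_key: Optional[tuple] = None
    availability: Optional[str] = None
    value_range: Optional[dict] = None
    aggregation_level: str = "raw"
    select_all: bool = False

    def __post_init__(self) -> None:
        if self.aggregation_level not in ("raw", "aggregated"):
            raise InvariantError("aggregation_level must be 'raw' or 'aggregated'")
        if self.trait_group is not None and self.trait_group not in core.TRAIT_GROUPS:
            raise InvariantError(f"unknown trait_group {self.trait_group!r}")
        has_filter = any(
            v is not None
            for v in (
                self.trait_group,
                self.trait_id,
                self.method_id,
                self.methodology_id,
                self.experiment_key,
                self.accession_key,
                self.availability,
                self.value_range,
            )
        )
        if not has_filter and not self.select_all:
            raise InvariantError("query needs at least one filter or select_all=True")


class PhenoStore:
    """Handle on one SQLite phenotyping database."""

    def __init__(self, path: Union[str, Path]):
        self.path = Path(path)
        self.schema_version = SCHEMA_VERSION
        self._conn = sqlite3.connect(str(self.path))
        self._conn.row_factory = sqlite3.Row
        self._conn.execute("PRAGMA foreign_keys = ON")

    # -- schema ------------------------------------------------------------

    def _init_schema(self) -> None:
        existing = {
            r["name"]
            for r in self._conn.execute("SELECT name FROM sqlite_master WHERE type='table'")
        }
        if existing:
            if "meta" not in existing:
                raise SchemaVersionError(f"{self.path} holds an unrelated schema (no meta table)")
            row = self._conn.execute("SELECT value FROM meta WHERE key='schema_version'").fetchone()
            if row is None or row["value"] != SCHEMA_VERSION:
                found = None if row is None else row["value"]
                raise SchemaVersionError(
                    f"schema version {found!r} incompatible with library version {SCHEMA_VERSION!r}"
                )
        with self._conn:
            self._conn.executescript(_DDL)
            self._conn.execute(
                "INSERT OR IGNORE INTO meta (key, value) VALUES ('schema_version', ?)",
                (SCHEMA_VERSION,),
            )

    def close(self) -> None:
        self._conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- generic CRUD --------------------------------------------------------

    def _table_for(self, entity) -> _Table:
        try:
            return _TABLES[type(entity)]
        except KeyError:
            raise StoreIntegrityError(f"unsupported entity type {type(entity).__name__}") from None

    def upsert(self, entity, _conn=None):
        """Insert an entity; identical re-insert is a no-op, a different
        payload under the same natural key is rejected."""
        conn = _conn or self._conn
        if isinstance(entity, Method):
            self._check_method_acyclic(entity, conn)
        spec = self._table_for(entity)
        row = spec.to_row(entity)
        key = {c: row[c] for c in spec.key_cols}
        where = " AND ".join(f"{c} IS ?" for c in key)
        cur = conn.execute(f"SELECT * FROM {spec.name} WHERE {where}", tuple(key.values()))
        existing = cur.fetchone()
        if existing is not None:
            same = all(existing[c] == row[c] for c in row if c in existing.keys())
            if same:
                return entity
            raise StoreIntegrityError(
                f"{spec.name} key {tuple(key.values())} exists with a different payload"
            )
        cols = ", ".join(row)
        marks = ", ".join("?" for _ in row)
        try:
            if _conn is None:
                with conn:
                    conn.execute(
                        f"INSERT INTO {spec.name} ({cols}) VALUES ({marks})", tuple(row.values())
                    )
            else:
                conn.execute(
                    f"INSERT INTO {spec.name} ({cols}) VALUES ({marks})", tuple(row.values())
                )
        except sqlite3.IntegrityError as e:
            raise StoreIntegrityError(str(e)) from e
        return entity

    def upsert_many(self, entities: Iterable) -> int:
        n = 0
        with self._conn:
            for e in entities:
                self.upsert(e, _conn=self._conn)
                n += 1
        return n

    def get(self, kind: str, key: tuple):
        cls = {**_KIND_TO_CLS, "experiment": FieldExperiment, "plot": Plot}.get(kind)
        if cls is None:
            raise StoreIntegrityError(f"unknown entity kind {kind!r}")
        spec = _TABLES[cls]
        key = tuple(key) if isinstance(key, (tuple, list)) else (key,)
        where = " AND ".join(f"{c} = ?" for c in spec.key_cols)
        row = self._conn.execute(
            f"SELECT * FROM {spec.name} WHERE {where}", tuple(map(str, key))
        ).fetchone()
        if row is None:
            return None
        if spec.from_row is not None:
            return spec.from_row(row)
        if cls is Method:
            return self._method_from_row(row)
        return dict(row)

    def delete(self, kind: str, key: tuple) -> int:
        cls = {**_KIND_TO_CLS, "experiment": FieldExperiment, "plot": Plot, "picture": Picture}.get(kind)
        if cls is None:
            raise StoreIntegrityError(f"unknown entity kind {kind!r}")
        spec = _TABLES[cls]
        key = tuple(key) if isinstance(key, (tuple, list)) else (key,)
        where = " AND ".join(f"{c} = ?" for c in spec.key_cols)
        try:
            with self._conn:
                cur = self._conn.execute(
                    f"DELETE FROM {spec.name} WHERE {where}", tuple(map(str, key))
                )
        except sqlite3.IntegrityError as e:
            raise StoreIntegrityError(str(e)) from e
        return cur.rowcount

    def count(self, table: str) -> int:
        return self._conn.execute(f"SELECT COUNT(*) AS c FROM {table}").fetchone()["c"]

    # -- methods & methodologies --------------------------------------------

    def _check_method_acyclic(self, method: Method, conn) -> None:
        for attr in ("parent_method_id", "denominator_method_id"):
            seen = {method.method_id}
            nxt = getattr(method, attr)
            while nxt is not None:
                if nxt in seen:
                    raise StoreIntegrityError(
                        f"method {method.method_id!r}: cyclic {attr} chain via {nxt!r}"
                    )
                seen.add(nxt)
                row = conn.execute(
                    f"SELECT {attr} FROM method WHERE method_id = ?", (nxt,)
                ).fetchone()
                nxt = row[attr] if row else None

    def _method_from_row(self, r) -> Method:
        key = None
        if r["scoring_key_id"] is not None:
            key = self.get("scoring_key", (r["scoring_key_id"],))
        return Method(
            method_id=r["method_id"],
            name=r["name"],
            method_type=r["method_type"],
            unit=r["unit"],
            scoring_key=key,
            protocol_ref=r["protocol_ref"],
            parent_method_id=r["parent_method_id"],
            denominator_method_id=r["denominator_method_id"],
        )

    def upsert_methodology(self, m: Methodology) -> Methodology:
        with self._conn:
            self.upsert(m.trait, _conn=self._conn)
            if m.method.scoring_key is not None:
                self.upsert(m.method.scoring_key, _conn=self._conn)
            self.upsert(m.method, _conn=self._conn)
            row = {
                "methodology_id": m.methodology_id,
                "trait_id": m.trait.trait_id,
                "method_id": m.method.method_id,
                "recommended_stage": m.recommended_stage,
            }
            existing = self._conn.execute(
                "SELECT * FROM methodology WHERE methodology_id = ?", (m.methodology_id,)
            ).fetchone()
            if existing is not None:
                if all(existing[c] == row[c] for c in row):
                    return m
                raise StoreIntegrityError(f"methodology {m.methodology_id!r} exists with different payload")
            try:
                self._conn.execute(
                    "INSERT INTO methodology (methodology_id, trait_id, method_id, recommended_stage)"
                    " VALUES (?, ?, ?, ?)",
                    (m.methodology_id, m.trait.trait_id, m.method.method_id, m.recommended_stage),
                )
            except sqlite3.IntegrityError as e:
                raise StoreIntegrityError(str(e)) from e
        return m

    def get_methodology(self, methodology_id: str) -> Methodology:
        row = self._conn.execute(
            "SELECT * FROM methodology WHERE methodology_id = ?", (methodology_id,)
        ).fetchone()
        if row is None:
            raise StoreIntegrityError(f"unknown methodology {methodology_id!r}")
        trait = self.get("trait", (row["trait_id"],))
        method = self.get("method", (row["method_id"],))
        return Methodology(
            methodology_id=row["methodology_id"],
            trait=trait,
            method=method,
            recommended_stage=row["recommended_stage"],
        )

    def list_methodologies(self) -> list[Methodology]:
        ids = [
            r["methodology_id"]
            for r in self._conn.execute("SELECT methodology_id FROM methodology ORDER BY methodology_id")
        ]
        return [self.get_methodology(i) for i in ids]

    # -- plans ---------------------------------------------------------------

    def save_plan(self, plan: FieldPlan) -> int:
        """Persist a laid-out plan's plots (fill order retained)."""
        rows = plan.to_plot_rows()
        with self._conn:
            for i, (plot, planplot) in enumerate(zip(rows, plan.plots)):
                row = _plot_to_row(plot)
                row["fill_index"] = i
                cols = ", ".join(row)
                marks = ", ".join("?" for _ in row)
                try:
                    self._conn.execute(
                        f"INSERT INTO plot ({cols}) VALUES ({marks})", tuple(row.values())
                    )
                except sqlite3.IntegrityError as e:
                    raise StoreIntegrityError(str(e)) from e
        return len(rows)

    def load_plan(self, experiment_key: tuple) -> FieldPlan:
        exp = self.get("experiment", experiment_key)
        if exp is None:
            raise StoreIntegrityError(f"unknown experiment {tuple(experiment_key)}")
        where = " AND ".join(f"{c} = ?" for c in _EXP_COLS)
        rows = self._conn.execute(
            f"SELECT * FROM plot WHERE {where} ORDER BY COALESCE(fill_index, lane * 100000 + plot)",
            tuple(map(str, experiment_key)),
        ).fetchall()
        plots = [
            PlanPlot(
                block=r["block"],
                role=r["plot_role"],
                accession_key=(
                    (r["holding_institute_code"], r["accession_number"])
                    if r["holding_institute_code"] is not None
                    else None
                ),
                lane=r["lane"],
                plot=r["plot"],
            )
            for r in rows
        ]
        return FieldPlan(
            experiment_key=tuple(map(str, experiment_key)),
            design_type=exp.design_type,
            plots=plots,
            design_seed=0,
            plots_per_lane=exp.plots_per_lane,
        )

    # -- observations ---------------------------------------------------------

    def raw_values(self, experiment_key, methodology_id, observation_date) -> list[dict]:
        """Raw observations of one measurement joined with their plot context."""
        where = " AND ".join(f"o.{c} = ?" for c in _EXP_COLS)
        sql = f"""
            SELECT o.*, p.plot_role, p.block,
                   p.holding_institute_code AS acc_inst, p.accession_number AS acc_num
            FROM raw_observation o
            JOIN plot p ON {' AND '.join(f'o.{c} = p.{c}' for c in _EXP_COLS)}
                       AND o.lane = p.lane AND o.plot = p.plot
            WHERE {where} AND o.methodology_id = ? AND o.observation_date = ?
        """
        rows = self._conn.execute(
            sql, tuple(map(str, experiment_key)) + (methodology_id, str(observation_date))
        ).fetchall()
        out = []
        for r in rows:
            d = dict(r)
            d["accession_key"] = (
                (r["acc_inst"], r["acc_num"]) if r["acc_inst"] is not None else None
            )
            out.append(d)
        return out

    def query_observations(self, q: ObservationQuery) -> pd.DataFrame:
        """Run an attribute-centric query; returns a row per observation
        joined with accession identity and trait/method metadata."""
        if q.aggregation_level == "raw":
            base = """
                SELECT o.*, p.plot_role, p.block,
                       p.holding_institute_code, p.accession_number,
                       a.genus, a.species, a.accession_name,
                       t.trait_id, t.name AS trait_name, t.trait_group,
                       m.method_id, m.method_type
                FROM raw_observation o
                JOIN plot p ON {pj} AND o.lane = p.lane AND o.plot = p.plot
                LEFT JOIN accession a ON p.holding_institute_code = a.holding_institute_code
                      AND p.accession_number = a.accession_number
                JOIN methodology y ON o.methodology_id = y.methodology_id
                JOIN trait t ON y.trait_id = t.trait_id
                JOIN method m ON y.method_id = m.method_id
            """.format(pj=" AND ".join(f"o.{c} = p.{c}" for c in _EXP_COLS))
            acc_cols = ("p.holding_institute_code", "p.accession_number")
        else:
            base = """
                SELECT o.*, a.genus, a.species, a.accession_name,
                       t.trait_id, t.name AS trait_name, t.trait_group,
                       m.method_id, m.method_type
                FROM aggregated_observation o
                JOIN accession a ON o.holding_institute_code = a.holding_institute_code
                      AND o.accession_number = a.accession_number
                JOIN methodology y ON o.methodology_id = y.methodology_id
                JOIN trait t ON y.trait_id = t.trait_id
                JOIN method m ON y.method_id = m.method_id
            """
            acc_cols = ("o.holding_institute_code", "o.accession_number")
        conds, params = [], []
        if q.trait_group is not None:
            conds.append("t.trait_group = ?")
            params.append(q.trait_group)
        if q.trait_id is not None:
            conds.append("t.trait_id = ?")
            params.append(q.trait_id)
        if q.method_id is not None:
            conds.append("m.method_id = ?")
            params.append(q.method_id)
        if q.methodology_id is not None:
            conds.append("o.methodology_id = ?")
            params.append(q.methodology_id)
        if q.experiment_key is not None:
            for c, v in zip(_EXP_COLS, q.experiment_key):
                conds.append(f"o.{c} = ?")
                params.append(str(v))
        if q.accession_key is not None:
            conds.append(f"{acc_cols[0]} = ? AND {acc_cols[1]} = ?")
            params.extend(q.accession_key)
        if q.availability is not None and q.aggregation_level == "raw":
            conds.append("o.availability = ?")
            params.append(q.availability)
        if q.value_range:
            for fieldname, (lo, hi) in q.value_range.items():
                if fieldname not in core.VALUE_FIELDS:
                    raise InvariantError(f"unknown value field {fieldname!r}")
                if q.aggregation_level == "aggregated":
                    fieldname = "mean"
                if lo is not None:
                    conds.append(f"o.{fieldname} >= ?")
                    params.append(lo)
                if hi is not None:
                    conds.append(f"o.{fieldname} <= ?")
                    params.append(hi)
        sql = base + (" WHERE " + " AND ".join(conds) if conds else "")
        return pd.read_sql_query(sql, self._conn, params=params)

    # -- uploads & protocols ---------------------------------------------------

    def save_protocol(self, protocol: MappingProtocol) -> MappingProtocol:
        entries = json.dumps(
            [
                {
                    "column_head": e.column_head,
                    "attribute": e.attribute,
                    "methodology_id": e.methodology_id,
                    "observation_type": e.observation_type,
                }
                for e in protocol.entries
            ]
        )
        with self._conn:
            self._conn.execute(
                "INSERT OR REPLACE INTO mapping_protocol (protocol_id, registry_version, entries)"
                " VALUES (?, ?, ?)",
                (protocol.protocol_id, protocol.registry_version, entries),
            )
        return protocol

    def get_protocol(self, protocol_id: str) -> Optional[MappingProtocol]:
        row = self._conn.execute(
            "SELECT * FROM mapping_protocol WHERE protocol_id = ?", (protocol_id,)
        ).fetchone()
        if row is None:
            return None
        entries = tuple(MappingEntry(**e) for e in json.loads(row["entries"]))
        return MappingProtocol(
            protocol_id=row["protocol_id"],
            entries=entries,
            registry_version=row["registry_version"],
        )

    def active_upload_for(self, sha256: str, experiment_key: tuple) -> Optional[Upload]:
        where = " AND ".join(f"{c} = ?" for c in _EXP_COLS)
        row = self._conn.execute(
            f"SELECT * FROM upload WHERE sha256 = ? AND status = 'active' AND {where}",
            (sha256,) + tuple(map(str, experiment_key)),
        ).fetchone()
        return self._upload_from_row(row) if row else None

    def get_upload(self, upload_id: int) -> Optional[Upload]:
        row = self._conn.execute(
            "SELECT * FROM upload WHERE upload_id = ?", (upload_id,)
        ).fetchone()
        return self._upload_from_row(row) if row else None

    @staticmethod
    def _upload_from_row(row) -> Upload:
        return Upload(
            file_name=row["file_name"],
            sha256=row["sha256"],
            uploaded_at=row["uploaded_at"],
            experiment_key=tuple(row[c] for c in _EXP_COLS),
            protocol_id=row["protocol_id"],
            status=row["status"],
            upload_id=row["upload_id"],
        )

    # -- CSV I/O ----------------------------------------------------------------

    def export_csv(self, kind: str, path: Union[str, Path]) -> int:
        """Write all entities of a kind to CSV in canonical (key) order."""
        if kind not in CSV_KINDS:
            raise StoreIntegrityError(f"unknown CSV kind {kind!r}; known: {CSV_KINDS}")
        if kind == "methodology":
            rows = self._conn.execute(
                "SELECT methodology_id, trait_id, method_id, recommended_stage"
                " FROM methodology ORDER BY methodology_id"
            ).fetchall()
            cols = ["methodology_id", "trait_id", "method_id", "recommended_stage"]
        else:
            spec = _TABLES[_KIND_TO_CLS[kind]]
            order = ", ".join(spec.key_cols)
            rows = self._conn.execute(f"SELECT * FROM {spec.name} ORDER BY {order}").fetchall()
            cols = rows[0].keys() if rows else [
                r[1] for r in self._conn.execute(f"PRAGMA table_info({spec.name})")
            ]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for r in rows:
                w.writerow(["" if r[c] is None else r[c] for c in cols])
        return len(rows)

    def import_csv(self, kind: str, path: Union[str, Path]) -> int:
        """Read entities from CSV; all-or-nothing with line-numbered errors.

        Empty strings and "NA" are read as null.
        """
        if kind not in CSV_KINDS:
            raise StoreIntegrityError(f"unknown CSV kind {kind!r}; known: {CSV_KINDS}")
        entities, errors = [], []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for lineno, rec in enumerate(reader, start=2):
                rec = {k: (None if v in ("", "NA") else v) for k, v in rec.items()}
                try:
                    entities.append(self._entity_from_csv(kind, rec))
                except (InvariantError, ValueError, TypeError, KeyError) as e:
                    errors.append(f"line {lineno}: {e}")
        if errors:
            raise InvariantError(f"{path}: " + "; ".join(errors))
        with self._conn:
            for e in entities:
                if isinstance(e, Methodology):
                    pass
                else:
                    self.upsert(e, _conn=self._conn)
        for e in entities:
            if isinstance(e, Methodology):
                self.upsert_methodology(e)
        return len(entities)

    def _entity_from_csv(self, kind: str, rec: dict):
        if kind == "accession":
            return Accession(
                holding_institute_code=rec["holding_institute_code"],
                accession_number=rec["accession_number"],
                genus=rec["genus"],
                accession_name=rec.get("accession_name"),
                species=rec.get("species"),
                biological_status=rec.get("biological_status"),
            )
        if kind == "trait":
            return TraitDescriptor(
                trait_id=rec["trait_id"],
                name=rec["name"],
                trait_group=rec["trait_group"],
                plant_part=rec.get("plant_part"),
                source_list=rec.get("source_list"),
            )
        if kind == "scoring_key":
            classes = tuple(ScoreClass(c, l, int(o)) for c, l, o in json.loads(rec["classes"]))
            return ScoringKey(key_id=rec["key_id"], classes=classes, direction=rec["direction"])
        if kind == "method":
            key = None
            if rec.get("scoring_key_id"):
                key = self.get("scoring_key", (rec["scoring_key_id"],))
                if key is None:
                    raise InvariantError(f"unknown scoring key {rec['scoring_key_id']!r}")
            return Method(
                method_id=rec["method_id"],
                name=rec["name"],
                method_type=rec["method_type"],
                unit=rec.get("unit"),
                scoring_key=key,
                protocol_ref=rec.get("protocol_ref"),
                parent_method_id=rec.get("parent_method_id"),
                denominator_method_id=rec.get("denominator_method_id"),
            )
        if kind == "site":
            return Site(
                site_id=rec["site_id"],
                country=rec["country"],
                latitude=float(rec["latitude"]),
                longitude=float(rec["longitude"]),
                municipality=rec.get("municipality"),
                elevation_m=float(rec["elevation_m"]) if rec.get("elevation_m") else None,
                external_env_ref=rec.get("external_env_ref"),
            )
        if kind == "methodology":
            trait = self.get("trait", (rec["trait_id"],))
            method = self.get("method", (rec["method_id"],))
            if trait is None or method is None:
                raise InvariantError(f"methodology {rec['methodology_id']!r} references unknown trait/method")
            return Methodology(
                methodology_id=rec["methodology_id"],
                trait=trait,
                method=method,
                recommended_stage=rec.get("recommended_stage"),
            )
        raise StoreIntegrityError(f"unknown kind {kind!r}")


def init_schema(path: Union[str, Path]) -> PhenoStore:
    """Create (or open, if compatible) a phenotyping store at ``path``.

    Idempotent on an existing compatible schema; an alien or version-
    mismatched file raises :class:`SchemaVersionError`.
    """
    store = PhenoStore(path)
    try:
        store._init_schema()
    except SchemaVersionError:
        store.close()
        raise
    return store
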