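"""Spreadsheet import: column mapping, consistency checks, replaceable uploads.

The import workflow mirrors how field and laboratory spreadsheets reach the
database: column heads are mapped to identifier attributes or to observation
methodologies (interactively or via the template header grammar), the
mapping protocol is stored for reuse on files with the same layout, and the
data are imported all-or-nothing after two gates -- the same spreadsheet may
not be imported twice into an experiment (SHA-256 of the file bytes), and
the genotype stated in each row must agree with the field plan's accession
at that plot. A faulty upload can be atomically replaced by a corrected one.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .core import (
    ATTRIBUTE_REGISTRY,
    InvariantError,
    MappingEntry,
    MappingProtocol,
    Measurement,
    Methodology,
    RawObservation,
    Upload,
    validate_observation,
    value_field_for,
)
from .design import FieldPlan
from .fieldbook import parse_header
from .store import PhenoStore, StoreIntegrityError

__all__ = [
    "Mismatch",
    "ImportReport",
    "DuplicateUploadError",
    "ConsistencyError",
    "ValidationFailedError",
    "propose_mapping",
    "register_mapping",
    "check_plot_genotype_consistency",
    "import_spreadsheet",
    "replace_upload",
    "read_table",
]


class DuplicateUploadError(ValueError):
    """The same spreadsheet (byte-identical) is already actively uploaded."""


class ConsistencyError(ValueError):
    """Plot-genotype mismatches between file and field plan; nothing written."""

    def __init__(self, mismatches: list["Mismatch"]):
        self.mismatches = mismatches
        super().__init__(
            f"{len(mismatches)} plot-genotype mismatch(es); file rejected: "
            + "; ".join(str(m) for m in mismatches[:5])
        )


class ValidationFailedError(ValueError):
    """Observation values violate their methodology; nothing written."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(f"{len(violations)} validation violation(s): " + "; ".join(violations[:5]))


@dataclass(frozen=True)
class Mismatch:
    row: int
    lane: Optional[int]
    plot: Optional[int]
    expected_accession: Optional[str]
    found_accession: Optional[str]
    kind: str = "genotype"  # genotype | unknown_plot

    def __str__(self) -> str:
        if self.kind == "unknown_plot":
            return f"row {self.row}: plot ({self.lane},{self.plot}) not in field plan"
        return (
            f"row {self.row}: plot ({self.lane},{self.plot}) expected "
            f"{self.expected_accession}, file says {self.found_accession}"
        )


@dataclass
class ImportReport:
    n_rows_read: int = 0
    n_observations_written: int = 0
    n_skipped: int = 0  # empty/NA observation cells
    mismatches: list = field(default_factory=list)
    violations: list = field(default_factory=list)
    upload: Optional[Upload] = None


def _normalize(head: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", head.strip().lower()).strip("_")


def read_table(path: Union[str, Path]) -> tuple[pd.DataFrame, bytes]:
    """Read a CSV or XLSX observation file; returns (frame, file bytes)."""
    path = Path(path)
    data = path.read_bytes()
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path, sheet_name=0)
    else:
        df = pd.read_csv(path)
    return df, data


def propose_mapping(
    column_heads: Sequence[str], catalog: Sequence[Methodology], protocol_id: str = "draft"
) -> MappingProtocol:
    """Draft a mapping by matching column heads against the attribute
    registry (case/whitespace-insensitively) and the template header grammar
    ``trait__method``. Unmatched columns are returned unmapped and need an
    explicit methodology assignment before registration."""
    if not column_heads:
        raise InvariantError("empty header row")
    if len(set(column_heads)) != len(column_heads):
        raise InvariantError("duplicate column heads in file")
    by_pair = {m.pair: m for m in catalog}
    by_id = {m.methodology_id: m for m in catalog}
    entries = []
    for head in column_heads:
        norm = _normalize(head)
        if norm in ATTRIBUTE_REGISTRY:
            entries.append(MappingEntry(column_head=head, attribute=norm))
            continue
        if norm == "experiment":  # template identifier column, informational only
            entries.append(MappingEntry(column_head=head))
            continue
        parsed = parse_header(head)
        meth = None
        if parsed and parsed in by_pair:
            meth = by_pair[parsed]
        elif head in by_id:
            meth = by_id[head]
        if meth is not None:
            entries.append(
                MappingEntry(
                    column_head=head,
                    methodology_id=meth.methodology_id,
                    observation_type=meth.observation_type,
                )
            )
        else:
            entries.append(MappingEntry(column_head=head))
    return MappingProtocol(protocol_id=protocol_id, entries=tuple(entries))


def register_mapping(
    draft: MappingProtocol,
    assignments: Mapping[str, tuple[str, str]] = (),
    catalog: Sequence[Methodology] = (),
    store: Optional[PhenoStore] = None,
    protocol_id: Optional[str] = None,
) -> MappingProtocol:
    """Complete a draft with (methodology_id, observation_type) assignments
    for its unmapped columns and persist the protocol.

    A column already mapped to an attribute cannot also be assigned a
    methodology; any column left without a target is an error listing the
    columns still open. The identifier column ``experiment`` may remain
    unmapped (it is informational).
    """
    assignments = dict(assignments)
    by_id = {m.methodology_id: m for m in catalog}
    entries = []
    for e in draft.entries:
        if e.column_head in assignments:
            if e.attribute is not None:
                raise InvariantError(
                    f"column {e.column_head!r} is mapped to attribute {e.attribute!r}; "
                    "it cannot also carry a methodology"
                )
            mid, otype = assignments.pop(e.column_head)
            if by_id and mid not in by_id:
                raise LookupError(f"unknown methodology {mid!r}")
            entries.append(
                MappingEntry(column_head=e.column_head, methodology_id=mid, observation_type=otype)
            )
        else:
            entries.append(e)
    if assignments:
        raise LookupError(f"assignments for columns not in draft: {sorted(assignments)}")
    open_cols = [
        e.column_head for e in entries if not e.is_mapped and _normalize(e.column_head) != "experiment"
    ]
    if open_cols:
        raise InvariantError(f"columns still unmapped: {open_cols}")
    protocol = MappingProtocol(
        protocol_id=protocol_id or draft.protocol_id, entries=tuple(entries)
    )
    if store is not None:
        store.save_protocol(protocol)
    return protocol


def _is_empty(v) -> bool:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return True
    return isinstance(v, str) and v.strip() in ("", "NA")


def _attr_columns(protocol: MappingProtocol) -> dict[str, str]:
    return {e.attribute: e.column_head for e in protocol.entries if e.attribute is not None}


def _resolve_rows(df: pd.DataFrame, protocol: MappingProtocol, plan: FieldPlan) -> list[dict]:
    """Resolve each file row to a plan plot by (lane, plot), falling back to
    the accession when it occupies a unique plot."""
    attr = _attr_columns(protocol)
    by_coord = {(p.lane, p.plot): p for p in plan.plots}
    acc_plots: dict[str, list] = {}
    for p in plan.data_plots:
        acc_plots.setdefault(p.accession_key[1], []).append(p)
    resolved = []
    for i, rec in enumerate(df.to_dict("records")):
        lane = plot = None
        if "lane" in attr and "plot" in attr:
            lv, pv = rec.get(attr["lane"]), rec.get(attr["plot"])
            if not _is_empty(lv) and not _is_empty(pv):
                lane, plot = int(lv), int(pv)
        found_acc = None
        if "accession_number" in attr and not _is_empty(rec.get(attr["accession_number"])):
            found_acc = str(rec[attr["accession_number"]]).strip()
        target = None
        if lane is not None:
            target = by_coord.get((lane, plot))
        elif found_acc is not None and len(acc_plots.get(found_acc, [])) == 1:
            target = acc_plots[found_acc][0]
            lane, plot = target.lane, target.plot
        resolved.append(
            {"row": i, "lane": lane, "plot": plot, "found_accession": found_acc, "target": target, "rec": rec}
        )
    return resolved


def check_plot_genotype_consistency(rows, plan: FieldPlan) -> list[Mismatch]:
    """Compare each row's stated accession with the plan's accession at the
    addressed plot.

    ``rows`` are resolved row dicts (internal) or any iterable of mappings
    with keys row, lane, plot, found_accession. A row addressing a plot
    absent from the plan yields an ``unknown_plot`` mismatch; an accession
    stated for an orientation plot always mismatches.
    """
    by_coord = {(p.lane, p.plot): p for p in plan.plots}
    mismatches = []
    for r in rows:
        target = r.get("target") or by_coord.get((r.get("lane"), r.get("plot")))
        if target is None:
            mismatches.append(
                Mismatch(
                    row=r["row"],
                    lane=r.get("lane"),
                    plot=r.get("plot"),
                    expected_accession=None,
                    found_accession=r.get("found_accession"),
                    kind="unknown_plot",
                )
            )
            continue
        found = r.get("found_accession")
        if found is None:
            continue
        if target.role == "orientation":
            mismatches.append(
                Mismatch(r["row"], r["lane"], r["plot"], None, found, kind="genotype")
            )
        elif target.accession_key[1] != found:
            mismatches.append(
                Mismatch(r["row"], r["lane"], r["plot"], target.accession_key[1], found)
            )
    return mismatches


def _coerce(value, observation_type: str):
    if observation_type == "count":
        return int(float(value))
    if observation_type == "text_score":
        return str(value).strip()
    return float(value)


def _prepare(
    store: PhenoStore,
    df: pd.DataFrame,
    protocol: MappingProtocol,
    experiment_key: tuple,
    observation_date: str,
    data_owner: str,
    availability: str,
):
    """Shared validation pipeline: resolve rows, check consistency, build
    the observation payloads. Raises on any gate failure; writes nothing."""
    plan = store.load_plan(experiment_key)
    if not plan.plots:
        raise StoreIntegrityError(f"experiment {tuple(experiment_key)} has no stored field plan")
    missing = [c for e in protocol.entries if (c := e.column_head) not in df.columns and e.is_mapped]
    if missing:
        raise InvariantError(f"protocol covers columns absent from file: {missing}")

    resolved = _resolve_rows(df, protocol, plan)
    mismatches = check_plot_genotype_consistency(resolved, plan)
    if mismatches:
        raise ConsistencyError(mismatches)

    methodologies = {
        e.methodology_id: store.get_methodology(e.methodology_id)
        for e in protocol.observation_entries
    }
    payloads = []  # (methodology_id, plot_key, field dict)
    n_skipped = 0
    violations: list[str] = []
    for r in resolved:
        target = r["target"]
        for e in protocol.observation_entries:
            cell = r["rec"].get(e.column_head)
            if _is_empty(cell):
                n_skipped += 1
                continue
            meth = methodologies[e.methodology_id]
            fieldname = value_field_for(e.observation_type)
            try:
                fields = {fieldname: _coerce(cell, e.observation_type)}
            except (TypeError, ValueError):
                violations.append(
                    f"row {r['row']}, column {e.column_head!r}: cannot parse {cell!r} "
                    f"as {e.observation_type}"
                )
                continue
            report = validate_observation(fields, meth)
            if not report.ok:
                violations.extend(
                    f"row {r['row']}, column {e.column_head!r}: {v}" for v in report.violations
                )
                continue
            payloads.append((e.methodology_id, (target.lane, target.plot), fields))
    if violations:
        raise ValidationFailedError(violations)
    return plan, resolved, payloads, n_skipped, methodologies


def _write(
    store: PhenoStore,
    conn,
    payloads,
    methodologies,
    experiment_key,
    observation_date,
    upload_id,
    data_owner,
    availability,
) -> int:
    exp = tuple(map(str, experiment_key))
    for mid in sorted({mid for mid, _, _ in payloads}):
        store.upsert(
            Measurement(experiment_key=exp, methodology_id=mid, observation_date=str(observation_date)),
            _conn=conn,
        )
    n = 0
    for mid, (lane, plot), fields in payloads:
        obs = RawObservation(
            measurement_key=exp + (mid, str(observation_date)),
            plot_key=exp + (lane, plot),
            data_owner=data_owner,
            availability=availability,
            upload_id=upload_id,
            **fields,
        )
        store.upsert(obs, _conn=conn)
        n += 1
    return n


def import_spreadsheet(
    store: PhenoStore,
    file: Union[str, Path],
    protocol: MappingProtocol,
    experiment_key: tuple,
    observation_date: str,
    data_owner: str = "import",
    availability: str = "project",
) -> ImportReport:
    """Import an observation spreadsheet under a mapping protocol.

    All-or-nothing: a byte-identical active upload for the experiment raises
    :class:`DuplicateUploadError`; any plot-genotype mismatch raises
    :class:`ConsistencyError` with the full mismatch list; any value failing
    its methodology raises :class:`ValidationFailedError`. On success one
    raw observation is written per non-empty observation cell, linked to the
    (experiment, methodology, date) measurement, created if absent.
    """
    df, data = read_table(file)
    sha = hashlib.sha256(data).hexdigest()
    if store.active_upload_for(sha, experiment_key) is not None:
        raise DuplicateUploadError(
            f"{Path(file).name}: the same spreadsheet is already uploaded for this experiment"
        )
    plan, resolved, payloads, n_skipped, methodologies = _prepare(
        store, df, protocol, experiment_key, observation_date, data_owner, availability
    )
    store.save_protocol(protocol)
    conn = store._conn
    with conn:
        cur = conn.execute(
            "INSERT INTO upload (file_name, sha256, uploaded_at, project_code, institute_code,"
            " experiment_code, initiation_date, protocol_id, status)"
            " VALUES (?, ?, ?, ?, ?, ?, ?, ?, 'active')",
            (Path(file).name, sha, datetime.now(timezone.utc).isoformat())
            + tuple(map(str, experiment_key))
            + (protocol.protocol_id,),
        )
        upload_id = cur.lastrowid
        n_written = _write(
            store, conn, payloads, methodologies, experiment_key, observation_date,
            upload_id, data_owner, availability,
        )
    return ImportReport(
        n_rows_read=len(df),
        n_observations_written=n_written,
        n_skipped=n_skipped,
        upload=store.get_upload(upload_id),
    )


def replace_upload(
    store: PhenoStore,
    old_upload_id: int,
    file: Union[str, Path],
    protocol: MappingProtocol,
    observation_date: str,
    data_owner: str = "import",
    availability: str = "project",
) -> ImportReport:
    """Atomically replace a faulty upload with a corrected file.

    The old upload's observations are deleted and its status set to
    ``replaced``, then the new file is imported -- all in one transaction.
    If the new file fails any gate the old upload is left untouched.
    """
    old = store.get_upload(old_upload_id)
    if old is None or old.status != "active":
        raise StoreIntegrityError(f"upload {old_upload_id} is not an active upload")
    experiment_key = old.experiment_key

    df, data = read_table(file)
    sha = hashlib.sha256(data).hexdigest()
    existing = store.active_upload_for(sha, experiment_key)
    if existing is not None and existing.upload_id != old_upload_id:
        raise DuplicateUploadError(
            f"{Path(file).name}: the same spreadsheet is already uploaded for this experiment"
        )
    # validation gates run before any state is touched
    plan, resolved, payloads, n_skipped, methodologies = _prepare(
        store, df, protocol, experiment_key, observation_date, data_owner, availability
    )
    store.save_protocol(protocol)
    conn = store._conn
    with conn:
        conn.execute("DELETE FROM raw_observation WHERE upload_id = ?", (old_upload_id,))
        conn.execute("UPDATE upload SET status = 'replaced' WHERE upload_id = ?", (old_upload_id,))
        cur = conn.execute(
            "INSERT INTO upload (file_name, sha256, uploaded_at, project_code, institute_code,"
            " experiment_code, initiation_date, protocol_id, status)"
            " VALUES (?, ?, ?, ?, ?, ?, ?, ?, 'active')",
            (Path(file).name, sha, datetime.now(timezone.utc).isoformat())
            + tuple(map(str, experiment_key))
            + (protocol.protocol_id,),
        )
        upload_id = cur.lastrowid
        n_written = _write(
            store, conn, payloads, methodologies, experiment_key, observation_date,
            upload_id, data_owner, availability,
        )
    return ImportReport(
        n_rows_read=len(df),
        n_observations_written=n_written,
        n_skipped=n_skipped,
        upload=store.get_upload(upload_id),
    )
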