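"""Domain model for field-phenotyping information.

The phenotypic observation is the core entity: a trait expression recorded
in an experimental unit (a field plot), stored raw or aggregated in an
entity-attribute-value style table that references explanatory metadata --
the accession observed, the methodology (trait x method) applied, the
measurement event, the field experiment and its plot design.

All types are plain dataclasses with invariants enforced at construction.
Entities are identified by natural (often compound) keys; meaningful keys
implement meaningful integrity rules, so surrogate ids are used only where
no natural key exists (pictures, uploads).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, fields, replace
from datetime import date as _date
from typing import Optional, Sequence

__all__ = [
    "InvariantError",
    "ReferenceError_",
    "TRAIT_GROUPS",
    "METHOD_TYPES",
    "OBSERVATION_TYPES",
    "AVAILABILITY_LEVELS",
    "ATTRIBUTE_REGISTRY",
    "Accession",
    "SeedStock",
    "TraitDescriptor",
    "ScoreClass",
    "ScoringKey",
    "Method",
    "Methodology",
    "Site",
    "FieldExperiment",
    "Infestation",
    "FieldTreatment",
    "Intervention",
    "Plot",
    "Measurement",
    "RawObservation",
    "AggregatedObservation",
    "Upload",
    "MappingEntry",
    "MappingProtocol",
    "Picture",
    "PictureFile",
    "PlotPictureLink",
    "AccessionPictureLink",
    "ValidationReport",
    "validate_observation",
    "compose_methodology",
    "value_field_for",
]


class InvariantError(ValueError):
    """A domain-type invariant was violated at construction or update."""


class ReferenceError_(ValueError):
    """A reference between entities is malformed or dangling."""


TRAIT_GROUPS = (
    "abiotic_stress",
    "biotic_stress",
    "agronomy",
    "morphology",
    "phenology",
    "physiology",
    "quality",
)

METHOD_TYPES = ("measurement", "count", "percentage", "numeric_score", "text_score")

#: spreadsheet observation-column types; aliases of the method types plus
#: 'absolute value' wording used on import forms
OBSERVATION_TYPES = METHOD_TYPES

AVAILABILITY_LEVELS = ("public", "project", "owner")

#: closed registry of identifier attributes a spreadsheet column may map to
ATTRIBUTE_REGISTRY = (
    "accession_number",
    "accession_name",
    "holding_institute_code",
    "lane",
    "plot",
    "block",
    "observation_date",
    "stage",
    "homogeneity_code",
)

ATTRIBUTE_REGISTRY_VERSION = "1"

_ISO_DATE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvariantError(msg)


def _nonempty(value: str, name: str) -> None:
    _require(isinstance(value, str) and value.strip() != "", f"{name} must be a non-empty string")


def _check_iso_date(value: Optional[str], name: str) -> None:
    if value is None:
        return
    if isinstance(value, _date):
        return
    _require(bool(_ISO_DATE.match(str(value))), f"{name} must be an ISO-8601 date (YYYY-MM-DD)")


def _enum(value: str, allowed: Sequence[str], name: str) -> None:
    _require(value in allowed, f"{name} must be one of {allowed}, got {value!r}")


# ---------------------------------------------------------------------------
# germplasm


@dataclass(frozen=True)
class Accession:
    """A genebank accession, breeding line or cultivar (MCPD identity).

    Identified by the FAO-WIEWS code of the holding institute plus the
    institute's accession number.
    """

    holding_institute_code: str
    accession_number: str
    genus: str
    accession_name: Optional[str] = None
    species: Optional[str] = None
    biological_status: Optional[str] = None

    def __post_init__(self) -> None:
        _nonempty(self.holding_institute_code, "holding_institute_code")
        _nonempty(self.accession_number, "accession_number")
        _nonempty(self.genus, "genus")
        # FAO WIEWS convention: institute codes upper case
        object.__setattr__(self, "holding_institute_code", self.holding_institute_code.strip().upper())
        object.__setattr__(self, "accession_number", self.accession_number.strip())

    @property
    def key(self) -> tuple[str, str]:
        return (self.holding_institute_code, self.accession_number)

    @property
    def label(self) -> str:
        return f"{self.holding_institute_code}:{self.accession_number}"


@dataclass(frozen=True)
class SeedStock:
    """Physical seed lot of an accession in a working collection."""

    holding_institute_code: str
    accession_number: str
    stock_id: str
    quantity_grams: Optional[float] = None
    germination_rate: Optional[float] = None
    harvest_year: Optional[int] = None

    def __post_init__(self) -> None:
        _nonempty(self.stock_id, "stock_id")
        if self.quantity_grams is not None:
            _require(self.quantity_grams >= 0, "quantity_grams must be non-negative")
        if self.germination_rate is not None:
            _require(0.0 <= self.germination_rate <= 1.0, "germination_rate must lie in [0, 1]")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.holding_institute_code, self.accession_number, self.stock_id)


# ---------------------------------------------------------------------------
# traits & methodology


@dataclass(frozen=True)
class TraitDescriptor:
    """An observable trait from a descriptor list or trait ontology."""

    trait_id: str
    name: str
    trait_group: str
    plant_part: Optional[str] = None
    source_list: Optional[str] = None

    def __post_init__(self) -> None:
        _nonempty(self.trait_id, "trait_id")
        _nonempty(self.name, "name")
        _enum(self.trait_group, TRAIT_GROUPS, "trait_group")


@dataclass(frozen=True)
class ScoreClass:
    code: str
    label: str
    ordinal: int


@dataclass(frozen=True)
class ScoringKey:
    """Ordered classification key for categorical scoring methods."""

    key_id: str
    classes: tuple[ScoreClass, ...]
    direction: str = "neutral"

    def __post_init__(self) -> None:
        _nonempty(self.key_id, "key_id")
        object.__setattr__(self, "classes", tuple(self.classes))
        _require(len(self.classes) > 0, "scoring key needs at least one class")
        codes = [c.code for c in self.classes]
        _require(len(set(codes)) == len(codes), "scoring-key codes must be unique")
        ordinals = [c.ordinal for c in self.classes]
        _require(
            all(a < b for a, b in zip(ordinals, ordinals[1:])),
            "scoring-key ordinals must be strictly increasing",
        )
        _enum(self.direction, ("higher_is_better", "lower_is_better", "neutral"), "direction")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.classes)


@dataclass(frozen=True)
class Method:
    """A concrete observation method.

    Method types map to observation value fields: measurement -> absolute
    value with a unit; count -> integer count; percentage -> percent;
    numeric_score / text_score -> value from the attached scoring key.
    Methods may be developed from another method (parent) or complement one
    (denominator, e.g. a count method whose percentage sibling divides by it).
    """

    method_id: str
    name: str
    method_type: str
    unit: Optional[str] = None
    scoring_key: Optional[ScoringKey] = None
    protocol_ref: Optional[str] = None
    parent_method_id: Optional[str] = None
    denominator_method_id: Optional[str] = None

    def __post_init__(self) -> None:
        _nonempty(self.method_id, "method_id")
        _nonempty(self.name, "name")
        _enum(self.method_type, METHOD_TYPES, "method_type")
        if self.method_type in ("numeric_score", "text_score"):
            _require(self.scoring_key is not None, f"{self.method_type} method requires a scoring key")
        if self.method_type == "measurement":
            _require(bool(self.unit), "measurement method requires a unit")


@dataclass(frozen=True)
class Methodology:
    """The observable variable: a trait paired with a concrete method.

    Optionally carries the phenological stage (BBCH-style code, free string)
    recommended for the observation.
    """

    methodology_id: str
    trait: TraitDescriptor
    method: Method
    recommended_stage: Optional[str] = None

    def __post_init__(self) -> None:
        _nonempty(self.methodology_id, "methodology_id")
        if self.recommended_stage is not None:
            _nonempty(self.recommended_stage, "recommended_stage")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.trait.trait_id, self.method.method_id)

    @property
    def observation_type(self) -> str:
        return self.method.method_type


def compose_methodology(
    trait: TraitDescriptor,
    method: Method,
    stage: Optional[str] = None,
    methodology_id: Optional[str] = None,
    existing: Sequence[Methodology] = (),
) -> Methodology:
    """Compose a trait and a method into a methodology.

    Rejects a (trait, method) pair already present in ``existing`` unless the
    composition is identical (idempotence).
    """
    mid = methodology_id or f"{trait.trait_id}__{method.method_id}"
    candidate = Methodology(methodology_id=mid, trait=trait, method=method, recommended_stage=stage)
    for m in existing:
        if m.pair == candidate.pair:
            if m == candidate:
                return m
            raise InvariantError(f"methodology for pair {candidate.pair} already exists")
    return candidate


# ---------------------------------------------------------------------------
# experimental context


@dataclass(frozen=True)
class Site:
    """Geographic identity of an experiment site.

    ``external_env_ref`` is a hook (URI) for linking soil/weather/GIS systems.
    """

    site_id: str
    country: str
    latitude: float
    longitude: float
    municipality: Optional[str] = None
    elevation_m: Optional[float] = None
    external_env_ref: Optional[str] = None

    def __post_init__(self) -> None:
        _nonempty(self.site_id, "site_id")
        _nonempty(self.country, "country")
        _require(-90.0 <= self.latitude <= 90.0, "latitude must lie in [-90, 90]")
        _require(-180.0 <= self.longitude <= 180.0, "longitude must lie in [-180, 180]")


DESIGN_TYPES = ("block", "augmented", "latin_square", "lattice")


@dataclass(frozen=True)
class FieldExperiment:
    """A one-site / one-season field experiment.

    Identified by the compound key (project, institute, experiment code,
    initiation date). Multi-site series are sets of experiments under one
    project code. latin_square / lattice are accepted as metadata but their
    randomization is out of scope.
    """

    project_code: str
    institute_code: str
    experiment_code: str
    initiation_date: str
    design_type: str = "block"
    replications: int = 1
    plots_per_lane: int = 1
    site_id: Optional[str] = None
    season_year: Optional[int] = None

    def __post_init__(self) -> None:
        for f in ("project_code", "institute_code", "experiment_code"):
            _nonempty(getattr(self, f), f)
        _check_iso_date(self.initiation_date, "initiation_date")
        _enum(self.design_type, DESIGN_TYPES, "design_type")
        _require(self.replications >= 1, "replications must be positive")
        _require(self.plots_per_lane >= 1, "plots_per_lane must be >= 1")
        object.__setattr__(self, "institute_code", self.institute_code.strip().upper())

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.project_code, self.institute_code, self.experiment_code, str(self.initiation_date))

    @property
    def label(self) -> str:
        return "/".join(self.key)


@dataclass(frozen=True)
class Infestation:
    """Artificial inoculation with a biotic agent (disease, pest, symbiont)."""

    infestation_id: str
    agent_name: str
    agent_strain: Optional[str] = None
    inoculation_method: Optional[str] = None
    dose: Optional[str] = None
    date: Optional[str] = None

    def __post_init__(self) -> None:
        _nonempty(self.infestation_id, "infestation_id")
        _nonempty(self.agent_name, "agent_name")
        _check_iso_date(self.date, "date")


@dataclass(frozen=True)
class FieldTreatment:
    """Agronomic treatment context applied to plots of an experiment."""

    experiment_key: tuple[str, str, str, str]
    treatment_id: str
    planting: Optional[str] = None
    cultivation: Optional[str] = None
    pre_crop: Optional[str] = None
    irrigation: Optional[str] = None
    fertilization: Optional[str] = None
    plant_protection: Optional[str] = None
    infestation_id: Optional[str] = None

    def __post_init__(self) -> None:
        _nonempty(self.treatment_id, "treatment_id")
        object.__setattr__(self, "experiment_key", tuple(self.experiment_key))

    @property
    def key(self):
        return self.experiment_key + (self.treatment_id,)


@dataclass(frozen=True)
class Intervention:
    """A factor/level pair intervention on an experiment (vertical design)."""

    experiment_key: tuple[str, str, str, str]
    factor: str
    level: str
    date: Optional[str] = None

    def __post_init__(self) -> None:
        _nonempty(self.factor, "factor")
        _nonempty(self.level, "level")
        _check_iso_date(self.date, "date")
        object.__setattr__(self, "experiment_key", tuple(self.experiment_key))

    @property
    def key(self):
        return self.experiment_key + (self.factor, self.date or "")


PLOT_ROLES = ("entry", "check", "orientation")


@dataclass(frozen=True)
class Plot:
    """An experimental unit at matrix position (lane, plot).

    ``block`` is the first randomization stratum below the experiment.
    Orientation plots carry no accession; they aid sowing and are excluded
    from statistics.
    """

    experiment_key: tuple[str, str, str, str]
    lane: int
    plot: int
    block: int
    plot_role: str = "entry"
    accession_key: Optional[tuple[str, str]] = None
    treatment_id: Optional[str] = None

    def __post_init__(self) -> None:
        _require(self.lane >= 1, "lane must be >= 1")
        _require(self.plot >= 1, "plot must be >= 1")
        _require(self.block >= 1, "block must be >= 1")
        _enum(self.plot_role, PLOT_ROLES, "plot_role")
        if self.plot_role in ("entry", "check"):
            _require(self.accession_key is not None, f"{self.plot_role} plot requires an accession")
        object.__setattr__(self, "experiment_key", tuple(self.experiment_key))
        if self.accession_key is not None:
            object.__setattr__(self, "accession_key", tuple(self.accession_key))

    @property
    def key(self):
        return self.experiment_key + (self.lane, self.plot)


@dataclass(frozen=True)
class Measurement:
    """One application of a methodology over an experiment's plots at a date."""

    experiment_key: tuple[str, str, str, str]
    methodology_id: str
    observation_date: str
    stage_observed: Optional[str] = None

    def __post_init__(self) -> None:
        _nonempty(self.methodology_id, "methodology_id")
        _check_iso_date(self.observation_date, "observation_date")
        _require(self.observation_date is not None, "observation_date required")
        object.__setattr__(self, "experiment_key", tuple(self.experiment_key))

    @property
    def key(self):
        return self.experiment_key + (self.methodology_id, str(self.observation_date))


# ---------------------------------------------------------------------------
# observations

#: method type -> the raw-observation value field it implies
_VALUE_FIELD = {
    "measurement": "value_absolute",
    "count": "value_count",
    "percentage": "value_percent",
    "numeric_score": "value_score_numeric",
    "text_score": "value_score_text",
}

VALUE_FIELDS = tuple(_VALUE_FIELD.values())


def value_field_for(method_type: str) -> str:
    """Raw-observation field implied by a method (or observation) type."""
    try:
        return _VALUE_FIELD[method_type]
    except KeyError:
        raise InvariantError(f"unknown method type {method_type!r}") from None


@dataclass(frozen=True)
class RawObservation:
    """A plot-level trait expression in its original state.

    Separate typed value fields support calculation, aggregation, sorting and
    validation; more than one may be populated when several data types apply
    to the same observation (e.g. diseased plants as count and percentage).
    """

    measurement_key: tuple
    plot_key: tuple
    value_absolute: Optional[float] = None
    value_percent: Optional[float] = None
    value_count: Optional[int] = None
    value_score_numeric: Optional[float] = None
    value_score_text: Optional[str] = None
    homogeneity_code: Optional[str] = None
    data_owner: str = "unknown"
    availability: str = "project"
    upload_id: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurement_key", tuple(self.measurement_key))
        object.__setattr__(self, "plot_key", tuple(self.plot_key))
        _require(
            any(getattr(self, f) is not None for f in VALUE_FIELDS),
            "at least one value field must be populated",
        )
        if self.value_percent is not None:
            _require(0.0 <= self.value_percent <= 100.0, "value_percent must lie in [0, 100]")
        if self.value_count is not None:
            _require(int(self.value_count) >= 0, "value_count must be >= 0")
        _enum(self.availability, AVAILABILITY_LEVELS, "availability")
        _nonempty(self.data_owner, "data_owner")

    @property
    def key(self):
        return self.measurement_key + self.plot_key


@dataclass(frozen=True)
class AggregatedObservation:
    """Per-accession summary of an experiment's raw plot values.

    Carries the descriptive statistics preferred for presentation (mean,
    median, sd/se, range, skewness, kurtosis) with the replication count;
    raw data are always retained alongside. ``harmonized_score`` is the
    universal 1-9 grade, a presentation aid, never a substitute for raw data.
    """

    experiment_key: tuple[str, str, str, str]
    accession_key: tuple[str, str]
    methodology_id: str
    observation_date: str
    n_replications: int
    mean: Optional[float] = None
    median: Optional[float] = None
    sd: Optional[float] = None
    se: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None
    skewness: Optional[float] = None
    kurtosis: Optional[float] = None
    n_plants: Optional[int] = None
    harmonized_score: Optional[int] = None
    modal_score_text: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "experiment_key", tuple(self.experiment_key))
        object.__setattr__(self, "accession_key", tuple(self.accession_key))
        _require(self.n_replications >= 1, "n_replications must be >= 1")
        if self.min is not None and self.mean is not None and self.max is not None:
            _require(
                self.min - 1e-9 <= self.mean <= self.max + 1e-9,
                "mean must lie between min and max",
            )
        if self.sd is not None and self.se is not None:
            _require(
                math.isclose(self.se, self.sd / math.sqrt(self.n_replications), rel_tol=1e-9, abs_tol=1e-12),
                "se must equal sd / sqrt(n)",
            )
        if self.harmonized_score is not None:
            _require(1 <= self.harmonized_score <= 9, "harmonized_score must lie in [1, 9]")

    @property
    def key(self):
        return self.experiment_key + self.accession_key + (self.methodology_id, str(self.observation_date))


# ---------------------------------------------------------------------------
# provenance & mapping


@dataclass
class Upload:
    """Provenance record of one imported spreadsheet (surrogate id)."""

    file_name: str
    sha256: str
    uploaded_at: str
    experiment_key: tuple[str, str, str, str]
    protocol_id: Optional[str] = None
    status: str = "active"
    upload_id: Optional[int] = None

    def __post_init__(self) -> None:
        _nonempty(self.file_name, "file_name")
        _require(bool(re.fullmatch(r"[0-9a-f]{64}", self.sha256)), "sha256 must be a 64-char hex digest")
        _enum(self.status, ("active", "replaced"), "status")
        self.experiment_key = tuple(self.experiment_key)


@dataclass(frozen=True)
class MappingEntry:
    """One column mapping: either to a registry attribute or a methodology."""

    column_head: str
    attribute: Optional[str] = None
    methodology_id: Optional[str] = None
    observation_type: Optional[str] = None

    def __post_init__(self) -> None:
        _nonempty(self.column_head, "column_head")
        if self.attribute is not None:
            _require(self.methodology_id is None, "column cannot map to both attribute and methodology")
            _enum(self.attribute, ATTRIBUTE_REGISTRY, "attribute")
        if self.observation_type is not None:
            _enum(self.observation_type, OBSERVATION_TYPES, "observation_type")
            _require(self.methodology_id is not None, "observation-type targets require a methodology")
        if self.methodology_id is not None:
            _require(self.observation_type is not None, "methodology targets require an observation type")

    @property
    def is_mapped(self) -> bool:
        return self.attribute is not None or self.methodology_id is not None


@dataclass(frozen=True)
class MappingProtocol:
    """Stored assignment of spreadsheet columns to schema targets.

    Reusable across uploads with the same layout.
    """

    protocol_id: str
    entries: tuple[MappingEntry, ...]
    registry_version: str = ATTRIBUTE_REGISTRY_VERSION

    def __post_init__(self) -> None:
        _nonempty(self.protocol_id, "protocol_id")
        object.__setattr__(self, "entries", tuple(self.entries))
        heads = [e.column_head for e in self.entries]
        _require(len(set(heads)) == len(heads), "each column head may be mapped at most once")

    def entry_for(self, column_head: str) -> Optional[MappingEntry]:
        for e in self.entries:
            if e.column_head == column_head:
                return e
        return None

    @property
    def unmapped(self) -> tuple[str, ...]:
        return tuple(e.column_head for e in self.entries if not e.is_mapped)

    @property
    def observation_entries(self) -> tuple[MappingEntry, ...]:
        return tuple(e for e in self.entries if e.methodology_id is not None)


# ---------------------------------------------------------------------------
# pictures


@dataclass
class Picture:
    """Image metadata; files are referenced by locator, never copied."""

    picture_id: str
    description: Optional[str] = None
    camera_make: Optional[str] = None
    camera_model: Optional[str] = None
    exposure: Optional[str] = None
    taken_at: Optional[str] = None

    def __post_init__(self) -> None:
        _nonempty(self.picture_id, "picture_id")


@dataclass(frozen=True)
class PictureFile:
    picture_id: str
    locator: str
    file_type: str
    size_bytes: Optional[int] = None

    def __post_init__(self) -> None:
        _nonempty(self.locator, "locator")


@dataclass(frozen=True)
class PlotPictureLink:
    picture_id: str
    plot_key: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "plot_key", tuple(self.plot_key))


@dataclass(frozen=True)
class AccessionPictureLink:
    picture_id: str
    accession_key: tuple[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "accession_key", tuple(self.accession_key))


# ---------------------------------------------------------------------------
# observation validation


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)


def validate_observation(obs, meth: Methodology) -> ValidationReport:
    """Validate a raw observation against its methodology.

    ``obs`` may be a :class:`RawObservation` or a plain mapping of its value
    fields (the form spreadsheet rows take before construction). The report
    is empty iff: at least one value field is set; the field implied by the
    method type is set; score values occur in the scoring key; percentages
    lie in [0, 100]. Extra populated fields are allowed -- more than one
    data type may apply to an observation.
    """
    if not isinstance(meth, Methodology):
        raise ReferenceError_("meth must be a Methodology")
    report = ValidationReport()

    if isinstance(obs, dict):
        get = obs.get
    else:
        get = lambda f: getattr(obs, f)  # noqa: E731

    populated = [f for f in VALUE_FIELDS if get(f) is not None]
    if not populated:
        report.add("no value field populated")

    implied = value_field_for(meth.method.method_type)
    if get(implied) is None:
        report.add(
            f"method type {meth.method.method_type!r} requires field {implied!r}, which is empty"
        )

    key = meth.method.scoring_key
    if key is not None:
        text = get("value_score_text")
        if text is not None:
            codes = {c.lower() for c in key.codes}
            if str(text).lower() not in codes:
                report.add(f"text score {text!r} not in scoring key {key.key_id!r}")
        numeric = get("value_score_numeric")
        if numeric is not None and meth.method.method_type == "numeric_score":
            numeric_codes = set()
            for c in key.codes:
                try:
                    numeric_codes.add(float(c))
                except ValueError:
                    pass
            if numeric_codes and float(numeric) not in numeric_codes:
                report.add(f"numeric score {numeric} not in scoring key {key.key_id!r}")

    percent = get("value_percent")
    if percent is not None and not (0.0 <= float(percent) <= 100.0):
        report.add(f"value_percent {percent} outside [0, 100]")

    count = get("value_count")
    if count is not None and (float(count) < 0 or float(count) != int(float(count))):
        report.add(f"value_count {count} is not a non-negative integer")

    return report
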