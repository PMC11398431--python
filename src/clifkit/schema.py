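"""CLIF entity-relationship model, controlled vocabularies, and conformance checks.

The Common Longitudinal ICU data Format (CLIF) organises critical-care EHR
data into longitudinal tables linked by ``patient_id`` and
``hospitalization_id``. Every standardized concept column carries the
``_category`` suffix and a controlled vocabulary of permissible values
(the minimum Common ICU Data Elements), and is paired with a sibling
``_name`` column that preserves the raw label used by the source EHR.
Site-level harmonization therefore never destroys information: the raw
``_name`` stays, the ``_category`` makes it comparable across sites.

This module defines the table registry, the vocabularies, typed loading of
Parquet/CSV table files, name-to-category mapping, a rule-based validator,
and the per-site cohort summary used in federated aggregation.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .federate import SiteSummary

logger = logging.getLogger(__name__)

TABLE_FILE_PREFIX = "clif_"

#: Timezone every datetime column is normalised to on load.
TIMEZONE = "UTC"


# ---------------------------------------------------------------------------
# Exceptions
# ---------------------------------------------------------------------------

class ClifError(Exception):
    """Base class for errors raised by clifkit."""


class UnknownTableError(ClifError):
    """A table name is not present in the schema registry."""


class MissingColumnError(ClifError):
    """A required column is absent from a table file."""


class CoercionError(ClifError):
    """Type coercion failed for more than the tolerated fraction of rows."""


class VocabularyError(ClifError):
    """A controlled vocabulary is internally inconsistent or mismatched."""


class ConfigError(ClifError):
    """A configuration object references unknown elements."""


# ---------------------------------------------------------------------------
# Controlled vocabularies (mCIDE)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryVocabulary:
    """Permissible values of one ``_category`` data element.

    Parameters
    ----------
    element:
        Name of the category column, e.g. ``"lab_category"``.
    permitted:
        Permissible category values. Stored lower-cased; membership tests
        are case-insensitive.
    mapping:
        Site-specific raw-name -> category pairs used to populate the
        ``_category`` column from the source ``_name`` column.
    """

    element: str
    permitted: frozenset
    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = frozenset(str(v).strip().lower() for v in self.permitted)
        object.__setattr__(self, "permitted", norm)
        cleaned = {}
        for name, cat in dict(self.mapping).items():
            cat_l = str(cat).strip().lower()
            if cat_l not in norm:
                raise VocabularyError(
                    f"{self.element}: mapping target {cat!r} for {name!r} "
                    f"is not a permissible value"
                )
            cleaned[str(name).strip().lower()] = cat_l
        object.__setattr__(self, "mapping", cleaned)

    @property
    def name_column(self) -> str:
        return self.element.replace("_category", "_name")

    def is_permitted(self, value: object) -> bool:
        return str(value).strip().lower() in self.permitted

    def map_name(self, name: object) -> Optional[str]:
        """Category for a raw source name, or ``None`` when unmapped."""
        if name is None or (isinstance(name, float) and np.isnan(name)):
            return None
        return self.mapping.get(str(name).strip().lower())


def load_vocabularies(path) -> dict:
    """Load vocabularies from a JSON/YAML config of the form
    ``{element: {"permitted": [...], "mapping": {name: category, ...}}}``.
    Elements absent from the file fall back to the defaults."""
    import json

    import yaml
    text = Path(path).read_text()
    payload = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
        else json.loads(text)
    vocab = default_vocabularies()
    for element, spec in payload.items():
        vocab[element] = CategoryVocabulary(
            element=element,
            permitted=frozenset(spec.get("permitted", ())),
            mapping=spec.get("mapping", {}),
        )
    return vocab


def default_vocabularies() -> dict:
    """Vocabularies for the data elements the case-study tables use.

    Category strings are lower_snake_case; comparison is case-insensitive.
    Sites extend these with their own ``_name`` -> ``_category`` mappings.
    """
    vocab = {
        "sex_category": {"male", "female", "unknown"},
        "race_category": {"asian", "black", "white", "other", "unknown"},
        "ethnicity_category": {"hispanic", "non_hispanic", "unknown"},
        "discharge_category": {
            "home", "expired", "hospice", "snf", "ltach", "acute_rehab",
            "acute_care_hospital", "against_medical_advice", "other",
        },
        "location_category": {"icu", "ward", "ed", "procedural", "stepdown", "other"},
        "vital_category": {
            "temp_c", "temp_f", "heart_rate", "sbp", "dbp", "map_mmhg",
            "resp_rate", "spo2", "weight_kg", "height_cm",
        },
        "lab_category": {
            "albumin", "ast", "alt", "hemoglobin", "creatinine", "wbc",
            "lactate", "sodium", "potassium", "bilirubin_total",
            "platelet_count", "glucose",
        },
        "device_category": {
            "imv", "nippv", "high_flow_nc", "nasal_cannula", "face_mask",
            "trach_collar", "room_air", "other",
        },
        "mode_category": {
            "assist_control_volume", "simv", "pressure_support",
            "pressure_control", "cpap", "other",
        },
        "med_category": {
            "norepinephrine", "epinephrine", "vasopressin", "phenylephrine",
            "propofol", "fentanyl", "midazolam", "dexmedetomidine", "other",
        },
        "assessment_category": {"gcs_total", "rass", "cam_icu", "braden", "other"},
    }
    return {el: CategoryVocabulary(el, frozenset(vals)) for el, vals in vocab.items()}


# ---------------------------------------------------------------------------
# Table schemas
# ---------------------------------------------------------------------------

#: semantic types a column may declare
SEMANTIC_TYPES = ("id", "datetime", "numeric", "category", "free_text")


@dataclass(frozen=True)
class ColumnSpec:
    """Declared name, semantic type and vocabulary binding of one column."""

    name: str
    semantic_type: str
    required: bool = True
    unit: Optional[str] = None
    vocabulary: Optional[str] = None  # element name, only for _category columns

    def __post_init__(self) -> None:
        if self.semantic_type not in SEMANTIC_TYPES:
            raise ConfigError(f"unknown semantic type {self.semantic_type!r}")
        if self.name.endswith("_category") and self.vocabulary is None:
            # minimal tables may carry unconstrained category columns, but
            # the fully specified ones must bind a vocabulary
            pass


@dataclass(frozen=True)
class TableSchema:
    """Schema of one CLIF table: columns, keys and foreign-key links."""

    table_name: str
    columns: tuple
    keys: tuple = ()           # columns unique within the table
    links: tuple = ()          # foreign keys: "patient_id", "hospitalization_id"
    monotonic: tuple = ()      # (earlier_col, later_col) datetime ordering rules

    def __post_init__(self) -> None:
        names = {c.name for c in self.columns}
        for col in self.columns:
            if col.name.endswith("_category"):
                sibling = col.name.replace("_category", "_name")
                if sibling not in names:
                    raise ConfigError(
                        f"{self.table_name}.{col.name} lacks sibling column {sibling}"
                    )

    @property
    def column_names(self) -> tuple:
        return tuple(c.name for c in self.columns)

    @property
    def required_columns(self) -> tuple:
        return tuple(c.name for c in self.columns if c.required)

    def column(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)


def _minimal_schema(table_name: str, prefix: str, link: str = "hospitalization_id") -> TableSchema:
    """Keys + timestamp + a ``_name``/``_category`` pair; used for tables whose
    full column lists the case studies do not touch."""
    return TableSchema(
        table_name=table_name,
        columns=(
            ColumnSpec(link, "id"),
            ColumnSpec(f"{prefix}_dttm", "datetime", required=False),
            ColumnSpec(f"{prefix}_name", "free_text", required=False),
            ColumnSpec(f"{prefix}_category", "category", required=False),
        ),
        links=(link,),
    )


def build_default_registry() -> dict:
    """The CLIF table registry.

    The entity-relationship model names 23 table slots; "Respiratory
    Support" occupies two of them, leaving 22 unique tables, all present
    here. The tables the cohort-discovery, mortality-model and
    temperature-trajectory analyses read get fully specified columns; the
    remainder get minimal schemas (keys, a timestamp, and a name/category
    pair) and can be extended by sites.
    """
    registry: dict = {}

    registry["patient"] = TableSchema(
        "patient",
        columns=(
            ColumnSpec("patient_id", "id"),
            ColumnSpec("sex_name", "free_text", required=False),
            ColumnSpec("sex_category", "category", vocabulary="sex_category"),
            ColumnSpec("race_name", "free_text", required=False),
            ColumnSpec("race_category", "category", vocabulary="race_category"),
            ColumnSpec("ethnicity_name", "free_text", required=False),
            ColumnSpec("ethnicity_category", "category", vocabulary="ethnicity_category"),
        ),
        keys=("patient_id",),
    )
    registry["hospitalization"] = TableSchema(
        "hospitalization",
        columns=(
            ColumnSpec("hospitalization_id", "id"),
            ColumnSpec("patient_id", "id"),
            ColumnSpec("admission_dttm", "datetime"),
            ColumnSpec("discharge_dttm", "datetime"),
            ColumnSpec("age_at_admission", "numeric", unit="years"),
            ColumnSpec("discharge_name", "free_text", required=False),
            ColumnSpec("discharge_category", "category", vocabulary="discharge_category"),
        ),
        keys=("hospitalization_id",),
        links=("patient_id",),
        monotonic=(("admission_dttm", "discharge_dttm"),),
    )
    registry["adt"] = TableSchema(
        "adt",
        columns=(
            ColumnSpec("hospitalization_id", "id"),
            ColumnSpec("hospital_id", "id"),
            ColumnSpec("in_dttm", "datetime"),
            ColumnSpec("out_dttm", "datetime"),
            ColumnSpec("location_name", "free_text", required=False),
            ColumnSpec("location_category", "category", vocabulary="location_category"),
        ),
        links=("hospitalization_id",),
        monotonic=(("in_dttm", "out_dttm"),),
    )
    registry["vitals"] = TableSchema(
        "vitals",
        columns=(
            ColumnSpec("hospitalization_id", "id"),
            ColumnSpec("recorded_dttm", "datetime"),
            ColumnSpec("vital_name", "free_text", required=False),
            ColumnSpec("vital_category", "category", vocabulary="vital_category"),
            ColumnSpec("vital_value", "numeric"),
        ),
        links=("hospitalization_id",),
    )
    registry["labs"] = TableSchema(
        "labs",
        columns=(
            ColumnSpec("hospitalization_id", "id"),
            ColumnSpec("lab_result_dttm", "datetime"),
            ColumnSpec("lab_name", "free_text", required=False),
            ColumnSpec("lab_category", "category", vocabulary="lab_category"),
            ColumnSpec("lab_value", "numeric"),
        ),
        links=("hospitalization_id",),
    )
    registry["respiratory_support"] = TableSchema(
        "respiratory_support",
        columns=(
            ColumnSpec("hospitalization_id", "id"),
            ColumnSpec("recorded_dttm", "datetime"),
            ColumnSpec("device_name", "free_text", required=False),
            ColumnSpec("device_category", "category", vocabulary="device_category"),
            ColumnSpec("mode_name", "free_text", required=False),
            ColumnSpec("mode_category", "category", required=False, vocabulary="mode_category"),
            ColumnSpec("fio2_set", "numeric", required=False),
        ),
        links=("hospitalization_id",),
    )
    registry["medication_admin_continuous"] = TableSchema(
        "medication_admin_continuous",
        columns=(
            ColumnSpec("hospitalization_id", "id"),
            ColumnSpec("admin_dttm", "datetime"),
            ColumnSpec("med_name", "free_text", required=False),
            ColumnSpec("med_category", "category", vocabulary="med_category"),
            ColumnSpec("med_dose", "numeric", required=False),
            ColumnSpec("med_dose_unit", "free_text", required=False),
        ),
        links=("hospitalization_id",),
    )
    registry["scores"] = TableSchema(
        "scores",
        columns=(
            ColumnSpec("hospitalization_id", "id"),
            ColumnSpec("recorded_dttm", "datetime"),
            ColumnSpec("assessment_name", "free_text", required=False),
            ColumnSpec("assessment_category", "category", vocabulary="assessment_category"),
            ColumnSpec("numerical_value", "numeric", required=False),
        ),
        links=("hospitalization_id",),
    )

    for name, prefix in [
        ("admission_diagnosis", "diagnosis"),
        ("provider", "provider"),
        ("dialysis", "dialysis"),
        ("intake_output", "fluid"),
        ("procedures", "procedure"),
        ("therapy_session", "therapy_session"),
        ("therapy_details", "therapy_detail"),
        ("position", "position"),
        ("ecmo_mcs", "ecmo"),
        ("microbiology_culture", "organism"),
        ("sensitivity", "antibiotic"),
        ("microbiology_nonculture", "micro_nonculture"),
        ("medication_orders", "med_order"),
        ("medication_admin_intermittent", "med_intermittent"),
    ]:
        registry[name] = _minimal_schema(name, prefix)

    return registry


#: tables the validator requires for a usable dataset
REQUIRED_TABLES = ("patient", "hospitalization", "adt", "vitals", "labs")


# ---------------------------------------------------------------------------
# Dataset container and IO
# ---------------------------------------------------------------------------

@dataclass
class ClifDataset:
    """A named collection of CLIF tables for one site.

    ``tables`` maps registry table names to pandas DataFrames. All datetime
    columns are timezone-aware UTC.
    """

    tables: dict
    site_label: str = "site"

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.tables

    def copy(self) -> "ClifDataset":
        return ClifDataset({k: v.copy() for k, v in self.tables.items()}, self.site_label)

    def write(self, directory, fmt: str = "parquet") -> None:
        """Write tables as ``clif_<name>.parquet`` (or ``.csv``, RFC 4180
        UTF-8 with ISO-8601 datetimes)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            path = directory / f"{TABLE_FILE_PREFIX}{name}.{fmt}"
            if fmt == "parquet":
                df.to_parquet(path, index=False)
            elif fmt == "csv":
                df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S%z")
            else:
                raise ValueError(f"unsupported format {fmt!r}")


def _coerce_columns(df: pd.DataFrame, schema: TableSchema,
                    tolerance: float) -> pd.DataFrame:
    """Coerce columns to their declared semantic types.

    Unparseable datetimes/numerics become missing and are counted; when the
    failure fraction of any column exceeds ``tolerance`` a
    :class:`CoercionError` is raised instead of silently degrading.
    """
    out = df.copy()
    for col in schema.columns:
        if col.name not in out.columns:
            continue
        series = out[col.name]
        if col.semantic_type == "datetime":
            coerced = pd.to_datetime(series, errors="coerce", utc=True, format="ISO8601")
        elif col.semantic_type == "numeric":
            coerced = pd.to_numeric(series, errors="coerce")
        else:
            if col.semantic_type in ("id", "category", "free_text"):
                out[col.name] = series.astype("object").where(series.notna(), None)
            continue
        n_new_na = int((coerced.isna() & series.notna()).sum())
        if len(series) and n_new_na / len(series) > tolerance:
            raise CoercionError(
                f"{schema.table_name}.{col.name}: {n_new_na}/{len(series)} values "
                f"failed {col.semantic_type} coercion (tolerance {tolerance})"
            )
        if n_new_na:
            logger.warning("%s.%s: %d values failed coercion and are now missing",
                           schema.table_name, col.name, n_new_na)
        out[col.name] = coerced
    return out


def load_clif_table(path, table_name: str, registry: Optional[dict] = None,
                    coercion_tolerance: float = 0.01) -> pd.DataFrame:
    """Load one CLIF table from Parquet or CSV and coerce declared types.

    Raises :class:`UnknownTableError` for unregistered names,
    :class:`MissingColumnError` when a required column is absent, and
    :class:`CoercionError` when type coercion fails for more than
    ``coercion_tolerance`` of a column's rows.
    """
    registry = registry or build_default_registry()
    if table_name not in registry:
        raise UnknownTableError(
            f"{table_name!r} is not a registered CLIF table; known tables: "
            f"{sorted(registry)}"
        )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    elif path.suffix == ".csv":
        df = pd.read_csv(path)
    else:
        raise ValueError(f"unsupported file type {path.suffix!r}")
    schema = registry[table_name]
    missing = [c for c in schema.required_columns if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"{table_name}: required column(s) missing: {missing}"
        )
    return _coerce_columns(df, schema, coercion_tolerance)


def read_dataset(directory, registry: Optional[dict] = None,
                 site_label: Optional[str] = None) -> ClifDataset:
    """Load every ``clif_*.parquet`` / ``clif_*.csv`` file in a directory."""
    registry = registry or build_default_registry()
    directory = Path(directory)
    tables = {}
    for path in sorted(directory.glob(f"{TABLE_FILE_PREFIX}*")):
        if path.suffix not in (".parquet", ".csv"):
            continue
        name = path.stem[len(TABLE_FILE_PREFIX):]
        if name not in registry:
            raise UnknownTableError(f"file {path.name} does not match a registered table")
        tables[name] = load_clif_table(path, name, registry)
    if not tables:
        raise FileNotFoundError(f"no {TABLE_FILE_PREFIX}* table files in {directory}")
    return ClifDataset(tables, site_label or directory.name)


# ---------------------------------------------------------------------------
# Name -> category mapping
# ---------------------------------------------------------------------------

@dataclass
class MappingResult:
    """Outcome of applying a vocabulary mapping to one table."""

    table: pd.DataFrame
    n_mapped: int
    n_unmapped: int


def apply_category_mapping(table: pd.DataFrame,
                           vocabulary: CategoryVocabulary) -> MappingResult:
    """Populate a ``_category`` column from its ``_name`` sibling.

    Rows whose (case-insensitive) name appears in ``vocabulary.mapping``
    receive the mapped category; unmapped names leave the category missing
    and are counted. ``_name`` values are never altered. The operation is
    idempotent.
    """
    cat_col = vocabulary.element
    name_col = vocabulary.name_column
    if cat_col not in table.columns or name_col not in table.columns:
        raise VocabularyError(
            f"table lacks {cat_col!r}/{name_col!r} columns for element "
            f"{vocabulary.element!r}"
        )
    out = table.copy()
    if len(out) == 0:
        return MappingResult(out, 0, 0)
    mapped = out[name_col].map(vocabulary.map_name)
    has_name = out[name_col].notna()
    n_mapped = int(mapped.notna().sum())
    n_unmapped = int((has_name & mapped.isna()).sum())
    out[cat_col] = mapped.where(mapped.notna(), None)
    return MappingResult(out, n_mapped, n_unmapped)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    table: str
    row: Optional[int]          # positional row locator, None for table-level rules
    column: Optional[str]
    rule: str
    message: str


@dataclass
class ValidationReport:
    """Violations found by :func:`validate_dataset`; data, not exceptions."""

    violations: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return len(self.violations) == 0

    @property
    def counts(self) -> Counter:
        return Counter(v.rule for v in self.violations)

    def count(self, rule: str) -> int:
        return self.counts.get(rule, 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.table, v.row, v.column, v.rule, v.message) for v in self.violations],
            columns=["table", "row", "column", "rule", "message"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "pass": self.passed,
            "counts": dict(self.counts),
            "violations": [
                {"table": v.table, "row": v.row, "column": v.column,
                 "rule": v.rule, "message": v.message}
                for v in self.violations
            ],
        }
        if path is not None:
            import json
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


# rule identifiers
RULE_REQUIRED_TABLE = "required_table"
RULE_REQUIRED_COLUMN = "required_column"
RULE_DTYPE = "dtype"
RULE_PERMITTED_VALUE = "permitted_value"
RULE_KEY_UNIQUE = "key_unique"
RULE_REFERENTIAL = "referential_integrity"
RULE_DATETIME_ORDER = "datetime_order"


def validate_dataset(dataset: ClifDataset, registry: Optional[dict] = None,
                     vocabularies: Optional[dict] = None) -> ValidationReport:
    """Check a dataset against the registry and vocabularies.

    Rules: required tables present; required columns present; declared
    dtypes; category values within permitted sets; key uniqueness;
    referential integrity against patient and hospitalization; and declared
    datetime orderings (e.g. ADT out >= in). Violations are returned as
    data — validation itself never raises.
    """
    registry = registry or build_default_registry()
    vocabularies = vocabularies if vocabularies is not None else default_vocabularies()
    report = ValidationReport()
    add = report.violations.append

    for name in REQUIRED_TABLES:
        if name not in dataset.tables:
            add(Violation(name, None, None, RULE_REQUIRED_TABLE,
                          f"required table {name!r} is missing"))

    known_patients = None
    known_hosp = None
    if "patient" in dataset and "patient_id" in dataset["patient"].columns:
        known_patients = set(dataset["patient"]["patient_id"].dropna())
    if "hospitalization" in dataset and "hospitalization_id" in dataset["hospitalization"].columns:
        known_hosp = set(dataset["hospitalization"]["hospitalization_id"].dropna())

    for name, df in dataset.tables.items():
        schema = registry.get(name)
        if schema is None:
            add(Violation(name, None, None, RULE_REQUIRED_TABLE,
                          f"table {name!r} is not registered"))
            continue

        present = set(df.columns)
        for col in schema.required_columns:
            if col not in present:
                add(Violation(name, None, col, RULE_REQUIRED_COLUMN,
                              f"required column {col!r} missing"))

        for col in schema.columns:
            if col.name not in present:
                continue
            s = df[col.name]
            if col.semantic_type == "datetime":
                if not (pd.api.types.is_datetime64_any_dtype(s) and s.dt.tz is not None):
                    add(Violation(name, None, col.name, RULE_DTYPE,
                                  "expected timezone-aware datetime column"))
            elif col.semantic_type == "numeric":
                if not pd.api.types.is_numeric_dtype(s):
                    add(Violation(name, None, col.name, RULE_DTYPE,
                                  "expected numeric column"))

        # permitted values
        for col in schema.columns:
            if col.vocabulary is None or col.name not in present:
                continue
            vocab = vocabularies.get(col.vocabulary)
            if vocab is None:
                continue
            values = df[col.name]
            bad = values.notna() & ~values.astype(str).str.strip().str.lower().isin(vocab.permitted)
            for pos in np.flatnonzero(bad.to_numpy()):
                add(Violation(name, int(pos), col.name, RULE_PERMITTED_VALUE,
                              f"value {values.iloc[pos]!r} not in permitted set of "
                              f"{col.vocabulary}"))

        # key uniqueness and non-nullness
        for key in schema.keys:
            if key not in present:
                continue
            s = df[key]
            for pos in np.flatnonzero(s.isna().to_numpy()):
                add(Violation(name, int(pos), key, RULE_KEY_UNIQUE,
                              "key value is null"))
            dup = s.duplicated(keep="first") & s.notna()
            for pos in np.flatnonzero(dup.to_numpy()):
                add(Violation(name, int(pos), key, RULE_KEY_UNIQUE,
                              f"duplicate key value {s.iloc[pos]!r}"))

        # referential integrity
        if "patient_id" in schema.links and known_patients is not None \
                and "patient_id" in present:
            s = df["patient_id"]
            orphan = s.notna() & ~s.isin(known_patients)
            for pos in np.flatnonzero(orphan.to_numpy()):
                add(Violation(name, int(pos), "patient_id", RULE_REFERENTIAL,
                              f"patient_id {s.iloc[pos]!r} not found in patient"))
        if "hospitalization_id" in schema.links and known_hosp is not None \
                and "hospitalization_id" in present:
            s = df["hospitalization_id"]
            orphan = s.notna() & ~s.isin(known_hosp)
            for pos in np.flatnonzero(orphan.to_numpy()):
                add(Violation(name, int(pos), "hospitalization_id", RULE_REFERENTIAL,
                              f"hospitalization_id {s.iloc[pos]!r} not found in "
                              f"hospitalization"))

        # declared datetime orderings
        for earlier, later in schema.monotonic:
            if earlier not in present or later not in present:
                continue
            a, b = df[earlier], df[later]
            if not (pd.api.types.is_datetime64_any_dtype(a)
                    and pd.api.types.is_datetime64_any_dtype(b)):
                continue
            bad = a.notna() & b.notna() & (b < a)
            for pos in np.flatnonzero(bad.to_numpy()):
                add(Violation(name, int(pos), later, RULE_DATETIME_ORDER,
                              f"{later} precedes {earlier}"))

    return report


# ---------------------------------------------------------------------------
# Per-site cohort summary
# ---------------------------------------------------------------------------

def dataset_summary(dataset: ClifDataset, cohort) -> SiteSummary:
    """Table-one style per-site summary over a cohort of encounters.

    ``cohort`` is an iterable of hospitalization ids or a DataFrame with a
    ``hospitalization_id`` column. Counts use the dataset tables:
    in-hospital death is ``discharge_category == "expired"`` and invasive
    mechanical ventilation is any respiratory-support row with
    ``device_category == "imv"``.
    """
    if isinstance(cohort, pd.DataFrame):
        ids = cohort["hospitalization_id"]
    else:
        ids = pd.Series(list(cohort))
    ids = pd.Index(ids.dropna().unique())
    if len(ids) == 0:
        raise ValueError("cohort is empty")

    hosp = dataset["hospitalization"]
    hosp = hosp[hosp["hospitalization_id"].isin(ids)]
    patient = dataset["patient"]
    merged = hosp.merge(patient, on="patient_id", how="left")

    age = pd.to_numeric(merged["age_at_admission"], errors="coerce")
    deaths = int((merged["discharge_category"].astype(str).str.lower() == "expired").sum())
    female = int((merged["sex_category"].astype(str).str.lower() == "female").sum())

    race = Counter(merged["race_category"].dropna().astype(str).str.lower())
    ethnicity = Counter(merged["ethnicity_category"].dropna().astype(str).str.lower())

    imv = 0
    if "respiratory_support" in dataset:
        rs = dataset["respiratory_support"]
        imv_rows = rs[(rs["device_category"].astype(str).str.lower() == "imv")
                      & rs["hospitalization_id"].isin(ids)]
        imv = int(imv_rows["hospitalization_id"].nunique())

    hospitals = 0
    if "adt" in dataset and "hospital_id" in dataset["adt"].columns:
        adt = dataset["adt"]
        hospitals = int(adt.loc[adt["hospitalization_id"].isin(ids), "hospital_id"].nunique())

    return SiteSummary(
        site=dataset.site_label,
        encounters=int(len(merged)),
        hospitals=hospitals,
        age_mean=float(age.mean()),
        age_sd=float(age.std(ddof=1)) if len(age.dropna()) > 1 else 0.0,
        female=female,
        race=dict(sorted(race.items())),
        ethnicity=dict(sorted(ethnicity.items())),
        imv=imv,
        deaths=deaths,
    )
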