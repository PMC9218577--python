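"""Tabular data model for multi-facility task-based exposure studies.

One air sample is one :class:`ExposureRecord`: a concentration in ppb (or a
left-censoring bound at the per-sample limit of detection), identifiers for
facility and worker, a task label, and a mapping of determinant values.
Determinants (covariates hypothesised to modify exposure) are described by
:class:`DeterminantSpec` objects that carry the encoding metadata: categorical
determinants expand to reference-coded 0/1 indicators, continuous ones enter
on their raw scale (a ``unit_scale`` multiplier is applied only when effects
are reported as percent changes).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ANALYTES = ("diacetyl", "pentanedione_23")
SAMPLE_TYPES = ("task", "instant_activity", "instant_source")

#: The ten short-term task categories of the coffee-production study design.
TASKS = (
    "roasting",
    "grinding",
    "packaging",
    "qc",
    "flavoring",
    "cleaning_machines",
    "moving_beans",
    "misc_production",
    "misc_cafe",
    "maintenance",
)

#: Task-group filters used by the task-specific models. ``overall`` keeps all
#: task samples; the named groups keep a single task category.
TASK_GROUPS = {
    "overall": None,
    "roasting": {"roasting"},
    "grinding": {"grinding"},
    "packaging": {"packaging"},
    "qc": {"qc"},
    "flavoring": {"flavoring"},
}


class SchemaError(ValueError):
    """A file or record violates the study schema."""


class ValidationError(ValueError):
    """A dataset-level invariant is violated."""


@dataclass
class ExposureRecord:
    """One air sample.

    ``censored=True`` means the measurement fell below the per-sample limit
    of detection: ``concentration_ppb`` is absent and ``lod_ppb`` is the
    left-censoring bound.
    """

    sample_id: str
    facility_id: str
    analyte: str
    lod_ppb: float
    censored: bool
    duration_min: float
    task: str
    concentration_ppb: float | None = None
    subject_id: str | None = None
    sample_type: str = "task"
    determinants: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.analyte not in ANALYTES:
            raise SchemaError(f"sample {self.sample_id!r}: unknown analyte {self.analyte!r}")
        if self.sample_type not in SAMPLE_TYPES:
            raise SchemaError(
                f"sample {self.sample_id!r}: unknown sample_type {self.sample_type!r}"
            )
        if not (self.lod_ppb > 0):
            raise SchemaError(f"sample {self.sample_id!r}: lod_ppb must be positive")
        if self.censored:
            if self.concentration_ppb is not None:
                raise SchemaError(
                    f"sample {self.sample_id!r}: censored record must not carry a concentration"
                )
        else:
            if self.concentration_ppb is None:
                raise SchemaError(
                    f"sample {self.sample_id!r}: uncensored record lacks both "
                    "concentration_ppb and a censored flag"
                )
            if not (self.concentration_ppb > 0):
                raise SchemaError(f"sample {self.sample_id!r}: concentration_ppb must be > 0")
        if self.sample_type == "task" and not (self.duration_min > 0):
            raise SchemaError(f"sample {self.sample_id!r}: duration_min must be > 0")

    @property
    def log_bound(self) -> float:
        """ln of the observed concentration, or of the LOD when censored."""
        return math.log(self.lod_ppb if self.censored else self.concentration_ppb)


@dataclass
class DeterminantSpec:
    """Metadata for one determinant (covariate).

    ``level`` distinguishes sample-level determinants (vary sample to sample)
    from process-level ones (constant within a facility). ``nested_within``
    declares determinants this one is a subset of; nested pairs are barred
    from entering the same regression model.
    """

    name: str
    level: str  # "sample" | "process"
    kind: str  # "categorical" | "continuous"
    reference: str | None = None
    categories: tuple | None = None
    unit_scale: float = 1.0
    nested_within: tuple = ()
    applicable_tasks: tuple | None = None
    group: str = ""  # editorial grouping used in report tables

    def __post_init__(self):
        if self.level not in ("sample", "process"):
            raise SchemaError(f"determinant {self.name!r}: level must be sample|process")
        if self.kind not in ("categorical", "continuous"):
            raise SchemaError(f"determinant {self.name!r}: kind must be categorical|continuous")
        if self.kind == "categorical":
            if not self.categories or len(self.categories) < 2:
                raise SchemaError(f"determinant {self.name!r}: needs >=2 categories")
            self.categories = tuple(str(c) for c in self.categories)
            if self.reference is None:
                raise SchemaError(f"determinant {self.name!r}: categorical needs a reference")
            self.reference = str(self.reference)
            if self.reference not in self.categories:
                raise SchemaError(
                    f"determinant {self.name!r}: reference {self.reference!r} "
                    f"not among categories {self.categories}"
                )
            self.unit_scale = 1.0
        else:
            if not (self.unit_scale > 0):
                raise SchemaError(f"determinant {self.name!r}: unit_scale must be > 0")
        self.nested_within = tuple(self.nested_within or ())

    def column_name(self, category: str | None = None) -> str:
        return self.name if category is None else f"{self.name}[{category}]"


@dataclass
class StudyDataset:
    """All records of one study plus the determinant dictionary."""

    records: list
    determinants: list
    analyte: str

    def __post_init__(self):
        self.validate()

    def spec(self, name: str) -> DeterminantSpec:
        for spec in self.determinants:
            if spec.name == name:
                return spec
        raise KeyError(f"unknown determinant {name!r}")

    def validate(self) -> None:
        spec_by_name = {s.name: s for s in self.determinants}
        process_values: dict = {}
        for rec in self.records:
            for name, value in rec.determinants.items():
                spec = spec_by_name.get(name)
                if spec is None:
                    raise ValidationError(
                        f"sample {rec.sample_id!r}: value for undeclared determinant {name!r}"
                    )
                if spec.kind == "categorical" and value is not None:
                    if str(value) not in spec.categories:
                        raise ValidationError(
                            f"sample {rec.sample_id!r}: determinant {name!r} has "
                            f"unseen category {value!r}"
                        )
                if spec.level == "process" and value is not None:
                    key = (rec.facility_id, name)
                    if key in process_values and process_values[key] != value:
                        raise ValidationError(
                            f"process-level determinant {name!r} varies within "
                            f"facility {rec.facility_id!r} "
                            f"({process_values[key]!r} vs {value!r})"
                        )
                    process_values[key] = value

    def task_records(self, task_filter: str | set | None = "overall") -> list:
        """Task samples of this dataset's analyte passing a task-group filter."""
        if isinstance(task_filter, str):
            if task_filter not in TASK_GROUPS:
                raise KeyError(
                    f"unknown task group {task_filter!r}; expected one of {sorted(TASK_GROUPS)} "
                    "or an explicit set of task labels"
                )
            keep = TASK_GROUPS[task_filter]
        else:
            keep = task_filter
        out = []
        for rec in self.records:
            if rec.sample_type != "task" or rec.analyte != self.analyte:
                continue
            if keep is not None and rec.task not in keep:
                continue
            out.append(rec)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "sample_id": r.sample_id,
                "facility_id": r.facility_id,
                "subject_id": r.subject_id,
                "analyte": r.analyte,
                "concentration_ppb": r.concentration_ppb,
                "lod_ppb": r.lod_ppb,
                "censored": int(r.censored),
                "duration_min": r.duration_min,
                "task": r.task,
                "sample_type": r.sample_type,
            }
            row.update(r.determinants)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class DesignMatrix:
    """Row-aligned response, censoring bounds and predictor columns.

    ``response`` holds ln(concentration) for uncensored rows and ln(LOD) for
    censored rows (the latter is the left-censoring bound, also exposed as
    ``bound``). ``block_map`` maps each selected determinant to the predictor
    columns it contributed.
    """

    response: np.ndarray
    bound: np.ndarray
    censored: np.ndarray
    X: np.ndarray
    columns: list
    subject_index: np.ndarray
    subject_labels: list
    block_map: dict
    record_ids: list
    task_filter: object = "overall"

    @property
    def n(self) -> int:
        return len(self.response)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def n_repeat_subjects(self) -> int:
        """Number of subjects contributing >=2 rows."""
        counts = np.bincount(self.subject_index, minlength=len(self.subject_labels))
        return int((counts >= 2).sum())


def encode_determinant(spec: DeterminantSpec, values) -> pd.DataFrame:
    """Expand one determinant into named predictor columns.

    Categorical: one 0/1 indicator per non-reference category *observed in
    the data*, in the spec's declared category order. Continuous: a single
    column of raw values (``unit_scale`` is not applied here). Rows with a
    missing value get NaN in every produced column.
    """
    values = pd.Series(list(values))
    if spec.kind == "continuous":
        col = pd.to_numeric(values, errors="coerce")
        return pd.DataFrame({spec.column_name(): col.to_numpy(dtype=float)})

    missing = values.isna()
    strvals = values.astype("object").where(missing, values.astype(str))
    seen = set(strvals[~missing])
    unknown = seen - set(spec.categories)
    if unknown:
        raise ValidationError(
            f"determinant {spec.name!r}: unseen categories {sorted(unknown)!r}"
        )
    cols = {}
    for cat in spec.categories:
        if cat == spec.reference or cat not in seen:
            continue
        ind = (strvals == cat).astype(float)
        ind[missing] = np.nan
        cols[spec.column_name(cat)] = ind.to_numpy(dtype=float)
    if not cols:
        warnings.warn(
            f"determinant {spec.name!r} is degenerate here (only the reference "
            "category observed); it contributes no columns",
            UserWarning,
            stacklevel=2,
        )
        return pd.DataFrame(index=range(len(values)))
    return pd.DataFrame(cols)


def build_design_matrix(
    dataset: StudyDataset,
    selected,
    task_filter="overall",
) -> DesignMatrix:
    """Assemble the regression design for the selected determinants.

    Rows are the analyte's task samples passing ``task_filter``; columns are
    an intercept plus the encoding of each selected determinant. Rows with a
    missing value for any selected determinant are dropped (logged);
    determinants that become degenerate after filtering contribute no
    columns (warned).
    """
    records = dataset.task_records(task_filter)
    if not records:
        raise ValidationError(f"no rows left after task filter {task_filter!r}")

    frames = [pd.DataFrame({"intercept": np.ones(len(records))})]
    block_map: dict = {"intercept": ["intercept"]}
    for name in selected:
        spec = dataset.spec(name)
        vals = [rec.determinants.get(name) for rec in records]
        enc = encode_determinant(spec, vals)
        block_map[name] = list(enc.columns)
        if len(enc.columns):
            frames.append(enc)
    X = pd.concat(frames, axis=1)

    keep = ~X.isna().any(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "dropping %d rows with missing values for selected determinants", n_dropped
        )
    records = [r for r, k in zip(records, keep) if k]
    if not records:
        raise ValidationError("all rows dropped due to missing determinant values")
    X = X.loc[keep]

    # drop columns that became constant after row filtering (degenerate)
    degenerate = [c for c in X.columns if c != "intercept" and X[c].nunique() <= 1]
    if degenerate:
        warnings.warn(
            f"dropping degenerate predictor columns after filtering: {degenerate}",
            UserWarning,
            stacklevel=2,
        )
        X = X.drop(columns=degenerate)
        block_map = {
            det: [c for c in cols if c not in degenerate] for det, cols in block_map.items()
        }

    subj_labels: list = []
    subj_pos: dict = {}
    subject_index = np.empty(len(records), dtype=int)
    for i, rec in enumerate(records):
        sid = rec.subject_id if rec.subject_id is not None else f"__anon_{rec.sample_id}"
        if sid not in subj_pos:
            subj_pos[sid] = len(subj_labels)
            subj_labels.append(sid)
        subject_index[i] = subj_pos[sid]

    response = np.array([r.log_bound for r in records])
    bound = np.log([r.lod_ppb for r in records])
    censored = np.array([r.censored for r in records], dtype=bool)
    return DesignMatrix(
        response=response,
        bound=bound,
        censored=censored,
        X=X.to_numpy(dtype=float),
        columns=list(X.columns),
        subject_index=subject_index,
        subject_labels=subj_labels,
        block_map=block_map,
        record_ids=[r.sample_id for r in records],
        task_filter=task_filter,
    )


# ---------------------------------------------------------------------------
# File I/O

_SAMPLE_COLUMNS = [
    "sample_id",
    "facility_id",
    "subject_id",
    "analyte",
    "concentration_ppb",
    "lod_ppb",
    "censored",
    "duration_min",
    "task",
    "sample_type",
]


def load_determinants(path) -> list:
    """Read a determinant dictionary (YAML list of spec mappings)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise SchemaError(f"{path}: determinant dictionary must be a YAML list")
    specs = []
    for i, entry in enumerate(raw):
        try:
            specs.append(
                DeterminantSpec(
                    name=entry["name"],
                    level=entry["level"],
                    kind=entry["kind"],
                    reference=entry.get("reference"),
                    categories=tuple(entry["categories"]) if entry.get("categories") else None,
                    unit_scale=float(entry.get("unit_scale", 1.0)),
                    nested_within=tuple(entry.get("nested_within", []) or []),
                    applicable_tasks=(
                        tuple(entry["applicable_tasks"]) if entry.get("applicable_tasks") else None
                    ),
                    group=entry.get("group", ""),
                )
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"{path}: entry {i}: {exc}") from exc
    return specs


def load_dataset(samples_path, determinants_path, analyte, facilities_path=None) -> StudyDataset:
    """Load and validate a study from samples.csv + determinants.yaml.

    Process-level determinant values may be supplied in a separate
    facilities.csv keyed by ``facility_id``; they are merged onto every record
    of that facility.
    """
    if analyte not in ANALYTES:
        raise SchemaError(f"unknown analyte {analyte!r}")
    specs = load_determinants(determinants_path)
    spec_by_name = {s.name: s for s in specs}

    df = pd.read_csv(samples_path, dtype={"sample_id": str, "facility_id": str, "subject_id": str})
    missing_cols = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{samples_path}: missing columns {missing_cols}")

    facility_vals: dict = {}
    if facilities_path is not None:
        fac = pd.read_csv(facilities_path, dtype={"facility_id": str})
        if "facility_id" not in fac.columns:
            raise SchemaError(f"{facilities_path}: missing facility_id column")
        for _, row in fac.iterrows():
            vals = {
                k: row[k]
                for k in fac.columns
                if k != "facility_id" and k in spec_by_name and pd.notna(row[k])
            }
            facility_vals[row["facility_id"]] = vals

    sample_level = [
        s.name for s in specs if s.level == "sample" and s.name in df.columns
    ]
    records = []
    for idx, row in df.iterrows():
        try:
            censored = bool(int(row["censored"]))
            conc = row["concentration_ppb"]
            conc = None if (censored or pd.isna(conc)) else float(conc)
            if pd.isna(row["lod_ppb"]) and conc is None:
                raise SchemaError("both concentration_ppb and lod_ppb are missing")
            dets = {}
            for name in sample_level:
                v = row[name]
                dets[name] = None if pd.isna(v) else v
            dets.update(facility_vals.get(row["facility_id"], {}))
            records.append(
                ExposureRecord(
                    sample_id=str(row["sample_id"]),
                    facility_id=str(row["facility_id"]),
                    subject_id=None if pd.isna(row["subject_id"]) else str(row["subject_id"]),
                    analyte=str(row["analyte"]),
                    concentration_ppb=conc,
                    lod_ppb=float(row["lod_ppb"]),
                    censored=censored,
                    duration_min=float(row["duration_min"]),
                    task=str(row["task"]),
                    sample_type=str(row["sample_type"]),
                    determinants=dets,
                )
            )
        except (SchemaError, ValueError) as exc:
            raise SchemaError(f"{samples_path}: row {idx} ({row.get('sample_id')}): {exc}") from exc

    return StudyDataset(records=records, determinants=specs, analyte=analyte)


def write_samples_csv(dataset: StudyDataset, path) -> None:
    df = dataset.to_frame()
    sample_cols = [s.name for s in dataset.determinants if s.level == "sample"]
    cols = _SAMPLE_COLUMNS + [c for c in sample_cols if c in df.columns]
    df[cols].to_csv(path, index=False)


def write_facilities_csv(dataset: StudyDataset, path) -> None:
    rows: dict = {}
    process = [s.name for s in dataset.determinants if s.level == "process"]
    for rec in dataset.records:
        row = rows.setdefault(rec.facility_id, {"facility_id": rec.facility_id})
        for name in process:
            if name in rec.determinants and rec.determinants[name] is not None:
                row[name] = rec.determinants[name]
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["facility_id"]))
    df.to_csv(path, index=False)


def write_determinants_yaml(specs, path) -> None:
    out = []
    for s in specs:
        entry = {"name": s.name, "level": s.level, "kind": s.kind, "group": s.group}
        if s.kind == "categorical":
            entry["reference"] = s.reference
            entry["categories"] = list(s.categories)
        else:
            entry["unit_scale"] = float(s.unit_scale)
        if s.nested_within:
            entry["nested_within"] = list(s.nested_within)
        if s.applicable_tasks:
            entry["applicable_tasks"] = list(s.applicable_tasks)
        out.append(entry)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
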