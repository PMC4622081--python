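"""Core data types and tabular/report I/O.

A dataset is a :class:`PatientTable`: one row per patient, a right-censored
survival outcome (time in days + event indicator) and a set of raw predictor
variables, each described by a :class:`VariableSpec` carrying its kind
(continuous or categorical), its ordered levels (categorical only, first
level = reference) and a free-form group label such as ``"clinicopathological"``
or ``"proteomic"``.  Modelling code consumes the reference-coded
:class:`DesignMatrix` produced by :func:`encode`.

CSV conventions: comma-separated, UTF-8, header row required, ``.`` decimal
separator.  The variable schema travels in a YAML (or JSON) sidecar, see
:func:`read_schema` / :func:`write_schema`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored time-to-event outcome (PFS-like or OS-like).

    Parameters
    ----------
    time:
        Positive follow-up times in days.
    event:
        1 if the event (progression / death) was observed, 0 if the
        patient was right-censored at ``time``.
    """

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        object.__setattr__(self, "time", time)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValidationError("time and event must be 1-d arrays of equal length")
        if not np.all(np.isfinite(time)):
            raise ValidationError("survival times must be finite")
        bad = np.flatnonzero(time <= 0)
        if bad.size:
            raise ValidationError(f"non-positive survival time at row {bad[0]}")
        if not np.isin(event, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")
        object.__setattr__(self, "event", event.astype(np.int8))

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one predictor variable."""

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    group: str = ""

    def __post_init__(self):
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise SchemaError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == CATEGORICAL:
            if self.levels is None or len(self.levels) < 2:
                raise SchemaError(f"categorical variable {self.name!r} needs >= 2 levels")
            object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        elif self.levels is not None:
            raise SchemaError(f"continuous variable {self.name!r} must not declare levels")


@dataclass(frozen=True)
class PatientTable:
    """Patient-indexed predictor table plus outcome.

    ``values`` holds raw (pre-encoding) values: floats for continuous
    variables, level labels for categorical ones.
    """

    patient_ids: tuple[str, ...]
    outcome: SurvivalOutcome
    variables: tuple[VariableSpec, ...]
    values: pd.DataFrame

    def __post_init__(self):
        ids = tuple(str(i) for i in self.patient_ids)
        object.__setattr__(self, "patient_ids", ids)
        object.__setattr__(self, "variables", tuple(self.variables))
        if len(set(ids)) != len(ids):
            raise ValidationError("patient identifiers must be unique")
        if len(self.outcome) != len(ids):
            raise ValidationError("outcome length does not match number of patients")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("variable names must be unique")
        if list(self.values.columns) != names:
            raise SchemaError("values columns must match schema variable names, in order")
        if len(self.values) != len(ids):
            raise ValidationError("values row count does not match number of patients")
        for spec in self.variables:
            col = self.values[spec.name]
            if col.isna().any():
                row = int(np.flatnonzero(col.isna().to_numpy())[0])
                raise ValidationError(f"missing value for {spec.name!r} at row {row}")
            if spec.kind == CATEGORICAL:
                known = set(spec.levels)
                bad = ~col.astype(str).isin(known)
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    raise ValidationError(
                        f"unknown level {col.iloc[row]!r} for {spec.name!r} at row {row}"
                    )
            else:
                arr = pd.to_numeric(col, errors="coerce")
                if arr.isna().any():
                    row = int(np.flatnonzero(arr.isna().to_numpy())[0])
                    raise ValidationError(
                        f"non-numeric value for continuous {spec.name!r} at row {row}"
                    )

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def variable(self, name: str) -> VariableSpec:
        for spec in self.variables:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for spec in self.variables:
            if spec.group not in seen:
                seen.append(spec.group)
        return tuple(seen)

    def group_variables(self, group: str) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.group == group)

    def subset(self, names: Sequence[str]) -> "PatientTable":
        """Restrict to the given variables (table order preserved)."""
        keep = [v for v in self.variables if v.name in set(names)]
        missing = set(names) - {v.name for v in keep}
        if missing:
            raise SchemaError(f"unknown variables: {sorted(missing)}")
        return PatientTable(
            patient_ids=self.patient_ids,
            outcome=self.outcome,
            variables=tuple(keep),
            values=self.values[[v.name for v in keep]].copy(),
        )

    def with_values(self, values: pd.DataFrame) -> "PatientTable":
        return PatientTable(self.patient_ids, self.outcome, self.variables, values)


@dataclass(frozen=True)
class DesignMatrix:
    """Reference-coded numeric design matrix (patients x columns).

    Each categorical variable with L declared levels expands to L-1
    indicator columns, the first declared level being the dropped
    reference.  ``mapping`` sends each design column to its source
    variable name; ``degenerate_columns`` flags indicator columns that
    are identically zero because a declared level never occurs.
    """

    column_names: tuple[str, ...]
    matrix: np.ndarray
    mapping: Mapping[str, str]
    degenerate_columns: tuple[str, ...] = ()

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def columns_of(self, variable: str) -> list[int]:
        return [i for i, c in enumerate(self.column_names) if self.mapping[c] == variable]


def encode(table: PatientTable) -> DesignMatrix:
    """Expand a :class:`PatientTable` into a reference-coded design matrix.

    Continuous variables are copied unchanged; a categorical variable with
    levels ``(ref, l2, ..., lL)`` contributes indicator columns
    ``name[l2] ... name[lL]``.  Column order is deterministic: table order,
    then declared level order.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    mapping: dict[str, str] = {}
    degenerate: list[str] = []
    for spec in table.variables:
        col = table.values[spec.name]
        if spec.kind == CONTINUOUS:
            names.append(spec.name)
            mapping[spec.name] = spec.name
            cols.append(col.to_numpy(dtype=float))
        else:
            labels = col.astype(str).to_numpy()
            for level in spec.levels[1:]:
                cname = f"{spec.name}[{level}]"
                indicator = (labels == level).astype(float)
                if indicator.sum() == 0:
                    degenerate.append(cname)
                names.append(cname)
                mapping[cname] = spec.name
                cols.append(indicator)
    matrix = np.column_stack(cols) if cols else np.empty((table.n_patients, 0))
    return DesignMatrix(tuple(names), matrix, mapping, tuple(degenerate))


# ---------------------------------------------------------------------------
# CSV + schema sidecar I/O


def read_schema(path: str | Path) -> tuple[list[VariableSpec], tuple[str, str]]:
    """Read a YAML/JSON schema sidecar.

    Returns the variable specs (in declared order) and the pair of outcome
    column names ``(time_column, event_column)``.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    try:
        out = doc["outcome"]
        outcome_columns = (str(out["time"]), str(out["event"]))
        specs = [
            VariableSpec(
                name=str(v["name"]),
                kind=str(v["kind"]),
                levels=tuple(v["levels"]) if v.get("levels") else None,
                group=str(v.get("group", "")),
            )
            for v in doc["variables"]
        ]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed schema file {path}: {exc}") from exc
    return specs, outcome_columns


def write_schema(
    specs: Sequence[VariableSpec],
    outcome_columns: tuple[str, str],
    path: str | Path,
) -> None:
    doc = {
        "outcome": {"time": outcome_columns[0], "event": outcome_columns[1]},
        "variables": [
            {
                "name": s.name,
                "kind": s.kind,
                **({"levels": list(s.levels)} if s.levels else {}),
                "group": s.group,
            }
            for s in specs
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_patient_table(
    path: str | Path,
    schema: Sequence[VariableSpec],
    outcome_columns: tuple[str, str] = ("time", "event"),
    id_column: str = "patient_id",
) -> PatientTable:
    """Load and validate a patient CSV against a declared schema."""
    df = pd.read_csv(path, float_precision="round_trip")
    tcol, ecol = outcome_columns
    for col in (tcol, ecol):
        if col not in df.columns:
            raise SchemaError(f"outcome column {col!r} missing from {path}")
    for spec in schema:
        if spec.name not in df.columns:
            raise SchemaError(f"variable column {spec.name!r} missing from {path}")
    if id_column in df.columns:
        ids = tuple(str(i) for i in df[id_column])
    else:
        ids = tuple(str(i) for i in range(len(df)))
    outcome = SurvivalOutcome(df[tcol].to_numpy(dtype=float), df[ecol].to_numpy())
    values = df[[s.name for s in schema]].copy()
    for spec in schema:
        if spec.kind == CATEGORICAL:
            values[spec.name] = values[spec.name].astype(str)
    values = values.reset_index(drop=True)
    return PatientTable(ids, outcome, tuple(schema), values)


def write_patient_table(
    table: PatientTable,
    path: str | Path,
    outcome_columns: tuple[str, str] = ("time", "event"),
    id_column: str = "patient_id",
) -> None:
    df = pd.DataFrame({id_column: list(table.patient_ids)})
    df[outcome_columns[0]] = table.outcome.time
    df[outcome_columns[1]] = table.outcome.event
    for spec in table.variables:
        df[spec.name] = table.values[spec.name].to_numpy()
    # %.17g guarantees bit-exact float round-trip through the CSV
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# JSON reports


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonify(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return {c: _jsonify(obj[c].to_numpy()) for c in obj.columns}
    return obj


def write_report(result: Any, path: str | Path) -> None:
    """Serialize any result dataclass (or dict of them) to a JSON report.

    Field order follows dataclass declaration order, so reports with the
    same content are byte-identical.
    """
    doc = _jsonify(result)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)
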