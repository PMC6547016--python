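"""Domain types and delimited-text I/O for ward vital-sign data.

The package revolves around three record types:

``ObservationSet``
    one timestamped set of ward vital signs plus the inhaled-gas
    information (delivery device, oxygen flow, prescribed FiO2) needed to
    estimate the inspired oxygen fraction.

``Admission``
    one hospital admission with demographics, the stay interval and the
    composite adverse-event outcome (in-hospital death or unplanned ICU
    admission) with its event time.

``LabeledObservation``
    an observation set annotated with the 24-hour look-back event label,
    the time to event in hours and the calculated FiO2.

FiO2 is held internally as a fraction in [0.21, 1.0]; conversion to the
percentages used in reports happens only at I/O and reporting boundaries.
Timestamps are timezone-naive local time throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "AVPU_LEVELS",
    "DEVICES",
    "FORMULA_DEVICES",
    "ObservationSet",
    "Admission",
    "LabeledObservation",
    "RowDiagnostic",
    "ReadResult",
    "SchemaError",
    "ValidationError",
    "read_observations",
    "write_observations",
    "read_admissions",
    "write_admissions",
    "load_schema_config",
]

AVPU_LEVELS = ("A", "V", "P", "U")

#: Oxygen-delivery categories understood by the default device table.
DEVICES = (
    "room_air",
    "nasal_cannula",
    "simple_mask",
    "reservoir_mask",
    "fixed_performance_mask",
    "high_flow_nasal",
    "niv",
)

#: Devices whose FiO2 comes from the dilution formula and therefore need a flow.
FORMULA_DEVICES = frozenset({"nasal_cannula", "simple_mask", "reservoir_mask"})

OUTCOMES = ("none", "death", "unplanned_icu")

ISO_FMT = "%Y-%m-%dT%H:%M:%S"


class SchemaError(ValueError):
    """The input file is structurally unusable (e.g. a mandatory column is absent)."""


class ValidationError(ValueError):
    """One or more rows violated a record invariant in strict mode."""

    def __init__(self, diagnostics: Sequence["RowDiagnostic"]):
        self.diagnostics = list(diagnostics)
        preview = "; ".join(str(d) for d in self.diagnostics[:5])
        more = "" if len(self.diagnostics) <= 5 else f" (+{len(self.diagnostics) - 5} more)"
        super().__init__(f"{len(self.diagnostics)} invalid row(s): {preview}{more}")


@dataclass(frozen=True)
class RowDiagnostic:
    """A located complaint about one input row."""

    row: int  # 0-based data-row index (header excluded)
    message: str
    severity: str = "error"  # "error" rejects the row, "warning" keeps it

    def __str__(self) -> str:  # pragma: no cover - formatting
        return f"row {self.row}: [{self.severity}] {self.message}"


@dataclass(frozen=True)
class ObservationSet:
    """One complete simultaneous recording of vital signs and inhaled gas."""

    admission_id: str
    timestamp: datetime
    hr: float
    rr: float
    sbp: float
    spo2: float
    temp: float
    avpu: str | None = None
    gcs: int | None = None
    device: str = "room_air"
    o2_flow_lpm: float | None = None
    prescribed_fio2: float | None = None

    def invariant_errors(self) -> list[str]:
        """Return every violated record invariant (empty list means valid)."""
        errs: list[str] = []
        if not 0 <= self.spo2 <= 100:
            errs.append(f"spo2 {self.spo2} outside [0, 100]")
        for name, value in (("rr", self.rr), ("hr", self.hr), ("sbp", self.sbp)):
            if not value > 0:
                errs.append(f"{name} {value} must be > 0")
        if self.avpu is None and self.gcs is None:
            errs.append("both avpu and gcs absent")
        if self.avpu is not None and self.avpu not in AVPU_LEVELS:
            errs.append(f"avpu {self.avpu!r} not one of {AVPU_LEVELS}")
        if self.gcs is not None and not 3 <= self.gcs <= 15:
            errs.append(f"gcs {self.gcs} outside [3, 15]")
        if self.device not in DEVICES:
            errs.append(f"unknown device {self.device!r}")
        elif self.device in FORMULA_DEVICES and self.o2_flow_lpm is None:
            errs.append(f"device {self.device} requires o2_flow_lpm")
        elif self.device == "fixed_performance_mask" and self.prescribed_fio2 is None:
            errs.append("fixed_performance_mask requires prescribed_fio2")
        if self.o2_flow_lpm is not None and self.o2_flow_lpm < 0:
            errs.append(f"o2_flow_lpm {self.o2_flow_lpm} must be >= 0")
        if self.prescribed_fio2 is not None and not 0.21 <= self.prescribed_fio2 <= 1.0:
            errs.append(f"prescribed_fio2 {self.prescribed_fio2} outside [0.21, 1.0]")
        return errs

    def validate(self) -> "ObservationSet":
        errs = self.invariant_errors()
        if errs:
            raise ValidationError([RowDiagnostic(-1, e) for e in errs])
        return self

    @property
    def on_room_air(self) -> bool:
        return self.device == "room_air"

    def is_complete(self) -> bool:
        """A complete set has every vital sign, a consciousness level and gas info."""
        core = (self.hr, self.rr, self.sbp, self.spo2, self.temp, self.device)
        if any(v is None or (isinstance(v, float) and pd.isna(v)) for v in core):
            return False
        if self.avpu is None and self.gcs is None:
            return False
        if self.device in FORMULA_DEVICES and self.o2_flow_lpm is None:
            return False
        if self.device == "fixed_performance_mask" and self.prescribed_fio2 is None:
            return False
        return True


@dataclass(frozen=True)
class Admission:
    """One hospital admission; repeat admissions are independent units."""

    admission_id: str
    patient_id: str
    age_years: int
    admit_time: datetime
    discharge_time: datetime
    outcome: str = "none"
    event_time: datetime | None = None
    planned_icu_before_ward: bool = False

    def invariant_errors(self) -> list[str]:
        errs: list[str] = []
        if self.age_years < 0:
            errs.append(f"age_years {self.age_years} negative")
        if self.outcome not in OUTCOMES:
            errs.append(f"outcome {self.outcome!r} not one of {OUTCOMES}")
        if not self.discharge_time > self.admit_time:
            errs.append("discharge_time must be after admit_time")
        if (self.outcome != "none") != (self.event_time is not None):
            errs.append("event_time required iff outcome != none")
        if self.event_time is not None and not (
            self.admit_time <= self.event_time <= self.discharge_time
        ):
            errs.append("event_time outside the stay interval")
        return errs

    def validate(self) -> "Admission":
        errs = self.invariant_errors()
        if errs:
            raise ValidationError([RowDiagnostic(-1, e) for e in errs])
        return self

    @property
    def has_event(self) -> bool:
        return self.outcome != "none"

    @property
    def stay_hours(self) -> float:
        return (self.discharge_time - self.admit_time).total_seconds() / 3600.0


@dataclass(frozen=True)
class LabeledObservation:
    """An observation set with its look-back event label and calculated FiO2.

    ``label`` is true iff the admission's adverse event occurred within the
    look-back window after the observation; ``time_to_event_h`` is then the
    positive gap in hours.
    """

    observation: ObservationSet
    label: bool
    calculated_fio2: float
    time_to_event_h: float | None = None

    def __post_init__(self) -> None:
        if self.label and self.time_to_event_h is None:
            raise ValueError("label=True requires time_to_event_h")
        if not self.label and self.time_to_event_h is not None:
            raise ValueError("label=False forbids time_to_event_h")
        if not 0.21 <= self.calculated_fio2 <= 1.0:
            raise ValueError(f"calculated_fio2 {self.calculated_fio2} outside [0.21, 1.0]")


@dataclass
class ReadResult:
    """Validated records plus the row-level diagnostics produced while reading."""

    records: list
    diagnostics: list[RowDiagnostic] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# --------------------------------------------------------------------------
# CSV schemas
# --------------------------------------------------------------------------

OBSERVATION_COLUMNS = [
    "admission_id",
    "timestamp",
    "hr",
    "rr",
    "sbp",
    "spo2",
    "temp",
    "avpu",
    "gcs",
    "device",
    "o2_flow_lpm",
    "prescribed_fio2",
]

ADMISSION_COLUMNS = [
    "admission_id",
    "patient_id",
    "age_years",
    "admit_time",
    "discharge_time",
    "outcome",
    "event_time",
    "planned_icu_before_ward",
]

_OBS_MANDATORY = {"admission_id", "timestamp", "hr", "rr", "sbp", "spo2", "temp", "device"}
_ADM_MANDATORY = {"admission_id", "patient_id", "age_years", "admit_time", "discharge_time"}


def load_schema_config(path: str | Path) -> dict[str, str]:
    """Load a field -> column-name mapping from a YAML configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise SchemaError(f"schema config {path} must be a mapping")
    return {str(k): str(v) for k, v in cfg.items()}


def _parse_dt(value, row: int, col: str) -> datetime:
    ts = pd.to_datetime(value, errors="coerce")
    if pd.isna(ts):
        raise ValueError(f"unparseable datetime {value!r} in column {col}")
    return ts.to_pydatetime()


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, str) and value.strip() == "") or pd.isna(value):
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or pd.isna(value) or str(value).strip() == "":
        return None
    return str(value).strip()


def _read_table(path: str | Path, schema_config: Mapping[str, str] | None,
                canonical: Sequence[str], mandatory: set[str]) -> pd.DataFrame:
    mapping = dict(schema_config or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in mapping.items()}
    df = df.rename(columns=rename)
    missing = mandatory - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    for col in canonical:
        if col not in df.columns:
            df[col] = ""
    return df[list(canonical)]


def read_observations(
    path: str | Path,
    schema_config: Mapping[str, str] | None = None,
    permissive: bool = False,
) -> ReadResult:
    """Read and validate observation sets from a CSV file.

    Every row either becomes a validated :class:`ObservationSet` or produces a
    located :class:`RowDiagnostic`. In strict mode (default) any rejected row
    raises :class:`ValidationError`; with ``permissive=True`` rejected rows are
    dropped but still reported in the result's diagnostics. Duplicate
    (admission_id, timestamp) pairs are kept and flagged with a warning.
    """
    df = _read_table(path, schema_config, OBSERVATION_COLUMNS, _OBS_MANDATORY)
    records: list[ObservationSet] = []
    diagnostics: list[RowDiagnostic] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            gcs = _opt_float(row.gcs)
            obs = ObservationSet(
                admission_id=str(row.admission_id),
                timestamp=_parse_dt(row.timestamp, i, "timestamp"),
                hr=float(row.hr),
                rr=float(row.rr),
                sbp=float(row.sbp),
                spo2=float(row.spo2),
                temp=float(row.temp),
                avpu=_opt_str(row.avpu),
                gcs=None if gcs is None else int(gcs),
                device=str(row.device).strip(),
                o2_flow_lpm=_opt_float(row.o2_flow_lpm),
                prescribed_fio2=_opt_float(row.prescribed_fio2),
            )
        except (ValueError, TypeError) as exc:
            diagnostics.append(RowDiagnostic(i, str(exc)))
            continue
        errs = obs.invariant_errors()
        if errs:
            diagnostics.append(RowDiagnostic(i, "; ".join(errs)))
        else:
            records.append(obs)

    seen: dict[tuple[str, datetime], int] = {}
    for i, obs in enumerate(records):
        key = (obs.admission_id, obs.timestamp)
        if key in seen:
            diagnostics.append(RowDiagnostic(
                i, f"duplicate timestamp for admission {obs.admission_id}; both kept",
                severity="warning",
            ))
        seen.setdefault(key, i)

    rejected = [d for d in diagnostics if d.severity == "error"]
    if rejected and not permissive:
        raise ValidationError(rejected)
    return ReadResult(records, diagnostics)


def write_observations(collection: Iterable[ObservationSet], path: str | Path) -> None:
    """Write observation sets with deterministic column order and ISO datetimes."""
    rows = []
    for obs in collection:
        rows.append({
            "admission_id": obs.admission_id,
            "timestamp": obs.timestamp.strftime(ISO_FMT),
            "hr": obs.hr,
            "rr": obs.rr,
            "sbp": obs.sbp,
            "spo2": obs.spo2,
            "temp": obs.temp,
            "avpu": obs.avpu if obs.avpu is not None else "",
            "gcs": obs.gcs if obs.gcs is not None else "",
            "device": obs.device,
            "o2_flow_lpm": obs.o2_flow_lpm if obs.o2_flow_lpm is not None else "",
            "prescribed_fio2": obs.prescribed_fio2 if obs.prescribed_fio2 is not None else "",
        })
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(path, index=False)


def read_admissions(
    path: str | Path,
    schema_config: Mapping[str, str] | None = None,
    permissive: bool = False,
) -> ReadResult:
    """Read and validate admissions from a CSV file (same contract as observations)."""
    df = _read_table(path, schema_config, ADMISSION_COLUMNS, _ADM_MANDATORY)
    records: list[Admission] = []
    diagnostics: list[RowDiagnostic] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            event_raw = _opt_str(row.event_time)
            adm = Admission(
                admission_id=str(row.admission_id),
                patient_id=str(row.patient_id),
                age_years=int(float(row.age_years)),
                admit_time=_parse_dt(row.admit_time, i, "admit_time"),
                discharge_time=_parse_dt(row.discharge_time, i, "discharge_time"),
                outcome=_opt_str(row.outcome) or "none",
                event_time=None if event_raw is None else _parse_dt(event_raw, i, "event_time"),
                planned_icu_before_ward=str(row.planned_icu_before_ward).strip().lower()
                in {"true", "1", "yes"},
            )
        except (ValueError, TypeError) as exc:
            diagnostics.append(RowDiagnostic(i, str(exc)))
            continue
        errs = adm.invariant_errors()
        if errs:
            diagnostics.append(RowDiagnostic(i, "; ".join(errs)))
        else:
            records.append(adm)
    rejected = [d for d in diagnostics if d.severity == "error"]
    if rejected and not permissive:
        raise ValidationError(rejected)
    return ReadResult(records, diagnostics)


def write_admissions(collection: Iterable[Admission], path: str | Path) -> None:
    rows = []
    for adm in collection:
        rows.append({
            "admission_id": adm.admission_id,
            "patient_id": adm.patient_id,
            "age_years": adm.age_years,
            "admit_time": adm.admit_time.strftime(ISO_FMT),
            "discharge_time": adm.discharge_time.strftime(ISO_FMT),
            "outcome": adm.outcome,
            "event_time": adm.event_time.strftime(ISO_FMT) if adm.event_time else "",
            "planned_icu_before_ward": adm.planned_icu_before_ward,
        })
    pd.DataFrame(rows, columns=ADMISSION_COLUMNS).to_csv(path, index=False)
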