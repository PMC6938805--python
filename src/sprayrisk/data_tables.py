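"""Three-table data model: substance database, crop interception table, scenario.

The model is driven by three delimited-text tables:

* ``compoundtab`` — one row per active ingredient: identity, chemical class
  and agricultural use (both optional, used as imputation donor keys), soil
  dissipation half-life DT50 [d], earthworm endpoints LC50 and NOEC
  [mg a.i./kg dry soil], and the organic-carbon-normalised Freundlich sorption
  coefficient Kfoc [L/kg].
* ``croptab`` — crop interception percentages keyed by crop and BBCH
  development-stage range.
* ``maintab`` — the application scenario: the spray series itself plus
  monthly temperatures, simulation horizon and the model constants.

``maintab`` uses a variables-as-rows layout: the first column names the
variable, subsequent columns hold one value per application for per-event
variables, and the first value column for scenario-level variables.  All
tables share one configurable CSV dialect (default: comma separator, ``.``
decimal, UTF-8, single header row for compoundtab/croptab).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .calendar365 import month_of_day
from .errors import ImputationError, ScenarioError, TableError

#: substance properties that participate in the missing-value routine
IMPUTABLE_FIELDS = ("degt50_soil", "lc50_earthworm", "noec_earthworm", "kfoc")

MixingDepthSpec = Union[float, str]  # fixed depth in metres, or the token "mix"
MIX_TOKEN = "mix"


@dataclass
class Dialect:
    """Delimited-text dialect shared by all three tables."""

    delimiter: str = ","
    decimal: str = "."
    encoding: str = "utf-8"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SubstanceRecord:
    """One compoundtab row: physicochemical + ecotoxicological properties.

    Numeric fields are ``None`` while missing; :func:`impute_missing` fills
    them from class/use donors before simulation.
    """

    compound_id: int
    name: str
    cas_nr: str = ""
    chemical_class: str | None = None
    chemical_use: str | None = None
    degt50_soil: float | None = None  # [d] at reference temperature
    lc50_earthworm: float | None = None  # [mg a.i./kg dw], acute endpoint
    noec_earthworm: float | None = None  # [mg a.i./kg dw], chronic endpoint
    kfoc: float | None = None  # [L/kg]

    def __post_init__(self) -> None:
        for f in ("degt50_soil", "lc50_earthworm", "noec_earthworm"):
            v = getattr(self, f)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise TableError(f"substance {self.name!r}: {f} must be > 0, got {v}")
        if self.kfoc is not None and (not math.isfinite(self.kfoc) or self.kfoc < 0):
            raise TableError(f"substance {self.name!r}: kfoc must be >= 0, got {self.kfoc}")

    def missing_fields(self, fields: Sequence[str] = IMPUTABLE_FIELDS) -> tuple[str, ...]:
        return tuple(f for f in fields if getattr(self, f) is None)

    def is_complete(self, fields: Sequence[str] = IMPUTABLE_FIELDS) -> bool:
        return not self.missing_fields(fields)


@dataclass
class CropInterceptionRow:
    """Interception percentage for one crop over one BBCH stage range."""

    crop_id: int
    crop_name: str
    bbch_min: int
    bbch_max: int
    interception_pct: float

    def __post_init__(self) -> None:
        if not (0 <= self.bbch_min <= self.bbch_max <= 99):
            raise TableError(
                f"crop {self.crop_id}: BBCH range [{self.bbch_min}, {self.bbch_max}] "
                "must satisfy 0 <= min <= max <= 99"
            )
        if not 0 <= self.interception_pct <= 100:
            raise TableError(
                f"crop {self.crop_id}: interception {self.interception_pct} outside [0, 100] %"
            )

    def covers(self, bbch: int) -> bool:
        return self.bbch_min <= bbch <= self.bbch_max


@dataclass
class ApplicationEvent:
    """One spray event of the series."""

    event_index: int
    compound_id: int
    compound_name: str
    application_day: int  # julian day, may exceed 365 for multi-year runs
    application_month: int
    rate_kg_ai_ha: float
    bbch: int
    degradation_factor: float = 1.0  # 1 = use compoundtab half-life unchanged
    mixing_depth_spec: MixingDepthSpec = MIX_TOKEN  # metres, or "mix"

    def __post_init__(self) -> None:
        if self.application_day < 1:
            raise ScenarioError(f"event {self.event_index}: application_day must be >= 1")
        if not 1 <= self.application_month <= 12:
            raise ScenarioError(f"event {self.event_index}: month {self.application_month} outside 1-12")
        if month_of_day(self.application_day) != self.application_month:
            raise ScenarioError(
                f"event {self.event_index}: application_day {self.application_day} falls in "
                f"month {month_of_day(self.application_day)} (non-leap calendar), "
                f"not the stated month {self.application_month}"
            )
        if self.rate_kg_ai_ha <= 0:
            raise ScenarioError(f"event {self.event_index}: rate must be > 0 kg a.i./ha")
        if not 0 <= self.bbch <= 99:
            raise ScenarioError(f"event {self.event_index}: BBCH {self.bbch} outside 0-99")
        if self.degradation_factor <= 0:
            raise ScenarioError(f"event {self.event_index}: degradation_factor must be > 0")
        if isinstance(self.mixing_depth_spec, str):
            if self.mixing_depth_spec != MIX_TOKEN:
                raise ScenarioError(
                    f"event {self.event_index}: mixing depth must be a depth in m or {MIX_TOKEN!r}"
                )
        elif self.mixing_depth_spec <= 0:
            raise ScenarioError(f"event {self.event_index}: fixed mixing depth must be > 0 m")


@dataclass
class Scenario:
    """Full maintab content: spray series + environment + model constants."""

    description: str
    crop_id: int
    events: list[ApplicationEvent]
    #: one 12-tuple of monthly mean temperatures [degC] per simulated year; a
    #: single set is recycled across years
    monthly_temperature: tuple[tuple[float, ...], ...]
    simulation_days: int
    bulk_density: float = 1.5  # [g/cm^3], dry soil
    reference_temperature: float = 20.0  # [degC], half-life reference
    activation_energy: float = 54000.0  # [J/mol]
    gas_constant: float = 8.314  # [J/(mol K)]
    ter_threshold_acute: float = 10.0
    ter_threshold_chronic: float = 5.0

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.application_day)
        for i, e in enumerate(self.events):  # chronological event indices
            e.event_index = i
        if not self.events:
            raise ScenarioError("scenario has no application events")
        last = max(e.application_day for e in self.events)
        if self.simulation_days < last:
            raise ScenarioError(
                f"simulation_days {self.simulation_days} < last application day {last}"
            )
        self.monthly_temperature = tuple(tuple(map(float, y)) for y in self.monthly_temperature)
        for y in self.monthly_temperature:
            if len(y) != 12:
                raise ScenarioError("each simulated year needs 12 monthly temperatures")
        if not self.monthly_temperature:
            raise ScenarioError("monthly temperatures missing")
        if self.bulk_density <= 0:
            raise ScenarioError("bulk density must be > 0 g/cm^3")

    def temperature(self, year_index: int, month: int) -> float:
        """Monthly mean temperature [degC]; a single year set is recycled."""
        years = self.monthly_temperature
        return years[min(year_index, len(years) - 1)][month - 1]


# ---------------------------------------------------------------------------
# compoundtab
# ---------------------------------------------------------------------------

_COMPOUND_COLUMNS = (
    "compound_id",
    "compound_name",
    "cas_nr",
    "chemical_class",
    "chemical_use",
    "degt50_soil",
    "lc50_earthworm",
    "noec_earthworm",
    "kfoc",
)
_COMPOUND_NUMERIC = ("degt50_soil", "lc50_earthworm", "noec_earthworm", "kfoc")


def _read_table(path: str | Path, dialect: Dialect) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableError(f"input table not found: {path}")
    return pd.read_csv(
        path, sep=dialect.delimiter, encoding=dialect.encoding, dtype=str,
        keep_default_na=False, skipinitialspace=True,
    )


def _parse_number(raw: str, *, table: str, row: int, column: str, dialect: Dialect) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw.replace(dialect.decimal, ".", 1) if dialect.decimal != "." else raw)
    except ValueError:
        raise TableError(
            f"{table}: non-numeric value {raw!r} in column {column!r}, data row {row}"
        ) from None


def load_compoundtab(path: str | Path, dialect: Dialect | None = None) -> list[SubstanceRecord]:
    """Read the substance database.

    Blank cells become missing values (imputed later); any non-numeric text in
    a numeric column is a hard error naming the cell.  ``compound_id`` must be
    unique and follow the row-position convention (first data row -> id 0).
    """
    dialect = dialect or Dialect()
    df = _read_table(path, dialect)
    missing_cols = set(_COMPOUND_COLUMNS) - set(df.columns)
    if missing_cols:
        raise TableError(f"compoundtab: missing columns {sorted(missing_cols)}")

    records: list[SubstanceRecord] = []
    seen: set[int] = set()
    for pos, (_, row) in enumerate(df.iterrows()):
        cid_raw = row["compound_id"].strip()
        try:
            cid = int(cid_raw)
        except ValueError:
            raise TableError(
                f"compoundtab: non-integer compound_id {cid_raw!r} in data row {pos + 1}"
            ) from None
        if cid in seen:
            raise TableError(f"compoundtab: duplicate compound_id {cid}")
        if cid != pos:
            raise TableError(
                f"compoundtab: compound_id {cid} in data row {pos + 1} violates the "
                f"row-position convention (expected row number minus one = {pos})"
            )
        seen.add(cid)
        numeric = {
            c: _parse_number(row[c], table="compoundtab", row=pos + 1, column=c, dialect=dialect)
            for c in _COMPOUND_NUMERIC
        }
        records.append(
            SubstanceRecord(
                compound_id=cid,
                name=row["compound_name"].strip(),
                cas_nr=row["cas_nr"].strip(),
                chemical_class=row["chemical_class"].strip() or None,
                chemical_use=row["chemical_use"].strip() or None,
                **numeric,
            )
        )
    return records


def write_compoundtab(records: Iterable[SubstanceRecord], path: str | Path,
                      dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    rows = []
    for r in records:
        rows.append({
            "compound_id": r.compound_id,
            "compound_name": r.name,
            "cas_nr": r.cas_nr,
            "chemical_class": r.chemical_class or "",
            "chemical_use": r.chemical_use or "",
            **{f: ("" if getattr(r, f) is None else repr(getattr(r, f))) for f in _COMPOUND_NUMERIC},
        })
    pd.DataFrame(rows, columns=list(_COMPOUND_COLUMNS)).to_csv(
        path, sep=dialect.delimiter, index=False, encoding=dialect.encoding
    )


# ---------------------------------------------------------------------------
# missing-value routine
# ---------------------------------------------------------------------------


def impute_missing(
    record: SubstanceRecord, db: Sequence[SubstanceRecord], field_name: str
) -> tuple[float, str]:
    """Fill one missing substance property from class/use donors.

    Returns ``(value, provenance)`` where provenance is ``"class-mean"`` or
    ``"use-mean"`` depending on which donor level fired, and updates the
    record in place.  Donors are all *other* records sharing the key that
    have the field present; the replacement is their arithmetic mean.
    """
    if field_name not in IMPUTABLE_FIELDS:
        raise ValueError(f"field {field_name!r} is not imputable")
    if getattr(record, field_name) is not None:
        raise ImputationError(
            f"{record.name}: {field_name} already present; nothing to impute"
        )
    for key, tag in (("chemical_class", "class-mean"), ("chemical_use", "use-mean")):
        group = getattr(record, key)
        if group is None:
            continue
        donors = [
            getattr(r, field_name)
            for r in db
            if r.compound_id != record.compound_id
            and getattr(r, key) == group
            and getattr(r, field_name) is not None
        ]
        if donors:
            value = sum(donors) / len(donors)
            setattr(record, field_name, value)
            return value, tag
    raise ImputationError(
        f"cannot impute {field_name} for {record.name!r}: no donor with the same "
        "chemical class or agricultural use has a value"
    )


def impute_for_scenario(
    db: Sequence[SubstanceRecord],
    scenario: Scenario,
    *,
    include_kfoc: bool = True,
) -> list[dict]:
    """Complete every substance the scenario references; return a provenance log.

    Kfoc participates by default because the variable-mixing-depth rule needs
    it; pass ``include_kfoc=False`` to restrict imputation to degradation and
    toxicity values.  Emits a warning (never an error) when a completed record
    has NOEC > LC50.
    """
    fields = IMPUTABLE_FIELDS if include_kfoc else IMPUTABLE_FIELDS[:3]
    by_id = {r.compound_id: r for r in db}
    log: list[dict] = []
    for cid in sorted({e.compound_id for e in scenario.events}):
        if cid not in by_id:
            raise ScenarioError(f"scenario references unknown compound_id {cid}")
        rec = by_id[cid]
        for f in rec.missing_fields(fields):
            value, tag = impute_missing(rec, db, f)
            log.append({"compound_id": cid, "compound_name": rec.name,
                        "field": f, "value": value, "provenance": tag})
        if (
            rec.noec_earthworm is not None
            and rec.lc50_earthworm is not None
            and rec.noec_earthworm > rec.lc50_earthworm
        ):
            warnings.warn(
                f"{rec.name}: NOEC ({rec.noec_earthworm}) exceeds LC50 "
                f"({rec.lc50_earthworm}); check the endpoint data",
                stacklevel=2,
            )
    return log


# ---------------------------------------------------------------------------
# croptab
# ---------------------------------------------------------------------------

_CROP_COLUMNS = ("crop_id", "crop_name", "bbch_min", "bbch_max", "interception_pct")


def load_croptab(path: str | Path, dialect: Dialect | None = None) -> list[CropInterceptionRow]:
    """Read the crop-interception table and check BBCH ranges do not overlap."""
    dialect = dialect or Dialect()
    df = _read_table(path, dialect)
    missing_cols = set(_CROP_COLUMNS) - set(df.columns)
    if missing_cols:
        raise TableError(f"croptab: missing columns {sorted(missing_cols)}")
    rows: list[CropInterceptionRow] = []
    for pos, (_, row) in enumerate(df.iterrows()):
        try:
            rows.append(
                CropInterceptionRow(
                    crop_id=int(row["crop_id"]),
                    crop_name=row["crop_name"].strip(),
                    bbch_min=int(row["bbch_min"]),
                    bbch_max=int(row["bbch_max"]),
                    interception_pct=float(row["interception_pct"]),
                )
            )
        except ValueError:
            raise TableError(f"croptab: malformed numeric value in data row {pos + 1}") from None
    by_crop: dict[int, list[CropInterceptionRow]] = {}
    for r in rows:
        by_crop.setdefault(r.crop_id, []).append(r)
    for cid, group in by_crop.items():
        group = sorted(group, key=lambda r: r.bbch_min)
        for a, b in zip(group, group[1:]):
            if b.bbch_min <= a.bbch_max:
                raise TableError(
                    f"croptab: crop {cid} has overlapping BBCH ranges "
                    f"[{a.bbch_min},{a.bbch_max}] and [{b.bbch_min},{b.bbch_max}]"
                )
    return rows


def write_croptab(rows: Iterable[CropInterceptionRow], path: str | Path,
                  dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    pd.DataFrame(
        [
            {"crop_id": r.crop_id, "crop_name": r.crop_name, "bbch_min": r.bbch_min,
             "bbch_max": r.bbch_max, "interception_pct": repr(r.interception_pct)}
            for r in rows
        ],
        columns=list(_CROP_COLUMNS),
    ).to_csv(path, sep=dialect.delimiter, index=False, encoding=dialect.encoding)


# ---------------------------------------------------------------------------
# maintab
# ---------------------------------------------------------------------------

# per-event variables: one value column per application
_EVENT_VARS = (
    "compound_name", "Com_ID", "application_month", "ApplicationRate_kgai_ha",
    "application_day", "BBCH", "degradation_factor", "mixing_depth_m",
)
_MONTH_VARS = tuple(
    f"TEMP_{m}" for m in ("JAN", "FEB", "MAR", "APR", "MAY", "JUN",
                          "JUL", "AUG", "SEP", "OCT", "NOV", "DEC")
)
# scenario-level variables with (attribute, parser); value in first value column
_SCALAR_VARS: Mapping[str, str] = {
    "description": "description",
    "numb_applications": "numb_applications",
    "crop_id": "crop_id",
    "days_of_year": "simulation_days",
    "bulk_density": "bulk_density",
    "reference_temperature": "reference_temperature",
    "activation_energy": "activation_energy",
    "gas_constant": "gas_constant",
    "ter_threshold_acute": "ter_threshold_acute",
    "ter_threshold_chronic": "ter_threshold_chronic",
}
_OPTIONAL_SCALARS = (
    "bulk_density", "reference_temperature", "activation_energy", "gas_constant",
    "ter_threshold_acute", "ter_threshold_chronic",
)


def load_maintab(
    path: str | Path,
    compound_db: Sequence[SubstanceRecord],
    crop_db: Sequence[CropInterceptionRow],
    dialect: Dialect | None = None,
) -> Scenario:
    """Read and cross-validate the scenario table.

    Checks performed: every cell of every per-event variable is filled for
    the declared number of applications; each ``Com_ID`` exists in the
    substance database and ``crop_id`` in the crop table; each application
    month matches the calendar month of its julian day (non-leap calendar);
    ``numb_applications`` equals the event count; the horizon covers every
    application day.  Monthly temperature rows may carry one value (recycled)
    or one value per simulated year.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    if not path.exists():
        raise TableError(f"input table not found: {path}")
    raw = pd.read_csv(
        path, sep=dialect.delimiter, encoding=dialect.encoding, dtype=str,
        keep_default_na=False, header=None, skipinitialspace=True,
    )
    table: dict[str, list[str]] = {}
    for _, row in raw.iterrows():
        key = row.iloc[0].strip()
        if not key:
            continue
        if key in table:
            raise TableError(f"maintab: duplicate variable row {key!r}")
        table[key] = [str(v).strip() for v in row.iloc[1:]]

    def cell(var: str, idx: int = 0, *, required: bool = True) -> str:
        if var not in table:
            if required:
                raise TableError(f"maintab: required variable row {var!r} is missing")
            return ""
        values = table[var]
        v = values[idx] if idx < len(values) else ""
        if required and v == "":
            raise TableError(f"maintab: cell ({var!r}, application {idx + 1}) is not filled in")
        return v

    def number(var: str, idx: int = 0) -> float:
        v = _parse_number(cell(var, idx), table="maintab", row=idx + 1,
                          column=var, dialect=dialect)
        assert v is not None  # cell() already rejected blanks
        return v

    n_apps = int(number("numb_applications"))
    crop_id = int(number("crop_id"))
    if crop_id not in {r.crop_id for r in crop_db}:
        raise TableError(f"maintab: crop_id {crop_id} not present in croptab")
    # how many event columns actually carry data?
    n_cols = max(
        (len([v for v in table.get(var, []) if v != ""]) for var in _EVENT_VARS),
        default=0,
    )
    if n_cols != n_apps:
        raise TableError(
            f"maintab: numb_applications = {n_apps} but {n_cols} application column(s) are filled"
        )

    known_ids = {r.compound_id for r in compound_db}
    events: list[ApplicationEvent] = []
    for i in range(n_apps):
        cid = int(number("Com_ID", i))
        if cid not in known_ids:
            raise TableError(f"maintab: application {i + 1} references unknown Com_ID {cid}")
        depth_raw = cell("mixing_depth_m", i)
        spec: MixingDepthSpec
        if depth_raw.lower() == MIX_TOKEN:
            spec = MIX_TOKEN
        else:
            spec = _parse_number(depth_raw, table="maintab", row=i + 1,
                                 column="mixing_depth_m", dialect=dialect)  # type: ignore[assignment]
        try:
            events.append(
                ApplicationEvent(
                    event_index=i,
                    compound_id=cid,
                    compound_name=cell("compound_name", i),
                    application_day=int(number("application_day", i)),
                    application_month=int(number("application_month", i)),
                    rate_kg_ai_ha=number("ApplicationRate_kgai_ha", i),
                    bbch=int(number("BBCH", i)),
                    degradation_factor=number("degradation_factor", i),
                    mixing_depth_spec=spec,
                )
            )
        except ScenarioError as exc:
            raise TableError(f"maintab: {exc}") from exc

    temp_columns = [
        [v for v in table.get(var, []) if v != ""] for var in _MONTH_VARS
    ]
    for var, vals in zip(_MONTH_VARS, temp_columns):
        if not vals:
            raise TableError(f"maintab: required variable row {var!r} is missing or empty")
    n_years = {len(v) for v in temp_columns}
    if len(n_years) != 1:
        raise TableError("maintab: TEMP_JAN-DEC rows must all carry the same number of years")
    years = n_years.pop()
    monthly = tuple(
        tuple(
            _parse_number(temp_columns[m][y], table="maintab", row=y + 1,
                          column=_MONTH_VARS[m], dialect=dialect)
            for m in range(12)
        )
        for y in range(years)
    )

    kwargs = {}
    for var in _OPTIONAL_SCALARS:
        v = cell(var, required=False)
        if v != "":
            kwargs[_SCALAR_VARS[var]] = float(
                _parse_number(v, table="maintab", row=1, column=var, dialect=dialect)
            )
    try:
        return Scenario(
            description=cell("description"),
            crop_id=crop_id,
            events=events,
            monthly_temperature=monthly,  # type: ignore[arg-type]
            simulation_days=int(number("days_of_year")),
            **kwargs,
        )
    except ScenarioError as exc:
        raise TableError(f"maintab: {exc}") from exc


def write_maintab(scenario: Scenario, path: str | Path, dialect: Dialect | None = None) -> None:
    """Write a scenario back to the maintab dialect (lossless round-trip)."""
    dialect = dialect or Dialect()
    n = len(scenario.events)
    width = max(n, len(scenario.monthly_temperature))

    def pad(values: list) -> list[str]:
        out = [str(v) for v in values]
        return out + [""] * (width - len(out))

    rows: list[list[str]] = [
        ["description", *pad([scenario.description])],
        ["numb_applications", *pad([n])],
        ["crop_id", *pad([scenario.crop_id])],
        ["days_of_year", *pad([scenario.simulation_days])],
        ["compound_name", *pad([e.compound_name for e in scenario.events])],
        ["Com_ID", *pad([e.compound_id for e in scenario.events])],
        ["application_month", *pad([e.application_month for e in scenario.events])],
        ["ApplicationRate_kgai_ha", *pad([repr(e.rate_kg_ai_ha) for e in scenario.events])],
        ["application_day", *pad([e.application_day for e in scenario.events])],
        ["BBCH", *pad([e.bbch for e in scenario.events])],
        ["degradation_factor", *pad([repr(e.degradation_factor) for e in scenario.events])],
        ["mixing_depth_m", *pad([
            e.mixing_depth_spec if isinstance(e.mixing_depth_spec, str)
            else repr(e.mixing_depth_spec)
            for e in scenario.events
        ])],
    ]
    for m, var in enumerate(_MONTH_VARS):
        rows.append([var, *pad([repr(y[m]) for y in scenario.monthly_temperature])])
    for var in _OPTIONAL_SCALARS:
        rows.append([var, *pad([repr(getattr(scenario, _SCALAR_VARS[var]))])])
    pd.DataFrame(rows).to_csv(
        path, sep=dialect.delimiter, index=False, header=False, encoding=dialect.encoding
    )
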