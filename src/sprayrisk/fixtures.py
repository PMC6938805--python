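"""Programmatic generation of self-consistent input-table trios.

Everything the simulator needs is synthesised here: a substance database, a
crop-interception table and a scenario table that always pass validation
(unless a corruption flag deliberately breaks one for negative tests),
written in the same CSV dialect the loaders read.  A ground-truth sidecar
accompanies each trio with the intended initial concentrations, the
per-month rate constants and the analytic concentration series computed via
the closed form c0 * exp(-sum k), so the daily simulation engine can be
checked against an independent path.

:func:`make_reference_apple_scenario` builds a six-application apple spray
series shaped like the published example output excerpt: four applications
of a fast-degrading fungicide and two of a slow one, with kinetics
back-solved from consecutive printed concentration values rather than
guessed from property databases.  All back-solved quantities are tagged
"inferred" in the sidecar.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .calendar365 import month_of_day, year_index_of_day
from .data_tables import (
    ApplicationEvent,
    CropInterceptionRow,
    Dialect,
    Scenario,
    SubstanceRecord,
    impute_for_scenario,
    write_compoundtab,
    write_croptab,
    write_maintab,
)
from .engine import event_piec
from .errors import ScenarioError
from .kinetics import CELSIUS_OFFSET

#: monthly mean air temperatures [degC] of a temperate north-German year
DEFAULT_MONTHLY_TEMPS = (0.5, 1.5, 5.0, 9.0, 13.5, 16.5, 18.5, 18.0, 14.5, 9.5, 4.5, 1.5)

_DEFAULT_CROPTAB = (
    CropInterceptionRow(1, "apple", 0, 9, 0.0),
    CropInterceptionRow(1, "apple", 10, 19, 20.0),
    CropInterceptionRow(1, "apple", 20, 39, 40.0),
    CropInterceptionRow(1, "apple", 40, 69, 60.0),
    CropInterceptionRow(1, "apple", 70, 99, 70.0),
)

CORRUPTIONS = ("month-mismatch", "count-mismatch", "unknown-compound", "blank-cell")


@dataclass
class FixtureSpec:
    """Knobs of the synthetic-table generator (defaults are the study conditions)."""

    n_substances: int = 3
    n_events: int = 6
    horizon_days: int = 365
    seed: int = 0
    dt50_range: tuple[float, float] = (5.0, 60.0)  # [d]
    kfoc_range: tuple[float, float] = (50.0, 1500.0)  # [L/kg]
    lc50_range: tuple[float, float] = (50.0, 1500.0)  # [mg/kg dw]
    noec_range: tuple[float, float] = (1.0, 50.0)  # [mg/kg dw]
    rate_range: tuple[float, float] = (0.2, 3.0)  # [kg a.i./ha]
    #: per-field probability of blanking a substance value (imputation path);
    #: a value is only dropped while a same-class donor still holds the field
    missing_prob: float | Mapping[str, float] = 0.0
    monthly_temperature: tuple[float, ...] = DEFAULT_MONTHLY_TEMPS
    corruption: str | None = None

    def missing_prob_for(self, field_name: str) -> float:
        if isinstance(self.missing_prob, Mapping):
            return float(self.missing_prob.get(field_name, 0.0))
        return float(self.missing_prob)


@dataclass
class FixturePaths:
    compoundtab: Path
    croptab: Path
    maintab: Path
    sidecar: Path
    scenario: Scenario = field(repr=False)
    compounds: list[SubstanceRecord] = field(repr=False)
    croptab_rows: list[CropInterceptionRow] = field(repr=False)


def _closed_form_series(
    piec_value: float,
    application_day: int,
    scenario: Scenario,
    dt50_soil: float,
    degradation_factor: float,
) -> tuple[list[float], dict[str, float]]:
    """Analytic per-event series via c0 * exp(-cumulative k), month by month."""
    ts = scenario.reference_temperature + CELSIUS_OFFSET
    ea_r = scenario.activation_energy / scenario.gas_constant

    def k_of(day: int) -> tuple[str, float]:
        month = month_of_day(day)
        year = min(year_index_of_day(day), len(scenario.monthly_temperature) - 1)
        t = scenario.monthly_temperature[year][month - 1] + CELSIUS_OFFSET
        dt50s = dt50_soil * degradation_factor * math.exp(ea_r * (1.0 / t - 1.0 / ts))
        return f"y{year + 1}m{month:02d}", math.log(2.0) / dt50s

    series = [0.0] * scenario.simulation_days
    k_by_month: dict[str, float] = {}
    cum_k = 0.0
    for day in range(application_day, scenario.simulation_days + 1):
        if day > application_day:
            key, k = k_of(day - 1)  # decay over day-1 brings us into `day`
            k_by_month.setdefault(key, k)
            cum_k += k
        series[day - 1] = piec_value * math.exp(-cum_k)
    return series, k_by_month


def make_fixture(spec: FixtureSpec, outdir: str | Path,
                 dialect: Dialect | None = None) -> FixturePaths:
    """Write a compoundtab/croptab/maintab trio plus its ground-truth sidecar.

    Identical specs (including the seed) produce byte-identical files.
    """
    if spec.corruption is not None and spec.corruption not in CORRUPTIONS:
        raise ValueError(f"unknown corruption flag {spec.corruption!r}")
    dialect = dialect or Dialect()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    classes = ("dithiocarbamate", "anilinopyrimidine", "triazole")
    uses = ("fungicide", "herbicide")
    compounds: list[SubstanceRecord] = []
    for i in range(spec.n_substances):
        compounds.append(
            SubstanceRecord(
                compound_id=i,
                name=f"substance_{i:02d}",
                cas_nr=f"{1000 + i}-00-{i}",
                chemical_class=classes[i % 2],  # two classes guarantee donors
                chemical_use=uses[i % len(uses)],
                degt50_soil=round(float(rng.uniform(*spec.dt50_range)), 6),
                lc50_earthworm=round(float(rng.uniform(*spec.lc50_range)), 6),
                noec_earthworm=round(float(rng.uniform(*spec.noec_range)), 6),
                kfoc=round(float(rng.uniform(*spec.kfoc_range)), 6),
            )
        )
    # blank values for the imputation path, never removing the last donor
    for field_name in ("degt50_soil", "lc50_earthworm", "noec_earthworm", "kfoc"):
        p = spec.missing_prob_for(field_name)
        if p <= 0:
            continue
        for rec in compounds:
            donors = [
                r for r in compounds
                if r is not rec and r.chemical_class == rec.chemical_class
                and getattr(r, field_name) is not None
            ]
            if donors and rng.random() < p:
                setattr(rec, field_name, None)

    croptab_rows = list(_DEFAULT_CROPTAB)

    first_day = 60
    last_day = min(spec.horizon_days, 300)
    if last_day < first_day:
        raise ScenarioError(
            f"horizon of {spec.horizon_days} d leaves no room for application days"
        )
    days = np.sort(rng.integers(first_day, last_day + 1, size=spec.n_events))
    events: list[ApplicationEvent] = []
    for i, day in enumerate(days):
        cid = int(rng.integers(0, spec.n_substances))
        events.append(
            ApplicationEvent(
                event_index=i,
                compound_id=cid,
                compound_name=compounds[cid].name,
                application_day=int(day),
                application_month=month_of_day(int(day)),
                rate_kg_ai_ha=round(float(rng.uniform(*spec.rate_range)), 6),
                bbch=int(rng.integers(0, 100)),
                degradation_factor=1.0,
                mixing_depth_spec="mix" if rng.random() < 0.7 else 0.05,
            )
        )
    scenario = Scenario(
        description=f"synthetic series seed {spec.seed}",
        crop_id=1,
        events=events,
        monthly_temperature=(tuple(spec.monthly_temperature),),
        simulation_days=spec.horizon_days,
    )

    # ground truth from completed (imputed) copies of the records
    completed = copy.deepcopy(compounds)
    impute_for_scenario(completed, scenario)
    by_id = {r.compound_id: r for r in completed}
    sidecar_events = []
    for col, ev in enumerate(scenario.events):
        sub = by_id[ev.compound_id]
        c0 = event_piec(scenario, ev, sub, croptab_rows)
        series, k_by_month = _closed_form_series(
            c0, ev.application_day, scenario, sub.degt50_soil, ev.degradation_factor
        )
        sidecar_events.append({
            "column": col,
            "compound_name": ev.compound_name,
            "application_day": ev.application_day,
            "piec": c0,
            "k_by_month": k_by_month,
            "series": series,
        })

    compound_path = outdir / "compoundtab.csv"
    crop_path = outdir / "croptab.csv"
    main_path = outdir / "maintab.csv"
    sidecar_path = outdir / "sidecar.json"
    write_compoundtab(compounds, compound_path, dialect)
    write_croptab(croptab_rows, crop_path, dialect)
    write_maintab(scenario, main_path, dialect)
    if spec.corruption is not None:
        _corrupt_maintab(main_path, spec.corruption, dialect)
    sidecar_path.write_text(
        json.dumps({"seed": spec.seed, "inferred": False, "events": sidecar_events})
        + "\n",
        encoding=dialect.encoding,
    )
    return FixturePaths(
        compoundtab=compound_path, croptab=crop_path, maintab=main_path,
        sidecar=sidecar_path, scenario=scenario, compounds=compounds,
        croptab_rows=croptab_rows,
    )


def _corrupt_maintab(path: Path, corruption: str, dialect: Dialect) -> None:
    """Deliberately break one cell so the loader's validation can be exercised."""
    lines = path.read_text(encoding=dialect.encoding).splitlines()
    out = []
    for line in lines:
        cells = line.split(dialect.delimiter)
        if corruption == "month-mismatch" and cells[0] == "application_month":
            cells[1] = str(1 + int(cells[1]) % 12)
        elif corruption == "count-mismatch" and cells[0] == "numb_applications":
            cells[1] = str(int(cells[1]) + 1)
        elif corruption == "unknown-compound" and cells[0] == "Com_ID":
            cells[1] = "999"
        elif corruption == "blank-cell" and cells[0] == "ApplicationRate_kgai_ha":
            cells[1] = ""
        out.append(dialect.delimiter.join(cells))
    path.write_text("\n".join(out) + "\n", encoding=dialect.encoding)


# ---------------------------------------------------------------------------
# published-excerpt-shaped apple scenario
# ---------------------------------------------------------------------------

#: consecutive printed concentrations [mg/kg] of the fast substance
#: (application day and day after) from which its kinetics are back-solved
FAST_PAIR = (5.33333333, 0.01952397)
#: same for the slow substance
SLOW_PAIR = (0.4, 0.39796516)


def inferred_dt50(pair: tuple[float, float]) -> float:
    """Half-life [d] implied by two consecutive daily concentrations."""
    c0, c1 = pair
    return math.log(2.0) / math.log(c0 / c1)


def make_reference_apple_scenario(
    second_slow_day: int = 120,
) -> tuple[Scenario, list[SubstanceRecord], list[CropInterceptionRow]]:
    """Six-application apple spray series mirroring the published PEC excerpt.

    Four applications of a fast-degrading dithiocarbamate fungicide
    (mancozeb-like, Kfoc > 500 so the "mix" rule takes 1 cm) on days 91, 101,
    104 and 113, and two of a slow anilinopyrimidine (pyrimethanil-like,
    Kfoc < 500, 2.5 cm) on days 106 and ``second_slow_day`` (the second onset
    lies outside the printed excerpt, hence configurable).  Half-lives are
    back-solved from consecutive printed values; temperatures are held at the
    reference temperature so the implied rate constant is constant, which the
    printed excerpt's constant day-over-day ratios show.  Rates and
    interception reproduce the printed initial concentrations (5.33333333 and
    0.4 mg/kg) with the 60 % interception of a fully developed orchard.
    Endpoints are representative synthetic values, not database lookups.
    """
    fast = SubstanceRecord(
        compound_id=0, name="Mancozeb", cas_nr="8018-01-7",
        chemical_class="dithiocarbamate", chemical_use="fungicide",
        degt50_soil=inferred_dt50(FAST_PAIR),  # ~0.1236 d, inferred
        lc50_earthworm=1000.0, noec_earthworm=10.0, kfoc=998.0,
    )
    slow = SubstanceRecord(
        compound_id=1, name="Pyrimethanil", cas_nr="53112-28-0",
        chemical_class="anilinopyrimidine", chemical_use="fungicide",
        degt50_soil=inferred_dt50(SLOW_PAIR),  # ~135.9 d, inferred
        lc50_earthworm=600.0, noec_earthworm=30.0, kfoc=301.0,
    )
    croptab_rows = [
        CropInterceptionRow(1, "apple", 0, 69, 0.0),
        CropInterceptionRow(1, "apple", 70, 99, 60.0),
    ]

    def ev(i: int, sub: SubstanceRecord, day: int, rate: float) -> ApplicationEvent:
        return ApplicationEvent(
            event_index=i, compound_id=sub.compound_id, compound_name=sub.name,
            application_day=day, application_month=month_of_day(day),
            rate_kg_ai_ha=rate, bbch=75, degradation_factor=1.0,
            mixing_depth_spec="mix",
        )

    fast_days = (91, 101, 104, 113)
    slow_days = (106, second_slow_day)
    events = [ev(i, fast, d, 2.0) for i, d in enumerate(fast_days)]
    events += [ev(len(events) + i, slow, d, 0.375) for i, d in enumerate(slow_days)]
    scenario = Scenario(
        description="apple spray series",
        crop_id=1,
        events=events,
        monthly_temperature=((20.0,) * 12,),
        simulation_days=365,
        reference_temperature=20.0,
    )
    return scenario, [fast, slow], croptab_rows
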