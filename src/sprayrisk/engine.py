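"""Daily simulation of per-event and cumulative soil concentrations.

For every application event the engine computes the crop interception factor
from the crop and BBCH stage, resolves the mixing depth, places the full
initial concentration (PIEC) on the application day, and then decays it day
by day with the rate constant of the calendar month the residue sits in.
Events are the columns of the result — the same substance applied on two
dates stays in two columns — and the cumulative series is the daily row sum.
The model is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import exposure, kinetics
from .calendar365 import month_of_day, year_index_of_day
from .data_tables import ApplicationEvent, CropInterceptionRow, Scenario, SubstanceRecord
from .errors import ScenarioError


@dataclass
class ConcentrationMatrix:
    """Daily soil concentrations [mg a.i./kg dw], one column per event."""

    days: np.ndarray  # 1..simulation_days
    labels: list[str]  # compound_name per event, chronological order
    values: np.ndarray  # shape (n_days, n_events)
    events: list[ApplicationEvent]

    @property
    def cumulative(self) -> np.ndarray:
        """Summed concentration over all events per day ("cumulated PEC")."""
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: days, one column per event, plus the cumulative sum."""
        df = pd.DataFrame(self.values, copy=True)
        df.columns = list(self.labels)
        df.insert(0, "days", self.days)
        df["cumulative"] = self.cumulative
        return df

    def aggregated_by_substance(self) -> "ConcentrationMatrix":
        """Presentation variant with one column per substance (columns summed)."""
        order: list[int] = []
        for e in self.events:
            if e.compound_id not in order:
                order.append(e.compound_id)
        cols = np.column_stack([
            self.values[:, [i for i, e in enumerate(self.events) if e.compound_id == cid]].sum(axis=1)
            for cid in order
        ])
        labels = [
            next(e.compound_name for e in self.events if e.compound_id == cid)
            for cid in order
        ]
        reps = [next(e for e in self.events if e.compound_id == cid) for cid in order]
        return ConcentrationMatrix(days=self.days, labels=labels, values=cols, events=reps)


def daily_rate_constants(
    scenario: Scenario,
    substance: SubstanceRecord,
    event: ApplicationEvent,
    *,
    freeze_stop: bool = False,
) -> np.ndarray:
    """Rate constant k [1/d] for each simulated day for one event's substance.

    k is piecewise constant per calendar month; monthly temperatures are
    recycled for multi-year horizons unless per-year sets were supplied.
    With ``freeze_stop`` degradation halts (k = 0) in months at or below
    0 degC; by default the Arrhenius correction is applied as-is.
    """
    if substance.degt50_soil is None:
        raise ScenarioError(f"substance {substance.name!r}: DT50 missing (imputation not run?)")
    ts_K = scenario.reference_temperature + kinetics.CELSIUS_OFFSET
    k_cache: dict[tuple[int, int], float] = {}
    out = np.empty(scenario.simulation_days)
    for day in range(1, scenario.simulation_days + 1):
        year = year_index_of_day(day)
        month = month_of_day(day)
        key = (min(year, len(scenario.monthly_temperature) - 1), month)
        if key not in k_cache:
            temp_c = scenario.temperature(year, month)
            if freeze_stop and temp_c <= 0.0:
                k_cache[key] = 0.0
            else:
                dt50s = kinetics.corrected_half_life(
                    kinetics.KineticParams(
                        dt50_soil=substance.degt50_soil,
                        degradation_factor=event.degradation_factor,
                        activation_energy=scenario.activation_energy,
                        gas_constant=scenario.gas_constant,
                        reference_temperature_K=ts_K,
                        temperature_K=temp_c + kinetics.CELSIUS_OFFSET,
                    )
                )
                k_cache[key] = kinetics.rate_constant(dt50s)
        out[day - 1] = k_cache[key]
    return out


def event_piec(
    scenario: Scenario,
    event: ApplicationEvent,
    substance: SubstanceRecord,
    croptab: Sequence[CropInterceptionRow],
) -> float:
    """PIEC [mg/kg] of one event (rate in kg/ha is converted to g/ha here)."""
    cif = exposure.crop_interception(scenario.crop_id, event.bbch, croptab)
    depth_cm = exposure.resolve_mixing_depth(event.mixing_depth_spec, substance.kfoc)
    return exposure.piec(
        exposure.ExposureParams(
            rate_g_ai_ha=1000.0 * event.rate_kg_ai_ha,
            cif_pct=cif,
            mixing_depth_cm=depth_cm,
            bulk_density=scenario.bulk_density,
        )
    )


def simulate(
    scenario: Scenario,
    compounds: Sequence[SubstanceRecord] | Mapping[int, SubstanceRecord],
    croptab: Sequence[CropInterceptionRow],
    *,
    freeze_stop: bool = False,
) -> ConcentrationMatrix:
    """Run the exposure + degradation chain for a whole spray series.

    Each event's series is zero before its application day, equals the full
    PIEC on the application day (any pre-existing residue lives in its own
    column and is added by the cumulative sum), and decays daily afterwards;
    the step from day t to day t+1 uses the rate constant of day t's month.
    """
    if isinstance(compounds, Mapping):
        by_id = dict(compounds)
    else:
        by_id = {r.compound_id: r for r in compounds}
    n_days = scenario.simulation_days
    values = np.zeros((n_days, len(scenario.events)))
    for col, event in enumerate(scenario.events):
        try:
            substance = by_id.get(event.compound_id)
            if substance is None:
                raise ScenarioError(f"unknown compound_id {event.compound_id}")
            c0 = event_piec(scenario, event, substance, croptab)
            k = daily_rate_constants(scenario, substance, event, freeze_stop=freeze_stop)
            c = c0
            values[event.application_day - 1, col] = c
            for day in range(event.application_day + 1, n_days + 1):
                c = kinetics.decay_step(c, k[day - 2])
                values[day - 1, col] = c
        except ScenarioError as exc:
            raise ScenarioError(
                f"application {event.event_index + 1} "
                f"({event.compound_name}, day {event.application_day}): {exc}"
            ) from exc
    return ConcentrationMatrix(
        days=np.arange(1, n_days + 1),
        labels=[e.compound_name for e in scenario.events],
        values=values,
        events=list(scenario.events),
    )
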