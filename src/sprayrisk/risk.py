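"""Daily single-substance and mixture risk indices under concentration addition.

Every simulated day is treated as one pesticide mixture made of that day's
per-event soil concentrations.  The exposure-toxicity ratio of a component is
ETR = PEC / endpoint (LC50 for acute, NOEC for chronic risk); the mixture
index sums the component ETRs daily (toxic-unit summation, with the
concentration-addition effect boundary at sum = 1).  The reciprocal
toxicity-exposure ratio combines like resistors in parallel,

    TERmix = ( sum_i 1/TER_i )^-1,

so TERmix = 1/ETRmix wherever anything is in the soil; days with zero
exposure carry TER = +inf rather than being dropped, which log-scale plots
clip gracefully.  Regulatory acceptability requires TER at or above a
threshold; an exceedance is a day with TERmix strictly below it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_tables import SubstanceRecord
from .engine import ConcentrationMatrix
from .errors import ScenarioError

ENDPOINT_FIELDS = {"acute": "lc50_earthworm", "chronic": "noec_earthworm"}
DEFAULT_THRESHOLDS = {"acute": 10.0, "chronic": 5.0}


@dataclass
class RiskCourse:
    """Daily risk indices for one endpoint kind (acute or chronic)."""

    endpoint_kind: str
    days: np.ndarray
    labels: list[str]
    per_event_etr: np.ndarray  # shape (n_days, n_events)
    etr_mix: np.ndarray
    per_event_ter: np.ndarray  # +inf on zero-concentration days
    ter_mix: np.ndarray
    threshold: float
    exceedance_intervals: list[tuple[int, int]]  # [first_day, last_day], 1-based
    first_exceedance_day: int | None
    days_below: int


def etr(pec: float, endpoint: float) -> float:
    """Exposure-toxicity ratio of one substance on one day."""
    if endpoint <= 0:
        raise ScenarioError(f"ecotoxicological endpoint must be > 0, got {endpoint}")
    if pec < 0:
        raise ScenarioError(f"PEC must be >= 0, got {pec}")
    return pec / endpoint


def etr_mix(per_event_etrs: Iterable[float]) -> float:
    """Mixture ETR: daily sum of component ETRs (concentration addition)."""
    total = 0.0
    for v in per_event_etrs:
        if v < 0:
            raise ScenarioError(f"component ETR must be >= 0, got {v}")
        total += v
    return total


def ter_mix(per_event_ters: Iterable[float]) -> float:
    """Mixture TER: reciprocal of the summed reciprocal component TERs.

    Components with infinite TER (zero exposure) drop out; an all-infinite
    day returns +inf.
    """
    total = 0.0
    for v in per_event_ters:
        if v <= 0:
            raise ScenarioError(f"component TER must be > 0, got {v}")
        total += 0.0 if np.isinf(v) else 1.0 / v
    return np.inf if total == 0.0 else 1.0 / total


def exceedance(
    ter_mix_series: Sequence[float], threshold: float
) -> tuple[list[tuple[int, int]], int | None, int]:
    """Maximal runs of consecutive days with TERmix strictly below the threshold.

    Returns ``(intervals, first_day, n_days_below)`` with 1-based inclusive
    day intervals; equality with the threshold counts as compliant.
    """
    if threshold <= 0:
        raise ScenarioError(f"TER threshold must be > 0, got {threshold}")
    below = np.asarray(ter_mix_series) < threshold
    intervals: list[tuple[int, int]] = []
    start: int | None = None
    for i, b in enumerate(below, start=1):
        if b and start is None:
            start = i
        elif not b and start is not None:
            intervals.append((start, i - 1))
            start = None
    if start is not None:
        intervals.append((start, len(below)))
    first = intervals[0][0] if intervals else None
    return intervals, first, int(below.sum())


def assess(
    matrix: ConcentrationMatrix,
    compounds: Sequence[SubstanceRecord] | Mapping[int, SubstanceRecord],
    endpoint_kind: str,
    threshold: float | None = None,
) -> RiskCourse:
    """Convert a concentration matrix into a daily risk course.

    ``endpoint_kind`` selects the denominator: ``"acute"`` divides by the
    earthworm LC50, ``"chronic"`` by the reproduction NOEC.
    """
    if endpoint_kind not in ENDPOINT_FIELDS:
        raise ScenarioError(f"endpoint kind must be one of {sorted(ENDPOINT_FIELDS)}")
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[endpoint_kind]
    if isinstance(compounds, Mapping):
        by_id = dict(compounds)
    else:
        by_id = {r.compound_id: r for r in compounds}
    field_name = ENDPOINT_FIELDS[endpoint_kind]
    endpoints = np.empty(len(matrix.events))
    for i, ev in enumerate(matrix.events):
        value = getattr(by_id[ev.compound_id], field_name)
        if value is None or value <= 0:
            raise ScenarioError(
                f"substance {ev.compound_name!r}: {field_name} missing or non-positive"
            )
        endpoints[i] = value

    per_etr = matrix.values / endpoints
    mix_etr = per_etr.sum(axis=1)
    # TER overflowing the float range on vanishing concentrations is +inf
    with np.errstate(divide="ignore", over="ignore"):
        per_ter = np.where(matrix.values > 0, endpoints / np.where(matrix.values > 0, matrix.values, 1.0), np.inf)
        inv_sum = np.where(np.isinf(per_ter), 0.0, 1.0 / per_ter).sum(axis=1)
        mix_ter = np.where(inv_sum > 0, 1.0 / np.where(inv_sum > 0, inv_sum, 1.0), np.inf)
    intervals, first, n_below = exceedance(mix_ter, threshold)
    return RiskCourse(
        endpoint_kind=endpoint_kind,
        days=matrix.days,
        labels=list(matrix.labels),
        per_event_etr=per_etr,
        etr_mix=mix_etr,
        per_event_ter=per_ter,
        ter_mix=mix_ter,
        threshold=threshold,
        exceedance_intervals=intervals,
        first_exceedance_day=first,
        days_below=n_below,
    )
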