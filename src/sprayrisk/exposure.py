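"""Crop interception and the predicted initial environmental concentration.

The soil concentration immediately after a spray application (PIEC, predicted
initial environmental concentration) follows the standard soil-persistence
form

    PIEC [mg/kg] = AR * (1 - CIF/100) / (100 * d * p)

with AR the application rate in g a.i./ha, CIF the crop interception factor
in percent, d the mixing depth in cm and p the dry-soil bulk density in
g/cm^3.  The factor 100 in the denominator carries the unit conversion: one
hectare mixed to d cm at density p holds 10^8 cm^2 * d * p grams of soil, so
AR grams spread into 100 * d * p tonnes, i.e. AR / (100 d p) mg per kg.

The mixing depth is either a user-fixed value or, under the German
registration convention (token ``"mix"``), 1 cm for strongly sorbing
substances (Kfoc > 500 L/kg) and 2.5 cm otherwise; the shallow depth yields
2.5-fold higher initial concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .data_tables import MIX_TOKEN, CropInterceptionRow, MixingDepthSpec
from .errors import ScenarioError

#: Kfoc above which the variable-depth rule assumes a 1 cm mixing layer
KFOC_DEPTH_SWITCH = 500.0  # [L/kg], strict ">"
SHALLOW_MIXING_CM = 1.0
DEFAULT_MIXING_CM = 2.5


@dataclass
class ExposureParams:
    """Inputs of the PIEC formula for one application event."""

    rate_g_ai_ha: float  # AR [g a.i./ha] = 1000 x maintab rate in kg a.i./ha
    cif_pct: float  # CIF [%]
    mixing_depth_cm: float  # d [cm]
    bulk_density: float  # p [g/cm^3]


def crop_interception(
    crop_id: int, bbch: int, croptab: Sequence[CropInterceptionRow]
) -> float:
    """Interception percentage for a crop at a BBCH development stage.

    The unique croptab row of this crop whose BBCH range contains ``bbch``
    supplies the value; there is no interpolation and a stage not covered by
    any range is a hard error.
    """
    if not 0 <= bbch <= 99:
        raise ScenarioError(f"BBCH stage {bbch} outside 0-99")
    rows = [r for r in croptab if r.crop_id == crop_id]
    if not rows:
        raise ScenarioError(f"crop_id {crop_id} not present in croptab")
    for r in rows:
        if r.covers(bbch):
            return r.interception_pct
    raise ScenarioError(
        f"croptab has no BBCH range covering stage {bbch} for crop {crop_id}"
    )


def resolve_mixing_depth(spec: MixingDepthSpec, kfoc: float | None = None) -> float:
    """Mixing depth in cm from a fixed depth in metres or the "mix" rule."""
    if isinstance(spec, str):
        if spec != MIX_TOKEN:
            raise ScenarioError(f"unknown mixing depth token {spec!r}")
        if kfoc is None:
            raise ScenarioError('mixing depth "mix" requires a Kfoc value')
        return SHALLOW_MIXING_CM if kfoc > KFOC_DEPTH_SWITCH else DEFAULT_MIXING_CM
    if spec <= 0:
        raise ScenarioError(f"fixed mixing depth must be > 0 m, got {spec}")
    return spec * 100.0  # m -> cm


def piec(params: ExposureParams) -> float:
    """Initial soil concentration [mg a.i./kg dry soil] after one application."""
    if params.mixing_depth_cm <= 0:
        raise ScenarioError("mixing depth must be > 0 cm")
    if params.bulk_density <= 0:
        raise ScenarioError("bulk density must be > 0 g/cm^3")
    if not 0 <= params.cif_pct <= 100:
        raise ScenarioError(f"crop interception {params.cif_pct} outside [0, 100] %")
    if not math.isfinite(params.rate_g_ai_ha) or params.rate_g_ai_ha < 0:
        raise ScenarioError("application rate must be finite and >= 0 g/ha")
    return (
        params.rate_g_ai_ha
        * (1.0 - params.cif_pct / 100.0)
        / (100.0 * params.mixing_depth_cm * params.bulk_density)
    )
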