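"""Exception hierarchy for scenario and table validation."""


class SprayRiskError(ValueError):
    """Base class for all input-validation and modelling errors."""


class TableError(SprayRiskError):
    """A delimited-text input table is malformed or inconsistent."""


class ImputationError(SprayRiskError):
    """A missing substance property cannot be imputed (no donor records)."""


class ScenarioError(SprayRiskError):
    """A scenario violates a cross-table or calendar constraint."""
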