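"""Exception hierarchy shared across the toolkit."""


class HydrochemError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(HydrochemError):
    """Input table does not match the declared schema (missing/unknown column)."""


class ValidationError(HydrochemError):
    """A value violates a physical invariant (negative concentration, pH out of range)."""


class ConfigError(HydrochemError):
    """Inconsistent or incomplete configuration (weights, standards, distributions)."""


class UndefinedQuantityError(HydrochemError):
    """A requested quantity is mathematically undefined for this input
    (zero ion sums, missing pH, empty result set)."""


class ModelRangeError(HydrochemError):
    """Input lies outside the validity range of a model (e.g. Davies I > 0.5 mol/L)."""
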