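"""Exception hierarchy shared across the pipeline stages."""


class SocCurveError(Exception):
    """Base class for all package errors."""


class SchemaError(SocCurveError):
    """An input table is missing required columns or has malformed cells."""


class IntegrityError(SocCurveError):
    """Duplicate keys or other referential-integrity violations in a table."""


class DomainError(SocCurveError, ValueError):
    """A value is outside its admissible domain (non-positive area, D <= 0, ...)."""


class FactorLookupError(SocCurveError, KeyError):
    """A (kind, level, climate) or (climate, soil) key does not resolve."""


class ClassificationError(SocCurveError):
    """A stratum's dated management states do not map to a tillage sequence."""


class UndefinedCostError(SocCurveError):
    """Unit cost is undefined (zero or negative sequestration rate)."""


class ConfigurationError(SocCurveError):
    """Run configuration is inconsistent (e.g. states missing from payments)."""


class GenerationError(SocCurveError):
    """The synthetic-data generator config is infeasible."""


class EmptyInputError(SocCurveError):
    """An operation requiring at least one record received none."""


class PipelineError(SocCurveError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
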