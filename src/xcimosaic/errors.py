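"""Exception hierarchy for xcimosaic.

All package-specific failures derive from :class:`XciMosaicError` so callers
(and the CLI) can distinguish model/data problems from programming errors.
"""


class XciMosaicError(Exception):
    """Base class for all xcimosaic errors."""


class ConfigurationError(XciMosaicError, ValueError):
    """A simulation configuration violates its invariants."""


class SchemaError(XciMosaicError, ValueError):
    """A count/trajectory table violates the expected schema."""


class UndefinedEstimateError(XciMosaicError, ValueError):
    """Survival is undefined because the GFP-positive fraction is zero."""


class InfeasibleCorrectionError(XciMosaicError, ValueError):
    """Observed fraction below the assumed false-positive rate."""


class EmptyGroupError(XciMosaicError, ValueError):
    """A grouping produced no animals to aggregate."""


class InsufficientSampleError(XciMosaicError, ValueError):
    """A statistical comparison received fewer observations than required."""


class UnderdeterminedFitError(XciMosaicError, ValueError):
    """Too few stages to fit a staged-hazard model."""


class UnidentifiableCompetitionError(XciMosaicError, ValueError):
    """Competition coefficient cannot be identified (no high-fitness cells)."""
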