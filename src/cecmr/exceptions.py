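"""Exception hierarchy for cecmr.

All package-specific failures derive from :class:`CecmrError` so callers can
catch one base class; the leaf types distinguish malformed input files,
records violating statistical invariants, allele-reconciliation failures and
estimator preconditions.
"""


class CecmrError(Exception):
    """Base class for all cecmr errors."""


class FormatError(CecmrError):
    """Input file cannot be parsed (missing mandatory column, bad delimiter)."""


class ValidationError(CecmrError):
    """A record violates a domain invariant (e.g. non-positive SE)."""


class HarmonizationError(CecmrError):
    """Exposure and outcome allele sets cannot be reconciled."""


class DegenerateInstrumentError(CecmrError):
    """Instrument with zero exposure effect: the Wald ratio is undefined."""


class InsufficientInstrumentsError(CecmrError):
    """Fewer instruments than the estimator's degrees of freedom allow."""


class CollinearityError(CecmrError):
    """Exposure design matrix is rank deficient in multivariable MR."""
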