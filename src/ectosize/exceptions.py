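"""Exception hierarchy shared across the package."""


class EctosizeError(Exception):
    """Base class for package errors."""


class InsufficientDataError(EctosizeError, ValueError):
    """Too few usable records for the requested computation."""


class DegenerateDataError(EctosizeError, ValueError):
    """Zero-variance or otherwise degenerate input (e.g. constant vector)."""


class CollinearityError(EctosizeError, ValueError):
    """Rank-deficient design matrix; the message names the dependent columns."""


class IntegrityError(EctosizeError, ValueError):
    """Referential-integrity failure between the individual and site tables."""
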