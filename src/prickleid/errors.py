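"""Exception hierarchy.

Every error raised by prickleid derives from :class:`PrickleidError` so
callers can catch the package's failures with one clause.
"""


class PrickleidError(Exception):
    """Base class for all prickleid errors."""


class SchemaError(PrickleidError):
    """A tabular input is missing a required column or has a malformed header."""


class ValidationError(PrickleidError):
    """A record violates a domain invariant (negative count, zero length, ...)."""


class TaxonMismatchError(PrickleidError):
    """Prior scenario and likelihood table disagree on the taxon set."""

    def __init__(self, message: str, missing=(), extra=()):
        super().__init__(message)
        self.missing = tuple(missing)
        self.extra = tuple(extra)


class ImpossibleObservationError(PrickleidError):
    """The observed prickle type has zero marginal likelihood under the prior."""


class InconsistentPosteriorError(PrickleidError):
    """A posterior is positive where the prior was zero: Bayes' rule cannot
    have produced it, so the posterior table is internally inconsistent."""


class UndefinedLikelihoodError(PrickleidError):
    """A taxon contributed zero prickles and no smoothing was requested."""
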