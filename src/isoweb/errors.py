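"""Exception hierarchy for isoweb.

All package-specific failures derive from :class:`IsowebError` so callers can
catch one base class at pipeline boundaries.
"""


class IsowebError(Exception):
    """Base class for all isoweb errors."""


class SchemaError(IsowebError):
    """An input table is missing a required column or has a bad layout."""


class ParseError(IsowebError):
    """A cell could not be parsed (e.g. non-numeric delta value)."""


class ValidationError(IsowebError):
    """A value violates a domain invariant (bad zone label, non-binary link, ...)."""


class EmptyInputError(IsowebError):
    """An operation received an empty collection where at least one item is required."""


class InsufficientDataError(IsowebError):
    """Too few points/chains/draws for the requested computation."""


class DegenerateFitError(IsowebError):
    """A regression or fit is degenerate (e.g. zero variance in the predictor)."""


class MissingDataError(IsowebError):
    """A required record (e.g. a source biomass) is absent."""


class GeometryError(IsowebError):
    """A geometric construction is impossible (fewer than 3 polygon vertices)."""


class ComparisonError(IsowebError):
    """Models being compared were not fitted to identical data."""


class FeasibilityError(IsowebError):
    """A requested synthetic structure (e.g. target connectance) is infeasible."""


class SamplerError(IsowebError):
    """The MCMC sampler failed irrecoverably."""
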