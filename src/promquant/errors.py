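"""Exception hierarchy for promquant.

All promquant errors derive from :class:`PromquantError`; argument problems
additionally derive from :class:`ValueError` so generic callers can catch them.
"""


class PromquantError(Exception):
    """Base class for all promquant errors."""


class InvalidArgumentError(PromquantError, ValueError):
    """An argument violates a documented precondition."""


class GenerationError(PromquantError):
    """Synthetic-data generation could not satisfy its constraints."""


class DegenerateRegionError(PromquantError):
    """A promoter interval is empty (adjacent or overlapping ORFs)."""


class NotFoundError(PromquantError, KeyError):
    """A requested gene/contig does not exist."""


class InsufficientDataError(PromquantError):
    """Too few observations for the requested statistic."""


class DegenerateMeasurementError(PromquantError):
    """A measurement ratio has a zero denominator."""


class FixtureError(PromquantError):
    """A packaged fixture failed its integrity checks."""
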