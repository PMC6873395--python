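"""Exception hierarchy.

All package errors derive from :class:`OtusimError` so the CLI can map any
data/parameter problem to a nonzero exit with a readable message.
"""


class OtusimError(Exception):
    """Base class for all errors raised by otusim."""


class InvalidParameterError(OtusimError, ValueError):
    """A simulation or estimator parameter violates its contract."""


class DegenerateSampleError(OtusimError, ValueError):
    """A sample is unusable (e.g. all-zero abundances or counts)."""


class InsufficientPopulationError(OtusimError, ValueError):
    """Requested more draws than items available in the population urn."""


class TableFormatError(OtusimError, ValueError):
    """A count table or metadata file violates the expected format."""


class EstimationError(OtusimError, ValueError):
    """Parameter estimation cannot proceed on the given table."""
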