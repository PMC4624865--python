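"""Exception hierarchy for the decoding pipeline.

Every error raised deliberately by this package derives from
:class:`DecoderError`, so callers (and the CLI) can distinguish pipeline
failures from programming errors.
"""


class DecoderError(Exception):
    """Base class for all emg2pen errors."""


class InvalidParameterError(DecoderError, ValueError):
    """A parameter value is outside its admissible range (e.g. fc >= Nyquist)."""


class InvalidInputError(DecoderError, ValueError):
    """Input data violate a precondition (empty, too short, misaligned)."""


class FitDegenerateError(DecoderError):
    """A least-squares fit is underdetermined or rank deficient."""


class MissingDataError(DecoderError):
    """A required group (subject, symbol) has no or too few trials."""


class NumericalDegeneracyError(DecoderError):
    """A linear solve inside the filter failed (singular covariance)."""


class UndefinedMetricError(DecoderError):
    """The reconstruction metric is undefined (constant actual trace)."""


class DegenerateTestError(DecoderError):
    """A statistical test cannot be carried out (all paired differences zero)."""


class FormatError(DecoderError):
    """A trial container file is malformed (missing column, bad header)."""


class IntegrityError(DecoderError):
    """A dataset manifest checksum does not match the file on disk."""
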