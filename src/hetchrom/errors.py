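"""Exception hierarchy shared across the analysis stages."""


class HetchromError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(HetchromError):
    """Malformed input record (e.g. a sequence with illegal characters)."""


class MissingAccessionError(HetchromError, KeyError):
    """An accession was requested that is absent from the collection."""


class RangeError(HetchromError, IndexError):
    """A coordinate lies outside the valid range (e.g. residue index past
    the end of an ungapped sequence)."""


class DegenerateInputError(HetchromError):
    """Input is structurally valid but carries no usable signal
    (e.g. a sequence with zero canonical residues, a curve with no
    bleach depth, fewer observations than parameters)."""


class ConfigError(HetchromError):
    """Unknown configuration key (e.g. an unrecognised pKa scale name)."""


class ParameterError(HetchromError, ValueError):
    """A parameter value violates its documented constraints."""


class NormalizationError(HetchromError):
    """A normalization denominator is non-positive; the message names the
    offending frame."""


class AlignmentGridError(HetchromError):
    """Curves to be averaged do not share a common time grid."""


class FitError(HetchromError):
    """Nonlinear fit failed to converge from every start point."""
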