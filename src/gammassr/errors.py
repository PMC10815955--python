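"""Exception hierarchy: distinguishes configuration, parsing and degenerate-data errors."""


class GammassrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GammassrError):
    """Invalid parameter combination (bad sampling rate, empty analysis window, ...)."""


class ParseError(GammassrError):
    """Malformed input file; message names the offending field/row."""


class IntegrityError(GammassrError):
    """Internally inconsistent data (mismatched channel lengths, out-of-range values)."""


class EmptyInputError(GammassrError):
    """No usable data remained (zero extractable events, recording too short)."""


class DegenerateInputError(GammassrError):
    """Analysis undefined on this input (fewer than 2 epochs, zero variance, ...)."""


class NormalizationError(GammassrError):
    """Percent-of-reference undefined because the reference mean is not positive."""
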