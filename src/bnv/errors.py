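"""Exception hierarchy.

Every user-facing failure derives from :class:`BnvError` so the CLI can map
any of them onto a single-line, machine-greppable error code and a nonzero
exit status.
"""


class BnvError(Exception):
    """Base class for all errors raised by this package."""

    #: short machine-greppable code, overridden by subclasses
    code = "BNV_ERROR"


class FormatError(BnvError):
    """A file does not conform to its on-disk format."""

    code = "BNV_FORMAT"


class ValidationError(BnvError):
    """Inputs are well-formed but mutually or internally inconsistent."""

    code = "BNV_VALIDATION"


class ParameterError(BnvError):
    """An option or numeric parameter is outside its legal domain."""

    code = "BNV_PARAMETER"


class CombinationError(BnvError):
    """The set of input file kinds is not one of the accepted combinations."""

    code = "BNV_COMBINATION"


class ClassificationError(BnvError):
    """A path's suffix does not map to any known file kind."""

    code = "BNV_CLASSIFY"


class ConfigError(BnvError):
    """A configuration file violates the configuration schema."""

    code = "BNV_CONFIG"


class LayoutError(BnvError):
    """The requested panel layout cannot be built for the given surface."""

    code = "BNV_LAYOUT"


class UnsupportedInputError(BnvError):
    """The input is recognized but deliberately not supported."""

    code = "BNV_UNSUPPORTED"
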