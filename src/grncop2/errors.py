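"""Exception hierarchy for the grncop2 package."""


class GrncopError(ValueError):
    """Base class for all validation and inference errors raised by grncop2."""


class ValidationError(GrncopError):
    """Input data or parameters violate a documented contract."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending cell."""


class NoInformativeThreshold(GrncopError):
    """Every candidate regulator threshold leaves one side of the partition empty.

    Raised for constant regulator profiles, for which no relative regulation
    threshold can discriminate the target's states.
    """
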