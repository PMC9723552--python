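"""Exception and warning types shared across the toolkit."""


class GenefishError(Exception):
    """Base class for all toolkit errors."""


class InvalidParameterError(GenefishError, ValueError):
    """A numeric or categorical parameter violates its documented range."""


class InfeasibleDesignError(GenefishError):
    """No probe tiling satisfies the length constraints; message names the bound."""


class ParseError(GenefishError):
    """A sequence or table file could not be parsed; message carries the location."""


class ValidationError(GenefishError, ValueError):
    """An input record violates an invariant (e.g. positive cells > total cells)."""


class ProbeUnstableWarning(UserWarning):
    """The duplex melts below the hybridization temperature even with a perfect match."""


class StringencyWarning(UserWarning):
    """A requested mismatch tolerance cannot be fully compensated by formamide alone."""


class ConstraintsRelaxedWarning(UserWarning):
    """No primer pair met every constraint; the least-bad pair is returned."""


class AmbiguityWarning(UserWarning):
    """IUPAC ambiguity codes other than N were mapped to N on read."""
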