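"""Typed exceptions shared across modules."""


class GametokitError(Exception):
    """Base class for all package errors."""


class ParseError(GametokitError):
    """Malformed or inconsistent input table/sequence; names the record."""


class FrameError(GametokitError):
    """Sequence length or offset violates the codon reading frame."""


class DomainError(GametokitError):
    """Parameter outside its mathematical domain (theta <= 0, mu <= 0, ...)."""


class SaturationError(GametokitError):
    """K2P correction undefined: observed divergence beyond the formula's domain."""


class UndefinedStatisticError(GametokitError):
    """A statistic cannot be computed (zero synonymous sites, zero variance)."""
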