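"""Exception types shared across the pipeline stages."""


class HomeobiasError(Exception):
    """Base class for all package-specific errors."""


class HitTableParseError(HomeobiasError):
    """A tabular alignment file could not be parsed; message names the line."""


class SelfHitError(HomeobiasError):
    """A transcript aligned to itself, which means the two parental
    identifier namespaces overlap and pairing would be ambiguous."""


class ExcludedPairError(HomeobiasError):
    """A homeolog pair does not meet the non-zero expression requirement of
    the bias test and must be excluded rather than produce NaN."""
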