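"""Exception types shared across the package."""


class BreathpairError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BreathpairError, ValueError):
    """A configuration field violates its invariant. Message names the field."""


class ParseError(BreathpairError, ValueError):
    """A cohort table on disk is malformed. Message carries the row number."""


class InsufficientDataError(BreathpairError, ValueError):
    """Too few complete subjects / rows / iterations for the requested step."""


class DegenerateDataError(BreathpairError, ValueError):
    """Input is constant or otherwise leaves the statistic undefined."""


class FeatureMismatchError(BreathpairError, ValueError):
    """A matrix does not carry the feature set a fitted model expects."""
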