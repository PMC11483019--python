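"""Exception types shared across the pipeline."""


class BilestateError(Exception):
    """Base class for pipeline errors."""


class ConfigError(BilestateError, ValueError):
    """An invalid configuration value or combination."""


class FormatError(BilestateError, ValueError):
    """A malformed or inconsistent on-disk input."""


class EmptyResultError(BilestateError, ValueError):
    """An operation removed or excluded everything; thresholds need review."""


class InvalidRankError(BilestateError, ValueError):
    """A factorization rank incompatible with the matrix dimensions."""
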