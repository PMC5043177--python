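"""Exception types shared across the pipeline."""


class CodetectError(Exception):
    """Base class for pipeline errors."""


class ConfigError(CodetectError):
    """Invalid simulator or pipeline configuration."""


class FormatError(CodetectError):
    """An input file does not match its declared schema."""


class UndefinedMetricError(CodetectError):
    """A statistic is undefined for the given input (e.g. all-zero vector)."""
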