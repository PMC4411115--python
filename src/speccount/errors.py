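"""Exception hierarchy shared across the pipeline."""


class SpecCountError(Exception):
    """Base class for all package-specific errors."""


class ReportFormatError(SpecCountError):
    """A protein report file is malformed (e.g. a mandatory column is missing)."""


class ValidationError(SpecCountError):
    """A value violates a domain invariant (negative count, bad coverage, ...)."""


class DesignError(SpecCountError):
    """Reports and the sample design disagree (unknown run, duplicate run, ...)."""


class DegenerateSampleError(SpecCountError):
    """A run cannot be normalized (all-zero column, zero trimmed mean)."""


class ConfigError(SpecCountError):
    """A simulation or pipeline configuration is invalid."""
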