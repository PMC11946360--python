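"""Exception hierarchy shared across the pipeline stages."""


class ExomeScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ExomeScreenError):
    """Bad or missing configuration: unknown columns, absent files, unknown samples."""


class ValidationError(ExomeScreenError):
    """Input data violates a contract (e.g. non-ACGT alleles, ref == alt)."""


class PipelineError(ExomeScreenError):
    """A pipeline stage failed; the message names the stage."""
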