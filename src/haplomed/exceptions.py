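"""Exception types shared across the pipeline."""


class HaplomedError(Exception):
    """Base class for all package-specific errors."""


class CollinearityError(HaplomedError, ValueError):
    """Raised when a regression design matrix is rank deficient."""


class EmptyResultError(HaplomedError, ValueError):
    """Raised when a filtering step leaves nothing to analyse."""


class MonomorphicSNPError(HaplomedError, ValueError):
    """Raised when a statistic is undefined for a monomorphic SNP."""
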