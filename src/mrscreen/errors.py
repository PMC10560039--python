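"""Exception and warning types shared across the package."""


class MrError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MrError):
    """An invalid configuration value; the message names the offending field."""


class UndefinedRatioError(MrError):
    """Wald ratio requested for an instrument with a zero exposure effect."""


class SingularDesignError(MrError):
    """A regression design matrix is rank deficient (no spread, or collinear exposures)."""


class WeakInstrumentWarning(UserWarning):
    """Mean instrument F statistic below the conventional threshold of 10."""


class HarmonizationWarning(UserWarning):
    """A SNP was dropped or modified during allele harmonization."""
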