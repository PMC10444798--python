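"""Package-wide exception and warning types."""


class ColonyPhyloError(Exception):
    """Base class for package errors."""


class ConfigurationError(ColonyPhyloError):
    """Invalid simulation or analysis configuration."""


class DataError(ColonyPhyloError):
    """Malformed or contradictory input data."""


class EmptyResultError(ColonyPhyloError):
    """An operation removed or produced nothing (e.g. QC dropped every colony)."""


class ConvergenceWarning(UserWarning):
    """MCMC diagnostics indicate the chains may not have mixed."""
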