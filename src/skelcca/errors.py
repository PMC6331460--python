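"""Exception hierarchy.

Errors are grouped into three families so the CLI can map them onto distinct
exit codes: schema/configuration problems (the run was mis-specified), data
problems (the inputs are unusable), and numerical problems (the computation is
undefined or ill-conditioned for these inputs).
"""


class SkelccaError(Exception):
    """Base class for all package errors."""


# -- schema / configuration -------------------------------------------------

class SchemaError(SkelccaError):
    """A required column, score name, or config key is missing or unknown."""


class ConfigError(SkelccaError):
    """A configuration value is out of its valid range."""


# -- data -------------------------------------------------------------------

class DataError(SkelccaError):
    """Input values are unusable (non-finite, non-numeric, ...)."""


class GeometryError(SkelccaError):
    """Image and mask grids disagree, or a volume violates mask geometry."""


class PairingError(SkelccaError):
    """Imaging and behavioral tables share no subjects."""


# -- numerical --------------------------------------------------------------

class ParameterError(SkelccaError):
    """A numeric argument (q, radius, fold count, ...) is out of range."""


class DegenerateDataError(SkelccaError):
    """A statistic is undefined (constant score vector, zero variance)."""


class ConditioningError(SkelccaError):
    """A linear system is rank deficient beyond the documented tolerance."""
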