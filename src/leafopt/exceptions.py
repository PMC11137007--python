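"""Exception hierarchy for leafopt."""


class LeafoptError(Exception):
    """Base class for all leafopt errors."""


class DomainError(LeafoptError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigError(LeafoptError, ValueError):
    """A configuration file is missing, malformed, or schema-invalid."""


class SolverError(LeafoptError, RuntimeError):
    """Numerical integration failed (non-finite state, no convergence)."""


class ConsistencyError(LeafoptError, RuntimeError):
    """An internal cross-check failed, signalling a solver fault."""


class UndefinedPeakError(LeafoptError, ValueError):
    """A peak-location diagnostic was requested where no peak exists."""


class ElasticityUndefinedError(LeafoptError, ValueError):
    """Elasticity of a quantity that is zero (or pinned) at the base point."""
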