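"""Exception types shared across the package."""


class GroupSigmaError(ValueError):
    """Base class for all groupsigma errors."""


class InvalidParameterError(GroupSigmaError):
    """A parameter is outside its admissible domain (e.g. M < 2 for global migration)."""


class DegenerateParameterError(GroupSigmaError):
    """Parameters for which the requested quantity is a 0/0 form (e.g. sigma at u = 0)."""


class ConfigurationError(GroupSigmaError):
    """A simulation configuration that cannot be run as stated (e.g. negative fitness)."""


class ReducibleChainError(GroupSigmaError):
    """The requested Markov chain is not irreducible, so no unique stationary law exists."""
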