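"""Exception hierarchy shared across the package."""


class FertisimError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FertisimError, ValueError):
    """An input violates a physical or mathematical precondition."""


class ConfigurationError(FertisimError, ValueError):
    """A configuration file or parameter set is inconsistent or incomplete."""


class StateError(FertisimError, RuntimeError):
    """An operation was applied to a state that cannot accept it."""


class FitError(FertisimError, RuntimeError):
    """A calibration routine failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
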