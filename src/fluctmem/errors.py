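"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value or key is invalid; the message names the key."""


class IntegrationBlowupError(FloatingPointError):
    """The simulated state left the representable range.

    Carries the simulation time at which non-finite values first appeared.
    """

    def __init__(self, message: str, t: float):
        super().__init__(message)
        self.t = t


class DegenerateInputError(ValueError):
    """An input is degenerate for the requested operation (e.g. a zero-norm
    spanning vector for a plane overlap)."""


class MissingArtifactError(IOError):
    """A run directory is missing an expected artifact; the message names it."""
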