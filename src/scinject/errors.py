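"""Exception types shared across the simulator."""


class InvalidInputError(ValueError):
    """A physical quantity is outside its admissible domain."""


class ConfigurationError(ValueError):
    """A scenario or model configuration is inconsistent or unknown."""
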