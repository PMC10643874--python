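"""Shared exception types."""


class ConfigurationError(ValueError):
    """A user-supplied configuration violates its invariants.

    The message names the offending field.
    """


class InsufficientDataError(RuntimeError):
    """A computation has too little data to produce a reliable result."""
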