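"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A parameter or input violates a documented invariant."""


class ChannelNotFoundError(KeyError):
    """A requested image channel is not present in the event."""


class ConstantChannelError(ValueError):
    """Pearson correlation is undefined: a channel is constant within the mask."""
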