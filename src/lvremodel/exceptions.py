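"""Package-wide exception types."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(ValueError):
    """A file could not be read as the expected format.

    The message names the offending header field or structural problem.
    """


class DegenerateEntropyError(ValueError):
    """A similarity metric was asked to operate on a constant image."""
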