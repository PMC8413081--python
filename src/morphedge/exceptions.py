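"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or type invariant."""


class ImageIOError(OSError):
    """A file could not be read or written as a grayscale image."""
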