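"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant.

    The message always names the offending field, cell or pair so that
    problems in large tables can be located without a debugger.
    """


class ChecksumError(RuntimeError):
    """Raised when a packaged data file does not match its recorded digest."""
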