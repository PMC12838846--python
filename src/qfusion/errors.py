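"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition.

    The CLI maps this to exit code 2; everything else is a runtime failure.
    """
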