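"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Invalid user input or configuration (CLI exit code 2)."""
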