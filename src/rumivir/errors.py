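"""Exception types shared across the package."""


class DesignError(ValueError):
    """An experimental-design layout is impossible or inconsistent."""


class InputError(ValueError):
    """An input table violates a precondition (missing rows, bad values)."""
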