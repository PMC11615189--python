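"""Shared exception types with CLI exit-code semantics."""


class ConfigError(ValueError):
    """Invalid configuration; names the offending field. Exit code 2."""


class InputError(ValueError):
    """Malformed or missing input data. Exit code 3."""


class NumericalError(RuntimeError):
    """Numerical failure (non-convergence, degenerate fit). Exit code 4."""
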