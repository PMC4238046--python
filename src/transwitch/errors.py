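"""Exception hierarchy shared across the pipeline.

Three families so the CLI can map failures to distinct exit codes:
configuration problems (bad parameters, unknown methods), data problems
(malformed or inconsistent input files), and numerical problems
(degenerate statistics that cannot be guarded).
"""


class TranswitchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TranswitchError):
    """Invalid parameter values or unknown method names."""


class DataValidationError(TranswitchError):
    """Malformed, inconsistent or out-of-contract input data."""


class NumericalError(TranswitchError):
    """Degenerate numerical situation that has no guarded fallback."""
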