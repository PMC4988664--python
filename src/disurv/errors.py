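"""Exception hierarchy shared by all disurv modules.

The three classes map one-to-one onto the CLI exit codes: usage/configuration
problems (exit 2), data validation failures (exit 3) and numerical failures
during model fitting (exit 4).
"""


class DisurvError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(DisurvError):
    """A parameter, column name or option is wrong before any computation."""

    exit_code = 2


class ValidationError(DisurvError):
    """The data violate an invariant (negative time, bad status code, ...)."""

    exit_code = 3


class NumericalError(DisurvError):
    """An iterative fit failed (non-convergence, non-finite loss, ...)."""

    exit_code = 4
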