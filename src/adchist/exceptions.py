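"""Exception hierarchy with stable CLI exit codes.

ValidationError maps to exit code 2 (bad inputs or configuration),
NumericalError to exit code 3 (a computation failed on valid inputs).
"""


class AdchistError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(AdchistError):
    """Invalid input, configuration, or violated precondition."""

    exit_code = 2


class NumericalError(AdchistError):
    """A numerical procedure failed on otherwise valid inputs."""

    exit_code = 3
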