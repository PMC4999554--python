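"""Exception hierarchy shared across the pipeline.

``InputError`` maps to CLI exit code 2, ``ComputationError`` to 3.
"""


class PiptypeError(Exception):
    """Base class for all piptype errors."""


class InputError(PiptypeError):
    """Malformed or inconsistent user input (bad alphabet, empty file, ...)."""

    exit_code = 2


class ComputationError(PiptypeError):
    """A computation could not produce a defined result (e.g. all-gap identity)."""

    exit_code = 3
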