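"""Exception hierarchy.

``InputError`` covers malformed user inputs (files, sequences, configs);
``ComputationError`` covers failures arising during model fitting or
evaluation. The CLI maps them to distinct exit codes.
"""


class AarspredError(Exception):
    """Base class for all package errors."""


class InputError(AarspredError):
    """Malformed or inconsistent input (file format, sequence, config)."""


class FormatError(InputError):
    """A file does not conform to its declared format."""


class ValidationError(InputError):
    """A value violates a domain invariant (alphabet, ranges, ids)."""


class SpecMismatchError(InputError):
    """A feature vector's spec does not match the model's spec."""


class ComputationError(AarspredError):
    """Failure while fitting, scoring, or evaluating."""
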