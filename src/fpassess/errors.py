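"""Exception hierarchy.

Distinguishing schema problems (wrong file shape), validation problems
(well-formed but illegal values), and missing-input problems lets the CLI
map them onto distinct exit codes.
"""


class FPAssessError(Exception):
    """Base class for all package errors."""


class SchemaError(FPAssessError):
    """Input file does not match the documented schema."""


class ValidationError(FPAssessError):
    """Values are out of range or internally inconsistent."""


class MissingInputError(FPAssessError):
    """A required input (e.g. the rest session or a trained model) is absent."""
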