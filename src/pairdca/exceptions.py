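"""Exception hierarchy for the pairdca pipeline.

Every error raised deliberately by the package derives from
:class:`PairdcaError`, so callers (and the CLI) can distinguish pipeline
failures from programming errors.
"""


class PairdcaError(Exception):
    """Base class for all pairdca errors."""


class FormatError(PairdcaError):
    """Malformed input file (FASTA, PDB, pair table, report)."""


class EmptyInputError(PairdcaError):
    """An operation received no usable records."""


class DuplicateIdError(PairdcaError):
    """A sequence identifier occurs more than once within one file."""


class ParameterError(PairdcaError):
    """A numeric parameter is outside its documented range."""


class DegenerateInputError(PairdcaError):
    """Input is structurally valid but unusable (e.g. all-gap reference)."""


class InconsistencyError(PairdcaError):
    """Two artifacts that must describe the same alignment do not."""


class NumericalError(PairdcaError):
    """A numerical step failed (e.g. singular correlation matrix)."""


class ConvergenceError(PairdcaError):
    """An iterative solver did not converge within its iteration budget."""


class ResidueLookupError(PairdcaError):
    """A residue requested from a structure does not exist."""


class ConfigurationError(PairdcaError):
    """Pipeline configuration is invalid or references missing files."""
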