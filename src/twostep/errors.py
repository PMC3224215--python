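"""Exception hierarchy shared across the package.

Split into "the input was malformed" (:class:`InputError`) and "the numerics
broke down" (:class:`NumericalError`) so the command line layer can map them
to distinct exit codes.
"""


class TwoStepError(Exception):
    """Base class for all package-specific errors."""


class InputError(TwoStepError):
    """Malformed user input: bad files, bad sequences, shape mismatches."""


class EncodingError(InputError):
    """A peptide sequence could not be encoded (unknown residue etc.)."""


class ModelFormatError(InputError):
    """A serialized model file is corrupt or of an unsupported version."""


class NumericalError(TwoStepError):
    """Optimization or linear algebra failed (singular system, divergence)."""
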