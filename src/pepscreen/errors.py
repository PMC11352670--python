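"""Exception hierarchy shared across the package.

Each error family maps to a distinct CLI exit code so shell pipelines can
distinguish malformed input from broken cross-references or schema drift.
"""


class PepscreenError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(PepscreenError):
    """Malformed or missing input data (bad value, bad residue, bad file)."""

    exit_code = 3


class CrossReferenceError(PepscreenError):
    """An identifier in one input has no counterpart in another."""

    exit_code = 4


class SchemaError(PepscreenError):
    """A structured file does not conform to its published schema."""

    exit_code = 5


class PredictionError(PepscreenError):
    """A predictor could not produce a prediction for a peptide."""

    exit_code = 6
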