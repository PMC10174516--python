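"""Exception hierarchy shared across the package."""


class GasSelectError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GasSelectError, ValueError):
    """A table is missing a required column or has an inconsistent layout."""


class ParseError(GasSelectError, ValueError):
    """A cell could not be parsed; the message names the row and column."""


class EncodingError(GasSelectError, ValueError):
    """A column cannot be encoded under the declared rules."""


class StratificationError(GasSelectError, ValueError):
    """A class is too small to stratify a split."""


class ParameterError(GasSelectError, ValueError):
    """An argument is outside its documented domain."""


class EvaluationError(GasSelectError, RuntimeError):
    """An objective or classifier evaluation failed; the message names the agent/mask."""


class DegenerateTrainingError(GasSelectError, ValueError):
    """Training data contains fewer than two classes."""


class DegenerateTestError(GasSelectError, ValueError):
    """A paired statistical test has no usable differences."""


class PairingError(GasSelectError, ValueError):
    """Result rows for two models could not be paired run-for-run."""


class SelectionDegenerateError(GasSelectError, RuntimeError):
    """The optimizer's best position binarizes to an all-zero mask."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class RegistryError(GasSelectError, KeyError):
    """An unknown classifier name was requested."""
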