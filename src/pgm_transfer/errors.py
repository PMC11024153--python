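"""Exception hierarchy.

Exit codes used by the CLI: configuration errors map to 2, data errors to 3
and numeric errors to 4.
"""


class PGMTransferError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(PGMTransferError):
    """Invalid configuration, missing columns, incompatible settings."""

    exit_code = 2


class ComparabilityError(ConfigurationError):
    """Objects produced under different model/restart configurations."""


class DataError(PGMTransferError):
    """Problems with the data itself (empty datasets, unusable batches)."""

    exit_code = 3


class FeaturizationError(DataError):
    """A SMILES string could not be turned into a molecular graph."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"cannot featurize {smiles!r}: {reason}")


class SplitError(DataError):
    """Scaffold splitting impossible for the given dataset."""


class EvaluationError(DataError):
    """No subtask could be scored."""


class NumericError(PGMTransferError):
    """Non-finite gradients or degenerate numerical quantities."""

    exit_code = 4
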