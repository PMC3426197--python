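"""Exception hierarchy for the svmt package."""


class SVMTError(Exception):
    """Base class for all svmt-specific errors."""


class DataError(SVMTError, ValueError):
    """Invalid expression data: missing values, duplicate ids, bad labels."""


class FitError(SVMTError, ValueError):
    """The SVM fit contract cannot be satisfied (single class, no genes)."""


class NoSupportVectorError(SVMTError, ValueError):
    """A class has no support vectors above tolerance; SV-based criteria undefined."""


class LadderError(SVMTError, ValueError):
    """Invalid elimination-ladder parameters."""


class EliminationError(SVMTError, RuntimeError):
    """A criterion failed mid-elimination; message carries the ladder level."""


class FoldError(SVMTError, ValueError):
    """A cross-validation fold is degenerate (single class in its training part)."""
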