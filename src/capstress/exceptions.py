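"""Exception hierarchy shared across the package."""


class CapstressError(Exception):
    """Base class for all package-specific errors."""


class InvalidProtocolError(CapstressError, ValueError):
    """A test protocol violates its invariants (e.g. stress after gastric emptying)."""


class InvalidDesignError(CapstressError, ValueError):
    """A design specification would produce physically impossible factor settings."""


class SingularFitError(CapstressError, ValueError):
    """The design matrix is rank-deficient; the polynomial model cannot be fitted."""


class NotFittedError(CapstressError, RuntimeError):
    """A model was queried before fitting."""


class DegenerateTrainingError(CapstressError, ValueError):
    """Classifier training data contain a single class only."""


class CVConfigError(CapstressError, ValueError):
    """Cross-validation configuration impossible for the data (fewer runs than folds)."""


class InputError(CapstressError, ValueError):
    """Mismatched or malformed inputs to an operation."""


class FormatError(InputError):
    """A file does not conform to the expected on-disk format."""
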