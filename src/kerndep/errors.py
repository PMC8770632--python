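"""Exception hierarchy shared across the pipeline stages."""


class KerndepError(Exception):
    """Base class for all package-specific errors."""


class FormatError(KerndepError):
    """An input file does not conform to the expected dialect."""


class EmptyInputError(KerndepError):
    """An input that must contain data is empty."""


class EmptyNetworkError(KerndepError):
    """No interactions survive mapping/filtering."""


class ParameterError(KerndepError, ValueError):
    """A parameter is outside its admissible range."""


class ValidationError(KerndepError, ValueError):
    """A data value violates a documented contract."""


class LookupError_(KerndepError, KeyError):
    """A requested gene/marker/column is absent."""


class SelectionError(KerndepError):
    """Predictor selection produced an empty or unusable set."""


class DegenerateFitError(KerndepError):
    """The response is constant on the training split; no model can be fit."""


class EvaluationError(KerndepError):
    """Ensemble evaluation is impossible (e.g. no covered cell lines)."""
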