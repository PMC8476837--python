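"""Exception hierarchy for the metabmr pipeline."""


class MetabMRError(Exception):
    """Base class for all metabmr errors."""


class ConfigurationError(MetabMRError):
    """A configuration problem, e.g. a required column mapping is missing."""


class InputError(MetabMRError):
    """Malformed or invalid input data."""


class AnalysisError(MetabMRError):
    """An analysis step could not be carried out on the given data."""


class InsufficientInstrumentsError(AnalysisError):
    """Fewer instruments than the estimator's minimum."""


class UndefinedRatioError(AnalysisError):
    """Wald ratio requested for a SNP with zero exposure effect."""
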