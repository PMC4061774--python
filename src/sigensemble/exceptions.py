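"""Exception hierarchy for sigensemble."""


class SigEnsembleError(Exception):
    """Base class for all sigensemble errors."""


class ConfigError(SigEnsembleError):
    """An invalid configuration field; the message names the field."""


class DesignError(SigEnsembleError):
    """An inconsistent pipeline-variant design (e.g. a log2 variant whose
    normal-space partner is absent)."""


class InputError(SigEnsembleError):
    """Malformed or inconsistent input data (mismatched patient sets,
    missing vote cells, non-finite values...)."""


class ParseError(InputError):
    """A file could not be parsed; the message carries the offending line
    or identifier."""


class SignatureCoverageError(InputError):
    """No gene of a signature is present in an expression matrix."""


class DegenerateInputError(SigEnsembleError):
    """Statistically degenerate input (e.g. zero-variance paired
    differences) for which the requested statistic is undefined."""


class PairingError(SigEnsembleError):
    """Pipeline variants could not be paired off for a matched comparison."""


class ModelError(SigEnsembleError):
    """A linear model could not be estimated (rank deficiency, ...)."""
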