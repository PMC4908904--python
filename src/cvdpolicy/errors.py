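"""Exception hierarchy for the policy model."""


class CVDPolicyError(Exception):
    """Base class for all package errors."""


class ValidationError(CVDPolicyError):
    """An input object violates one of its invariants."""


class LoadError(CVDPolicyError):
    """A parameter directory or tabular file could not be loaded."""


class FitError(CVDPolicyError):
    """An estimation routine failed (rank deficiency, separation, ...)."""


class EngineError(CVDPolicyError):
    """The state-transition engine received malformed inputs at run time."""


class AnalysisError(CVDPolicyError):
    """An economic-evaluation or uncertainty routine could not complete."""
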