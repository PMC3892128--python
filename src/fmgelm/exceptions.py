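"""Exception hierarchy for the fmgelm package."""


class FmgElmError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FmgElmError, ValueError):
    """A parameter or configuration value violates its invariants."""


class ProtocolError(FmgElmError, ValueError):
    """A training/testing session does not satisfy the experimental protocol."""


class EvaluationError(FmgElmError, ValueError):
    """An evaluation step cannot be computed from the given session."""


class ParseError(FmgElmError, ValueError):
    """A session or model file is malformed."""
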