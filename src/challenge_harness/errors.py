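"""Exception hierarchy for the challenge harness."""


class HarnessError(Exception):
    """Base class for all harness-specific errors."""


class ParameterError(HarnessError, ValueError):
    """A caller supplied an out-of-range or ill-typed parameter."""


class FormatError(HarnessError, ValueError):
    """A file on disk violates the declared format or data dictionary."""


class ManifestError(HarnessError, ValueError):
    """A submission manifest is missing or malforms a required field."""


class RegistrationError(HarnessError, ValueError):
    """A submission cannot be registered (duplicate tag, second final, ...)."""


class EvaluationError(HarnessError, RuntimeError):
    """A repeated-evaluation cycle failed (run failure or invalid predictions)."""


class RankingError(HarnessError, ValueError):
    """A ranking input is incomplete or inconsistent."""
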