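"""Exception hierarchy for the awia package.

All package-specific failures derive from :class:`WiaError` so callers can
catch one base class; subclasses distinguish bad configuration from bad data.
"""


class WiaError(Exception):
    """Base class for all awia errors."""


class ConfigError(WiaError, ValueError):
    """Invalid analysis configuration (window sizes, fractions, dt...)."""


class ResolutionError(ConfigError):
    """Requested sampling interval too coarse for the beat."""


class DomainError(WiaError, ValueError):
    """Input value outside its physical/mathematical domain."""


class SignalQualityError(WiaError):
    """The waveform does not support the requested operation
    (e.g. no systolic upstroke to delimit)."""


class InsufficientDataError(WiaError):
    """Too few samples for a statistically meaningful estimate."""


class SpecError(WiaError, ValueError):
    """A simulation specification is internally inconsistent."""


class ParseError(WiaError, ValueError):
    """A waveform or cohort file violates the expected format."""


class PipelineError(WiaError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
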