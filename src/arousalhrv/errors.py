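"""Exception hierarchy shared across the pipeline."""


class ArousalHrvError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ArousalHrvError):
    """A file could not be parsed as the expected format."""


class ChannelNotFoundError(FormatError):
    """The requested signal channel is absent from the recording."""


class ValidationError(ArousalHrvError, ValueError):
    """Input data violates a documented invariant."""


class ScenarioError(ValidationError):
    """A synthetic scenario is infeasible or physiologically out of range."""


class CoverageError(ValidationError):
    """An event falls outside the span covered by the hypnogram."""


class InsufficientBeatsError(ArousalHrvError):
    """Too few R peaks in a segment for the requested statistic."""


class DegenerateSampleError(ArousalHrvError):
    """A statistical routine received a sample it cannot operate on."""


class DegenerateLabelsError(ValidationError):
    """ROC analysis needs both positive and negative labels."""
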