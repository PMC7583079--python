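"""Exception hierarchy shared across the platform."""


class TemposigError(Exception):
    """Base class for all platform errors."""


class TimeAxisError(TemposigError):
    """Time header is not strictly increasing or is unparseable."""


class DuplicateIdError(TemposigError):
    """Variable identifiers are not unique."""


class AllMissingRowError(TemposigError):
    """A variable has no observed value at any time point."""

    def __init__(self, variable_ids):
        self.variable_ids = list(variable_ids)
        super().__init__(
            f"rows with no observed values: {', '.join(map(str, self.variable_ids))}"
        )


class ParameterError(TemposigError):
    """A parameter is outside its valid range or combination."""


class InsufficientPointsError(TemposigError):
    """Too few observed points for a cubic spline fit (minimum 4)."""


class NoEligibleVariablesError(TemposigError):
    """No variable qualifies for cross-validated smoothing selection."""


class ShapeError(TemposigError):
    """Two matrices that must align do not."""


class DegenerateCenterError(TemposigError):
    """A cluster center is constant; the membership regression is undefined."""


class ConfigError(TemposigError):
    """Unknown or invalid configuration key."""


class PipelineError(TemposigError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
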