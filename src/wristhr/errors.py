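"""Exception hierarchy for the wristhr pipeline."""


class WristHRError(Exception):
    """Base class for all wristhr errors."""


class FormatError(WristHRError):
    """A file does not follow the expected on-disk dialect."""


class DataError(WristHRError):
    """Loaded data violates a basic sanity invariant (NaN/Inf, short channels)."""


class ParameterError(WristHRError, ValueError):
    """An argument is outside its valid domain."""


class TooShortError(ParameterError):
    """A record is shorter than a single analysis window."""


class DegenerateChannelError(WristHRError):
    """A channel has (numerically) zero variance and cannot be standardized."""


class DivergenceError(WristHRError):
    """The adaptive filter produced non-finite weights."""

    def __init__(self, step: int, mu: float):
        self.step = step
        self.mu = mu
        super().__init__(
            f"LMS weights became non-finite at step {step}; "
            f"try a smaller step size than mu={mu}"
        )


class TrainingError(WristHRError):
    """The peak classifier cannot be trained or loaded."""


class InitializationError(WristHRError):
    """The tracker found no candidate peak in the first window."""


class StateError(WristHRError):
    """The tracker state is used before it is valid."""


class PipelineError(WristHRError):
    """A stage failed while estimating a session; carries window and stage."""

    def __init__(self, window_index: int, stage: str, cause: Exception):
        self.window_index = window_index
        self.stage = stage
        self.__cause__ = cause
        super().__init__(f"window {window_index}, stage '{stage}': {cause}")
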