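"""Exception hierarchy shared by all emgaug modules."""


class EmgaugError(Exception):
    """Base class for all errors raised by emgaug."""


class InvalidArgumentError(EmgaugError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(EmgaugError, ValueError):
    """The input is structurally valid but degenerate for the operation
    (e.g. a constant signal passed to min-max rescaling, or a
    zero-variance envelope passed to normalized cross-correlation)."""


class ConfigurationError(EmgaugError, ValueError):
    """A network or pipeline configuration is internally inconsistent
    (e.g. a convolution shape chain that cannot reach the output length)."""


class DataInsufficiencyError(EmgaugError, ValueError):
    """Not enough data to run the requested operation
    (e.g. fewer training windows than the batch size)."""


class TrainingDivergedError(EmgaugError, RuntimeError):
    """A training loop produced a non-finite loss; carries the epoch/step."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class PipelineError(EmgaugError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


class CsvFormatError(EmgaugError, ValueError):
    """A delimited EMG file could not be parsed (missing, empty, ragged,
    or containing non-numeric cells)."""
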