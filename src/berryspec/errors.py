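"""Exception types shared across the pipeline stages."""


class BerrySpecError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BerrySpecError):
    """A file on disk does not match the expected container layout."""


class CalibrationError(BerrySpecError):
    """Reference frames cannot be used to calibrate (e.g. white == dark)."""


class SegmentationError(BerrySpecError):
    """No fruit region could be isolated from the image."""


class DegenerateSpectrumError(BerrySpecError):
    """A spectrum is degenerate for the requested correction (e.g. zero
    slope against the MSC reference)."""


class AlignmentError(BerrySpecError):
    """Feature blocks refer to different samples or sample orders."""


class ContractError(BerrySpecError):
    """A fitted model was handed inputs of the wrong width."""


class PipelineStageError(BerrySpecError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
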