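"""Exception hierarchy for the TSMR pipeline."""


class TSMRError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TSMRError):
    """A configuration (column map, run config, thresholds) is invalid."""


class RowParseError(TSMRError):
    """A data row could not be parsed; carries the 1-based file line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class InvalidAlleleError(TSMRError, ValueError):
    """An allele is outside the {A, C, G, T} alphabet."""


class EmptyIntersectionError(TSMRError):
    """Exposure and outcome summary statistics share no SNPs."""


class LDLookupError(TSMRError, KeyError):
    """A SNP required for clumping is missing from the LD matrix."""


class InsufficientInstrumentsError(TSMRError):
    """An estimator or sensitivity test needs more instruments than supplied."""


class DegenerateCorrectionError(TSMRError):
    """Outlier correction would remove every instrument."""


class PipelineError(TSMRError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
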