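"""Exception hierarchy for ystrkit.

Every contract violation raises a distinct, named error so callers can
distinguish malformed input from degenerate-but-valid data.
"""


class YstrkitError(Exception):
    """Base class for all ystrkit errors."""


class TableFormatError(YstrkitError):
    """Header is missing a required column or names an unknown locus."""


class AlleleParseError(YstrkitError):
    """An allele token could not be parsed as a repeat designation."""


class DuplicateSampleError(YstrkitError):
    """Two rows share a SampleID."""


class MissingDataError(YstrkitError):
    """An operation that requires complete calls met a missing one."""


class EmptyLocusError(YstrkitError):
    """All calls at a locus are missing."""


class EmptyTableError(YstrkitError):
    """No haplotype with complete calls is available."""


class UndefinedDiversityError(YstrkitError):
    """Diversity requested with fewer than two observations."""


class DegenerateGroupError(YstrkitError):
    """An AMOVA group contributes no usable haplotype."""


class UndefinedRstError(YstrkitError):
    """Both variance components are zero: R_ST is undefined."""


class InvalidParameterError(YstrkitError):
    """A numeric or keyword parameter is outside its valid range."""


class PanelMismatchError(YstrkitError):
    """Inputs do not share a common locus panel."""


class TooFewTaxaError(YstrkitError):
    """Neighbor joining needs at least three labels."""


class InvalidMatrixError(YstrkitError):
    """A distance matrix is asymmetric, non-square, or otherwise invalid."""


class EmptyPanelError(YstrkitError):
    """A reference panel contains no labeled haplotypes."""


class ConstructiveFailureError(YstrkitError):
    """Requested synthetic structure cannot be constructed."""


class PipelineStageError(YstrkitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
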