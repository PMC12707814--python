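"""Exception hierarchy for glomquant.

All package-specific failures derive from :class:`GlomquantError` so callers
(and the CLI) can distinguish validation problems from stage failures.
"""


class GlomquantError(Exception):
    """Base class for all glomquant errors."""


class ValidationError(GlomquantError):
    """Invalid configuration or parameter values."""


class InfeasibleGeometryError(GlomquantError):
    """Requested geometry cannot fit in the imaging volume."""


class DegenerateGeometryError(GlomquantError):
    """Geometry with zero measure where positive measure is required."""


class MissingChannelError(GlomquantError, KeyError):
    """A named channel is absent from the imaging volume."""


class MetadataError(GlomquantError):
    """Required acquisition metadata (e.g. voxel sizes) is absent."""


class UnevaluablePunctumError(GlomquantError):
    """Co-localisation windows fall outside the volume for this punctum."""


class EmptyInputError(GlomquantError):
    """An operation requiring at least one element received none."""


class FitFailureError(GlomquantError):
    """A model fit did not converge or produced out-of-range parameters."""


class InconsistentEstimateError(GlomquantError):
    """Derived physical quantities violate model constraints (e.g. R_m <= 0)."""


class InsufficientDataError(GlomquantError):
    """Too few observations for the requested statistical test."""


class CannotEstimateError(GlomquantError):
    """Design does not identify the requested model (e.g. one animal per group)."""


class UnclassifiableWaveformError(GlomquantError):
    """Voltage trace has no suprathreshold upstroke to classify."""


class StageError(GlomquantError):
    """A pipeline stage failed; carries the stage name and input identifier."""

    def __init__(self, stage: str, ident: str, cause: Exception):
        self.stage = stage
        self.ident = ident
        self.cause = cause
        super().__init__(f"stage {stage!r} failed on {ident!r}: {cause}")
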