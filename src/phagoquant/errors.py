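"""Exception hierarchy shared across the package.

Undefined metrics (zero denominators) are deliberately errors, not zeros:
a Ph index with no apoptotic cells is *unestimable*, and report layers
translate the error into a missing value with a reason code.
"""


class PhagoquantError(Exception):
    """Base class for all package errors."""


class ValidationError(PhagoquantError, ValueError):
    """Input violates a documented schema or invariant."""


class UndefinedMetricError(PhagoquantError):
    """A metric is mathematically undefined for this input (e.g. zero denominator).

    Parameters
    ----------
    metric : name of the metric that could not be computed.
    reason : short machine-readable reason code (e.g. ``"zero_apoptotic_cells"``).
    sample_id : optional sample the error refers to.
    """

    def __init__(self, metric: str, reason: str, sample_id: str | None = None):
        self.metric = metric
        self.reason = reason
        self.sample_id = sample_id
        where = f" (sample {sample_id!r})" if sample_id else ""
        super().__init__(f"{metric} undefined{where}: {reason}")


class InfeasibleError(PhagoquantError):
    """The input data violate an assumption required for the inference."""


class GapError(PhagoquantError):
    """A process is missing from a z-slice required by the center-point rule."""
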