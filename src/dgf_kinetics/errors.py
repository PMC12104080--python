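"""Exception hierarchy for dgf-kinetics."""


class DgfKineticsError(Exception):
    """Base class for all package errors."""


class ConfigError(DgfKineticsError):
    """A configuration object violates one of its invariants."""


class SeriesError(DgfKineticsError):
    """A creatinine series is unusable for classification."""


class IndeterminateSeverityError(DgfKineticsError):
    """Follow-up ended before POD 21 without a resolution run.

    The severity group cannot be assigned: the duration is censored inside
    the moderate bin, so 'moderate' and 'severe' are indistinguishable.
    """


class CurveError(DgfKineticsError):
    """A renogram curve or its fit window is invalid."""


class FitError(DgfKineticsError):
    """The two-segment slope fit is undefined on the given data."""


class DerivationError(DgfKineticsError):
    """A biomarker derivation received a non-positive or degenerate input."""


class SeparationError(DgfKineticsError):
    """Logistic regression did not converge (perfect or quasi-separation).

    The maximum-likelihood odds ratio diverges; re-fit with ``firth=True``
    for a penalized estimate, or report the odds ratio as unbounded.
    """


class CohortIOError(DgfKineticsError):
    """A cohort file could not be parsed."""


class PipelineError(DgfKineticsError):
    """A pipeline stage failed; carries the stage name and offending unit."""

    def __init__(self, stage: str, message: str, patient_id: str | None = None,
                 pod: int | None = None):
        self.stage = stage
        self.patient_id = patient_id
        self.pod = pod
        where = f" (patient={patient_id}" + (f", pod={pod})" if pod is not None else ")") \
            if patient_id else ""
        super().__init__(f"stage '{stage}' failed{where}: {message}")
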