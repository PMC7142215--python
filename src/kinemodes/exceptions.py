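"""Errors raised by the waveform-preparation and modeling pipeline."""


class KinemodesError(ValueError):
    """Base class for pipeline errors."""


class DegenerateTrialError(KinemodesError):
    """The knee-flexion channel carries no usable extremum (e.g. constant)."""


class UnusableTrialError(KinemodesError):
    """The trial cannot be aligned (peak flexion at a recording boundary)."""


class NoUsableTrialsError(KinemodesError):
    """Every trial of a cohort was discarded by filtering."""


class DegenerateObservationError(KinemodesError):
    """An observation (row of the training matrix) has zero variance."""
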