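"""Alignment, trimming, and time-normalization of raw trials.

Recorded squat/lunge repetitions start and end with irrelevant standing
transients, and their durations differ between subjects and repetitions.
Before any statistical modeling, each trial is

1. *trimmed* to the window around peak knee flexion in which the flexion
   angle exceeds the standing baseline by at least 5 % of the trial's
   flexion range,
2. *aligned* so the frame of peak knee flexion defines 50 % motion
   progress, and
3. *resampled* by linear interpolation onto a common 101-instant progress
   grid (51 evenly spaced samples over 0-50 %, 50 more over 51-100 %).

The aligned 6x101 matrices of a subject's retained repetitions are averaged
into one matrix per subject, flattened into 606-long feature vectors
(channel-major, hip before knee), and stacked column-wise into the training
matrix.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateTrialError, NoUsableTrialsError, UnusableTrialError
from .trials import (
    CHANNELS,
    N_CHANNELS,
    N_FEATURES,
    N_INSTANTS,
    AlignedSubject,
    KineticTrial,
    TrainingMatrix,
)

__all__ = [
    "detect_peak_flexion",
    "trim_flexion_window",
    "filter_closed_chain",
    "align_resample",
    "assemble_feature_vector",
    "feature_vector_to_channels",
    "average_aligned",
    "build_training_matrix",
    "prepare_cohort",
]

#: Fraction of the flexion range above the minimum that defines the trim window.
DEFAULT_TRIM_THRESHOLD = 0.05


def detect_peak_flexion(flexion: np.ndarray) -> int:
    """Index of the (unique-valued) global knee-flexion maximum.

    Ties are broken toward the earliest frame.  A constant sequence has no
    extremum and raises :class:`DegenerateTrialError`; a peak on the first or
    last frame leaves no descent/ascent to align and raises
    :class:`UnusableTrialError`.
    """
    flexion = np.asarray(flexion, dtype=float).ravel()
    if flexion.size < 3:
        raise DegenerateTrialError("flexion sequence must have at least 3 frames")
    if not np.all(np.isfinite(flexion)):
        raise DegenerateTrialError("flexion sequence contains non-finite values")
    if np.ptp(flexion) == 0.0:
        raise DegenerateTrialError("flexion sequence is constant; no peak to align")
    peak = int(np.argmax(flexion))
    if peak == 0 or peak == flexion.size - 1:
        raise UnusableTrialError("peak knee flexion lies on a recording boundary")
    return peak


def trim_flexion_window(
    flexion: np.ndarray, threshold_fraction: float = DEFAULT_TRIM_THRESHOLD
) -> tuple[int, int]:
    """Half-open frame range ``[start, stop)`` of the motion window.

    The window is the maximal contiguous run of frames containing the flexion
    peak in which flexion exceeds ``min + threshold_fraction * range``, which
    cuts the near-standing plateaus at both ends of a recording.
    """
    flexion = np.asarray(flexion, dtype=float).ravel()
    peak = detect_peak_flexion(flexion)
    thr = flexion.min() + threshold_fraction * np.ptp(flexion)
    above = flexion > thr
    start = peak
    while start > 0 and above[start - 1]:
        start -= 1
    stop = peak + 1
    while stop < flexion.size and above[stop]:
        stop += 1
    return start, stop


def filter_closed_chain(trials: list[KineticTrial]) -> list[KineticTrial]:
    """Drop lunge trials whose forward foot left its force plate.

    The closed-chain rule applies to the lunge only; squat trials pass
    through unchanged regardless of their flag.
    """
    kept = [t for t in trials if t.motion != "lunge" or t.closed_chain]
    if not kept:
        raise NoUsableTrialsError("no usable trials remain after closed-chain filtering")
    return kept


def align_resample(
    trial: KineticTrial, threshold_fraction: float | None = DEFAULT_TRIM_THRESHOLD
) -> AlignedSubject:
    """Trim, align, and resample one trial onto the 101-instant progress grid.

    Linear interpolation places 51 evenly spaced samples over [window start,
    peak] and 50 more over (peak, window end]; the output at instant 50 is the
    raw channel value at the peak frame, exactly.

    ``threshold_fraction=None`` skips trimming — appropriate for data whose
    standing transients were already removed, and what makes re-aligning an
    already-aligned 101-instant trial the identity map.
    """
    if threshold_fraction is None:
        detect_peak_flexion(trial.knee_flexion)  # validate peak interior
        start, stop = 0, trial.n_frames
    else:
        start, stop = trim_flexion_window(trial.knee_flexion, threshold_fraction)
    flexion = trial.knee_flexion[start:stop]
    forces = trial.forces[:, start:stop]
    peak = int(np.argmax(flexion))
    if peak == 0 or peak == flexion.size - 1:
        raise UnusableTrialError("peak knee flexion lies on the trimmed-window boundary")
    last = flexion.size - 1
    positions = np.concatenate(
        [np.linspace(0.0, peak, N_INSTANTS // 2 + 1), np.linspace(peak, last, N_INSTANTS // 2 + 1)[1:]]
    )
    frames = np.arange(flexion.size, dtype=float)
    values = np.empty((N_CHANNELS, N_INSTANTS))
    for c in range(N_CHANNELS):
        values[c] = np.interp(positions, frames, forces[c])
        values[c, N_INSTANTS // 2] = forces[c, peak]  # pin exactly, no round-off
    return AlignedSubject(subject_id=trial.subject_id, motion=trial.motion, values=values)


def assemble_feature_vector(subject: AlignedSubject) -> np.ndarray:
    """Flatten a 6x101 aligned matrix into the 606-long feature vector.

    Channel-major order: elements 0..100 are hip x over 0..100 % progress,
    elements 101..201 hip y, ..., elements 505..605 knee z.
    """
    return subject.values.reshape(N_FEATURES).copy()


def feature_vector_to_channels(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`assemble_feature_vector`: reshape 606 -> 6x101."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (N_FEATURES,):
        raise ValueError(f"expected a length-{N_FEATURES} vector, got {vector.shape}")
    return vector.reshape(N_CHANNELS, N_INSTANTS)


def average_aligned(subjects: list[AlignedSubject]) -> AlignedSubject:
    """Average the aligned matrices of repeated trials of one subject."""
    if not subjects:
        raise NoUsableTrialsError("cannot average an empty list of aligned trials")
    ids = {s.subject_id for s in subjects}
    motions = {s.motion for s in subjects}
    if len(ids) != 1 or len(motions) != 1:
        raise ValueError("can only average repetitions of a single subject and motion")
    values = np.mean([s.values for s in subjects], axis=0)
    return AlignedSubject(subject_id=subjects[0].subject_id, motion=subjects[0].motion, values=values)


def build_training_matrix(subjects: list[AlignedSubject]) -> TrainingMatrix:
    """Stack subject feature vectors column-wise, in input order."""
    if len(subjects) < 4:
        raise ValueError(f"need at least 4 subjects to build a training matrix, got {len(subjects)}")
    motions = {s.motion for s in subjects}
    if len(motions) != 1:
        raise ValueError(f"subjects mix motions {sorted(motions)}; model one motion at a time")
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in training cohort")
    X = np.column_stack([assemble_feature_vector(s) for s in subjects])
    return TrainingMatrix(X=X, subject_ids=ids, motion=motions.pop())


def prepare_cohort(
    trials: list[KineticTrial], threshold_fraction: float | None = DEFAULT_TRIM_THRESHOLD
) -> TrainingMatrix:
    """Full preparation pipeline: filter, align, average repetitions, stack.

    Subjects appear as training-matrix columns in order of first appearance
    in ``trials``; a subject's retained repetitions are averaged into one
    column.
    """
    kept = filter_closed_chain(trials)
    by_subject: dict[str, list[AlignedSubject]] = {}
    for t in kept:
        by_subject.setdefault(t.subject_id, []).append(align_resample(t, threshold_fraction))
    subjects = [average_aligned(reps) for reps in by_subject.values()]
    return build_training_matrix(subjects)
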