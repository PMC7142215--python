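"""Trial containers and delimited-text I/O.

A *trial* is one recorded repetition of a squat or lunge: a knee-flexion
angle channel plus six joint-reaction-force channels (hip x/y/z, knee x/y/z),
all expressed in multiples of body weight (BW).  Trials are stored on disk as
comma-separated text with a header row (columns ``time_s``,
``knee_flexion_deg``, the six force channels, and an optional vertical
ground-reaction column ``grf_z`` used to detect closed-chain contact), one
file per trial.  A cohort is described by a small YAML manifest mapping
subject identifiers to their trial files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import check_finite_array

__all__ = [
    "CHANNELS",
    "N_CHANNELS",
    "N_INSTANTS",
    "N_FEATURES",
    "MOTIONS",
    "KineticTrial",
    "AlignedSubject",
    "TrainingMatrix",
    "read_trial",
    "write_trial",
    "load_cohort",
    "write_manifest",
]

#: Force channel order used everywhere: hip then knee, x/y/z within each joint.
CHANNELS: tuple[str, ...] = ("hjrf_x", "hjrf_y", "hjrf_z", "kjrf_x", "kjrf_y", "kjrf_z")
N_CHANNELS = len(CHANNELS)
#: Time-normalized motion grid: 0..100 % progress in 1 % steps.
N_INSTANTS = 101
#: Length of a stacked feature vector (6 channels x 101 instants).
N_FEATURES = N_CHANNELS * N_INSTANTS

MOTIONS = ("squat", "lunge")

#: Vertical ground-reaction threshold (BW) below which the forward foot is
#: considered off its force plate at some point of the recording.
GRF_CONTACT_THRESHOLD = 0.05


@dataclass
class KineticTrial:
    """One raw squat/lunge repetition before alignment.

    ``forces`` has shape ``(6, n_frames)`` in :data:`CHANNELS` order, in BW.
    ``closed_chain`` records whether the forward foot stayed on its force
    plate for the whole recording (only meaningful for the lunge).
    """

    subject_id: str
    motion: str
    sample_rate: float
    knee_flexion: np.ndarray
    forces: np.ndarray
    closed_chain: bool = True

    def __post_init__(self) -> None:
        if self.motion not in MOTIONS:
            raise ValueError(f"motion must be one of {MOTIONS}, got {self.motion!r}")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        self.knee_flexion = check_finite_array(self.knee_flexion, "knee_flexion").ravel()
        self.forces = check_finite_array(self.forces, "forces")
        if self.forces.shape != (N_CHANNELS, self.knee_flexion.size):
            raise ValueError(
                f"forces must have shape (6, n_frames) matching knee_flexion; "
                f"got {self.forces.shape} vs {self.knee_flexion.size} frames"
            )
        if self.knee_flexion.size < 3:
            raise ValueError("a trial needs at least 3 frames")

    @property
    def n_frames(self) -> int:
        return self.knee_flexion.size


@dataclass
class AlignedSubject:
    """Time-normalized 6x101 force matrix for one subject.

    Instant index 50 (0-based) is pinned at peak knee flexion; instants run
    from 0 % (motion onset) to 100 % (return) in 1 % steps.
    """

    subject_id: str
    motion: str
    values: np.ndarray
    grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 100.0, N_INSTANTS))

    def __post_init__(self) -> None:
        self.values = check_finite_array(self.values, "values")
        if self.values.shape != (N_CHANNELS, N_INSTANTS):
            raise ValueError(f"values must be 6x101, got {self.values.shape}")
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.size != N_INSTANTS:
            raise ValueError("grid must hold exactly 101 progress values")


@dataclass
class TrainingMatrix:
    """Stacked feature vectors of a cohort: ``X`` is 606 x p, one column per subject."""

    X: np.ndarray
    subject_ids: list[str]
    motion: str

    def __post_init__(self) -> None:
        self.X = check_finite_array(self.X, "X")
        if self.X.ndim != 2 or self.X.shape[0] != N_FEATURES:
            raise ValueError(f"X must be {N_FEATURES} x p, got {self.X.shape}")
        if self.X.shape[1] != len(self.subject_ids):
            raise ValueError("number of columns must match subject_ids")
        if self.X.shape[1] < 4:
            raise ValueError("a training matrix needs at least 4 subjects")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[1]

    @property
    def samples(self) -> np.ndarray:
        """Subjects-as-rows view ``(p, 606)`` for estimator-style APIs."""
        return self.X.T


# ---------------------------------------------------------------------------
# delimited-text I/O

_REQUIRED_COLUMNS = ("time_s", "knee_flexion_deg", *CHANNELS)


def read_trial(
    path: str | Path,
    subject_id: str | None = None,
    motion: str = "squat",
    closed_chain: bool | None = None,
) -> KineticTrial:
    """Read one trial from a comma-separated text file.

    The closed-chain flag is taken from ``closed_chain`` when given; otherwise,
    if a ``grf_z`` column is present, the trial is flagged closed-chain when
    the vertical ground reaction stays above 5 % BW for the whole recording;
    otherwise the flag defaults to True.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"trial file {path.name} is missing column {col!r}")
    time = df["time_s"].to_numpy(dtype=float)
    if time.size < 3:
        raise ValueError(f"trial file {path.name} has fewer than 3 frames")
    dt = np.median(np.diff(time))
    if not dt > 0:
        raise ValueError(f"trial file {path.name} has a non-increasing time column")
    if closed_chain is None:
        if "grf_z" in df.columns:
            closed_chain = bool(np.all(df["grf_z"].to_numpy(dtype=float) > GRF_CONTACT_THRESHOLD))
        else:
            closed_chain = True
    return KineticTrial(
        subject_id=subject_id if subject_id is not None else path.stem,
        motion=motion,
        sample_rate=1.0 / dt,
        knee_flexion=df["knee_flexion_deg"].to_numpy(dtype=float),
        forces=df[list(CHANNELS)].to_numpy(dtype=float).T,
        closed_chain=closed_chain,
    )


def write_trial(path: str | Path, trial: KineticTrial, grf_z: np.ndarray | None = None) -> None:
    """Write one trial in the dialect :func:`read_trial` reads."""
    path = Path(path)
    n = trial.n_frames
    data = {"time_s": np.arange(n) / trial.sample_rate, "knee_flexion_deg": trial.knee_flexion}
    for c, name in enumerate(CHANNELS):
        data[name] = trial.forces[c]
    if grf_z is not None:
        data["grf_z"] = np.asarray(grf_z, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g", lineterminator="\n")


def write_manifest(
    path: str | Path, motion: str, subject_files: dict[str, list[str]]
) -> None:
    """Write a cohort manifest (YAML): motion label plus subject -> trial files."""
    doc = {"motion": motion, "subjects": {k: list(v) for k, v in subject_files.items()}}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def load_cohort(manifest_path: str | Path) -> list[KineticTrial]:
    """Load every trial listed in a cohort manifest.

    Trial paths are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    doc = yaml.safe_load(manifest_path.read_text(encoding="utf-8"))
    motion = doc.get("motion")
    if motion not in MOTIONS:
        raise ValueError(f"manifest motion must be one of {MOTIONS}, got {motion!r}")
    subjects = doc.get("subjects")
    if not isinstance(subjects, dict) or not subjects:
        raise ValueError("manifest must map subject ids to trial file lists")
    trials: list[KineticTrial] = []
    for subject_id, files in subjects.items():
        for f in files:
            trials.append(
                read_trial(manifest_path.parent / f, subject_id=str(subject_id), motion=motion)
            )
    return trials


def flag_open_chain(trial: KineticTrial) -> KineticTrial:
    """Return a copy of ``trial`` flagged as open-chain."""
    return replace(trial, closed_chain=False)
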