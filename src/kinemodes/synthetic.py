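"""Synthetic squat/lunge cohorts with known ground-truth mode structure.

Motion-capture plus musculoskeletal inverse dynamics is expensive; this
module emulates its output so that every pipeline stage can be exercised and
checked against a known truth.  A :class:`GroundTruthModel` fixes, per
motion:

* a smooth mean waveform per force channel, peaking at 50 % progress with
  cohort-typical magnitudes (resultant knee force 4.52 BW for the squat and
  7.16 BW for the lunge, hip 3.08 / 4.76 BW);
* an observation-wise spread profile (BW) that is widest at peak flexion;
* ``K`` orthonormal planted modes with a prescribed eigenvalue spectrum
  (defaults shaped like published squat/lunge spectra), defined in the
  row-standardized space the pipeline models;
* a white-noise level and a knee-flexion template with an interior peak.

Two constructions keep parameter-recovery tests sharp rather than merely
qualitative.  First, planted modes are *variance-levelled*: smooth random
curves are iteratively rescaled and re-orthonormalized until their
eigenvalue-weighted pooled variance is the same at every one of the 606
observations.  Row standardization then rescales all observations equally,
so the spectrum of the cohort's correlation structure equals the planted
spectrum instead of a distorted version of it.  Second, mode scores are
empirically whitened across the cohort by default, so the realized spectrum
does not carry the O(sqrt(2/p)) sampling noise of raw normal draws.

Generated subjects are embedded into raw recordings with standing plateaus,
flexion ramps, and per-trial length jitter, so trimming and alignment are
genuinely exercised when the cohort is fed back through the preparation
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json
import math

import numpy as np

from ._utils import substream
from .trials import (
    CHANNELS,
    N_CHANNELS,
    N_FEATURES,
    N_INSTANTS,
    KineticTrial,
    flag_open_chain,
    write_manifest,
    write_trial,
)
from .reference import (
    LUNGE_DEFAULT_EIGENVALUES,
    PEAK_FORCES_BW,
    PEAK_KNEE_FLEXION_DEG,
    SQUAT_REFERENCE_EIGENVALUES,
    TOTAL_VARIANCE,
)

__all__ = [
    "GroundTruthModel",
    "make_ground_truth",
    "simulate_cohort",
    "perturb_open_chain",
    "write_cohort",
]

MAX_MODES = 20
_DEFAULT_HARMONICS = 12

#: Standing (rest) values used by the raw-recording embedding.
REST_FLEXION_DEG = 5.0
ONSET_FLEXION_DEG = 15.0
REST_FORCE_BW = 0.5

# Fixed unit directions splitting a joint's resultant over its x/y/z channels.
_HIP_DIR = np.array([0.15, 0.25, 0.95])
_HIP_DIR /= np.linalg.norm(_HIP_DIR)
_KNEE_DIR = np.array([0.12, 0.30, 0.94])
_KNEE_DIR /= np.linalg.norm(_KNEE_DIR)


def _progress_bump(q: float = 2.0) -> np.ndarray:
    """Smooth 0->1->0 weight over the 101-instant grid, peaking at instant 50.

    The raised-cosine squared is flat at both ends, so the few held frames
    that trimming leaves around motion onset change the waveforms negligibly.
    """
    t = np.linspace(0.0, 1.0, N_INSTANTS)
    return ((1.0 - np.cos(2.0 * np.pi * t)) / 2.0) ** q


@dataclass
class GroundTruthModel:
    """Known population model behind a synthetic cohort."""

    motion: str
    mean: np.ndarray  # (6, 101) BW
    row_scale: np.ndarray  # (6, 101) BW, observation-wise SD profile
    modes: np.ndarray  # (K, 606) orthonormal, variance-levelled
    eigenvalues: np.ndarray  # (K,) standardized scale, non-increasing
    noise_sd: float  # white-noise SD in standardized space
    flexion: np.ndarray  # (101,) degrees over the motion window

    def __post_init__(self) -> None:
        K = self.eigenvalues.size
        if K < 1 or K > MAX_MODES:
            raise ValueError(f"number of planted modes must lie in [1, {MAX_MODES}]")
        if np.any(self.eigenvalues <= 0) or np.any(np.diff(self.eigenvalues) > 0):
            raise ValueError("eigenvalue spectrum must be positive and non-increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.modes.shape != (K, N_FEATURES):
            raise ValueError(f"modes must be (K, {N_FEATURES})")

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    def expected_spectrum(self) -> np.ndarray:
        """Planted eigenvalues as the pipeline's correlation model sees them.

        Every standardized observation has total variance
        ``sum(lambda)/606 + noise_sd**2``; the pipeline renormalizes rows to
        unit variance, which rescales the planted eigenvalues by that factor.
        """
        c = self.eigenvalues.sum() / TOTAL_VARIANCE + self.noise_sd**2
        return self.eigenvalues / c

    def to_json(self, path: str | Path) -> None:
        doc = {
            "format": "kinemodes-ground-truth",
            "motion": self.motion,
            "mean": self.mean.tolist(),
            "row_scale": self.row_scale.tolist(),
            "modes": self.modes.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "noise_sd": self.noise_sd,
            "flexion": self.flexion.tolist(),
        }
        Path(path).write_text(json.dumps(doc), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            motion=doc["motion"],
            mean=np.asarray(doc["mean"], dtype=float),
            row_scale=np.asarray(doc["row_scale"], dtype=float),
            modes=np.asarray(doc["modes"], dtype=float),
            eigenvalues=np.asarray(doc["eigenvalues"], dtype=float),
            noise_sd=float(doc["noise_sd"]),
            flexion=np.asarray(doc["flexion"], dtype=float),
        )


def _smooth_random_curves(rng: np.random.Generator, n_curves: int, n_harmonics: int) -> np.ndarray:
    """Random smooth (n_curves, 606) matrix from a low-order cosine basis."""
    t = np.linspace(0.0, 1.0, N_INSTANTS)
    basis = np.array([np.cos(np.pi * h * t) for h in range(1, n_harmonics + 1)])
    weights = 1.0 / (1.0 + np.arange(1, n_harmonics + 1))
    curves = np.empty((n_curves, N_FEATURES))
    for k in range(n_curves):
        coef = rng.standard_normal((N_CHANNELS, n_harmonics)) * weights
        curves[k] = (coef @ basis).reshape(N_FEATURES)
    return curves


def _level_mode_variance(
    U: np.ndarray, eigenvalues: np.ndarray, max_iter: int = 2000, tol: float = 1e-10
) -> np.ndarray:
    """Orthonormal modes whose weighted pooled variance is flat across rows.

    Alternates between rescaling observations so that
    ``sum_m lambda_m u_m(o)^2`` equals its target everywhere and
    re-orthonormalizing the columns; converges in a few dozen iterations for
    the spectra used here.
    """
    n = U.shape[1]
    target = eigenvalues.sum() / n
    V = U.T  # (n, K) columns = modes
    for _ in range(max_iter):
        energy = (V**2) @ eigenvalues
        err = np.max(np.abs(energy - target)) / target
        if err < tol:
            break
        V = V * np.sqrt(target / np.maximum(energy, 1e-300))[:, None]
        V, _ = np.linalg.qr(V)
    else:
        raise RuntimeError(f"variance levelling did not converge (residual {err:.2e})")
    return V.T


def make_ground_truth(
    motion: str = "squat",
    spectrum: np.ndarray | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    n_harmonics: int = _DEFAULT_HARMONICS,
) -> GroundTruthModel:
    """Build a ground-truth model with planted low-rank structure.

    ``spectrum`` defaults to the reference squat spectrum (15 modes) or the
    default lunge spectrum (17 modes).  ``noise_sd`` defaults to the value
    that makes every standardized observation have exactly unit variance
    (``sqrt(1 - sum(spectrum)/606)``), so the planted spectrum is exactly
    what the pipeline should recover.  Deterministic under ``seed``.
    """
    if motion not in PEAK_FORCES_BW:
        raise ValueError(f"unknown motion {motion!r}")
    if spectrum is None:
        spectrum = SQUAT_REFERENCE_EIGENVALUES if motion == "squat" else LUNGE_DEFAULT_EIGENVALUES
    spectrum = np.asarray(spectrum, dtype=float)
    K = spectrum.size
    if K > N_CHANNELS * n_harmonics:
        raise ValueError(
            f"{K} modes exceed the smooth basis size {N_CHANNELS * n_harmonics}; "
            f"raise n_harmonics"
        )
    if noise_sd is None:
        slack = 1.0 - spectrum.sum() / TOTAL_VARIANCE
        if slack < -1e-9:
            raise ValueError("spectrum sums to more than the total variance 606")
        noise_sd = math.sqrt(max(slack, 0.0))

    rng = substream(seed, "ground-truth")
    raw = _smooth_random_curves(rng, K, n_harmonics)
    U, _ = np.linalg.qr(raw.T)
    modes = _level_mode_variance(U.T, spectrum)

    bump = _progress_bump()
    mean = np.empty((N_CHANNELS, N_INSTANTS))
    for j, (joint, direction) in enumerate((("hjrf", _HIP_DIR), ("kjrf", _KNEE_DIR))):
        peak = PEAK_FORCES_BW[motion][joint]
        resultant = REST_FORCE_BW + (peak - REST_FORCE_BW) * bump
        mean[3 * j : 3 * j + 3] = direction[:, None] * resultant[None, :]
    row_scale = np.tile(0.02 + 0.13 * bump, (N_CHANNELS, 1))
    peak_flex = PEAK_KNEE_FLEXION_DEG[motion]
    flexion = ONSET_FLEXION_DEG + (peak_flex - ONSET_FLEXION_DEG) * bump

    return GroundTruthModel(
        motion=motion,
        mean=mean,
        row_scale=row_scale,
        modes=modes,
        eigenvalues=spectrum,
        noise_sd=float(noise_sd),
        flexion=flexion,
    )


def _subject_waveforms(
    gt: GroundTruthModel, p: int, rng: np.random.Generator, whiten_scores: bool
) -> np.ndarray:
    """Per-subject (p, 6, 101) BW waveforms drawn from the ground truth."""
    K = gt.n_modes
    S = rng.standard_normal((K, p))
    if whiten_scores and p > K + 1:
        S = S - S.mean(axis=1, keepdims=True)
        chol = np.linalg.cholesky(S @ S.T / (p - 1))
        S = np.linalg.solve(chol, S)
    R = gt.modes.T @ (np.sqrt(gt.eigenvalues)[:, None] * S)
    if gt.noise_sd > 0:
        R = R + gt.noise_sd * rng.standard_normal((N_FEATURES, p))
    X = gt.mean.reshape(-1, 1) + gt.row_scale.reshape(-1, 1) * R
    return X.T.reshape(p, N_CHANNELS, N_INSTANTS)


def simulate_cohort(
    gt: GroundTruthModel,
    p: int,
    seed: int = 0,
    n_trials: int = 1,
    trial_noise_sd: float = 0.0,
    whiten_scores: bool = True,
    sample_rate: float = 100.0,
) -> list[KineticTrial]:
    """Simulate a cohort of raw, un-aligned trials.

    Each subject's true waveforms are drawn once from the ground truth; each
    of its ``n_trials`` repetitions embeds them into a raw recording with a
    standing plateau of random length on both sides, a short flexion ramp,
    and optional per-trial measurement noise (``trial_noise_sd``, BW).

    The motion-segment frame counts and ramps are drawn once per cohort and
    shared by all subjects, so preparation applies the identical resampling
    to every subject and the planted rank is preserved exactly at zero noise.
    Deterministic under ``seed``.
    """
    if p < 4:
        raise ValueError("a cohort needs at least 4 subjects")
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    rng = substream(seed, "cohort")
    waveforms = _subject_waveforms(gt, p, rng, whiten_scores)

    # Shared raw-recording geometry (frames).  Motion-segment frame counts are
    # multiples of 50 so every 101-grid resample position coincides with a raw
    # frame and alignment reproduces the planted waveforms without
    # interpolation error.
    n_up = 50 * int(rng.integers(2, 4))  # frames for 0 -> 50 % progress
    n_down = 50 * int(rng.integers(2, 4))  # frames for 50 -> 100 %
    n_ramp = int(rng.integers(4, 9))  # standing -> motion-onset flexion ramp

    grid = np.arange(N_INSTANTS, dtype=float)
    prog = np.concatenate(
        [np.linspace(0.0, 50.0, n_up + 1), np.linspace(50.0, 100.0, n_down + 1)[1:]]
    )
    flex_motion = np.interp(prog, grid, gt.flexion)
    # The ramp tops out just below the 5 %-of-range trim threshold, so the
    # preparation stage cuts exactly at the motion segment and the aligned
    # grid coincides with the ground-truth progress grid.
    peak_flex = float(gt.flexion.max())
    ramp_top = REST_FLEXION_DEG + 0.045 * (peak_flex - REST_FLEXION_DEG)
    ramp_up = np.linspace(REST_FLEXION_DEG, ramp_top, n_ramp + 1)[1:]
    ramp_down = ramp_up[::-1]

    digits = max(2, len(str(p)))
    trials: list[KineticTrial] = []
    for i in range(p):
        subject_id = f"S{i + 1:0{digits}d}"
        curves = waveforms[i]
        force_motion = np.array([np.interp(prog, grid, curves[c]) for c in range(N_CHANNELS)])
        for _ in range(n_trials):
            pl_l = int(rng.integers(20, 60))
            pl_r = int(rng.integers(20, 60))
            flexion = np.concatenate(
                [np.full(pl_l, REST_FLEXION_DEG), ramp_up, flex_motion, ramp_down,
                 np.full(pl_r, REST_FLEXION_DEG)]
            )
            hold_l = np.tile(curves[:, :1], (1, pl_l + n_ramp))
            hold_r = np.tile(curves[:, -1:], (1, n_ramp + pl_r))
            forces = np.concatenate([hold_l, force_motion, hold_r], axis=1)
            if trial_noise_sd > 0:
                forces = forces + trial_noise_sd * rng.standard_normal(forces.shape)
            trials.append(
                KineticTrial(
                    subject_id=subject_id,
                    motion=gt.motion,
                    sample_rate=sample_rate,
                    knee_flexion=flexion,
                    forces=forces,
                    closed_chain=True,
                )
            )
    return trials


def perturb_open_chain(
    trials: list[KineticTrial], fraction: float, seed: int = 0
) -> list[KineticTrial]:
    """Flag ``ceil(fraction * len(trials))`` randomly chosen trials open-chain."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n_flag = math.ceil(fraction * len(trials))
    rng = substream(seed, "open-chain")
    flagged = set(rng.choice(len(trials), size=n_flag, replace=False).tolist()) if n_flag else set()
    return [flag_open_chain(t) if i in flagged else t for i, t in enumerate(trials)]


def write_cohort(
    trials: list[KineticTrial],
    directory: str | Path,
    gt: GroundTruthModel | None = None,
    manifest_name: str = "cohort.yaml",
) -> Path:
    """Write trials, a cohort manifest, and an optional ground-truth sidecar.

    Trial files carry a ``grf_z`` column encoding the closed-chain flag: a
    steady stance load for closed-chain trials, and a mid-recording loss of
    plate contact for open-chain ones, so the flag survives the text
    round-trip.  Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    motions = {t.motion for t in trials}
    if len(motions) != 1:
        raise ValueError("a cohort manifest covers a single motion")
    subject_files: dict[str, list[str]] = {}
    counters: dict[str, int] = {}
    for t in trials:
        counters[t.subject_id] = counters.get(t.subject_id, 0) + 1
        fname = f"{t.subject_id}_trial{counters[t.subject_id]}.csv"
        n = t.n_frames
        if t.closed_chain:
            grf = np.full(n, 0.95)
        else:
            grf = np.full(n, 0.95)
            lift = slice(n // 3, n // 3 + max(1, n // 5))
            grf[lift] = 0.0
        write_trial(directory / fname, t, grf_z=grf)
        subject_files.setdefault(t.subject_id, []).append(fname)
    manifest = directory / manifest_name
    write_manifest(manifest, motions.pop(), subject_files)
    if gt is not None:
        gt.to_json(directory / "ground_truth.json")
    return manifest
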