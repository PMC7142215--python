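"""Correlation-matrix principal-mode model of inter-subject waveform variability.

The training matrix holds one 606-long feature vector per subject (6 force
channels x 101 aligned instants).  Each observation (row) is mean-centered and
scaled to unit standard deviation, so the decomposition acts on the
*correlation* structure: channels with small absolute force ranges contribute
to the modes on an equal footing with large ones.

With ``R`` the standardized residual matrix (observations x subjects), the
thin singular value decomposition ``R = U L A^T`` yields orthonormal
waveform-space modes ``U`` and subject loadings ``A``; the eigenvalue of mode
``k`` is ``lambda_k = l_k^2 / (p - 1)``, the inter-subject variance carried by
that mode.  Because every row is standardized with denominator ``p - 1``, the
eigenvalues sum to the number of observations (606) — variance shares and
cumulative variance (model *compactness*) are reported against that total.

:class:`KineticPCA` exposes this model as a scikit-learn style transformer:
``fit`` estimates mean, row scales, modes and spectrum; ``transform`` maps
subjects to mode scores (variance ``lambda_k`` per mode); ``inverse_transform``
reconstructs body-weight-unit waveforms from truncated scores.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ._utils import substream
from .exceptions import DegenerateObservationError
from .trials import CHANNELS, N_CHANNELS, N_FEATURES, N_INSTANTS, TrainingMatrix

__all__ = [
    "KineticPCA",
    "standardize",
    "variance_shares",
    "cumulative_variance",
    "n_components_for_variance",
    "load_model",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# spectrum-level helpers (usable on any eigenvalue sequence, e.g. a published
# table, independently of a fitted model)


def variance_shares(eigenvalues: np.ndarray, total_variance: float | None = None) -> np.ndarray:
    """Per-mode variance fractions ``lambda_k / total``.

    ``total_variance`` defaults to the sum of the given eigenvalues; pass the
    full-model total (606 for fully standardized kinetic data) when the
    sequence is a truncated head of the spectrum.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    total = float(np.sum(lam)) if total_variance is None else float(total_variance)
    if total <= 0:
        raise ValueError("total variance must be positive")
    return lam / total


def cumulative_variance(eigenvalues: np.ndarray, total_variance: float | None = None) -> np.ndarray:
    """Cumulative variance fractions (model compactness curve)."""
    return np.cumsum(variance_shares(eigenvalues, total_variance))


def n_components_for_variance(
    eigenvalues: np.ndarray, fraction: float, total_variance: float | None = None
) -> int:
    """Smallest number of leading modes whose cumulative variance reaches ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    cum = cumulative_variance(eigenvalues, total_variance)
    reached = np.nonzero(cum >= fraction - _EPS)[0]
    if reached.size == 0:
        raise ValueError(
            f"the given spectrum reaches only {cum[-1]:.4f} of the total variance, "
            f"below the requested {fraction}"
        )
    return int(reached[0]) + 1


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-standardize an observations-x-subjects training matrix.

    Returns ``(R, mean, row_sd)`` with ``R[o, i] = (X[o, i] - mean[o]) / row_sd[o]``;
    every row of ``R`` has zero mean and unit standard deviation (denominator
    ``p - 1``).  A zero-variance observation is degenerate for correlation-scale
    modeling and raises :class:`DegenerateObservationError` naming the row.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be a 2-D observations-x-subjects matrix with p >= 2")
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    zero = np.nonzero(sd <= 0.0)[0]
    if zero.size:
        raise DegenerateObservationError(
            f"observation row(s) {zero[:5].tolist()} have zero variance across subjects"
        )
    return (X - mean[:, None]) / sd[:, None], mean, sd


class KineticPCA(TransformerMixin, BaseEstimator):
    """Principal-mode model of standardized kinetic waveforms.

    Parameters
    ----------
    n_components : int or None
        Maximum number of modes to retain; ``None`` keeps every mode with a
        non-negligible eigenvalue (at most ``p - 1``).
    min_eigenvalue_ratio : float
        Modes with ``lambda_k < ratio * lambda_1`` are treated as numerically
        zero variance and dropped at fit time.
    feature_layout : (int, int)
        ``(n_channels, n_instants)`` interpretation of the feature axis, used
        by :meth:`mode_curves` and channel-wise error reports.  The kinetic
        default is ``(6, 101)``.
    motion : str or None
        Optional metadata tag carried through serialization.

    Attributes
    ----------
    mean_ : ndarray of shape (n_features,)
        Observation-wise mean waveform (BW).
    scale_ : ndarray of shape (n_features,)
        Observation-wise standard deviations ``d_o`` (BW).
    components_ : ndarray of shape (n_modes, n_features)
        Orthonormal waveform-space modes (rows).
    loadings_ : ndarray of shape (n_samples, n_modes)
        Orthonormal subject loadings (columns of ``A``).
    explained_variance_ : ndarray of shape (n_modes,)
        Eigenvalues ``lambda_k``, non-increasing.
    explained_variance_ratio_ : ndarray of shape (n_modes,)
        ``lambda_k`` divided by the total variance of all modes.

    Examples
    --------
    >>> model = KineticPCA().fit(training.samples)   # (p, 606) subjects as rows
    >>> k95 = model.n_components_for_variance(0.95)
    >>> scores = model.transform(training.samples, n_components=k95)
    >>> reconstructed = model.inverse_transform(scores)
    """

    def __init__(
        self,
        n_components: int | None = None,
        min_eigenvalue_ratio: float = 1e-10,
        feature_layout: tuple[int, int] = (N_CHANNELS, N_INSTANTS),
        motion: str | None = None,
    ):
        self.n_components = n_components
        self.min_eigenvalue_ratio = min_eigenvalue_ratio
        self.feature_layout = feature_layout
        self.motion = motion

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the model on subjects-as-rows data of shape ``(p, n_features)``."""
        if isinstance(X, TrainingMatrix):
            X = X.samples
        X = check_array(X, dtype=float, ensure_min_samples=2)
        p, n_features = X.shape
        R_t, mean, sd = standardize(X.T)  # standardize observation-wise
        R = R_t.T  # back to (p, n_features)

        W, s, Vh = np.linalg.svd(R, full_matrices=False)
        lam = s**2 / (p - 1)
        total = float(lam.sum())

        keep = lam > self.min_eigenvalue_ratio * lam[0] if lam[0] > 0 else lam > 0
        r = int(np.count_nonzero(keep))
        if self.n_components is not None:
            r = min(r, int(self.n_components))
        W, s, Vh, lam = W[:, :r], s[:r], Vh[:r], lam[:r]

        # deterministic sign: largest-magnitude element of each mode positive
        flip = np.sign(Vh[np.arange(r), np.argmax(np.abs(Vh), axis=1)])
        flip[flip == 0] = 1.0
        Vh = Vh * flip[:, None]
        W = W * flip[None, :]

        self.mean_ = mean
        self.scale_ = sd
        self.components_ = Vh
        self.loadings_ = W
        self.singular_values_ = s
        self.explained_variance_ = lam
        self.total_variance_ = total
        self.explained_variance_ratio_ = lam / total
        self.n_components_ = r
        self.n_samples_ = p
        self.n_features_in_ = n_features
        return self

    # -- scores and reconstruction ------------------------------------------

    @property
    def scores_(self) -> np.ndarray:
        """Training-subject mode scores ``(p, r)``; column ``k`` has variance ``lambda_k``."""
        check_is_fitted(self)
        return self.loadings_ * self.singular_values_

    def transform(self, X, n_components: int | None = None) -> np.ndarray:
        """Project new subjects onto the leading modes.

        ``X`` has shape ``(n, n_features)`` (a single vector is accepted as
        1-D).  Each vector is standardized with the fitted mean and row scales
        and projected onto the first ``n_components`` modes (all by default).
        """
        check_is_fitted(self)
        t = self._check_t(n_components)
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        Z = ((X - self.mean_) / self.scale_) @ self.components_[:t].T
        return Z[0] if single else Z

    def inverse_transform(self, Z) -> np.ndarray:
        """Reconstruct body-weight waveform vectors from (truncated) scores."""
        check_is_fitted(self)
        Z = np.asarray(Z, dtype=float)
        single = Z.ndim == 1
        Z = np.atleast_2d(Z)
        t = Z.shape[1]
        self._check_t(t)
        X = self.mean_ + (Z @ self.components_[:t]) * self.scale_
        return X[0] if single else X

    def reconstruct(self, X, n_components: int | None = None) -> np.ndarray:
        """Round-trip: project onto ``n_components`` modes and reconstruct in BW."""
        return self.inverse_transform(self.transform(X, n_components))

    # -- spectrum summaries ---------------------------------------------------

    def compactness(self, k: int) -> float:
        """Cumulative variance fraction carried by the first ``k`` modes."""
        check_is_fitted(self)
        if not 0 <= k <= self.n_components_:
            raise ValueError(f"k must lie in [0, {self.n_components_}], got {k}")
        if k == 0:
            return 0.0
        return float(np.sum(self.explained_variance_ratio_[:k]))

    def n_components_for_variance(self, fraction: float) -> int:
        """Smallest mode count reaching the requested cumulative variance."""
        check_is_fitted(self)
        return n_components_for_variance(self.explained_variance_, fraction, self.total_variance_)

    def mode_curves(self, k: int, n_sd: float = 2.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Mean waveforms and ``+/- n_sd`` standard-deviation bands of mode ``k``.

        Returns three channel matrices (each ``feature_layout``-shaped, BW):
        the cohort mean and the mean perturbed by ``+/- n_sd * sqrt(lambda_k)``
        along mode ``k`` — the conventional visualization of what a mode does.
        """
        check_is_fitted(self)
        if not 1 <= k <= self.n_components_:
            raise ValueError(f"mode index must lie in [1, {self.n_components_}], got {k}")
        layout = tuple(self.feature_layout)
        if int(np.prod(layout)) != self.n_features_in_:
            raise ValueError(f"feature_layout {layout} does not match {self.n_features_in_} features")
        offset = n_sd * np.sqrt(self.explained_variance_[k - 1]) * self.components_[k - 1] * self.scale_
        mean = self.mean_.reshape(layout)
        return mean, (self.mean_ + offset).reshape(layout), (self.mean_ - offset).reshape(layout)

    # -- generative use -------------------------------------------------------

    def sample(
        self,
        n_samples: int = 1,
        n_components: int | None = None,
        random_state: int | np.random.Generator | None = None,
    ) -> np.ndarray:
        """Draw virtual subjects from the fitted mode distribution.

        Mode scores are assumed independent normal with variance ``lambda_k``:
        each virtual waveform is ``mean + D * sum_m n_m sqrt(lambda_m) u_m``
        with ``n_m ~ N(0, 1)``.  Returns an ``(n_samples, n_features)`` array
        in BW units.
        """
        check_is_fitted(self)
        t = self._check_t(n_components)
        if isinstance(random_state, np.random.Generator):
            rng = random_state
        else:
            rng = substream(random_state, "virtual-subjects")
        normals = rng.standard_normal((n_samples, t))
        return self.inverse_transform(normals * np.sqrt(self.explained_variance_[:t]))

    # -- serialization --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize the fitted model to a single JSON document.

        The layout is open: metadata (motion, channel and instant ordering,
        subject count) plus the numeric arrays as nested lists with full
        ``repr`` precision, so a round-trip is exact for metadata and
        faithful to double precision for numerics.
        """
        check_is_fitted(self)
        doc = {
            "format": "kinemodes-model",
            "version": 1,
            "motion": self.motion,
            "channels": list(CHANNELS) if self.n_features_in_ == N_FEATURES else None,
            "feature_layout": list(self.feature_layout),
            "n_samples": self.n_samples_,
            "n_features": self.n_features_in_,
            "total_variance": self.total_variance_,
            "mean": self.mean_.tolist(),
            "row_sd": self.scale_.tolist(),
            "eigenvalues": self.explained_variance_.tolist(),
            "singular_values": self.singular_values_.tolist(),
            "modes": self.components_.tolist(),
            "loadings": self.loadings_.tolist(),
        }
        Path(path).write_text(json.dumps(doc), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "KineticPCA":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if doc.get("format") != "kinemodes-model":
            raise ValueError(f"{path} is not a kinemodes model file")
        model = cls(feature_layout=tuple(doc["feature_layout"]), motion=doc["motion"])
        model.mean_ = np.asarray(doc["mean"], dtype=float)
        model.scale_ = np.asarray(doc["row_sd"], dtype=float)
        model.components_ = np.asarray(doc["modes"], dtype=float)
        model.loadings_ = np.asarray(doc["loadings"], dtype=float)
        model.singular_values_ = np.asarray(doc["singular_values"], dtype=float)
        model.explained_variance_ = np.asarray(doc["eigenvalues"], dtype=float)
        model.total_variance_ = float(doc["total_variance"])
        model.explained_variance_ratio_ = model.explained_variance_ / model.total_variance_
        model.n_components_ = model.components_.shape[0]
        model.n_samples_ = int(doc["n_samples"])
        model.n_features_in_ = int(doc["n_features"])
        return model

    # -- internals ------------------------------------------------------------

    def _check_t(self, n_components: int | None) -> int:
        if n_components is None:
            return self.n_components_
        t = int(n_components)
        if not 0 <= t <= self.n_components_:
            raise ValueError(f"n_components must lie in [0, {self.n_components_}], got {t}")
        return t


def load_model(path: str | Path) -> KineticPCA:
    """Convenience alias for :meth:`KineticPCA.load`."""
    return KineticPCA.load(path)
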