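"""Model validation: accuracy, compactness, generalization, specificity,
and Monte-Carlo permutation selection of signal components.

Four estimators quantify how good a fitted mode model is:

* **accuracy** — in-sample reconstruction error: RMSE (BW) between each
  training subject and its truncated-model reconstruction, per force channel;
* **compactness** — the cumulative-variance curve (delegated to the model);
* **generalization** — out-of-sample error: leave-one-out reconstructions of
  a held-out subject from models refit on ``n`` randomly drawn training
  subjects, as a post-hoc sample-size analysis;
* **specificity** — soundness of generated data: RMSE between virtual
  subjects drawn from the model and their nearest training subject.

Component selection uses Monte-Carlo permutation tests on the standardized
training matrix.  Permuting each observation row independently across
subjects destroys inter-row correlation while preserving every row's
marginal distribution, giving an exact null for "this component reflects
correlation structure rather than noise".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._utils import substream
from .decomposition import KineticPCA, n_components_for_variance, standardize
from .reference import DEFAULT_VARIANCE_LEVELS
from .trials import N_CHANNELS, N_INSTANTS

__all__ = [
    "channel_rmse",
    "accuracy",
    "accuracy_summary",
    "generalization_curve",
    "summarize_generalization",
    "sample_virtual_subjects",
    "specificity",
    "permutation_component_test",
    "significant_components",
    "ValidationReport",
    "validate_model",
]


def _median_iqr(values: np.ndarray) -> tuple[float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q3 - q1)


def channel_rmse(
    a: np.ndarray, b: np.ndarray, layout: tuple[int, int] = (N_CHANNELS, N_INSTANTS)
) -> np.ndarray:
    """Per-channel RMSE between waveform vectors (..., n_features) in BW."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = (a - b).reshape(a.shape[:-1] + tuple(layout))
    return np.sqrt(np.mean(d**2, axis=-1))


# ---------------------------------------------------------------------------
# accuracy


def accuracy(
    model: KineticPCA, X: np.ndarray, n_components: int | None = None
) -> np.ndarray:
    """In-sample reconstruction RMSE, one value per subject per channel (BW).

    ``X`` holds subjects as rows ``(p, n_features)``.  With all components the
    reconstruction is exact and every RMSE is numerically zero; with zero
    components it is the deviation from the mean waveform.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X_hat = model.reconstruct(X, n_components)
    return channel_rmse(X, X_hat, model.feature_layout)


def accuracy_summary(
    model: KineticPCA,
    X: np.ndarray,
    variance_levels: tuple[float, ...] = DEFAULT_VARIANCE_LEVELS,
) -> pd.DataFrame:
    """Accuracy per variance level: dimensionality, median, IQR, grand mean.

    The grand mean is the average subject-level RMSE over the full feature
    vector; median and IQR summarize the per-subject-per-channel values.
    """
    rows = []
    for level in variance_levels:
        t = model.n_components_for_variance(level)
        rmse = accuracy(model, X, t)
        med, iqr = _median_iqr(rmse.ravel())
        grand = float(np.mean(channel_rmse(X, model.reconstruct(X, t), (1, model.n_features_in_))))
        rows.append(
            {"variance_level": level, "dimensionality": t, "rmse_median": med,
             "rmse_iqr": iqr, "rmse_grand_mean": grand}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generalization


def generalization_curve(
    X: np.ndarray,
    n_values: np.ndarray | None = None,
    n_repeats: int = 200,
    variance_fraction: float = 0.95,
    random_state: int | None = None,
    feature_layout: tuple[int, int] = (N_CHANNELS, N_INSTANTS),
) -> dict[int, np.ndarray]:
    """Leave-one-out reconstruction error versus training-set size.

    For each training-set size ``n``, repeat ``n_repeats`` times: hold out one
    subject drawn uniformly, draw ``n`` training subjects uniformly without
    replacement from the rest, fit a model, keep the components reaching
    ``variance_fraction`` cumulative variance, and record the per-channel RMSE
    (BW) of the held-out subject's reconstruction.

    Returns a dict mapping ``n`` to an ``(n_repeats, n_channels)`` array.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[0]
    if n_values is None:
        n_values = np.arange(4, p)
    n_values = np.asarray(n_values, dtype=int)
    if np.any(n_values > p - 1):
        raise ValueError(f"training-set sizes must not exceed p - 1 = {p - 1}")
    if np.any(n_values < 2):
        raise ValueError("training-set sizes must be at least 2")
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    rng = substream(random_state, "generalization")
    out: dict[int, np.ndarray] = {}
    for n in n_values:
        errors = np.empty((n_repeats, feature_layout[0]))
        for rep in range(n_repeats):
            held = int(rng.integers(p))
            pool = np.delete(np.arange(p), held)
            train = rng.choice(pool, size=int(n), replace=False)
            sub = KineticPCA(feature_layout=feature_layout).fit(X[train])
            t = min(sub.n_components_for_variance(variance_fraction), sub.n_components_)
            x_hat = sub.reconstruct(X[held], t)
            errors[rep] = channel_rmse(X[held], x_hat, feature_layout)
        out[int(n)] = errors
    return out


def summarize_generalization(curve: dict[int, np.ndarray]) -> pd.DataFrame:
    """Median/quartile/whisker summary of a generalization curve, per n."""
    rows = []
    for n, errors in sorted(curve.items()):
        flat = errors.ravel()
        q1, med, q3 = np.percentile(flat, [25, 50, 75])
        rows.append(
            {"n_train": n, "rmse_median": float(med), "rmse_q1": float(q1),
             "rmse_q3": float(q3), "rmse_min": float(flat.min()), "rmse_max": float(flat.max())}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# specificity


def sample_virtual_subjects(
    model: KineticPCA,
    n_samples: int,
    n_components: int | None = None,
    random_state: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw virtual subjects (BW waveform vectors) from the fitted model."""
    return model.sample(n_samples, n_components, random_state)


def specificity(
    model: KineticPCA,
    X: np.ndarray,
    variance_levels: tuple[float, ...] = DEFAULT_VARIANCE_LEVELS,
    n_virtual: int = 2000,
    random_state: int | None = None,
    common_draws: bool = True,
    chunk: int = 512,
    dimensionalities: list[int] | None = None,
    excite_all_modes: bool = True,
) -> pd.DataFrame:
    """Distance of model-generated subjects to their nearest training subject.

    For each variance level, ``n_virtual`` virtual subjects are generated;
    each is matched to the training subject minimizing the whole-vector RMSE
    (BW), and the distribution of those nearest-neighbour RMSEs is summarized
    as median and IQR.

    With ``excite_all_modes`` (the default) the virtual-subject formula
    excites every retained mode regardless of the level — the level's
    dimensionality is reported alongside, and the near-equality of
    specificity across levels becomes a statistical observation over
    independent draws.  With ``excite_all_modes=False`` each level excites
    only its own dimensionality; ``common_draws`` then reuses one batch of
    standard-normal draws across levels, removing Monte-Carlo noise from
    between-level comparisons.
    """
    X = np.asarray(X, dtype=float)
    rng = substream(random_state, "specificity")
    if dimensionalities is not None:
        dims = [int(d) for d in dimensionalities]
        if len(dims) != len(variance_levels):
            raise ValueError("dimensionalities must match variance_levels in length")
    else:
        dims = [model.n_components_for_variance(level) for level in variance_levels]
    t_max = max(dims) if dims else 0
    base = rng.standard_normal((n_virtual, t_max)) if common_draws and not excite_all_modes else None
    rows = []
    for level, t_level in zip(variance_levels, dims):
        t = model.n_components_ if excite_all_modes else t_level
        if base is not None:
            normals = base[:, :t]
        else:
            normals = rng.standard_normal((n_virtual, t))
        scores = normals * np.sqrt(model.explained_variance_[:t])
        nearest = np.empty(n_virtual)
        for lo in range(0, n_virtual, chunk):
            virtual = model.inverse_transform(scores[lo : lo + chunk])
            d = cdist(virtual, X) / np.sqrt(model.n_features_in_)
            nearest[lo : lo + virtual.shape[0]] = d.min(axis=1)
        med, iqr = _median_iqr(nearest)
        rows.append(
            {"variance_level": level, "dimensionality": t_level, "rmse_median": med,
             "rmse_iqr": iqr, "rmse_mean": float(nearest.mean())}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation component selection


def permutation_component_test(
    X: np.ndarray,
    n_permutations: int = 999,
    max_components: int | None = None,
    random_state: int | None = None,
) -> pd.DataFrame:
    """Monte-Carlo permutation tests for the number of signal components.

    ``X`` holds subjects as rows.  Two criteria are evaluated per component:

    * **rank of roots** — is the k-th eigenvalue larger than chance, given the
      structure already explained?  The first ``k - 1`` fitted components are
      deflated from the standardized matrix, each observation row of the
      residual is permuted independently across subjects, and the top
      eigenvalue of the permuted residual forms the null for ``lambda_k``.
    * **equality of roots** — does the k-th root stand out from the remaining
      roots?  The statistic ``lambda_k / mean(lambda_k .. lambda_r)`` is
      compared with the same statistic at position ``k`` of the spectra of
      fully permuted (undeflated) matrices.

    P-values use the add-one rule ``(exceedances + 1) / (B + 1)``, so the
    smallest attainable value is ``1 / (B + 1)``.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations for a meaningful p-value floor")
    X = np.asarray(X, dtype=float)
    p = X.shape[0]
    R_t, _, _ = standardize(X.T)
    R = R_t.T
    W, s, Vh = np.linalg.svd(R, full_matrices=False)
    lam_all = s**2 / (p - 1)
    r = int(np.count_nonzero(lam_all > 1e-10 * lam_all[0]))
    lam = lam_all[:r]
    K = r if max_components is None else min(int(max_components), r)
    rng = substream(random_state, "permutation-test")
    B = int(n_permutations)

    # equality of roots: one shared batch of full-matrix permutations
    null_eq = np.empty((B, K))
    for b in range(B):
        P = rng.permuted(R, axis=0)  # permute each observation independently
        lam_b = np.sort(np.linalg.eigvalsh(P @ P.T))[::-1][:r] / (p - 1)
        tails = np.cumsum(lam_b[::-1])[::-1]  # sum(lam_b[k:]) for each k
        counts = r - np.arange(r)
        null_eq[b] = (lam_b * counts / tails)[:K]
    obs_tails = np.cumsum(lam[::-1])[::-1]
    obs_eq = lam * (r - np.arange(r)) / obs_tails
    p_eq = (np.sum(null_eq >= obs_eq[:K] - 1e-12, axis=0) + 1) / (B + 1)

    # rank of roots: sequential deflation, null = top eigenvalue of the
    # permuted residual
    p_rank = np.empty(K)
    scores = W * s
    for k in range(K):
        E = R - scores[:, :k] @ Vh[:k]
        exceed = 0
        for _ in range(B):
            P = rng.permuted(E, axis=0)
            top = np.linalg.eigvalsh(P @ P.T)[-1] / (p - 1)
            if top >= lam[k] - 1e-12:
                exceed += 1
        p_rank[k] = (exceed + 1) / (B + 1)

    shares = lam_all / lam_all.sum()
    return pd.DataFrame(
        {
            "component": np.arange(1, K + 1),
            "eigenvalue": lam[:K],
            "variance_pct": 100 * shares[:K],
            "cumulative_pct": 100 * np.cumsum(shares)[:K],
            "p_rank_of_roots": p_rank,
            "p_equality_of_roots": p_eq,
        }
    )


def significant_components(
    table: pd.DataFrame, alpha: float = 0.05, criterion: str = "rank_of_roots"
) -> int:
    """Number of leading components significant under the sequential rule.

    Components are counted from the first until the first p-value above
    ``alpha``; later isolated significances are attributed to chance.
    """
    col = f"p_{criterion}"
    if col not in table.columns:
        raise ValueError(f"unknown criterion {criterion!r}")
    below = (table[col].to_numpy() <= alpha).astype(int)
    stop = np.nonzero(below == 0)[0]
    return int(stop[0]) if stop.size else int(below.size)


# ---------------------------------------------------------------------------
# full report


@dataclass
class ValidationReport:
    """Bundle of the four goodness measures plus the permutation table."""

    motion: str | None
    accuracy: pd.DataFrame
    compactness: pd.DataFrame
    generalization: pd.DataFrame
    specificity: pd.DataFrame
    permutation: pd.DataFrame
    config: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """Machine-readable digest of the report."""
        return {
            "motion": self.motion,
            "config": self.config,
            "accuracy": self.accuracy.to_dict(orient="records"),
            "specificity": self.specificity.to_dict(orient="records"),
            "generalization": self.generalization.to_dict(orient="records"),
            "n_significant_rank_of_roots": significant_components(self.permutation),
            "n_significant_equality_of_roots": significant_components(
                self.permutation, criterion="equality_of_roots"
            ),
        }


def validate_model(
    model: KineticPCA,
    X: np.ndarray,
    variance_levels: tuple[float, ...] = DEFAULT_VARIANCE_LEVELS,
    n_generalization: int = 200,
    generalization_sizes: np.ndarray | None = None,
    n_virtual: int = 2000,
    n_permutations: int = 999,
    max_components: int | None = 15,
    random_state: int | None = None,
) -> ValidationReport:
    """Run every validation estimator at the configured scale."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"cohort has {X.shape[1]} features but the model expects {model.n_features_in_}"
        )
    compact = pd.DataFrame(
        {
            "component": np.arange(1, model.n_components_ + 1),
            "eigenvalue": model.explained_variance_,
            "variance_pct": 100 * model.explained_variance_ratio_,
            "cumulative_pct": 100 * np.cumsum(model.explained_variance_ratio_),
        }
    )
    curve = generalization_curve(
        X,
        n_values=generalization_sizes,
        n_repeats=n_generalization,
        random_state=random_state,
        feature_layout=model.feature_layout,
    )
    report = ValidationReport(
        motion=model.motion,
        accuracy=accuracy_summary(model, X, variance_levels),
        compactness=compact,
        generalization=summarize_generalization(curve),
        specificity=specificity(
            model, X, variance_levels, n_virtual=n_virtual, random_state=random_state
        ),
        permutation=permutation_component_test(
            X, n_permutations=n_permutations, max_components=max_components,
            random_state=random_state,
        ),
        config={
            "variance_levels": list(variance_levels),
            "n_generalization": n_generalization,
            "n_virtual": n_virtual,
            "n_permutations": n_permutations,
            "max_components": max_components,
            "random_state": random_state,
        },
    )
    return report
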