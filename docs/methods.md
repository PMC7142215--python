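# Methods

## Data model and preparation

A *trial* is one recorded repetition of a deep squat or forward lunge: a
knee-flexion channel (degrees) and six joint-reaction-force channels — hip
x/y/z then knee x/y/z — in body-weight (BW) units, sampled uniformly in
time.  Recordings begin and end with standing transients that carry no
information about the motion, and repetition durations differ, so before
modeling each trial is:

1. **Trimmed.**  The motion window is the maximal contiguous run of frames
   containing the flexion peak in which flexion exceeds
   `min + threshold_fraction · range` (default `threshold_fraction = 0.05`).
   The threshold is configurable; passing `None` skips trimming, which is
   the correct setting for data whose transients were already removed and
   what makes re-alignment of an already-aligned 101-instant trial an exact
   identity.
2. **Aligned and resampled.**  The frame of peak knee flexion defines 50 %
   motion progress.  Linear interpolation places 51 evenly spaced samples
   over [window start, peak] and 50 more over (peak, window end], giving a
   common 101-instant grid; the value at instant 50 is the raw peak-frame
   value exactly (assigned, not interpolated).  Linear interpolation is used
   because force transients must not overshoot.  Ties in the peak search go
   to the earliest frame (deterministic and order-stable); a constant
   flexion channel or a peak on a recording boundary is an error.
3. **Filtered (lunge only).**  Only the closed-chain phase — forward foot on
   its force plate — is modeled; trials flagged open-chain are discarded.
   The flag can be given explicitly or derived from an optional vertical
   ground-reaction column: closed-chain means `grf_z > 0.05 BW` at every
   frame.
4. **Averaged and stacked.**  A subject's retained repetitions are averaged
   instant-wise into one 6×101 matrix (how repeated trials collapse to one
   subject is a free design choice; averaging is the variance-minimizing
   one).  Matrices are flattened channel-major into 606-vectors and stacked
   column-wise into the training matrix `X` (606 × p, p ≥ 4).

Body-weight normalization is assumed done upstream (inverse-dynamics
pipelines emit BW units); the package neither divides by body weight nor
needs subject masses.

## The mode model

Rows (observations) of `X` are standardized: `R = D⁻¹(X − x̄ 1ᵀ)` with `D`
the diagonal of row standard deviations (denominator p − 1).  The thin SVD
`R = U L Aᵀ` yields orthonormal waveform-space modes (columns of `U`),
orthonormal subject loadings (columns of `A`), and eigenvalues
`λ_k = l_k²/(p − 1)`, non-increasing.  Standardization fixes the total
variance: `Σλ = 606` exactly, so variance shares and the compactness curve
`C(k) = Σ_{m≤k} λ_m / Σλ` are reported against 606.  This is
correlation-matrix PCA: channels with small absolute force ranges influence
the modes on an equal footing with large ones, at the price of needing a
few more components for the same cumulative variance than covariance PCA
would.

Conventions and numerical choices:

* Subjects are samples; the 606 observations are variables.  Mode scores
  `z_ik = l_k A_ik` have variance exactly `λ_k` (loading columns are
  orthogonal to the ones vector because rows of `R` are centered).
* New vectors are projected by standardizing with the fitted `x̄, D` and
  applying `Uₜᵀ`; reconstruction is `x̂ = x̄ + D Uₜ z`, so the full-rank
  round trip of any training column is exact to ~1e-9 BW.
* Modes with `λ_k < 1e-10 · λ_1` are numerically null and dropped at fit
  time.
* Each mode's sign is fixed so its largest-magnitude element is positive —
  serialization is reproducible across BLAS builds.
* Virtual subjects: scores are modeled as independent normals,
  `x̂′ = x̄ + D Σ_m n_m √λ_m u_m`, `n_m ~ N(0,1)`; the virtual-subject
  population covariance then equals the model covariance
  `D U diag(λ) Uᵀ D` (checked by a 50 000-draw recovery test).
* The fitted model serializes to a single JSON document (metadata exact,
  numerics at double precision).

`KineticPCA` follows the scikit-learn estimator contract (`fit`,
`transform`, `inverse_transform`, `get_params`/`set_params`, trailing
underscore fitted attributes), so it can sit inside sklearn pipelines; the
kinetic-specific surface (`compactness`, `n_components_for_variance`,
`mode_curves`, `sample`) lives on the same object.

## Validation estimators

All errors are RMSE in BW after un-standardization, computed per subject
and per channel (101 instants each) and summarized as median and IQR;
the grand mean over whole feature vectors is also exposed.

* **Accuracy** — reconstruction error of the training subjects from a
  t-component model, evaluated at the 80/90/95/98 % variance levels
  (dimensionality = smallest k whose cumulative variance reaches the
  level).  The median is non-increasing in t by construction of nested
  projections.
* **Generalization** — for each training-set size n: hold out one subject
  uniformly at random, fit on n subjects drawn without replacement from the
  rest, keep the components reaching 95 % variance, reconstruct the
  held-out subject.  The default number of repetitions per n is 200
  (configurable; precision of the median grows with it).  Read as a
  post-hoc sample-size analysis: the n at which the curve flattens toward
  the in-sample accuracy is the cohort size needed for a population model.
* **Specificity** — distance of model-generated virtual subjects to their
  nearest training subject (whole-vector RMSE), 2 000 draws per level by
  default.  Virtual subjects excite the full retained spectrum regardless
  of the reported level, so specificity is essentially level-independent
  and the per-level rows differ only by Monte-Carlo noise of independent
  draws — matching the near-equality observed in practice, which is itself
  the finding that questions specificity's usefulness in this setting.  A
  truncated-excitation variant (`excite_all_modes=False`), where each
  level's virtual subjects use only that level's dimensionality and one
  common batch of normal draws serves all levels, is available; it yields
  specificity increasing modestly with the level.
* **Permutation component selection** — two criteria per component, both
  with add-one p-values (`floor = 1/(B+1)`, default B = 999):
  * *Rank of roots*: deflate the first k−1 fitted components from `R`,
    permute each observation row of the residual independently across
    subjects (destroying inter-row correlation, preserving marginals), and
    compare the permuted top eigenvalue with `λ_k`.
  * *Equality of roots*: compare `λ_k / mean(λ_k..λ_r)` with the same
    statistic at position k of fully permuted (undeflated) matrices.  Note
    that defining this statistic on the *deflated* permuted matrices would
    collapse it onto the rank-of-roots test — Frobenius norm and residual
    rank are permutation-invariant, making the two statistics proportional
    — so the undeflated null is the substantive choice.
  A sequential selection rule counts leading components until the first
  p-value above α; isolated later significances are attributed to chance.

## Synthetic cohort generator

The generator emulates the output of a motion-capture +
musculoskeletal-simulation front end with known ground truth:

* **Mean waveforms** are smooth raised-cosine-squared bumps peaking at 50 %
  progress, split over x/y/z by fixed unit direction vectors per joint, with
  resultant peak magnitudes at the cohort-typical values (squat: hip
  3.08 BW, knee 4.52 BW; lunge: 4.76 / 7.16 BW) and a 0.5 BW standing load.
* **Spread profile** `D` is 0.02 + 0.13·bump BW per channel — inter-subject
  variability widest at peak flexion.
* **Planted modes** start as random smooth curves (≤ 12 cosine harmonics per
  channel), are orthonormalized, and are then *variance-levelled*: an
  alternating rescale/re-orthonormalize iteration makes the
  eigenvalue-weighted pooled variance `Σ_m λ_m u_m(o)²` identical at every
  observation (converges to ~1e-10 in a few dozen iterations).  Row
  standardization then rescales all observations equally, so the spectrum
  of the generated population's correlation structure *equals* the planted
  spectrum — parameter-recovery tests compare numbers, not tendencies.
  Levelling trades some smoothness of the planted modes for this exactness.
* **Spectra** default to the reference squat spectrum (15 modes) or the
  default lunge spectrum (first three modes at the reference shares, tail
  constructed to give dimensionality 5/9/13/17 at the 80/90/95/98 %
  levels).  The default noise SD makes every standardized observation have
  exactly unit variance, i.e. planted-spectrum recovery without
  renormalization; `GroundTruthModel.expected_spectrum()` gives the
  planted values as the pipeline sees them for any noise level.
* **Scores** are standard normal, and by default empirically whitened
  across the cohort (exact zero mean, identity sample covariance), so the
  realized spectrum does not carry the O(√(2/p)) eigenvalue sampling noise
  of raw draws — at p = 100 that noise alone is ~14 % per eigenvalue, which
  would drown recovery checks.  `whiten_scores=False` restores raw
  sampling.
* **Raw embedding**: each subject's 6×101 curves are sampled onto a
  motion segment whose frame count is a multiple of 50 (so alignment
  positions coincide with raw frames and preparation reproduces the
  planted waveforms without interpolation error), wrapped with a flexion
  ramp topping out just below the 5 % trim threshold, standing plateaus of
  random length per trial, and held boundary forces.  Motion-segment
  geometry is drawn once per cohort and shared by all subjects, keeping
  preparation an identical linear map across subjects; this is what makes
  the planted-rank invariant exact (exactly K nonzero eigenvalues at zero
  noise).  Optional per-trial measurement noise and an open-chain
  perturbation (flagging a fraction of trials) exercise averaging and
  filtering.

What the generator does **not** emulate: per-subject flexion-profile and
duration variability (geometry is shared within a cohort), channel-specific
spread profiles, non-Gaussian score distributions, and systematic
inverse-dynamics artifacts.  Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions
(multivariate normal scores, independent noise) — not robustness of the
modeling approach to real-data violations of those assumptions.

## Scaling and defaults

Reference-scale analyses use T_g = 10 000 generalization replicates per
size and T_s = 1 000 000 virtual subjects; the package defaults are
T_g = 200 and T_s = 2 000, which pin medians to ~1 % — appropriate for
interactive runs — and the reference values remain reachable through
function arguments or the CLI/config.  Permutation defaults: B = 999
(p-value floor 0.001), components 1–15 tested.  The test suite uses
cohorts of p = 20–100 subjects and B = 99–199.

## Known limitations

* The sequential rank-of-roots test is slightly anti-conservative one step
  past the true rank (the post-deflation residual's top eigenvalue and its
  permuted null both sit at the random-matrix bulk edge; the observed one
  rides systematically a little higher).  Measured at p = 100 with three
  strong planted modes: the selected rank exceeds 3 on roughly one cohort
  in five at α = 0.05, by one component.  The k = 1 test is exact (the
  permutation orbit is exchangeable under the null; verified uniform).
  Conclusions about model rank should rest on the modal outcome across
  cohorts, or on both criteria together, not on a single borderline
  p-value.
* Specificity compares in BW space; comparing in standardized space would
  weight low-variance observations more heavily and is not implemented.
* The generalization protocol samples the held-out subject rather than
  cycling exhaustively; for T_g much larger than p the difference is
  immaterial.
* Trimming assumes a unimodal flexion profile per repetition; recordings
  containing several repetitions must be segmented upstream.
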