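# Methods

## Overview

`hyfcnet` implements a network-of-networks analysis of ROI-averaged
resting-state fMRI time series for two-group classification (e.g.
patients vs controls).  The pipeline is:

1. **Sliding-window segmentation.** A subject's `P × R` series is cut
   into `K = ⌊(P − L)/S⌋ + 1` windows of `L` volumes sliding by `S`.
   The static analysis is the limiting case `L = P` (one window).
2. **Three FC network types per window.** With the window's columns
   centred and scaled to unit norm (`X'`):
   - low-order: `C = X'ᵀX'` — pairwise Pearson correlation of ROI
     signals;
   - high-order: `H = C'ᵀC'` — Pearson correlation between pairs of
     low-order connectivity profiles (columns of `C`, re-standardized);
   - associated high-order: `A = C'ᵀH'` — correlation of each low-order
     profile with each high-order profile, symmetrized as `(A + Aᵀ)/2`.
3. **Edge spectra.** Each edge's length-`K` dynamic series is mapped to
   `Q = ⌊K/2⌋ + 1` one-sided DFT power values; bin `q` of all edges
   forms a time-invariant spectral network `Z^q` (frequency
   `q/(K·S·TR)` Hz).
4. **Node features.** The weighted local clustering coefficient
   `f_i = 2 Σ_{j∈Ω_i} Z_ij^{1/3} / (v_i(v_i − 1))` of every node in
   every `Z^q`, concatenated frequency-major into a `Q·R` vector per
   subject and network type.
5. **Selection and classification.** Per network type: column
   standardization, PCA to the ≤ N−1 nonzero-variance components, LASSO
   (L1 regression on ±1 labels) keeping nonzero-coefficient components.
   Subject vectors are unit-normalized, turned into linear Gram
   matrices, fused as `K = τ₁K_L + τ₂K_H + τ₃K_A` with `(τ₁,τ₂,τ₃)` on
   the probability simplex, and classified by a soft-margin SVM (C = 1).
   Nested leave-one-out CV: the outer loop estimates performance, the
   inner loop (on each N−1 training set) picks the LASSO penalty per
   type and the kernel weights.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `window_length L` | 70 volumes | 210 s at TR = 3 s, above the 100 s wavelength of a 0.01 Hz high-pass cutoff — suppresses spurious dynamic-FC fluctuation |
| `window_step S` | 1 volume | maximal overlap; the edge series is sampled every `S·TR` = 3 s |
| spectrum | one-sided `|DFT|²`, DC bin kept | simplest reading; the DC bin carries the mean FC level. `demean_edge_series` and `spectrum_kind="amplitude"` are config switches |
| WLCC variant | `as_printed` | the formula above; no triangle requirement. An Onnela-style triangle variant (`onnela`) is available for comparison |
| neighbourhood `Ω_i` | `Z_ij > 0` | no magnitude threshold; power weights are generically positive, so `v_i = R − 1` except in degenerate graphs; `v_i ≤ 1` scores 0 |
| λ grid | 20 log-spaced in `[10⁻³λ_max, λ_max]` | `λ_max` (smallest penalty selecting nothing) from each outer-training set, shared across inner folds (glmnet convention). Zero-selection folds fall back to the smallest λ with a nonempty active set |
| τ grid | step 0.1 → 66 triples | matches the granularity at which weight optima like (0.3, 0.5, 0.2) are reported |
| SVM | linear kernel, C = 1, tol 1e−6 | the reference protocol's setting |
| feature normalization | unit Euclidean norm per subject | uses no cross-subject statistics, hence cannot leak test information |

Ties in inner-CV accuracy break deterministically: λ toward the
smallest value, τ toward larger weight on the low-order kernel, then on
the high-order kernel.

## Numerical choices

- Correlation products are clipped to [−1, 1], symmetrized by
  `(M + Mᵀ)/2` and (for C, H) the diagonal is pinned at 1, removing
  round-off outside the Pearson range.
- A centred column with Euclidean norm ≤ 1e−12 is treated as constant
  and raises an error naming the ROI/window rather than emitting NaNs,
  which would silently poison the FFT and WLCC stages.
- PCA components with eigenvalue < 1e−10 × the largest are dropped as
  numerically zero; LASSO coordinate descent runs at tolerance 1e−7.
- The precomputed-kernel C-SVC dual is solved by an in-package SMO
  routine (maximal-violating-pair selection, KKT tolerance 1e−6,
  intercept from the violation bounds) compiled with numba; nested
  LOOCV needs on the order of 10⁵ fits per cohort, which rules out
  constructing a full estimator object per fit.  The solver is
  cross-checked against scikit-learn's `SVC(kernel="precomputed")` in
  the test suite (agreement to 1e−4 in decision values).
- AUC is the rank statistic on decision values, ties counting ½.
- Point-biserial r² uses population (divide-by-n) standard deviations so
  it equals the squared Pearson correlation with 0/1 labels exactly;
  zero-variance edges are reported as missing (NaN), not zero.

## The synthetic cohort

Real two-group ROI data cannot ship with the package, so a generator
(`synthetic.py`) plants the kind of structure the method is built to
detect.  ROIs are split into contiguous modules, each driven by a
latent standard-normal factor; an ROI in module `m` observes

    x_i(t) = √c(t)·u_m(t) + √(1 − c(t))·ε_i(t) + σ·η_i(t),

so the instantaneous within-module coupling `c(t) = b + a_g·sin(2π f_g
t + φ)` *is* the planted connectivity, with group-specific modulation
amplitude `a_g` and frequency `f_g` and a uniform per-subject phase.

Defaults (chosen once as the study conditions): 15 subjects per group,
R = 30 ROIs in 3 modules, P = 130 volumes at TR = 3 s (so L = 70, S = 1
gives K = 61 and Q = 31), base coupling b = 0.30, measurement noise
σ = 0.25, modulation at 0.003 Hz.  The slow 0.003 Hz modulation is
deliberate: a 70-volume window acts as a 210 s moving average whose
transfer function suppresses anything much faster, and 0.003 Hz retains
roughly half its amplitude after windowing.  The "strong" preset gives
group 1 amplitude 0.4 and group 0 amplitude 0; because the sinusoid has
zero mean and signal variance is independent of `c`, the groups differ
*only* in connectivity dynamics — time-averaged FC, per-ROI variance
and module structure are matched, which is precisely the regime where
spectral dynamic-FC features should beat static ones.

What the generator does **not** emulate: hemodynamic convolution and
its low-pass spectrum, scanner drift and motion artifacts, spatially
heterogeneous coupling within modules, negative coupling, and
between-module anticorrelation.  Passing tests therefore show the
machinery is correct and sensitive to planted covariance dynamics at
realistic sizes — not that any particular clinical accuracy transfers
to real fMRI.

## Known limitations

- Nested LOOCV on N = 30 is noisy: inner-CV accuracy over 29 folds is
  quantized in steps of 1/29, so hyperparameter choices (especially the
  kernel weights) can flip on ties, and leave-one-out's slight training
  imbalance biases null-data accuracy somewhat below 50%.  These are
  properties of the protocol, not of the implementation.
- The associated network's raw asymmetry is discarded by default
  (symmetrization), matching the reference protocol; pass
  `symmetrize=False` to inspect the raw matrix.
- Static-mode WLCC needs nonnegative weights, so static correlation
  networks are passed through absolute value (or positive clipping) —
  an interpretation the dynamic pipeline does not need, since power
  spectra are nonnegative by construction.
- Feature provenance (network type, frequency, ROI) is tracked at the
  table level in CSV headers, not per PCA component; components mix all
  input columns by construction.
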