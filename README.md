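# hyfcnet

Hybrid low-, high- and associated high-order **dynamic functional
connectivity networks** for two-group rs-fMRI classification.

Conventional functional connectivity (FC) correlates the BOLD time
series of two brain regions.  `hyfcnet` builds, on every sliding
window `X^k` of a subject's ROI time series (columns standardized):

- the **low-order** network `C^k = (X^k)ᵀX^k` — pairwise Pearson
  correlation of ROI signals;
- the **high-order** network `H^k = (C^k)ᵀC^k` — the "correlation of
  correlations" between pairs of low-order connectivity profiles;
- the **associated high-order** network `A^k = (C^k)ᵀH^k`, symmetrized
  as `(A + Aᵀ)/2` — the cross-level correlation between each low-order
  profile and each high-order profile.

With `K = ⌊(P − L)/S⌋ + 1` windows, each edge's dynamic series
`g_ij = [C_ij¹, …, C_ij^K]` is transformed by FFT into one-sided power
spectra, giving `Q = ⌊K/2⌋ + 1` frequency-specific networks
`Z¹ … Z^Q`.  Nodal features are the weighted local clustering
coefficient

    f_i^q = 2 Σ_{j∈Ω_i} (Z_ij^q)^{1/3} / (v_i (v_i − 1)),

concatenated frequency-major per subject.  Per network type the
features pass standardization → PCA (≤ N−1 components) → LASSO
selection; linear kernels of the three types are fused as
`K = τ₁K_L + τ₂K_H + τ₃K_A` (τ on the probability simplex) and
classified by a soft-margin SVM (C = 1) under **nested leave-one-out
cross-validation** (outer loop for performance, inner loop for the
LASSO penalties and kernel weights).

The intended users are methods researchers who want a reproducible,
fully testable reference implementation of this family of dynamic-FC
pipelines; a synthetic modular-coupling cohort generator stands in for
clinical data, so everything runs from a clean checkout.

## Worked example

```python
from hyfcnet import CohortSpec, RunConfig, generate_cohort, run_pipeline

# two groups of 10 subjects; group 1's within-module coupling oscillates
# at 0.004 Hz (amplitude 0.5), group 0's coupling is constant
spec = CohortSpec(n_per_group=10, n_rois=16, n_timepoints=100, n_modules=4,
                  modulation_amplitude=(0.0, 0.5),
                  modulation_frequency_hz=(0.004, 0.004), seed=1)
cohort, labels = generate_cohort(spec)

config = RunConfig(window_length=40, n_lambdas=10, tau_step=0.2)
report, result = run_pipeline(cohort, labels, config)
m = result.metrics
print(f"ACC={100*m.acc:.1f}%  AUC={m.auc:.3f}  "
      f"SEN={100*m.sen:.1f}%  SPE={100*m.spe:.1f}%")
```

prints

```
ACC=75.0%  AUC=0.700  SEN=70.0%  SPE=80.0%
```

i.e. 15 of the 20 held-out predictions are correct, the decision values
rank a random patient above a random control with probability 0.70, and
the sensitivity/specificity split is 7/10 vs 8/10.  `report` addition-
ally records, per outer fold, the chosen kernel weights and the number
of LASSO-selected components per network type.

The same pipeline is scriptable from the shell:

```bash
hyfcnet simulate --preset strong --seed 1 --out cohort/
hyfcnet run --manifest cohort/manifest.csv --report report.json
hyfcnet evaluate --manifest cohort/manifest.csv --types low,high,associated --out maps/
```

Subjects are plain CSV (rows = time points, columns = ROIs, header =
ROI labels) listed in a `manifest.csv` with `subject_id`, `path` and a
binary `label` column, so real ROI-extracted data drops in unchanged.

## Layout

- `src/hyfcnet/networks.py` — windowing and the C/H/A constructions
- `src/hyfcnet/spectral.py` — edge dynamic series and power-spectral networks
- `src/hyfcnet/graph_features.py` — weighted local clustering coefficients
- `src/hyfcnet/selection.py` — standardize → PCA → LASSO with frozen train statistics
- `src/hyfcnet/svm.py`, `classification.py` — SMO solver, kernel fusion, nested LOOCV
- `src/hyfcnet/evaluation.py` — ACC/AUC/SEN/SPE and point-biserial r² separability maps
- `src/hyfcnet/synthetic.py` — modular latent-factor cohort generator
- `src/hyfcnet/io.py`, `config.py`, `cli.py`, `pipeline.py` — I/O, config, CLI, orchestration

See `docs/methods.md` for the model details, parameter rationale and
known limitations.
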