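# restdcm

Spectral dynamic causal modeling (DCM) of resting-state fMRI ROI time
series, built around the question of how the hippocampal formation couples
into the default mode network (DMN). The package provides, as tested
library code plus a thin CLI, the full analysis chain of a resting-state
effective-connectivity study:

* a **generative simulator**: latent neural dynamics `dx/dt = A x + v(t)`
  with a directed coupling matrix `A` (Hz) and power-law endogenous
  fluctuations, fed through the nonlinear balloon hemodynamic cascade to
  BOLD, sampled at TR with power-law observation noise;
* **feature extraction**: discrete cosine bases for the 0.0078–0.1 Hz
  resting band, principal eigenvariates of voxel clusters, confound
  residualization, and cross-spectral densities from multivariate
  autoregressive (MAR) or Welch estimators;
* the **spectral-DCM engine**: a linearized generative model of BOLD cross
  spectra `S(f) = T(f) G_v(f) T(f)^H + G_e(f)` with
  `T(f) = diag(K(f)) (i2πf I − A)^{-1}`, inverted by variational Laplace
  (damped Gauss–Newton with a free-energy acceptance rule), returning
  posterior moments and the free energy `F` ≈ log model evidence;
* the study's **model spaces**: 8 base DMN families (a–h) × 12 hippocampal
  inclusion patterns (1–12) = 96 five-node models per hemisphere, the
  PCC-removed 72-model space over the six deduplicated families
  (a′, e′, b′, f′, d′, h′), and the combined six-node model (a_1 for RHIP
  with a_6 for LHIP);
* **group inference**: fixed-effects Bayesian model selection, family
  posteriors, win counts, Bayesian model averaging (BMA), Bayesian
  parameter averaging (BPA), cross-subject F-value stability matrices, and
  left/right hippocampal lateralization contrasts;
* **functional connectivity**: Fisher-z Pearson correlations with
  Benjamini–Hochberg FDR control across the 15 unique region pairs.

The target users are researchers who want a transparent, dependency-light
re-implementation of this analysis style to study its statistical behavior
on fully known synthetic ground truth — no scanner data are required
anywhere.

## Worked example

Simulate eight subjects from the `a_6` model (fully connected DMN core,
LHIP receiving from the parietal nodes and driving all four), invert the
generating model, and compare estimated with generating couplings:

```python
import numpy as np
import restdcm as rd

spec = next(m for m in rd.full_space("LHIP") if m.name == "a_6")
base = rd.default_coupling(spec, strength=0.2)      # ±0.2 Hz couplings
cfg = rd.SimulationConfig(n_scans=1000, tr=2.0, seed=11, subject_sd=0.05)
truths = rd.make_group_truth(spec, base, cfg, n_subjects=8)
group = rd.synthetic_data.simulate_group(truths, cfg, regions=spec.regions)

mask = spec.mask.astype(bool)
est = []
for ts in group:
    res = rd.invert(rd.subject_csd(ts), spec)
    est.append(res.coupling_matrix()[mask])
gmean = np.mean(est, axis=0)
r = np.corrcoef(base.A[mask], gmean)[0, 1]
print(f"group-level recovery r = {r:.3f}")
```

```
group-level recovery r = 0.943
```

The printed correlation compares the generating off-diagonal couplings
(Hz) with their across-subject mean posterior estimates; values above 0.9
are typical for study-sized groups, while single-subject estimates carry
substantially more noise (pooled per-subject r ≈ 0.7–0.85).

The same pipeline is available from a shell:

```bash
restdcm space --include LHIP --out space.json     # 96 models
restdcm run --seed 1 --subjects 8 --out run/      # simulate→invert→group→FC
```

`run/manifest.json` lists every artifact with checksums; identically
seeded runs are byte-identical.

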