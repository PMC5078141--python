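# Methods

## Generative model

Subject-level resting BOLD over `n` regions is modeled in two stages.

**Latent neural dynamics.** A linear stochastic system
`dx/dt = A x + v(t)`, with `A` the effective-connectivity matrix in Hz:
`A[i, j]` is the directed influence of region `j` on region `i`, the
diagonal is self-inhibition and must keep every eigenvalue in the left
half-plane. Endogenous fluctuations `v` are zero-mean with two-sided
spectral density `amp_v · f^(−exp_v)` per region (pink, `exp_v = 1`, by
default). All densities in the package are two-sided densities evaluated
at positive frequencies, in signal-variance per Hz; the frequency-domain
noise synthesizer, the Welch estimator (after halving scipy's one-sided
output) and the model spectra all share this convention, which is what
makes the cross-estimator and simulator-vs-model tests meaningful.

**Hemodynamics.** Each region's latent state drives the balloon cascade
(vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q):

    s' = x − κs − γ(f − 1)
    f' = s
    τ v' = f − v^(1/α)
    τ q' = f·(1 − (1 − E0)^(1/f))/E0 − v^(1/α) q/v

with BOLD read-out `y = V0(k1(1−q) + k2(1−q/v) + k3(1−v))`,
`k1 = 7E0, k2 = 2, k3 = 2E0 − 0.2`. Constants (κ = 0.64 s⁻¹, γ = 0.32 s⁻¹,
τ = 2 s, α = 0.32, E0 = 0.4, V0 = 0.04) are the standard spectral-DCM
values and are overridable per region.

**Integration.** The latent SDE uses Euler–Maruyama at dt = 0.125 s with
the forcing synthesized exactly in the frequency domain (magnitudes from
the target density, uniform random phases). The balloon cascade is
deterministic given x, so it is integrated with classical RK4 at the same
step with the input held per step: Euler at dt = 0.125 s leaves a
discretization error near 10% of the signal SD, large enough to corrupt
coupling recovery, while the RK4 error is ~1% and indistinguishable from
an 8× finer reference. A 64 s burn-in is discarded and the output sampled
every TR = 2 s around a unit baseline; observation noise with density
`amp_e · f^(−exp_e)` is added at the scan level.

## Simulated study conditions

Defaults mirror the study design the package targets: groups of 26
subjects, 1000 scans at TR 2 s, six regions (mPFC, PCC, LIPC, RIPC, LHIP,
RHIP at their standard MNI coordinates), couplings on the ±0.2–0.3 Hz
scale with between-subject jitter SD 0.05 Hz (redrawn until stable),
`amp_v = 1.5·10⁻⁴` chosen so latent states have SD ≈ 0.1 — small enough
that the balloon stage stays near its linear regime, which is also the
regime the inversion model assumes — and `amp_e = 3.2·10⁻⁶`, i.e.
observation noise at roughly 17% of the BOLD signal SD. The resulting
mean/SD SNR per region is ≈ 30, far above the 2.4 floor reported for real
resting acquisitions. What the simulator does **not** emulate: head
motion, physiological confounds, scanner drift, spatial structure (voxel
synthesis is a rank-1 loading model for testing eigenvariate extraction),
and task-evoked inputs. Passing tests therefore demonstrate correctness
and calibration of the statistical machinery under the model's own
assumptions plus hemodynamic nonlinearity and sampling — not robustness to
artifacts of real scanner data.

## Feature path

Series are residualized against an intercept (optionally a discrete-cosine
drift block; if a high-pass is used, the analysis band must start above
the cutoff — filtering inside the fitted band biases the spectra and
measurably degrades recovery), standardized to unit mean variance, and
summarized by a cross-spectral density on 32 linearly spaced frequencies
in [1/128, 0.1] Hz. A log-spaced grid down to the fundamental 1/(N·TR)
was rejected: with power-law spectra it concentrates the fit where the
density is orders of magnitude larger than in the coupling-sensitive band.
The default estimator is an OLS MAR of order 12 (order 8 is the common
convention but measurably worse for coupling recovery here; both are one
keyword away), with a Welch estimator (Hann, 50% overlap, segments of
N/8 by default) as the independent cross-check.

## Inversion

The spectral-DCM likelihood treats the stacked real and imaginary parts of
the full Hermitian CSD (diagonal once, each off-diagonal pair with weight
√2) as Gaussian with a single shared precision `e^λ` across entries and
frequencies. Free parameters: masked off-diagonal couplings (prior
N(0, 1/64) Hz), self-connections `a_ii = −0.5·e^θ` with θ ~ N(0, 1/256),
per-region transit-time log-scales N(0, 1/256), and shared log noise
amplitudes N(0, 1/64) and spectral exponents N(1, 1/64); hyperprior
λ ~ N(4, 1). Reference noise amplitudes are set per dataset by scaling the
data to unit mean diagonal power and splitting it evenly between the
endogenous and observation arms at prior-mean parameters (the split barely
matters; the log-amplitudes adjust within their priors).

Optimization is damped Gauss–Newton on the parameters (finite-difference
residual Jacobian, Levenberg–Marquardt damping ×8 on rejection and ÷2 on
acceptance, steps accepted only if the Laplace free energy increases)
alternating with Newton updates of λ; convergence at |ΔF| < 0.01 nats or
64 iterations. F is the Laplace free energy — joint log density at the
mode plus the Gaussian-volume corrections from the curvature over (θ, λ)
— so only differences and ranks of F are meaningful across
implementations. Because near-noiseless data can strand the default start
on a plateau (worth hundreds of nats), `invert` runs three deterministic
starts by default (prior mean plus two coupling-jittered points, same
priors) and keeps the best-F run. Masked couplings are removed from the
parameter vector entirely; unstable proposals (spectral abscissa ≥ 0, or
|exponent| ≥ 6) are rejected via a −∞ objective sentinel.

## Group statistics

Fixed-effects BMS sums F over subjects and softmaxes; family posteriors
use logsumexp of member evidences minus log member count (uniform family
prior, so large families cannot win by size). BMA weights each subject's
per-model posterior means by that subject's softmaxed F row (optionally
within an Occam window) with absent couplings contributing zero;
significance is an across-subject one-sample t-test at p < 0.05, with a
Bonferroni flag emitted alongside since the convention in published
tables is ambiguous. BPA fuses single-subject Gaussian posteriors by
precision addition, subtracting the shared prior S−1 times, flagging
|mean| > 1.645 SD. Stability matrices are Pearson correlations between
subjects' F-vectors. The lateralization contrast is a paired t-test of
LHIP→target vs RHIP→target couplings on the combined six-node model,
which includes both inter-hippocampal directions a priori and lets the
inversion shrink the unsupported one.

## Functional connectivity

Per subject, Fisher z = atanh(r) of pairwise Pearson correlations
(diagonal excluded); at the group level, per-edge one-sample t-tests with
Benjamini–Hochberg FDR at q = 0.05 across the 15 unique edges of the
six-region set.

## Validation experiments and problem sizes

`restdcm.validation` regenerates everything from a seed: model-space
combinatorics (8/12/96/6/72), the 400-function cosine basis, evidence
bookkeeping over 26 subjects × (96 + 72) models (capped at one
Gauss–Newton iteration per inversion — the count, not the fit, is the
point), coupling recovery on 8 study-sized subjects, model identification
over the 12 family-a patterns (10 replicates × 2 subjects), the
grid-search and estimator checks, and FC calibration (26 × 1000 recovery;
1000-replicate null FDR). These sizes keep the whole battery in roughly
ten minutes on one CPU.

Two honest findings deserve emphasis. First, single-subject coupling
recovery from 1000 scans is information-limited: pooled per-subject
correlation with the generating couplings plateaus near 0.75–0.85 (a
linear-hemodynamics synthetic ceiling sits near 0.83), while group-mean
estimates reach 0.93–0.96; the recovery check is therefore stated at the
group level, matching how such studies tabulate connection strengths.
Second, evidence-based identification of the generating inclusion pattern
a_6 against its fully connected superset a_1 systematically fails on
estimated cross spectra: CSD sampling error is smooth and correlated, the
extra couplings absorb it (gaining more accuracy than the ~1 nat
complexity penalty per parameter), and a_1 wins most replicates. This is
a structural property of the shared-precision likelihood on MAR features
— it persists under multistart optimization, different grids, priors,
estimators, linearized hemodynamics, and 8× longer runs — and is a known
hazard of evidence-based selection among nested models. The corresponding
identification check in the validation battery is expected to fail and is
reported as measured.

## Known limitations

Single shared noise precision (no frequency-resolved hyperparameters), no
random-effects BMS or exceedance probabilities, no Bayesian model
reduction or hierarchical (PEB) group models, no volumetric data handling.
F values are implementation-relative; compare only within one pipeline.
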