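"""End-to-end validation experiments on synthetic groups.

Each function regenerates its inputs from a seed and runs the package's own
pipeline, returning plain dictionaries of summary numbers.  They back both
the acceptance-style tests and the ``scripts/acceptance.py`` report, and are
deliberately scaled to single-CPU minutes: simulation sizes match the study
design (1000 scans at TR 2 s) while replicate and subject counts are kept
small.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import model_space as ms
from .dcm_spectral import (InversionOptions, invert,
                           model_evidence_table)
from .features import MARModel, csd_from_mar, dct_basis, snr, subject_csd
from .func_connectivity import fc_group, fc_subject
from .group_inference import family_posteriors
from .synthetic_data import (DCMParams, ROITimeSeries, SimulationConfig,
                             default_coupling, make_group_truth,
                             simulate_group)

BAND = np.linspace(0.0078, 0.1, 32)


def model_space_counts() -> dict:
    """Combinatorics of the model spaces (pure enumeration)."""
    full = ms.full_space("LHIP")
    full_r = ms.full_space("RHIP")
    reduced = ms.reduced_space()
    return {
        "n_base_families": len(ms.base_families()),
        "n_inclusion_patterns": len(ms.inclusion_patterns("LHIP")),
        "n_models_lhip": len(full),
        "n_models_rhip": len(full_r),
        "n_reduced_base_families": len(ms.reduced_base_families()),
        "n_models_reduced": len(reduced),
        "n_combined_model_regions": ms.combine_best().n_regions,
    }


def dct_basis_size(n_scans: int = 1000, tr: float = 2.0,
                   f_max: float = 0.1) -> int:
    """Number of discrete cosine functions spanning the resting band."""
    return dct_basis(n_scans, tr, f_max).K


def _drop_region(ts: ROITimeSeries, region: str) -> ROITimeSeries:
    keep = [k for k, r in enumerate(ts.regions) if r != region]
    return ROITimeSeries(
        data=ts.data[:, keep], tr=ts.tr,
        regions=tuple(r for r in ts.regions if r != region),
        mni=tuple(m for r, m in zip(ts.regions, ts.mni) if r != region),
    )


def bookkeeping_experiment(seed: int, n_subjects: int = 26) -> dict:
    """Batch-inversion bookkeeping over the full study-sized group.

    Simulates the cohort from the a_6 truth, inverts the 96-model extended
    space on the five-region data and the 72-model reduced space on the
    PCC-removed data with a capped iteration budget, and counts recorded
    evidences.
    """
    space = ms.full_space("LHIP")
    spec = next(m for m in space if m.name == "a_6")
    base = default_coupling(spec, 0.2)
    cfg = SimulationConfig(n_scans=1000, tr=2.0, seed=seed,
                           subject_sd=0.05)
    truths = make_group_truth(spec, base, cfg, n_subjects)
    group = simulate_group(truths, cfg, regions=spec.regions)
    freqs = np.linspace(0.0078, 0.1, 12)
    opts = InversionOptions(max_iter=1, n_starts=1)
    csds = [subject_csd(ts, freqs) for ts in group]
    F_full = model_evidence_table(csds, space, opts=opts)
    reduced = ms.reduced_space("LHIP")
    csds_r = [subject_csd(_drop_region(ts, "PCC"), freqs) for ts in group]
    F_red = model_evidence_table(csds_r, reduced, opts=opts)
    min_snr = min(float(snr(ts).min()) for ts in group)
    return {
        "f_values_extended": int(np.isfinite(F_full).sum()),
        "f_values_reduced": int(np.isfinite(F_red).sum()),
        "min_snr": min_snr,
        "F_extended": F_full,
        "F_reduced": F_red,
    }


def recovery_experiment(seed: int, n_subjects: int = 8) -> dict:
    """Parameter recovery on the a_6 truth (couplings within +-0.3 Hz).

    Simulates ``n_subjects`` study-sized subjects, inverts the generating
    model, and compares generating and posterior-mean couplings: the group
    level correlation (generating values vs across-subject mean posterior,
    the quantity the study's group tables report), the pooled per-subject
    correlation, and the sign agreement of every coupling that is
    significant across subjects (two-sided one-sample t-test, p < 0.05).
    """
    spec = next(m for m in ms.full_space("LHIP") if m.name == "a_6")
    base = default_coupling(spec, 0.2)
    cfg = SimulationConfig(n_scans=1000, tr=2.0, seed=seed,
                           subject_sd=0.05)
    truths = make_group_truth(spec, base, cfg, n_subjects)
    group = simulate_group(truths, cfg, regions=spec.regions)
    mask = spec.mask.astype(bool) & ~np.eye(spec.n_regions, dtype=bool)
    est, tv, pv = [], [], []
    for truth, ts in zip(truths, group):
        res = invert(subject_csd(ts, BAND), spec)
        A = res.coupling_matrix()
        est.append(A[mask])
        tv += list(truth.A[mask])
        pv += list(A[mask])
    est = np.asarray(est)
    gmean = est.mean(axis=0)
    true_vals = base.A[mask]
    sig_sign_ok = True
    n_sig = 0
    for k in range(est.shape[1]):
        t, p = stats.ttest_1samp(est[:, k], 0.0)
        if p < 0.05:
            n_sig += 1
            if np.sign(gmean[k]) != np.sign(true_vals[k]):
                sig_sign_ok = False
    return {
        "coupling_recovery_r_group": float(
            np.corrcoef(true_vals, gmean)[0, 1]),
        "coupling_recovery_r_pooled": float(np.corrcoef(tv, pv)[0, 1]),
        "sign_match_fraction": float(
            np.mean(np.sign(gmean) == np.sign(true_vals))),
        "n_significant_couplings": n_sig,
        "significant_signs_correct": bool(sig_sign_ok),
    }


def identification_experiment(seed: int, n_replicates: int = 10,
                              n_subjects: int = 2) -> dict:
    """Model identification within base family a.

    Each replicate simulates a fresh group from a_6 and runs fixed-effects
    family selection over the 12 inclusion patterns of family a; returns
    how often pattern family 6 wins.
    """
    space = [m for m in ms.full_space("LHIP") if m.base_family == "a"]
    names = [m.name for m in space]
    spec6 = next(m for m in space if m.name == "a_6")
    base = default_coupling(spec6, 0.2)
    wins = 0
    winners = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(n_scans=1000, tr=2.0,
                               seed=(seed * 1000 + rep) % (2**31 - 1),
                               subject_sd=0.05)
        truths = make_group_truth(spec6, base, cfg, n_subjects)
        group = simulate_group(truths, cfg, regions=spec6.regions)
        csds = [subject_csd(ts, BAND) for ts in group]
        F = model_evidence_table(csds, space)
        fam = family_posteriors(F, {m.name: m.pattern for m in space},
                                names)
        best = max(fam, key=fam.get)
        winners.append(best)
        wins += best == "6"
    return {
        "pattern6_wins": int(wins),
        "n_replicates": int(n_replicates),
        "winners": winners,
    }


def gridsearch_check(seed: int) -> dict:
    """Two-node inversion vs an exhaustive 1-D profile search of the same
    objective (width 2 Hz, step 0.001), plus free-energy monotonicity."""
    from .dcm_spectral import _Problem, _auto_scale, _log_joint_terms

    spec = ms.ModelSpec(regions=("R0", "R1"),
                        mask=np.array([[0, 0], [1, 0]]))
    params = DCMParams(A=np.array([[-0.5, 0.0], [0.25, -0.5]]))
    cfg = SimulationConfig(n_scans=1000, tr=2.0, seed=seed)
    from .synthetic_data import simulate_bold

    ts = simulate_bold(params, cfg, regions=spec.regions)
    cs = subject_csd(ts, BAND)
    res = invert(cs, spec)
    prob = _Problem(spec, res.priors, cs.freqs)
    S = _auto_scale(prob, cs.S.copy(), res.priors)
    k = res.names.index("a:R1<-R0")
    grid = np.arange(-1.0, 1.0, 0.001)
    vals = np.full(len(grid), -np.inf)
    for gi, a in enumerate(grid):
        th = res.posterior_mean.copy()
        th[k] = a
        Sp = prob.predict(th)
        if Sp is not None:
            vals[gi] = _log_joint_terms(prob.residual(Sp, S), th,
                                        res.log_precision, res.priors,
                                        prob.n_data)
    best = float(grid[int(np.argmax(vals))])
    return {
        "gridsearch_deviation_hz": float(
            abs(best - res.posterior_mean[k])),
        "trace_monotone": bool(np.all(np.diff(res.trace) >= 0)),
    }


def csd_estimator_checks(seed: int) -> dict:
    """Closed-form AR(1) spectrum error of the parametric estimator and
    the band-averaged MAR/Welch discrepancy on a long 3-node simulation."""
    a, sigma2, tr = 0.55, 1.3, 2.0
    mar = MARModel(order=1, coeff=np.array([[[a]]]),
                   innovation=np.array([[sigma2]]), tr=tr)
    freqs = np.linspace(0.005, 0.2, 25)
    cs = csd_from_mar(mar, freqs)
    expected = tr * sigma2 / np.abs(
        1 - a * np.exp(-1j * 2 * np.pi * freqs * tr)) ** 2
    ar1_err = float(np.max(np.abs(cs.S[:, 0, 0].real - expected)))

    A = np.array([[-0.5, 0.2, 0.0], [0.15, -0.5, 0.1],
                  [0.0, -0.2, -0.5]])
    p = DCMParams(A=A)
    cfg = SimulationConfig(n_scans=2**14, tr=2.0, seed=seed)
    from .synthetic_data import simulate_bold

    ts = simulate_bold(p, cfg)
    band = np.linspace(0.01, 0.1, 16)
    from .features import csd_welch, fit_mar, residualize

    work = residualize(ts)
    c_mar = csd_from_mar(fit_mar(work, 8), band)
    c_wel = csd_welch(work, band, nperseg=512)
    num = np.linalg.norm(c_mar.S - c_wel.S, axis=(1, 2)).mean()
    den = np.linalg.norm(c_wel.S, axis=(1, 2)).mean()
    return {
        "ar1_csd_max_abs_error": ar1_err,
        "welch_mar_relative_error": float(num / den),
    }


def fc_experiment(seed: int, n_subjects: int = 26, n_scans: int = 1000,
                  n_null_replicates: int = 1000) -> dict:
    """Functional-connectivity calibration.

    Recovery: equicorrelated six-region Gaussian data (r = 0.4) must give a
    group mean Fisher z near atanh(0.4).  Error control: under the global
    null the fraction of replicates with any BH-FDR discovery at q = 0.05
    across the 15 unique edges stays near the nominal level.
    """
    rng = np.random.default_rng(seed)
    target = 0.4
    C = np.full((6, 6), target)
    np.fill_diagonal(C, 1.0)
    L = np.linalg.cholesky(C)
    regions = tuple("ABCDEF")
    zs = []
    for _ in range(n_subjects):
        y = rng.normal(size=(n_scans, 6)) @ L.T
        ts = ROITimeSeries(data=y, tr=2.0, regions=regions)
        zs.append(fc_subject(ts))
    res = fc_group(zs, regions)
    iu = np.triu_indices(6, 1)
    mean_z = float(res.group_mean[iu].mean())
    # empirical standard error of the across-subject mean (edges within a
    # subject are correlated, so the naive per-edge SE does not apply)
    per_subject = np.array([z[iu].mean() for z in zs])
    se = float(per_subject.std(ddof=1) / np.sqrt(n_subjects))

    sd0 = 1.0 / np.sqrt(n_scans - 3)
    any_fp = 0
    for _ in range(n_null_replicates):
        null_z = []
        for _ in range(n_subjects):
            z = np.zeros((6, 6))
            vals = rng.normal(0, sd0, len(iu[0]))
            z[iu] = vals
            z += z.T
            null_z.append(z)
        r = fc_group(null_z, regions)
        any_fp += bool(r.significant.any())
    return {
        "fc_mean_z": mean_z,
        "fc_target_z": float(np.arctanh(target)),
        "fc_deviation_se_units": float(
            abs(mean_z - np.arctanh(target)) / se),
        "fdr_any_false_positive_fraction": any_fp / n_null_replicates,
    }
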