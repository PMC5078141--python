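"""Spectral-DCM engine: hemodynamic kernel, generative cross spectra,
objective/gradient, variational-Laplace inversion, batch evidence tables."""

import numpy as np
import pytest

from restdcm.dcm_spectral import (InversionOptions, Priors, _Problem,
                                  _auto_scale, balloon_linearization,
                                  default_priors, hemo_transfer, invert,
                                  log_joint, model_evidence_table,
                                  neg_objective, objective_gradient,
                                  predicted_csd)
from restdcm.features import CrossSpectra, subject_csd
from restdcm.model_space import ModelSpec
from restdcm.synthetic_data import (DCMParams, DEFAULT_HEMO,
                                    SimulationConfig, balloon_bold,
                                    simulate_bold)

BAND = np.linspace(0.0078, 0.1, 32)


# ------------------------------------------------------ hemodynamic kernel

def test_hemo_kernel_is_low_pass():
    K = hemo_transfer([DEFAULT_HEMO], np.array([0.01, 10.0]))
    assert abs(K[1, 0]) < 0.01 * abs(K[0, 0])


def test_hemo_kernel_identical_regions_identical_kernels():
    K = hemo_transfer([DEFAULT_HEMO, dict(DEFAULT_HEMO)], BAND)
    assert np.array_equal(K[:, 0], K[:, 1])


def test_hemo_kernel_matches_nonlinear_impulse_response():
    """|K(f)|^2 against the squared gain of a direct impulse through the
    nonlinear balloon cascade (small-signal regime) within 10% in band."""
    dt, n_steps = 0.125, 2**13
    eps = 1e-4
    x = np.zeros((n_steps, 1))
    x[0, 0] = eps / dt  # unit-area impulse of amplitude eps/dt
    params = DCMParams(A=np.array([[-0.5]]))
    y = balloon_bold(x, params, dt)
    f = np.fft.rfftfreq(n_steps, dt)
    H = np.fft.rfft(y[:, 0]) * dt / eps
    band = (f >= 0.01) & (f <= 0.1)
    K = hemo_transfer([DEFAULT_HEMO], f[band])[:, 0]
    ratio = np.abs(H[band]) ** 2 / np.abs(K) ** 2
    assert np.max(np.abs(ratio - 1)) < 0.10


def test_unstable_hemodynamics_rejected():
    bad = dict(DEFAULT_HEMO, kappa=-1.0, gamma=-1.0)
    with pytest.raises(ValueError, match="unstable hemodynamics"):
        hemo_transfer([bad], BAND)


def test_balloon_linearization_is_stable():
    J, B, C = balloon_linearization(DEFAULT_HEMO)
    assert np.max(np.linalg.eigvals(J).real) < 0
    assert B[0] == pytest.approx(1.0)


# ----------------------------------------------------- generative spectra

def test_predicted_csd_no_fluctuations_reduces_to_noise_floor():
    p = DCMParams(
        A=np.array([[-0.5, 0.0], [0.2, -0.5]]),
        neural_noise=[{"amp_v": 1e-30, "exp_v": 1.0}] * 2,
        obs_noise=[{"amp_e": 2.0, "exp_e": 0.5}] * 2,
    )
    cs = predicted_csd(p, None, BAND)
    for fi, f in enumerate(BAND):
        assert np.allclose(cs.S[fi], 2.0 * f ** -0.5 * np.eye(2),
                           atol=1e-20)


def test_predicted_csd_symmetric_regions_diagonal():
    p = DCMParams(A=np.diag([-0.5, -0.5]))
    cs = predicted_csd(p, None, BAND)
    assert np.allclose(cs.S[:, 0, 1], 0)
    assert np.allclose(cs.S[:, 0, 0], cs.S[:, 1, 1])


def test_predicted_csd_two_node_chain_coherence_closed_form():
    """Independent elementwise evaluation of the 2x2 chain: coherence from
    scalar transfer functions must match to 1e-10."""
    a21, a = 0.3, -0.5
    p = DCMParams(A=np.array([[a, 0.0], [a21, a]]))
    amp_v = p.neural_noise[0]["amp_v"]
    exp_v = p.neural_noise[0]["exp_v"]
    amp_e = 1e-30
    for r in p.obs_noise:
        r["amp_e"] = amp_e
    cs = predicted_csd(p, None, BAND)
    coh = np.abs(cs.S[:, 1, 0]) / np.sqrt(
        cs.S[:, 0, 0].real * cs.S[:, 1, 1].real)
    iw = 1j * 2 * np.pi * BAND
    h = 1.0 / (iw - a)  # scalar latent transfer (kernel cancels)
    g = amp_v * BAND ** (-exp_v)
    S11 = g * np.abs(h) ** 2
    S21 = a21 * g * h * np.abs(h) ** 2
    S22 = g * np.abs(h) ** 2 * (1 + a21**2 * np.abs(h) ** 2)
    expected = np.abs(S21) / np.sqrt(S11 * S22)
    assert np.max(np.abs(coh - expected)) < 1e-10


def test_predicted_csd_rejects_zero_frequency_and_mask_violation():
    p = DCMParams(A=np.array([[-0.5]]))
    with pytest.raises(ValueError, match="power law|0"):
        predicted_csd(p, None, np.array([0.0, 0.01]))
    spec = ModelSpec(regions=("R0", "R1"), mask=np.array([[0, 0], [1, 0]]))
    bad = DCMParams(A=np.array([[-0.5, 0.2], [0.1, -0.5]]))
    with pytest.raises(ValueError, match="mask"):
        predicted_csd(bad, spec, BAND)


def test_predicted_csd_hermitian_psd(a6_spec, a6_group):
    _, truths, _ = a6_group
    cs = predicted_csd(truths[0], a6_spec, BAND)
    cs.validate()


# ------------------------------------------------- objective and gradient

@pytest.fixture(scope="module")
def small_problem():
    spec = ModelSpec(regions=("R0", "R1"), mask=np.array([[0, 0], [1, 0]]))
    priors = default_priors(spec)
    prob = _Problem(spec, priors, BAND)
    data = CrossSpectra(freqs=BAND, S=prob.predict(priors.mu.copy()),
                        source="model")
    return spec, priors, prob, data


def test_objective_at_perfect_fit_is_prior_constant(small_problem):
    spec, priors, prob, data = small_problem
    lam = 10.0
    val = log_joint(priors.mu, lam, data, spec, priors)
    # residual term vanishes: value equals likelihood normalization plus
    # log-prior constants
    from restdcm.dcm_spectral import _LN2PI, _log_joint_terms
    expected = _log_joint_terms(np.zeros(prob.n_data), priors.mu, lam,
                                priors, prob.n_data)
    assert val == pytest.approx(expected, abs=1e-8)
    assert neg_objective(priors.mu, lam, data, spec, priors) == -val


def test_masked_couplings_excluded_from_parameter_vector(small_problem):
    spec, priors, _, _ = small_problem
    assert "a:R1<-R0" in priors.names
    assert "a:R0<-R1" not in priors.names


def test_gradient_matches_central_finite_differences(small_problem):
    spec, priors, prob, data = small_problem
    rng = np.random.default_rng(0)
    theta = priors.mu + rng.normal(0, 0.05, len(priors.mu))
    lam = 3.0
    g = objective_gradient(theta, lam, data, spec, priors)
    h = 1e-5
    for k in rng.choice(len(theta), size=5, replace=False):
        hi, lo = theta.copy(), theta.copy()
        hi[k] += h
        lo[k] -= h
        fd = (log_joint(hi, lam, data, spec, priors)
              - log_joint(lo, lam, data, spec, priors)) / (2 * h)
        assert abs(g[k] - fd) < 1e-4 * max(1.0, abs(fd))


def test_unstable_parameters_return_minus_infinity():
    spec = ModelSpec(regions=("R0", "R1"),
                     mask=np.array([[0, 1], [1, 0]]))
    priors = default_priors(spec)
    prob = _Problem(spec, priors, BAND)
    data = CrossSpectra(freqs=BAND, S=prob.predict(priors.mu.copy()),
                        source="model")
    theta = priors.mu.copy()
    theta[0] = theta[1] = 5.0  # reciprocal 5 Hz couplings: unstable
    assert log_joint(theta, 2.0, data, spec, priors) == -np.inf


# -------------------------------------------------------------- inversion

def test_null_model_recovery():
    """Data from a fully disconnected model: self-connections recovered
    within 2 posterior SD, masked couplings exactly zero."""
    spec = ModelSpec(regions=("R0", "R1"), mask=np.zeros((2, 2), int))
    p = DCMParams(A=np.diag([-0.45, -0.6]))
    cfg = SimulationConfig(n_scans=1000, tr=2.0, seed=4)
    ts = simulate_bold(p, cfg, regions=spec.regions)
    res = invert(subject_csd(ts), spec)
    A = res.coupling_matrix()
    assert A[0, 1] == 0.0 and A[1, 0] == 0.0
    for i, true_self in enumerate((-0.45, -0.6)):
        theta = res[f"self:R{i}"]
        sd = res.sd(f"self:R{i}")
        assert abs(theta - np.log(-true_self / 0.5)) < 2 * max(sd, 0.05)


def test_two_node_coupling_recovered(two_node_subject):
    spec, params, ts, cs = two_node_subject
    res = invert(cs, spec)
    est = res["a:R1<-R0"]
    assert abs(est - 0.25) < 0.25  # right scale
    assert np.sign(est) == 1.0
    assert res.converged


def test_posterior_mode_matches_grid_search(two_node_subject):
    """The variational optimum of the free coupling agrees with an
    exhaustive 1-D profile search of the same objective to 0.01 Hz."""
    spec, params, ts, cs = two_node_subject
    priors = default_priors(spec)
    res = invert(cs, spec, priors)
    prob = _Problem(spec, res.priors, cs.freqs)
    S = _auto_scale(prob, cs.S.copy(), res.priors)
    k = res.names.index("a:R1<-R0")
    grid = np.arange(-1.0, 1.0, 0.001)
    vals = np.full(len(grid), -np.inf)
    from restdcm.dcm_spectral import _log_joint_terms
    for gi, a in enumerate(grid):
        th = res.posterior_mean.copy()
        th[k] = a
        Sp = prob.predict(th)
        if Sp is None:
            continue
        r = prob.residual(Sp, S)
        vals[gi] = _log_joint_terms(r, th, res.log_precision,
                                    res.priors, prob.n_data)
    best = grid[int(np.argmax(vals))]
    assert abs(best - res.posterior_mean[k]) <= 0.01


def test_free_energy_trace_non_decreasing(two_node_subject, a6_spec,
                                          a6_group):
    spec, _, _, cs = two_node_subject
    res = invert(cs, spec)
    assert np.all(np.diff(res.trace) >= 0)
    _, _, group = a6_group
    res6 = invert(subject_csd(group[0]), a6_spec)
    assert np.all(np.diff(res6.trace) >= 0)
    assert res6.posterior_cov.shape[0] == len(res6.names)
    assert np.all(np.linalg.eigvalsh(res6.posterior_cov) > 0)


def test_evidence_discriminates_true_from_disconnected():
    """F(true sparse 3-node mask) must beat F(fully disconnected) in at
    least 90% of seeded replicates."""
    spec_true = ModelSpec(
        regions=("R0", "R1", "R2"),
        mask=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]]),
    )
    spec_null = ModelSpec(regions=spec_true.regions,
                          mask=np.zeros((3, 3), int))
    A = np.array([[-0.5, 0, 0], [0.25, -0.5, 0], [0, 0.25, -0.5]])
    p = DCMParams(A=A)
    opts = InversionOptions(n_starts=1)
    wins = 0
    for seed in range(20):
        cfg = SimulationConfig(n_scans=600, tr=2.0, seed=seed)
        ts = simulate_bold(p, cfg, regions=spec_true.regions)
        cs = subject_csd(ts)
        f_true = invert(cs, spec_true, opts=opts).F
        f_null = invert(cs, spec_null, opts=opts).F
        wins += f_true > f_null
    assert wins >= 18


def test_complexity_penalty_on_nested_models():
    """With data carrying no evidence for the extra coupling, the larger
    model cannot beat its nested submodel."""
    spec_sub = ModelSpec(regions=("R0", "R1"), mask=np.zeros((2, 2), int))
    spec_super = ModelSpec(regions=("R0", "R1"),
                           mask=np.array([[0, 0], [1, 0]]))
    p = DCMParams(A=np.diag([-0.5, -0.5]))
    freqs = BAND
    cs0 = predicted_csd(p, None, freqs)
    rng = np.random.default_rng(2)
    scale = 0.02 * np.einsum("fii->fi", cs0.S).real.mean()
    E = scale * (rng.normal(size=cs0.S.shape)
                 + 1j * rng.normal(size=cs0.S.shape))
    S = cs0.S + 0.5 * (E + E.conj().transpose(0, 2, 1))
    data = CrossSpectra(freqs=freqs, S=S, source="model")
    f_sub = invert(data, spec_sub).F
    f_super = invert(data, spec_super).F
    assert f_sub >= f_super


def test_posterior_narrows_with_more_data(two_node_chain):
    spec, params = two_node_chain
    sds = []
    for n in (1000, 2000):
        cfg = SimulationConfig(n_scans=n, tr=2.0, seed=6)
        ts = simulate_bold(params, cfg, regions=spec.regions)
        res = invert(subject_csd(ts), spec)
        sds.append(res.sd("a:R1<-R0"))
    assert sds[1] < sds[0]


# ------------------------------------------------------------- F matrices

def test_single_pair_table_equals_direct_inversion(two_node_subject):
    spec, _, _, cs = two_node_subject
    opts = InversionOptions(n_starts=1)
    F = model_evidence_table([cs], [spec], opts=opts)
    assert F.shape == (1, 1)
    assert F[0, 0] == pytest.approx(invert(cs, spec, opts=opts).F)


def test_table_records_failures_as_missing(two_node_subject, monkeypatch):
    spec, _, _, cs = two_node_subject
    import restdcm.dcm_spectral as ds

    calls = {"n": 0}
    real_invert = ds.invert

    def flaky(data, sp, priors=None, opts=None):
        calls["n"] += 1
        if calls["n"] == 1:
            raise RuntimeError("synthetic failure")
        return real_invert(data, sp, priors, opts)

    monkeypatch.setattr(ds, "invert", flaky)
    F = ds.model_evidence_table([cs, cs], [spec])
    assert np.isnan(F[0, 0]) and np.isfinite(F[1, 0])


def test_table_resume_from_cache(two_node_subject, tmp_path):
    spec, _, _, cs = two_node_subject
    cache = tmp_path / "f.jsonl"
    opts = InversionOptions(n_starts=1)
    F1 = model_evidence_table([cs], [spec], opts=opts, cache_path=cache)
    assert cache.exists()
    # resumed run must reuse the cached value without recomputation
    F2 = model_evidence_table([cs], [spec], opts=opts, cache_path=cache)
    assert F2[0, 0] == F1[0, 0]
    assert len(cache.read_text().splitlines()) == 1


def test_table_requires_shared_region_count(two_node_subject):
    spec, _, _, cs = two_node_subject
    other = CrossSpectra(freqs=cs.freqs,
                         S=np.ones((len(cs.freqs), 3, 3), complex),
                         source="mar")
    with pytest.raises(ValueError, match="region"):
        model_evidence_table([cs, other], [spec])
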