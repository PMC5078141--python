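"""Synthetic resting-state BOLD groups from a known directed-coupling truth.

The generator mirrors the study design this package targets: groups of 26
subjects, 1000 scans at TR = 2 s, six DMN regions, directed couplings on the
order of +-0.3 Hz, endogenous fluctuations concentrated below 0.1 Hz, and
observation noise leaving every region with a mean/SD signal-to-noise ratio
comfortably above 2.4.

The latent neural dynamics are linear and stochastic,

    dx/dt = A x + v(t),

with ``A`` the coupling matrix (Hz; strictly negative diagonal, stable) and
``v`` zero-mean noise with a power-law spectrum ``amp_v * f**(-exp_v)``
synthesized in the frequency domain.  Each region's latent state drives the
nonlinear balloon hemodynamic cascade (vasodilatory signal s, blood flow f,
venous volume v, deoxyhemoglobin q):

    s' = x - kappa*s - gamma*(f - 1)
    f' = s
    tau * v' = f - v**(1/alpha)
    tau * q' = f*(1 - (1 - E0)**(1/f))/E0 - v**(1/alpha) * q/v

with BOLD read-out ``y = V0*(k1*(1-q) + k2*(1-q/v) + k3*(1-v))`` around a
unit baseline.  Observation noise with spectrum ``amp_e * f**(-exp_e)`` is
added at the scan level.

All spectral densities in this package are two-sided densities evaluated at
positive frequencies (units: signal-variance per Hz).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .model_space import MNI_COORDS, ModelSpec

#: Balloon-model constants (standard values from the spectral-DCM
#: literature; the read-out constants follow k1 = 7*E0, k2 = 2,
#: k3 = 2*E0 - 0.2).
DEFAULT_HEMO = {
    "kappa": 0.64,  # signal decay, 1/s
    "gamma": 0.32,  # autoregulation, 1/s
    "tau": 2.0,  # transit time, s
    "alpha_g": 0.32,  # Grubb stiffness exponent
    "E0": 0.4,  # resting oxygen extraction fraction
}
V0 = 0.04  # resting venous blood volume fraction


def bold_readout_constants(E0: float = DEFAULT_HEMO["E0"]):
    return 7.0 * E0, 2.0, 2.0 * E0 - 0.2


#: Default endogenous-fluctuation and observation-noise spectra.  amp_v is
#: calibrated so the latent states have SD near 0.1 under typical stable
#: couplings; amp_e keeps every region's mean/SD SNR above the study's
#: floor of 2.4 (in practice far above it, as for real resting-state data).
DEFAULT_NEURAL_NOISE = {"amp_v": 1.5e-4, "exp_v": 1.0}
DEFAULT_OBS_NOISE = {"amp_e": 3.2e-6, "exp_e": 1.0}

#: Baseline added to the BOLD read-out so the series has a physiological
#: mean (raw BOLD units are arbitrary; mean/SD is what the SNR check uses).
BOLD_BASELINE = 1.0


@dataclass
class DCMParams:
    """Ground-truth (or posterior) parameters of the generative model.

    ``A`` is the coupling matrix in Hz: ``A[i, j]`` is the influence of
    region j on region i; the diagonal is self-inhibition and must be
    strictly negative.  ``hemo``, ``neural_noise`` and ``obs_noise`` are
    per-region records (lists of dicts).
    """

    A: np.ndarray
    hemo: list[dict] = field(default_factory=list)
    neural_noise: list[dict] = field(default_factory=list)
    obs_noise: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if not self.hemo:
            self.hemo = [dict(DEFAULT_HEMO) for _ in range(n)]
        if not self.neural_noise:
            self.neural_noise = [dict(DEFAULT_NEURAL_NOISE) for _ in range(n)]
        if not self.obs_noise:
            self.obs_noise = [dict(DEFAULT_OBS_NOISE) for _ in range(n)]
        self.validate()

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    def validate(self) -> None:
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("diagonal of A must be strictly negative")
        if spectral_abscissa(self.A) >= 0:
            raise ValueError("A must be stable (all eigenvalues in the "
                             "left half-plane)")
        for blocks, keys in (
            (self.hemo, ("kappa", "gamma", "tau", "alpha_g", "E0")),
            (self.neural_noise, ("amp_v",)),
            (self.obs_noise, ("amp_e",)),
        ):
            if len(blocks) != self.n_regions:
                raise ValueError("per-region records must match A size")
            for rec in blocks:
                for k in keys:
                    if rec[k] <= 0:
                        raise ValueError(f"{k} must be positive")
        for rec in self.hemo:
            if rec["E0"] >= 1:
                raise ValueError("E0 must be < 1")

    def copy(self) -> "DCMParams":
        return DCMParams(
            A=self.A.copy(),
            hemo=copy.deepcopy(self.hemo),
            neural_noise=copy.deepcopy(self.neural_noise),
            obs_noise=copy.deepcopy(self.obs_noise),
        )

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "hemo": self.hemo,
            "neural_noise": self.neural_noise,
            "obs_noise": self.obs_noise,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DCMParams":
        return cls(
            A=np.asarray(d["A"], dtype=float),
            hemo=d["hemo"],
            neural_noise=d["neural_noise"],
            obs_noise=d["obs_noise"],
        )


@dataclass
class SimulationConfig:
    """Integration and sampling settings for one simulated group."""

    n_scans: int = 1000
    tr: float = 2.0  # s
    dt: float = 0.125  # integration step, s
    burn_in: float = 64.0  # s
    seed: int = 0
    subject_sd: float = 0.05  # between-subject coupling jitter SD, Hz

    def __post_init__(self) -> None:
        if self.n_scans < 2:
            raise ValueError("n_scans must be >= 2")
        if self.dt > self.tr / 8:
            raise ValueError("dt must be <= tr/8")
        if self.burn_in < 32:
            raise ValueError("burn_in must be >= 32 s")


@dataclass
class ROITimeSeries:
    """Sampled BOLD per region: the unit of subject-level data."""

    data: np.ndarray  # (n_scans, n_regions)
    tr: float
    regions: tuple[str, ...]
    mni: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (scans x regions)")
        if self.data.shape[1] != len(self.regions):
            raise ValueError("column count must match region labels")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region labels must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")
        self.regions = tuple(self.regions)
        if not self.mni:
            self.mni = tuple(
                MNI_COORDS.get(r, (0, 0, 0)) for r in self.regions
            )
        elif len(self.mni) != len(self.regions):
            raise ValueError("mni length must equal region count")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def region(self, label: str) -> np.ndarray:
        return self.data[:, self.regions.index(label)]


def spectral_abscissa(A: np.ndarray) -> float:
    return float(np.max(np.linalg.eigvals(A).real))


def default_coupling(spec: ModelSpec, strength: float = 0.2,
                     self_coupling: float = -0.5) -> DCMParams:
    """A convenient stable ground truth respecting ``spec``'s adjacency.

    Allowed off-diagonal couplings get alternating signs on the scale of
    ``strength`` (Hz); the diagonal is uniform self-inhibition.  Raises if
    the construction is unstable.
    """
    n = spec.n_regions
    A = np.zeros((n, n))
    sign = 1.0
    for i in range(n):
        for j in range(n):
            if i != j and spec.mask[i, j]:
                A[i, j] = sign * strength
                sign = -sign
    np.fill_diagonal(A, self_coupling)
    return DCMParams(A=A)


def make_group_truth(spec: ModelSpec, base: DCMParams,
                     cfg: SimulationConfig, n_subjects: int,
                     ) -> list[DCMParams]:
    """Per-subject ground-truth parameter sets around ``base``.

    Each allowed off-diagonal coupling receives independent Gaussian jitter
    with SD ``cfg.subject_sd`` (Hz); masked entries stay exactly zero, the
    diagonal is untouched, and each jittered system is redrawn (up to 100
    times) until stable.  Deterministic given ``cfg.seed``.
    """
    mask = np.asarray(spec.mask, dtype=bool)
    if np.any((base.A != 0) & ~mask & ~np.eye(spec.n_regions, dtype=bool)):
        raise ValueError("base.A has couplings outside the model's mask")
    rng = np.random.default_rng(cfg.seed)
    out = []
    free = mask & ~np.eye(spec.n_regions, dtype=bool)
    for s in range(n_subjects):
        for attempt in range(100):
            A = base.A.copy()
            A[free] += rng.normal(0.0, cfg.subject_sd, size=int(free.sum()))
            if spectral_abscissa(A) < 0:
                break
        else:
            raise RuntimeError(
                f"subject {s}: jittered coupling matrix unstable after "
                "100 redraws"
            )
        p = base.copy()
        p.A = A
        p.validate()
        out.append(p)
    return out


def powerlaw_noise(n: int, dt: float, amp: float, exp: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Real series whose two-sided spectral density is ``amp * f**(-exp)``.

    Synthesized in the frequency domain: coefficient magnitudes follow the
    square root of the target density, phases are uniform.  The DC term is
    zero (the process is defined only for f > 0).
    """
    if amp == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=dt)
    mag = np.zeros_like(freqs)
    mag[1:] = np.sqrt(amp * freqs[1:] ** (-exp) * n / dt)
    phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
    Z = mag * np.exp(1j * phases)
    Z[0] = 0.0
    if n % 2 == 0:
        Z[-1] = mag[-1] * np.sign(np.cos(phases[-1]))  # Nyquist bin is real
    return np.fft.irfft(Z, n=n)


def _integrate_latent_py(A: np.ndarray, v: np.ndarray,
                         dt: float) -> np.ndarray:
    n_steps, n = v.shape
    x = np.zeros((n_steps, n))
    xt = np.zeros(n)
    M = np.eye(n) + dt * A
    for t in range(n_steps):
        xt = M @ xt + dt * v[t]
        x[t] = xt
    return x


def _balloon_rhs_state(st: np.ndarray, xt: np.ndarray, kappa, gamma, tau,
                       alpha, E0) -> np.ndarray:
    n = xt.shape[0]
    s, f, v, q = st[0:n], st[n:2 * n], st[2 * n:3 * n], st[3 * n:4 * n]
    fc = np.maximum(f, 1e-6)
    vc = np.maximum(v, 1e-6)
    outflow = vc ** (1.0 / alpha)
    out = np.empty(4 * n)
    out[0:n] = xt - kappa * s - gamma * (fc - 1.0)
    out[n:2 * n] = s
    out[2 * n:3 * n] = (fc - outflow) / tau
    out[3 * n:4 * n] = (fc * (1.0 - (1.0 - E0) ** (1.0 / fc)) / E0
                        - outflow * q / vc) / tau
    return out


def _integrate_balloon_py(x: np.ndarray, dt: float, kappa, gamma, tau,
                          alpha, E0, k1, k2, k3, v0: float) -> np.ndarray:
    """Classical RK4 with the neural input held constant over each step;
    the cascade is deterministic given x, so a fourth-order step keeps the
    discretization error well below the signal scale at dt = tr/16."""
    n_steps, n = x.shape
    y = np.empty((n_steps, n))
    st = np.ones(4 * n)
    st[0:n] = 0.0  # s = 0, f = v = q = 1 at rest
    for t in range(n_steps):
        xt = x[t]
        d1 = _balloon_rhs_state(st, xt, kappa, gamma, tau, alpha, E0)
        d2 = _balloon_rhs_state(st + 0.5 * dt * d1, xt, kappa, gamma, tau,
                                alpha, E0)
        d3 = _balloon_rhs_state(st + 0.5 * dt * d2, xt, kappa, gamma, tau,
                                alpha, E0)
        d4 = _balloon_rhs_state(st + dt * d3, xt, kappa, gamma, tau,
                                alpha, E0)
        st = st + (dt / 6.0) * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
        v = st[2 * n:3 * n]
        q = st[3 * n:4 * n]
        y[t] = v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v)
                     + k3 * (1.0 - v))
    return y


try:  # optional JIT; the pure-numpy path is the reference implementation
    from numba import njit as _njit

    _balloon_rhs_state = _njit(cache=False)(_balloon_rhs_state)
    _integrate_latent = _njit(cache=False)(_integrate_latent_py)
    _integrate_balloon = _njit(cache=False)(_integrate_balloon_py)
except Exception:  # pragma: no cover - numba absent
    _integrate_latent = _integrate_latent_py
    _integrate_balloon = _integrate_balloon_py


def simulate_latent(params: DCMParams, cfg: SimulationConfig,
                    rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Euler-Maruyama integration of the latent neural states on the fine
    grid, burn-in included.  Returns (states (n_steps, n), dt)."""
    n = params.n_regions
    total = cfg.burn_in + cfg.n_scans * cfg.tr
    n_steps = int(round(total / cfg.dt))
    v = np.column_stack([
        powerlaw_noise(n_steps, cfg.dt, params.neural_noise[r]["amp_v"],
                       params.neural_noise[r]["exp_v"], rng)
        for r in range(n)
    ])
    x = _integrate_latent(params.A, v, cfg.dt)
    _check_finite(x, cfg.dt, "latent")
    return x, cfg.dt


def _check_finite(arr: np.ndarray, dt: float, what: str) -> None:
    finite = np.isfinite(arr)
    if not finite.all():
        t, region = np.argwhere(~finite)[0]
        raise FloatingPointError(
            f"non-finite {what} state at t={t * dt:.2f} s, region {region}"
        )


def balloon_bold(x: np.ndarray, params: DCMParams, dt: float) -> np.ndarray:
    """Feed latent states through the balloon cascade; returns BOLD on the
    same fine grid (fractional signal change around zero)."""
    n = x.shape[1]
    kappa = np.array([h["kappa"] for h in params.hemo])
    gamma = np.array([h["gamma"] for h in params.hemo])
    tau = np.array([h["tau"] for h in params.hemo])
    alpha = np.array([h["alpha_g"] for h in params.hemo])
    E0 = np.array([h["E0"] for h in params.hemo])
    k1 = 7.0 * E0
    k2 = np.full(n, 2.0)
    k3 = 2.0 * E0 - 0.2
    y = _integrate_balloon(x, dt, kappa, gamma, tau, alpha, E0,
                           k1, k2, k3, V0)
    _check_finite(y, dt, "hemodynamic")
    return y


def simulate_bold(params: DCMParams, cfg: SimulationConfig,
                  regions: tuple[str, ...] | None = None,
                  return_latent: bool = False):
    """Simulate one subject's ROI BOLD time series.

    Integrates the latent linear dynamics with power-law endogenous noise,
    runs the balloon cascade, discards ``burn_in``, samples every TR, and
    adds power-law observation noise around the unit baseline.
    """
    n = params.n_regions
    if regions is None:
        regions = tuple(f"R{i}" for i in range(n))
    rng = np.random.default_rng(cfg.seed)
    x, dt = simulate_latent(params, cfg, rng)
    y = balloon_bold(x, params, dt)
    skip = int(round(cfg.burn_in / dt))
    stride = int(round(cfg.tr / dt))
    idx = skip + stride * np.arange(cfg.n_scans)
    sampled = y[idx]
    noise = np.column_stack([
        powerlaw_noise(cfg.n_scans, cfg.tr,
                       params.obs_noise[r]["amp_e"],
                       params.obs_noise[r]["exp_e"], rng)
        for r in range(n)
    ])
    ts = ROITimeSeries(
        data=BOLD_BASELINE + sampled + noise, tr=cfg.tr, regions=regions
    )
    if return_latent:
        return ts, x[idx]
    return ts


def simulate_group(specs_or_params, cfg: SimulationConfig,
                   regions: tuple[str, ...] | None = None,
                   ) -> list[ROITimeSeries]:
    """Simulate one subject per parameter set, with per-subject seeds
    derived from ``cfg.seed``."""
    out = []
    for k, p in enumerate(specs_or_params):
        sub_cfg = SimulationConfig(
            n_scans=cfg.n_scans, tr=cfg.tr, dt=cfg.dt, burn_in=cfg.burn_in,
            seed=(cfg.seed * 10007 + k + 1) % (2**31 - 1),
            subject_sd=cfg.subject_sd,
        )
        out.append(simulate_bold(p, sub_cfg, regions=regions))
    return out


def simulate_voxels(ts: ROITimeSeries, region: str, n_voxels: int,
                    loading_sd: float, noise_sd: float,
                    seed: int) -> np.ndarray:
    """Voxel-level data for one region: random loadings on the region
    series plus white noise, for exercising eigenvariate extraction."""
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    series = ts.region(region)
    rng = np.random.default_rng(seed)
    loadings = 1.0 + rng.normal(0.0, loading_sd, size=n_voxels)
    vox = np.outer(series, loadings)
    sd = float(np.std(series))
    if noise_sd > 0:
        vox = vox + rng.normal(0.0, noise_sd * sd, size=vox.shape)
    return vox
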