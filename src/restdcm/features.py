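"""Feature extraction from ROI time series.

Provides the discrete cosine basis spanning the resting-state band, principal
eigenvariate summaries of voxel clusters, confound residualization, and two
independent cross-spectral density estimators: a parametric one based on a
multivariate autoregressive (MAR) fit, and a nonparametric Welch estimator.

Spectral convention: all cross-spectral densities are two-sided densities
evaluated at positive frequencies (variance per Hz); a one-sided estimate is
halved before storage so that the two estimators and the generative model are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic_data import ROITimeSeries


@dataclass
class BasisMatrix:
    """Discrete cosine basis restricted to a low-frequency band."""

    columns: np.ndarray  # (n_scans, K), orthonormal
    freqs: np.ndarray  # Hz, one per column, strictly increasing

    @property
    def K(self) -> int:
        return self.columns.shape[1]


@dataclass
class CrossSpectra:
    """Complex Hermitian cross-spectral matrices on a fixed frequency grid."""

    freqs: np.ndarray  # Hz, (n_f,)
    S: np.ndarray  # complex, (n_f, n, n)
    source: str = "model"  # {mar, welch, model}

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.S = np.asarray(self.S, dtype=complex)
        if self.S.ndim != 3 or self.S.shape[0] != len(self.freqs):
            raise ValueError("S must be (n_f, n, n) matching freqs")
        if np.any(self.freqs <= 0):
            raise ValueError("frequency grid must be strictly positive")

    @property
    def n_regions(self) -> int:
        return self.S.shape[1]

    def validate(self, tol: float = 1e-10) -> None:
        herm = np.max(np.abs(self.S - self.S.conj().transpose(0, 2, 1)))
        if herm > 1e-8 * (1 + np.abs(self.S).max()):
            raise ValueError(f"cross-spectra not Hermitian (dev {herm:.2e})")
        eig = np.linalg.eigvalsh(0.5 * (self.S + self.S.conj().transpose(0, 2, 1)))
        if eig.min() < -tol * max(1.0, eig.max()):
            raise ValueError(
                f"cross-spectra not PSD (min eigenvalue {eig.min():.2e})"
            )


@dataclass
class MARModel:
    """Multivariate autoregressive model of order p at sampling interval tr."""

    order: int
    coeff: np.ndarray  # (p, n, n): y_t = sum_k coeff[k] y_{t-k} + e_t
    innovation: np.ndarray  # (n, n) residual covariance
    tr: float

    @property
    def n_regions(self) -> int:
        return self.innovation.shape[0]

    def companion(self) -> np.ndarray:
        p, n, _ = self.coeff.shape
        if p == 0:
            return np.zeros((0, 0))
        C = np.zeros((n * p, n * p))
        C[:n] = np.concatenate(list(self.coeff), axis=1)
        if p > 1:
            C[n:, :-n] = np.eye(n * (p - 1))
        return C

    @property
    def stable(self) -> bool:
        if self.order == 0:
            return True
        return bool(np.max(np.abs(np.linalg.eigvals(self.companion()))) < 1)


def dct_basis(n_scans: int, tr: float, f_max: float) -> BasisMatrix:
    """Orthonormal discrete cosine basis up to ``f_max`` (constant excluded).

    Column k (k = 1..K) is cos(pi*k*(t + 1/2)/N) over scans t = 0..N-1,
    associated with frequency k/(2*N*tr); K = floor(2*N*tr*f_max).
    """
    if n_scans < 2:
        raise ValueError("n_scans must be >= 2")
    if tr <= 0 or f_max <= 0:
        raise ValueError("tr and f_max must be positive")
    nyquist = 1.0 / (2.0 * tr)
    if f_max > nyquist + 1e-12:
        raise ValueError(f"f_max {f_max} Hz exceeds Nyquist {nyquist} Hz")
    N = n_scans
    K = int(np.floor(2 * N * tr * f_max))
    t = np.arange(N)
    k = np.arange(1, K + 1)
    cols = np.cos(np.pi * np.outer(t + 0.5, k) / N)
    if K:
        cols = cols / np.linalg.norm(cols, axis=0, keepdims=True)
    freqs = k / (2.0 * N * tr)
    return BasisMatrix(columns=cols, freqs=freqs)


def principal_eigenvariate(voxels: np.ndarray) -> np.ndarray:
    """First-singular-vector summary series of a voxel matrix.

    The voxel matrix is column-centered; the output is the first left
    singular vector scaled by its singular value over sqrt(n_voxels), with
    sign anchored to the voxel-mean series.
    """
    voxels = np.asarray(voxels, dtype=float)
    if voxels.ndim != 2 or voxels.shape[0] < 2 or voxels.shape[1] < 2:
        raise ValueError("need >= 2 scans and >= 2 voxels")
    centered = voxels - voxels.mean(axis=0, keepdims=True)
    if not np.any(centered):
        raise ValueError("degenerate region: all voxels constant")
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    series = U[:, 0] * s[0] / np.sqrt(voxels.shape[1])
    mean_series = centered.mean(axis=1)
    if np.dot(series, mean_series) < 0:
        series = -series
    return series


def residualize(ts: ROITimeSeries, confounds: np.ndarray | None = None
                ) -> ROITimeSeries:
    """Replace each region series by its residual against an intercept plus
    the supplied confound regressors (e.g. a high-pass DCT block)."""
    X = np.ones((ts.n_scans, 1))
    if confounds is not None and np.size(confounds):
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != ts.n_scans:
            raise ValueError("confound rows must match n_scans")
        X = np.hstack([X, confounds])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a collinear set for the error message
        _, R = np.linalg.qr(X)
        bad = [int(i) for i in np.where(np.abs(np.diag(R)) < 1e-10)[0]]
        raise ValueError(f"rank-deficient confounds (columns {bad})")
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return ROITimeSeries(data=resid, tr=ts.tr, regions=ts.regions,
                         mni=ts.mni)


def fit_mar(ts: ROITimeSeries, p: int = 8) -> MARModel:
    """Ordinary-least-squares multivariate AR(p) fit on centered data."""
    n_scans, n = ts.data.shape
    if p < 0:
        raise ValueError("order must be >= 0")
    if n_scans <= p * n + 1:
        raise ValueError("too few scans for the requested MAR order")
    Y = ts.data - ts.data.mean(axis=0, keepdims=True)
    if p == 0:
        innov = (Y.T @ Y) / n_scans
        return MARModel(order=0, coeff=np.zeros((0, n, n)),
                        innovation=innov, tr=ts.tr)
    rows = n_scans - p
    X = np.hstack([Y[p - k - 1: p - k - 1 + rows] for k in range(p)])
    T = Y[p:]
    cond = np.linalg.cond(X.T @ X)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError("singular MAR design matrix")
    B, *_ = np.linalg.lstsq(X, T, rcond=None)  # (n*p, n)
    resid = T - X @ B
    innov = (resid.T @ resid) / (n_scans - p)
    coeff = np.stack([B[k * n:(k + 1) * n].T for k in range(p)])
    return MARModel(order=p, coeff=coeff, innovation=innov, tr=ts.tr)


def csd_from_mar(mar: MARModel, freqs: np.ndarray,
                 tr: float | None = None) -> CrossSpectra:
    """Parametric cross-spectral density of a fitted MAR model.

    S(f) = tr * H(f) Sigma H(f)^H with
    H(f) = (I - sum_k coeff_k exp(-i 2 pi f k tr))^(-1).
    """
    tr = mar.tr if tr is None else tr
    freqs = np.asarray(freqs, dtype=float)
    n = mar.n_regions
    I = np.eye(n)
    S = np.empty((len(freqs), n, n), dtype=complex)
    lags = np.arange(1, mar.order + 1)
    for fi, f in enumerate(freqs):
        M = I.astype(complex).copy()
        if mar.order:
            phase = np.exp(-1j * 2 * np.pi * f * lags * tr)
            M -= np.tensordot(phase, mar.coeff, axes=(0, 0))
        if np.linalg.cond(M) > 1e12:
            raise np.linalg.LinAlgError(
                f"transfer matrix ill-conditioned at f = {f:.6g} Hz"
            )
        H = np.linalg.inv(M)
        S[fi] = tr * H @ mar.innovation @ H.conj().T
    return CrossSpectra(freqs=freqs, S=S, source="mar")


def csd_welch(ts: ROITimeSeries, freqs: np.ndarray,
              nperseg: int | None = None) -> CrossSpectra:
    """Welch cross-spectral estimate interpolated onto ``freqs``.

    Hann-tapered segments of length N/8 with 50% overlap (>= 4 segments at
    the study's 1000 scans); the one-sided scipy output is halved to the
    package's two-sided convention.
    """
    freqs = np.asarray(freqs, dtype=float)
    fs = 1.0 / ts.tr
    n_scans, n = ts.data.shape
    if nperseg is None:
        nperseg = max(8, n_scans // 8)
    n_segments = 1 + (n_scans - nperseg) // (nperseg // 2)
    if n_segments < 4:
        raise ValueError("fewer than 4 Welch segments available")
    Y = ts.data - ts.data.mean(axis=0, keepdims=True)
    f_grid, _ = sps.csd(Y[:, 0], Y[:, 0], fs=fs, nperseg=nperseg,
                        window="hann")
    if freqs.min() < f_grid[1] or freqs.max() > f_grid[-1]:
        raise ValueError(
            f"requested grid [{freqs.min():.4g}, {freqs.max():.4g}] Hz "
            f"outside resolvable band [{f_grid[1]:.4g}, {f_grid[-1]:.4g}]"
        )
    S_grid = np.empty((len(f_grid), n, n), dtype=complex)
    for i in range(n):
        for j in range(i, n):
            _, Pij = sps.csd(Y[:, i], Y[:, j], fs=fs, nperseg=nperseg,
                             window="hann")
            # scipy's csd(x, y) estimates E[conj(X) Y]; this package stores
            # S[i, j] = E[X_i conj(X_j)] (the MAR/transfer-function
            # convention), hence the conjugate.
            S_grid[:, i, j] = np.conj(Pij)
            S_grid[:, j, i] = Pij
    # one-sided -> two-sided (interior bins carry the doubled density)
    interior = (f_grid > 0) & (f_grid < fs / 2)
    S_grid[interior] *= 0.5
    S = np.empty((len(freqs), n, n), dtype=complex)
    for i in range(n):
        for j in range(n):
            S[:, i, j] = np.interp(freqs, f_grid, S_grid[:, i, j].real) \
                + 1j * np.interp(freqs, f_grid, S_grid[:, i, j].imag)
    return CrossSpectra(freqs=freqs, S=S, source="welch")


def snr(ts: ROITimeSeries) -> np.ndarray:
    """Per-region signal-to-noise ratio: time-series mean over SD."""
    sd = ts.data.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = ts.regions[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance region {bad}")
    return ts.data.mean(axis=0) / sd


def default_freq_grid(n_scans: int, tr: float, f_max: float = 0.1,
                      n_points: int = 32) -> np.ndarray:
    """Linearly spaced analysis grid over the resting-state band.

    The lower edge is 1/128 Hz (~ 0.0078 Hz, the conventional resting-state
    high-pass) or the fundamental 1/(N*tr) if the run is too short to
    resolve 1/128 Hz.
    """
    f_min = max(1.0 / (n_scans * tr), 1.0 / 128.0)
    return np.linspace(f_min, f_max, n_points)


def subject_csd(ts: ROITimeSeries, freqs: np.ndarray | None = None,
                estimator: str = "mar", order: int = 12,
                high_pass: float | None = None) -> CrossSpectra:
    """Standard feature path: residualize (intercept only by default, or
    against a discrete-cosine drift block below ``high_pass``), standardize
    to unit mean variance, then estimate the CSD with the chosen estimator.

    ``high_pass`` is meant for data with scanner drift; when used, the
    analysis grid should start above the cutoff, since filtered-out power
    below it no longer matches the generative model's power law.
    """
    if freqs is None:
        freqs = default_freq_grid(ts.n_scans, ts.tr)
    work = ts
    if high_pass and high_pass > 0:
        drift = dct_basis(ts.n_scans, ts.tr, high_pass)
        work = residualize(ts, drift.columns)
    else:
        work = residualize(ts)
    scale = np.sqrt(np.mean(work.data.var(axis=0)))
    if scale > 0:
        work = ROITimeSeries(data=work.data / scale, tr=ts.tr,
                             regions=ts.regions, mni=ts.mni)
    if estimator == "mar":
        return csd_from_mar(fit_mar(work, p=order), freqs)
    if estimator == "welch":
        return csd_welch(work, freqs)
    raise ValueError("estimator must be 'mar' or 'welch'")
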