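"""Group-level statistics over per-subject model inversions.

Implements fixed-effects Bayesian model selection over the per-subject,
per-model free energies (the F-matrix), family-level posteriors with a
uniform family prior, win counts, Bayesian model averaging (BMA), Bayesian
parameter averaging (BPA), cross-subject stability correlation matrices, and
the left/right hippocampal lateralization contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .dcm_spectral import InversionResult, Priors

logger = logging.getLogger(__name__)


@dataclass
class GroupResult:
    """Container for the group-level summaries of one model space."""

    F: np.ndarray
    model_names: list[str]
    model_post: np.ndarray | None = None
    family_post: dict = field(default_factory=dict)
    wins: np.ndarray | None = None
    bma_table: list[dict] = field(default_factory=list)
    bpa_table: list[dict] = field(default_factory=list)
    stability: np.ndarray | None = None


def _clean_F(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.ndim != 2:
        raise ValueError("F must be subjects x models")
    bad = ~np.isfinite(F).all(axis=1)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} subject(s) with missing F values",
            stacklevel=3,
        )
        F = F[~bad]
    if F.size == 0:
        raise ValueError("no complete subject rows in F")
    return F


def ffx_bms(F: np.ndarray) -> np.ndarray:
    """Fixed-effects model posterior: softmax of the column-summed free
    energies (all subjects assumed to share one model)."""
    F = _clean_F(F)
    if F.shape[1] < 1:
        raise ValueError("need at least one model")
    group = F.sum(axis=0)
    group = group - group.max()
    w = np.exp(group)
    return w / w.sum()


def family_posteriors(F: np.ndarray, family_of: dict[str, str],
                      model_names: list[str]) -> dict[str, float]:
    """Family-level FFX posteriors under a uniform prior over families.

    Family evidence = logsumexp of member group evidences minus log member
    count (so large families do not win by size alone).
    """
    F = _clean_F(F)
    if set(model_names) - set(family_of):
        missing = sorted(set(model_names) - set(family_of))
        raise ValueError(f"models without a family: {missing}")
    group = F.sum(axis=0)
    families: dict[str, list[int]] = {}
    for k, name in enumerate(model_names):
        families.setdefault(family_of[name], []).append(k)
    labels = list(families)
    logev = np.array([
        logsumexp(group[idx]) - np.log(len(idx))
        for idx in families.values()
    ])
    logev -= logev.max()
    post = np.exp(logev)
    post /= post.sum()
    return dict(zip(labels, post))


def count_wins(F: np.ndarray) -> np.ndarray:
    """How often each model attains a subject's maximum F (ties broken by
    first index, with a warning)."""
    F = np.asarray(F, dtype=float)
    wins = np.zeros(F.shape[1], dtype=int)
    for row in F:
        best = np.nanargmax(row)
        if np.sum(row == row[best]) > 1:
            warnings.warn("tied F values; first-index tie break",
                          stacklevel=2)
        wins[best] += 1
    return wins


def _coupling_names(results_row: list[InversionResult]) -> list[str]:
    names: list[str] = []
    for res in results_row:
        if res is None:
            continue
        for n in res.names:
            if n.startswith("a:") and n not in names:
                names.append(n)
    return names


def bma(results: list[list[InversionResult]], F: np.ndarray,
        occam_window: float | None = None,
        alpha: float = 0.05) -> list[dict]:
    """Bayesian model averaging of the coupling parameters.

    Per subject, each coupling's estimate is the posterior-probability-
    weighted mean over models (softmax of that subject's F row; couplings
    absent from a model contribute zero).  ``occam_window`` restricts the
    average to models within that many nats of the subject's best.  The
    group row reports the across-subject mean with uncorrected and
    Bonferroni-corrected one-sample t-test flags.
    """
    F = np.asarray(F, dtype=float)
    n_sub, n_mod = F.shape
    names = sorted({n for row in results for n in _coupling_names(row)})
    est = np.zeros((n_sub, len(names)))
    for s in range(n_sub):
        row = F[s].copy()
        ok = np.isfinite(row)
        if not ok.any():
            raise ValueError(f"subject {s}: all model evidences missing")
        if occam_window is not None:
            ok &= row >= np.nanmax(row) - occam_window
        w = np.full(n_mod, -np.inf)
        w[ok] = row[ok] - np.nanmax(row[ok])
        w = np.exp(w)
        w /= w.sum()
        for m in range(n_mod):
            if w[m] == 0 or results[s][m] is None:
                continue
            res = results[s][m]
            for k, pname in enumerate(names):
                if pname in res.names:
                    est[s, k] += w[m] * res[pname]
    table = []
    n_tests = len(names)
    for k, pname in enumerate(names):
        vals = est[:, k]
        if n_sub > 1 and np.std(vals) > 0:
            t, p = stats.ttest_1samp(vals, 0.0)
        else:
            t, p = np.nan, 1.0
        table.append({
            "connection": pname,
            "mean_hz": float(vals.mean()),
            "t": float(t) if np.isfinite(t) else None,
            "p": float(p),
            "significant": bool(p < alpha),
            "significant_bonferroni": bool(p < alpha / max(n_tests, 1)),
            "subject_values": vals.tolist(),
        })
    return table


def bpa(results: list[InversionResult],
        priors: Priors | None = None) -> list[dict]:
    """Bayesian parameter averaging over subjects sharing one model.

    Precision-weighted Gaussian fusion with the shared prior removed S-1
    times (so it enters the group posterior exactly once); significance at
    the one-sided 95% level (|mean| > 1.645 x group SD).
    """
    if not results:
        raise ValueError("need at least one inversion result")
    names = results[0].names
    for res in results:
        if res.names != names:
            raise ValueError("all results must share the model")
    priors = priors or results[0].priors
    S = len(results)
    Lam_prior = np.diag(1.0 / priors.var)
    mu_prior = priors.mu
    P = -(S - 1) * Lam_prior
    b = -(S - 1) * (Lam_prior @ mu_prior)
    for res in results:
        Lam = np.linalg.inv(res.posterior_cov)
        P = P + Lam
        b = b + Lam @ res.posterior_mean
    eig = np.linalg.eigvalsh(0.5 * (P + P.T))
    if eig.min() <= 0:
        raise ValueError(
            f"group precision not positive definite (eigenvalues "
            f"{eig[:3]} ...)"
        )
    cov = np.linalg.inv(P)
    mean = cov @ b
    sd = np.sqrt(np.diag(cov))
    return [
        {
            "connection": nm,
            "mean_hz": float(mean[k]),
            "sd": float(sd[k]),
            "significant": bool(abs(mean[k]) > 1.645 * sd[k]),
        }
        for k, nm in enumerate(names) if nm.startswith("a:")
    ]


def stability_matrix(F: np.ndarray) -> np.ndarray:
    """Pearson correlations between subjects' F-vectors (models as
    observations); diagnoses whether models behave alike across subjects."""
    F = np.asarray(F, dtype=float)
    if F.shape[1] < 2:
        raise ValueError("need at least two models")
    sd = F.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant F row: undefined correlation set to NaN",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(F)
    np.fill_diagonal(C, 1.0)
    return C


def mean_offdiagonal(C: np.ndarray) -> float:
    n = C.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return float(np.nanmean(C[mask]))


def lateralization_contrast(six_node_results: list[InversionResult],
                            targets: tuple[str, ...] = ("mPFC", "LIPC",
                                                        "RIPC"),
                            ) -> list[dict]:
    """Paired contrasts of LHIP-> vs RHIP-> couplings onto shared targets."""
    if len(six_node_results) < 3:
        raise ValueError("need at least 3 subjects")
    out = []
    for tgt in targets:
        lh = np.array([r[f"a:{tgt}<-LHIP"] for r in six_node_results])
        rh = np.array([r[f"a:{tgt}<-RHIP"] for r in six_node_results])
        diff = lh - rh
        if np.std(diff) > 0:
            t, p = stats.ttest_rel(lh, rh)
        else:
            t, p = (np.nan, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
        out.append({
            "target": tgt,
            "mean_diff_hz": float(diff.mean()),
            "t": float(t) if np.isfinite(t) else None,
            "p": float(p),
            "significant_p01": bool(p < 0.01),
        })
    return out
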