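"""Functional connectivity: Fisher-z correlations with FDR control.

Complements the directed (effective-connectivity) analysis with the
undirected statistical dependence between region pairs: per-subject Pearson
correlations are Fisher-transformed (z = atanh r), averaged over the group,
and tested edge-wise with a one-sample t-test under Benjamini-Hochberg FDR
control at q = 0.05 across the unique region pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import ROITimeSeries


@dataclass
class FCResult:
    regions: tuple[str, ...]
    z: list[np.ndarray]  # per-subject Fisher-z matrices
    group_mean: np.ndarray
    pvals: np.ndarray  # per unique edge
    significant: np.ndarray  # boolean per unique edge, after FDR
    edges: list[tuple[str, str]] = field(default_factory=list)


def fc_subject(ts: ROITimeSeries) -> np.ndarray:
    """Fisher-z connectivity matrix of one subject (diagonal zeroed)."""
    if ts.n_scans < 3:
        raise ValueError("need at least 3 scans")
    sd = ts.data.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant region series")
    r = np.corrcoef(ts.data, rowvar=False)
    off = ~np.eye(ts.n_regions, dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        i, j = np.argwhere((np.abs(r) >= 1.0) & off)[0]
        raise ValueError(
            f"degenerate pair {ts.regions[i]}-{ts.regions[j]} (|r| = 1)"
        )
    np.fill_diagonal(r, 0.0)  # self-edges excluded
    z = np.arctanh(r)
    return z


def fc_group(z_list: list[np.ndarray],
             regions: tuple[str, ...],
             q: float = 0.05) -> FCResult:
    """Group FC: mean Fisher-z with BH-FDR-corrected edge significance."""
    if len(z_list) < 3:
        raise ValueError("need at least 3 subjects")
    n = len(regions)
    for z in z_list:
        if z.shape != (n, n):
            raise ValueError("inconsistent region sets across subjects")
    Z = np.stack(z_list)
    group_mean = Z.mean(axis=0)
    iu = np.triu_indices(n, k=1)
    edges = [(regions[i], regions[j]) for i, j in zip(*iu)]
    pvals = np.empty(len(edges))
    for k, (i, j) in enumerate(zip(*iu)):
        vals = Z[:, i, j]
        if np.std(vals) == 0:
            pvals[k] = 1.0 if np.allclose(vals, 0) else 0.0
        else:
            pvals[k] = stats.ttest_1samp(vals, 0.0).pvalue
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return FCResult(regions=tuple(regions), z=list(z_list),
                    group_mean=group_mean, pvals=pvals,
                    significant=reject, edges=edges)


def fc_from_group(ts_list: list[ROITimeSeries], q: float = 0.05) -> FCResult:
    """Convenience path: subject Fisher-z matrices then group inference."""
    regions = ts_list[0].regions
    for ts in ts_list:
        if ts.regions != regions:
            raise ValueError("inconsistent region sets across subjects")
    return fc_group([fc_subject(ts) for ts in ts_list], regions, q=q)
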