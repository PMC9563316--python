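"""AMMI-based stability indices.

Thirteen indices summarise how strongly each genotype participates in the
genotype-by-environment interaction captured by the first N' IPCA axes of an
AMMI fit. Throughout, for genotype i and axis n:

* ``gamma_in``  — genotype eigenvector element (unit-norm columns),
* ``s_in = sqrt(lambda_n) * gamma_in`` — the scaled IPCA score plotted in
  biplots (symmetric singular-value partitioning),
* ``theta_n``   — the proportion (0-1) of interaction SS on axis n,
* ``SS_n = lambda_n^2`` — the interaction SS of axis n (cell-mean scale).

Index definitions (sums over n = 1..N' unless noted):

=======  ==============================================================
ASTAB    sum lambda_n * gamma_in^2                        (Rao-Prabhakaran)
DA       sqrt( sum (lambda_n * gamma_in)^2 )              (Annicchiarico D)
DZ       sqrt( sum gamma_in^2 )                           (Zhang D)
EV       sum gamma_in^2 / N'                              (eigenvector sum)
FA       sum lambda_n^2 * gamma_in^2                      (Raju FA)
ASI      sqrt( (s_i1 theta_1)^2 + (s_i2 theta_2)^2 )      (Jambhulkar)
MASI     sqrt( sum (s_in theta_n)^2 )                     (Ajay, modified ASI)
WAAS     sum |s_in| theta_n / sum theta_n                 (Olivoto)
ASV      sqrt( (SS_1/SS_2 * s_i1)^2 + s_i2^2 )            (Purchase)
MASV     sqrt( sum_{n<N'} (SS_n/SS_{n+1} * s_in)^2 + s_iN'^2 )
SIPC     sum |s_in|                                       (Sneller)
ZA       sum theta_n |s_in|                               (absolute-value Z)
AVAMGE   sum_j sum_n | lambda_n gamma_in delta_jn |       (Zali AV_AMGE)
=======  ==============================================================

Every index is non-negative and zero for a genotype that takes no part in
the interaction; smaller means more stable, and rank 1 is the most stable
genotype (ties get average ranks). ASI and ASV need two axes; with N' < 2
they are reported as undefined (NaN) rather than zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ammi import AMMIResults
from .exceptions import DimensionError

INDEX_NAMES = [
    "ASTAB", "ASI", "ASV", "AVAMGE", "DA", "DZ", "EV", "FA",
    "MASI", "MASV", "SIPC", "WAAS", "ZA",
]


def default_n_retained(fit: AMMIResults, alpha: float = 0.05) -> int:
    """Default N': axes significant at ``alpha`` by the Gollob test, min 2."""
    n_sig = fit.significant_axes(alpha) if fit.axis_tests is not None else 0
    return int(min(max(n_sig, 2), fit.n_axes))


def stability_indices(fit: AMMIResults, n_retained: int | None = None) -> pd.DataFrame:
    """Compute the 13 AMMI stability indices and their ranks.

    Returns a DataFrame indexed by genotype with a value column and a
    ``rank_`` column per index. ``n_retained`` defaults to the number of
    significant axes (minimum 2, capped at the available axes).
    """
    n = default_n_retained(fit) if n_retained is None else int(n_retained)
    if not 1 <= n <= fit.n_axes:
        raise DimensionError(f"n_retained must be in [1, {fit.n_axes}], got {n}")
    lam = fit.lam[:n]
    gamma = fit.gamma[:, :n]
    delta = fit.delta[:, :n]
    theta = fit.theta[:n] / 100.0  # proportions
    s = gamma * np.sqrt(lam)  # scaled scores
    ss = lam**2

    out = pd.DataFrame(index=pd.Index(fit.genotypes, name="genotype"))
    out["ASTAB"] = (lam * gamma**2).sum(axis=1)
    out["DA"] = np.sqrt(((lam * gamma) ** 2).sum(axis=1))
    out["DZ"] = np.sqrt((gamma**2).sum(axis=1))
    out["EV"] = (gamma**2).sum(axis=1) / n
    out["FA"] = (lam**2 * gamma**2).sum(axis=1)
    out["MASI"] = np.sqrt(((s * theta) ** 2).sum(axis=1))
    out["WAAS"] = (np.abs(s) * theta).sum(axis=1) / theta.sum() if theta.sum() > 0 else 0.0
    out["SIPC"] = np.abs(s).sum(axis=1)
    out["ZA"] = (theta * np.abs(s)).sum(axis=1)
    out["AVAMGE"] = np.abs(lam * gamma[:, None, :] * delta[None, :, :]).sum(axis=(1, 2))
    if n >= 2:
        out["ASI"] = np.sqrt((s[:, 0] * theta[0]) ** 2 + (s[:, 1] * theta[1]) ** 2)
        if ss[1] > 0:
            out["ASV"] = np.sqrt((ss[0] / ss[1] * s[:, 0]) ** 2 + s[:, 1] ** 2)
            ratios = ss[:-1] / ss[1:]
            out["MASV"] = np.sqrt(
                ((ratios * s[:, :-1]) ** 2).sum(axis=1) + s[:, -1] ** 2
            )
        else:
            out["ASV"] = np.nan
            out["MASV"] = np.nan
    else:
        out["ASI"] = np.nan
        out["ASV"] = np.nan
        out["MASV"] = np.nan
    out = out[INDEX_NAMES]
    for name in INDEX_NAMES:
        out[f"rank_{name}"] = out[name].rank(method="average")
    out.attrs["n_retained"] = n
    out.attrs["trait"] = fit.trait
    return out


def rank_concordance(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlations among the stability indices.

    Takes the output of :func:`stability_indices`; undefined indices
    (all-NaN) and constant index vectors yield NaN correlations.
    """
    values = table[INDEX_NAMES]
    cols = [c for c in INDEX_NAMES if values[c].notna().all()]
    if len(cols) < 2:
        raise DimensionError("need at least two defined indices for concordance")
    mat = pd.DataFrame(np.nan, index=pd.Index(cols), columns=cols)
    for i, ci in enumerate(cols):
        mat.loc[ci, ci] = 1.0
        for cj in cols[i + 1:]:
            x, y = values[ci].to_numpy(), values[cj].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho = np.nan  # constant vector: correlation undefined
            else:
                rho = stats.spearmanr(x, y).statistic
            mat.loc[ci, cj] = mat.loc[cj, ci] = rho
    return mat
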