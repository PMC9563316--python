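"""WAASBY superiority index and the multi-trait stability index (MTSI).

For one trait, each genotype's mean performance and WAASB stability are
rescaled to 0-100 (100 = best mean, 100 = most stable) and blended:

    rG_i = 100 * (x_i - min x) / (max x - min x)        (higher mean better)
    rW_i = 100 * (max w - w_i) / (max w - min w)        (lower WAASB better)
    WAASBY_i = (rG_i * theta_Y + rW_i * theta_S) / (theta_Y + theta_S),

with equal weights theta_Y = theta_S = 50 by default. A genotype that is
simultaneously the best performer and the most stable attains 100.

The MTSI condenses the genotype x trait WAASBY matrix by exploratory factor
analysis: eigendecomposition of the trait correlation matrix, factors
retained by the Kaiser criterion (eigenvalue >= 1), varimax rotation, and
regression factor scores  S = Z R^{-1} A  (Z the column-standardised WAASBY
matrix, A the rotated loadings). The ideotype takes the per-trait maximum
WAASBY, is standardised with the same column statistics and projected with
the same coefficients; then

    MTSI_i = sqrt( sum_f (S_if - S^ideo_f)^2 ),

so smaller is better and the genotype coinciding with the ideotype scores 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DimensionError, ValidationError


def waasby(
    mean_perf: pd.Series,
    waasb_values: pd.Series,
    theta_y: float = 50.0,
    theta_s: float = 50.0,
    higher_is_better: bool = True,
) -> pd.DataFrame:
    """Blend rescaled mean performance and rescaled WAASB stability.

    Returns columns ``rG``, ``rW``, ``waasby`` indexed by genotype. A scale
    with no spread (max == min) cannot discriminate; it is set to all-100
    and flagged in ``DataFrame.attrs['degenerate']``.
    """
    if theta_y + theta_s <= 0:
        raise ValidationError("theta_y + theta_s must be positive")
    if len(mean_perf) < 2:
        raise ValidationError("need at least two genotypes")
    x = mean_perf.astype(float)
    w = waasb_values.reindex(x.index).astype(float)
    degenerate = []
    if x.max() > x.min():
        rg = 100.0 * (x - x.min()) / (x.max() - x.min())
        if not higher_is_better:
            rg = 100.0 - rg
    else:
        rg = pd.Series(100.0, index=x.index)
        degenerate.append("rG")
    if w.max() > w.min():
        rw = 100.0 * (w.max() - w) / (w.max() - w.min())
    else:
        rw = pd.Series(100.0, index=x.index)
        degenerate.append("rW")
    out = pd.DataFrame({
        "rG": rg, "rW": rw,
        "waasby": (rg * theta_y + rw * theta_s) / (theta_y + theta_s),
    })
    out.attrs["degenerate"] = degenerate
    return out


def _varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Varimax rotation (Kaiser, raw criterion) of a loading matrix."""
    p, k = loadings.shape
    if k < 2:
        return loadings
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        var_new = s.sum()
        if var_new <= var_old * (1 + tol):
            break
        var_old = var_new
    return loadings @ rot


class MTSI:
    """Multi-trait stability index model over a genotype x trait WAASBY matrix."""

    def __init__(self, waasby_matrix: pd.DataFrame):
        if waasby_matrix.shape[1] < 2:
            raise DimensionError("MTSI needs at least two traits")
        if waasby_matrix.shape[0] < 3:
            raise DimensionError("MTSI needs at least three genotypes")
        self.waasby_matrix = waasby_matrix.astype(float)

    def fit(
        self,
        min_eigenvalue: float = 1.0,
        rotate: bool = True,
        selection_fraction: float = 2.0 / 11.0,
    ) -> "MTSIResults":
        """Factor-analyse the WAASBY matrix and rank genotypes by ideotype distance.

        ``selection_fraction`` controls how many genotypes the ``selected``
        flag marks (default picks 2 of 11, rounded, at least 1).
        """
        X = self.waasby_matrix
        sd = X.std(axis=0, ddof=1)
        dropped = list(X.columns[sd == 0])
        if dropped:
            warnings.warn(
                f"dropping zero-variance trait(s) from MTSI: {dropped}", stacklevel=2
            )
            X = X.loc[:, sd > 0]
        if X.shape[1] < 2:
            raise DimensionError("fewer than two informative traits remain")
        mean, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
        Z = (X - mean) / sd
        R = np.corrcoef(Z.to_numpy(), rowvar=False)
        eigval, eigvec = np.linalg.eigh(R)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        nf = max(1, int((eigval >= min_eigenvalue).sum()))
        loadings = eigvec[:, :nf] * np.sqrt(np.maximum(eigval[:nf], 0.0))
        if rotate and nf >= 2:
            loadings = _varimax(loadings)
        # sign convention: each factor's largest loading positive
        for f in range(nf):
            if loadings[np.argmax(np.abs(loadings[:, f])), f] < 0:
                loadings[:, f] *= -1
        coef = np.linalg.pinv(R) @ loadings  # regression score coefficients
        scores = Z.to_numpy() @ coef
        ideotype = X.max(axis=0)
        z_ideo = ((ideotype - mean) / sd).to_numpy()
        ideo_scores = z_ideo @ coef
        mtsi_values = np.sqrt(((scores - ideo_scores[None, :]) ** 2).sum(axis=1))
        mtsi_series = pd.Series(mtsi_values, index=X.index, name="MTSI")
        ranks = mtsi_series.rank(method="average")
        n_sel = max(1, round(len(X) * selection_fraction))
        selected = set(mtsi_series.nsmallest(n_sel).index)
        factor_cols = [f"FA{f + 1}" for f in range(nf)]
        return MTSIResults(
            model=self,
            loadings=pd.DataFrame(loadings, index=X.columns, columns=factor_cols),
            scores=pd.DataFrame(scores, index=X.index, columns=factor_cols),
            ideotype_scores=pd.Series(ideo_scores, index=factor_cols),
            eigenvalues=pd.Series(eigval, index=range(1, len(eigval) + 1)),
            mtsi=mtsi_series, rank=ranks,
            selected=pd.Series([g in selected for g in X.index], index=X.index),
            dropped_traits=dropped,
        )


@dataclass
class MTSIResults:
    """Factor structure, genotype scores, ideotype and MTSI ranking."""

    model: MTSI
    loadings: pd.DataFrame
    scores: pd.DataFrame
    ideotype_scores: pd.Series
    eigenvalues: pd.Series
    mtsi: pd.Series
    rank: pd.Series
    selected: pd.Series
    dropped_traits: list[str]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def table(self) -> pd.DataFrame:
        out = self.scores.copy()
        out["MTSI"] = self.mtsi
        out["rank"] = self.rank
        out["selected"] = self.selected
        return out.sort_values("rank")

    def summary(self) -> str:
        sel = list(self.table()[self.table()["selected"]].index)
        return (
            f"MTSI over {self.model.waasby_matrix.shape[1]} traits, "
            f"{len(self.mtsi)} genotypes; {self.n_factors} factor(s) retained "
            f"(Kaiser)\nselected genotypes: {', '.join(sel)}\n"
            f"{self.table().round(3)}"
        )


def mtsi(waasby_matrix: pd.DataFrame, **kwargs) -> MTSIResults:
    """Functional wrapper: fit the MTSI model on a genotype x trait WAASBY matrix."""
    return MTSI(waasby_matrix).fit(**kwargs)
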