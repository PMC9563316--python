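"""AMMI: additive main effects and multiplicative interaction.

The model for the cell mean of genotype i in environment j is

    y_ij = mu + alpha_i + tau_j + sum_{k=1..p} lambda_k a_ik t_jk + rho_ij,

where the additive part comes from marginal means and the multiplicative part
is the singular value decomposition of the double-centred interaction matrix

    Z_ij = y_ij - ybar_i. - ybar_.j + ybar_.. = sum_k lambda_k a_ik t_jk,

with p = min(G-1, E-1) interaction principal component axes (IPCAs). The
share of interaction sum of squares captured by axis k is
theta_k = 100 * lambda_k^2 / sum(lambda^2). When only the first N' axes are
retained the leftover rho_ij is reported as the AMMI residual.

Axis significance uses Gollob degrees of freedom, df_k = G + E - 1 - 2k, with
F = (R * lambda_k^2 / df_k) / MS_residual against the replicate-level pooled
error when replicate data are available.

Organised in the statsmodels style: :class:`AMMI` is the model object,
``fit()`` returns an :class:`AMMIResults` carrying estimates, variance
shares, axis tests, biplot coordinates and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anova import AnovaTable, combined_anova
from .dataset import GEMatrix, METDataset
from .exceptions import DimensionError, ValidationError


def _signfix(gamma: np.ndarray, delta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per axis, flip signs so the largest-magnitude genotype score is positive."""
    for k in range(gamma.shape[1]):
        i = np.argmax(np.abs(gamma[:, k]))
        if gamma[i, k] < 0:
            gamma[:, k] *= -1
            delta[:, k] *= -1
    return gamma, delta


class AMMI:
    """AMMI model for a genotype x environment cell-mean matrix.

    Parameters
    ----------
    matrix : GEMatrix
        Complete cell-mean table for one trait.
    error_ms, error_df : float, int, optional
        Pooled residual mean square and its degrees of freedom from the
        replicate-level combined ANOVA; enables axis F tests.

    Use :meth:`from_dataset` to construct from replicate-level data, which
    derives the error line (and the ANOVA used by variance-share reporting)
    automatically.
    """

    def __init__(self, matrix: GEMatrix, error_ms: float | None = None,
                 error_df: int | None = None, anova: AnovaTable | None = None):
        self.matrix = matrix
        self.error_ms = error_ms
        self.error_df = error_df
        self.anova = anova

    @classmethod
    def from_dataset(cls, data: METDataset, trait: str) -> "AMMI":
        matrix = data.cell_means(trait)
        table, _ = combined_anova(data, trait)
        return cls(
            matrix,
            error_ms=float(table["residual"]["MS"]),
            error_df=int(table["residual"]["df"]),
            anova=table,
        )

    def fit(self, n_retained: int | str = "all") -> "AMMIResults":
        """Fit the additive part by marginal means and the bilinear part by SVD."""
        y = self.matrix.to_numpy()
        G, E = y.shape
        p = min(G - 1, E - 1)
        if n_retained == "all":
            n_ret = p
        else:
            n_ret = int(n_retained)
            if not 0 <= n_ret <= p:
                raise DimensionError(f"n_retained must be in [0, {p}], got {n_ret}")
        mu = y.mean()
        alpha = y.mean(axis=1) - mu
        tau = y.mean(axis=0) - mu
        z = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + mu
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        lam = s[:p]
        gamma, delta = _signfix(u[:, :p].copy(), vt[:p].T.copy())
        gei_ss = float((lam**2).sum())
        degenerate = gei_ss <= max(1e-12 * y.size, 1e-300)
        theta = np.zeros(p) if degenerate else 100.0 * lam**2 / gei_ss
        residual = z - (gamma[:, :n_ret] * lam[:n_ret]) @ delta[:, :n_ret].T
        axis_tests = self._axis_tests(lam, G, E)
        return AMMIResults(
            model=self, mu=float(mu), alpha=alpha, tau=tau, lam=lam,
            gamma=gamma, delta=delta, theta=theta, n_retained=n_ret,
            residual=residual, axis_tests=axis_tests, degenerate=degenerate,
        )

    def _axis_tests(self, lam: np.ndarray, G: int, E: int) -> pd.DataFrame | None:
        """Gollob-df F tests of each IPCA against the pooled replicate error."""
        if self.error_ms is None or self.error_df is None:
            return None
        from scipy import stats

        R = self.matrix.n_rep
        rows = []
        for k, l in enumerate(lam, start=1):
            df_k = G + E - 1 - 2 * k
            ss_k = R * l**2  # replicate-level SS for the axis
            ms_k = ss_k / df_k if df_k > 0 else np.nan
            if self.error_ms > 0 and df_k > 0:
                f = ms_k / self.error_ms
                pval = float(stats.f.sf(f, df_k, self.error_df))
            else:
                f, pval = np.inf if ss_k > 0 else np.nan, 0.0 if ss_k > 0 else np.nan
            rows.append({"axis": f"PC{k}", "df": df_k, "SS": ss_k, "F": f, "p": pval})
        return pd.DataFrame(rows).set_index("axis")


@dataclass
class AMMIResults:
    """Fitted AMMI decomposition for one trait."""

    model: AMMI
    mu: float
    alpha: np.ndarray
    tau: np.ndarray
    lam: np.ndarray
    gamma: np.ndarray  # G x p genotype eigenvectors (a_ik)
    delta: np.ndarray  # E x p environment eigenvectors (t_jk)
    theta: np.ndarray  # percent of GEI SS per axis
    n_retained: int
    residual: np.ndarray
    axis_tests: pd.DataFrame | None = None
    degenerate: bool = False
    _scores_cache: dict = field(default_factory=dict, repr=False)

    # -- bookkeeping -------------------------------------------------------

    @property
    def genotypes(self) -> list[str]:
        return self.model.matrix.genotypes

    @property
    def environments(self) -> list[str]:
        return self.model.matrix.environments

    @property
    def trait(self) -> str:
        return self.model.matrix.trait

    @property
    def n_axes(self) -> int:
        return len(self.lam)

    def interaction_matrix(self) -> np.ndarray:
        """The double-centred matrix Z reconstructed from all axes."""
        return (self.gamma * self.lam) @ self.delta.T

    def gei_ss(self) -> float:
        """Interaction sum of squares on the cell-mean scale."""
        return float((self.lam**2).sum())

    def reconstruct(self, n_axes: int | None = None) -> np.ndarray:
        """Cell means implied by the additive part plus the first n axes."""
        n = self.n_retained if n_axes is None else n_axes
        add = self.mu + self.alpha[:, None] + self.tau[None, :]
        return add + (self.gamma[:, :n] * self.lam[:n]) @ self.delta[:, :n].T

    def significant_axes(self, alpha: float = 0.05) -> int:
        """Number of IPCAs significant at ``alpha`` (Gollob F test)."""
        if self.axis_tests is None:
            return 0
        return int((self.axis_tests["p"] < alpha).sum())

    # -- biplots -----------------------------------------------------------

    def scores(self, svp_exponent: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """IPCA scores lambda^f * gamma (genotypes) and lambda^f * delta."""
        lf = self.lam**svp_exponent
        return self.gamma * lf, self.delta * lf

    def biplot_coords(self, kind: str = "AMMI2", svp_exponent: float = 0.5) -> pd.DataFrame:
        """Coordinates for the AMMI1 (mean vs PC1) or AMMI2 (PC1 vs PC2) biplot.

        AMMI1: x = mean performance (mu+alpha_i for genotypes, mu+tau_j for
        environments), y = scaled PC1 score. AMMI2: (PC1, PC2) scores; the
        ``distance`` column is the distance from the origin (environment
        vectors far from the origin mark strong interaction).
        """
        gs, es = self.scores(svp_exponent)
        if kind == "AMMI1":
            gx, gy = self.mu + self.alpha, gs[:, 0]
            ex, ey = self.mu + self.tau, es[:, 0]
        elif kind == "AMMI2":
            if self.n_axes < 2:
                raise DimensionError("AMMI2 biplot needs at least 2 IPCA axes")
            gx, gy = gs[:, 0], gs[:, 1]
            ex, ey = es[:, 0], es[:, 1]
        else:
            raise ValueError("kind must be 'AMMI1' or 'AMMI2'")
        frame = pd.DataFrame({
            "entity": self.genotypes + self.environments,
            "type": ["genotype"] * len(self.genotypes) + ["environment"] * len(self.environments),
            "x": np.concatenate([gx, ex]),
            "y": np.concatenate([gy, ey]),
        })
        if kind == "AMMI2":
            frame["distance"] = np.hypot(frame["x"], frame["y"])
        return frame

    def ss_shares(self, anova: AnovaTable | None = None) -> pd.DataFrame:
        """Percent of the replicate-level total SS per variance source.

        Environment, block, genotype, GEI (with per-axis breakdown) and
        residual shares; they sum to 100. Requires the combined ANOVA of the
        same trait (taken from the model when built via ``from_dataset``).
        """
        anova = anova if anova is not None else self.model.anova
        if anova is None:
            raise ValidationError("ss_shares needs the replicate-level combined ANOVA")
        if anova.trait != self.trait:
            raise ValidationError(
                f"ANOVA is for trait {anova.trait!r}, fit is for {self.trait!r}"
            )
        total = anova.total_ss
        rows = []
        for source in ("environment", "block(environment)", "genotype", "GEI", "residual"):
            rows.append({"source": source, "SS": float(anova[source]["SS"]),
                         "percent": 100.0 * float(anova[source]["SS"]) / total})
        R = self.model.matrix.n_rep
        for k, l in enumerate(self.lam, start=1):
            rows.append({"source": f"GEI:PC{k}", "SS": R * l**2,
                         "percent": 100.0 * R * l**2 / total})
        return pd.DataFrame(rows).set_index("source")

    def scores_frame(self, svp_exponent: float = 0.5) -> pd.DataFrame:
        """Long table of scaled IPCA scores for genotypes and environments."""
        gs, es = self.scores(svp_exponent)
        cols = [f"PC{k + 1}" for k in range(self.n_axes)]
        gdf = pd.DataFrame(gs, columns=cols)
        gdf.insert(0, "entity", self.genotypes)
        gdf.insert(1, "type", "genotype")
        edf = pd.DataFrame(es, columns=cols)
        edf.insert(0, "entity", self.environments)
        edf.insert(1, "type", "environment")
        return pd.concat([gdf, edf], ignore_index=True)

    def summary(self) -> str:
        lines = [
            f"AMMI fit — trait {self.trait!r}: "
            f"{len(self.genotypes)} genotypes x {len(self.environments)} environments",
            f"grand mean {self.mu:.4f}; GEI SS {self.gei_ss():.4f}; "
            f"{self.n_axes} axes, {self.n_retained} retained",
            "axis   lambda      theta%   " + ("F        p" if self.axis_tests is not None else ""),
        ]
        for k in range(self.n_axes):
            line = f"PC{k + 1:<4d} {self.lam[k]:<11.4f} {self.theta[k]:<8.2f}"
            if self.axis_tests is not None:
                t = self.axis_tests.iloc[k]
                line += f" {t['F']:<8.3f} {t['p']:.4g}"
            lines.append(line)
        return "\n".join(lines)


def fit_ammi(matrix: GEMatrix, n_retained: int | str = "all",
             error_ms: float | None = None, error_df: int | None = None) -> AMMIResults:
    """Functional wrapper: fit AMMI to a cell-mean matrix."""
    return AMMI(matrix, error_ms=error_ms, error_df=error_df).fit(n_retained)
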