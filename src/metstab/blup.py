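"""Mixed-model genotypic values (BLUPs) and BLUP-based stability indices.

The mixed model treats environment and block-within-environment as fixed and
genotype and genotype-by-environment as random:

    y_ijr = mu + tau_j + b_jr + g_i + (ge)_ij + e_ijr,
    g_i ~ N(0, s2g),  (ge)_ij ~ N(0, s2ge),  e ~ N(0, s2e).

Variance components come from REML (closed-form ANOVA estimators are used on
balanced data, where they coincide with REML; statsmodels MixedLM otherwise)
and the random effects are the solutions of Henderson's mixed model
equations, i.e. shrunken predictions. The genotypic value of genotype i in
environment j is

    Gv_ij = mu + tau_j (+ mean block effect) + g~_i + (ge)~_ij.

Stability/performance indices over E environments with environment means
mu_j (observed trait means):

    HMGV_i   = E / sum_j (1 / Gv_ij)               harmonic mean
    RPGV_i   = (1/E) sum_j Gv_ij / mu_j            relative performance
    HMRPGV_i = E / sum_j (mu_j / Gv_ij)            harmonic mean of relatives

Rank 1 is the *largest* value (best performer). Harmonic means require all
Gv_ij > 0; genotypes violating this are flagged and excluded from ranking,
which is why these indices are normally computed on a positive measurement
scale (e.g. TIC-normalised intensities) rather than on log/Pareto scores.

WAASB applies the weighted-average-of-absolute-scores idea to the SVD of the
matrix of predicted interaction effects (ge)~_ij; smaller is more stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import VarianceComponents, combined_anova, reml_components
from .dataset import METDataset
from .exceptions import ConvergenceError, DimensionError, ValidationError


class METMixedModel:
    """Mixed model for one trait of a replicated MET (statsmodels-style).

    ``fit()`` estimates variance components by REML and predicts the random
    genotype and interaction effects, returning a :class:`BLUPResults`.
    """

    def __init__(self, data: METDataset, trait: str):
        if data.n_genotypes < 2 or data.n_environments < 2:
            raise DimensionError("mixed model needs >=2 genotypes and >=2 environments")
        self.data = data
        self.trait = trait

    def fit(self, method: str = "auto") -> "BLUPResults":
        """Fit by REML.

        method='auto' uses the closed-form ANOVA estimators when the design
        is balanced and they are interior (they equal REML there), falling
        back to statsmodels MixedLM; 'reml' forces the iterative fit.
        """
        data, trait = self.data, self.trait
        balanced = True
        try:
            y = data.trait_array(trait)
        except ValidationError:
            balanced = False
        vc = None
        if method == "auto" and balanced:
            _, vc_ems = combined_anova(data, trait, method="ems")
            if not vc_ems.truncated:
                vc = VarianceComponents(
                    sigma2_g=vc_ems.sigma2_g, sigma2_ge=vc_ems.sigma2_ge,
                    sigma2_e=vc_ems.sigma2_e, n_rep=vc_ems.n_rep,
                    n_loc=vc_ems.n_loc, method="reml",
                )
        if vc is None:
            try:
                s2g, s2ge, s2e = reml_components(data, trait)
            except Exception as err:  # optimizer failures surface here
                raise ConvergenceError(f"REML fit failed for {trait!r}: {err}") from err
            vc = VarianceComponents(
                sigma2_g=s2g, sigma2_ge=s2ge, sigma2_e=s2e,
                n_rep=data.n_replicates, n_loc=data.n_environments, method="reml",
            )
        return self._predict(vc)

    def _predict(self, vc: VarianceComponents) -> "BLUPResults":
        """Solve Henderson's mixed model equations at the given components."""
        from .anova import _met_design

        gens = self.data.genotypes
        envs = self.data.environments
        G, E = len(gens), len(envs)
        yv, X, Zg, Zge, gi, ej = _met_design(self.data, self.trait)
        n = len(yv)
        Z = np.hstack([Zg, Zge])

        # ridge weights sigma2_e / sigma2_u per random term; a vanishing
        # residual variance means no shrinkage, a vanishing component means
        # total shrinkage of that term
        yscale = max(yv.var(), 1.0)
        s2e = max(vc.sigma2_e, 1e-10 * yscale)
        lam_g = s2e / max(vc.sigma2_g, 1e-12 * yscale)
        lam_ge = s2e / max(vc.sigma2_ge if vc.sigma2_ge else 0.0, 1e-12 * yscale)
        D = np.concatenate([np.full(G, lam_g), np.full(G * E, lam_ge)])

        # penalised least squares in augmented form (numerically preferable
        # to forming the normal equations): min ||y - Xb - Zu||^2 + u'Du
        n_fixed = X.shape[1]
        A = np.vstack([
            np.hstack([X, Z]),
            np.hstack([np.zeros((Z.shape[1], n_fixed)), np.diag(np.sqrt(D))]),
        ])
        b = np.concatenate([yv, np.zeros(Z.shape[1])])
        sol = np.linalg.lstsq(A, b, rcond=None)[0]
        beta = sol[:n_fixed]
        g_blup = sol[n_fixed: n_fixed + G]
        ge_blup = sol[n_fixed + G:].reshape(G, E)

        # fixed cell value for (i, j): average fitted fixed part over blocks in j
        fixed_cell = np.zeros(E)
        for j in range(E):
            mask = ej == j
            fixed_cell[j] = (X[mask] @ beta).mean()
        gv = fixed_cell[None, :] + g_blup[:, None] + ge_blup
        env_mean = np.array([yv[ej == j].mean() for j in range(E)])
        return BLUPResults(
            model=self, varcomp=vc,
            gv=pd.DataFrame(gv, index=gens, columns=envs),
            genotype_blup=pd.Series(g_blup, index=gens),
            ge_blup=pd.DataFrame(ge_blup, index=gens, columns=envs),
            env_mean=pd.Series(env_mean, index=envs),
        )


@dataclass
class BLUPResults:
    """Genotypic values, predicted effects and variance components."""

    model: METMixedModel
    varcomp: VarianceComponents
    gv: pd.DataFrame            # G x E genotypic values Gv_ij
    genotype_blup: pd.Series    # shrunken genotype effects
    ge_blup: pd.DataFrame       # shrunken interaction effects
    env_mean: pd.Series         # observed environment means mu_j

    @property
    def trait(self) -> str:
        return self.model.trait

    def indices(self) -> pd.DataFrame:
        """HMGV, RPGV and HMRPGV with descending ranks (rank 1 = best)."""
        gv = self.gv.to_numpy()
        mu = self.env_mean.to_numpy()
        E = gv.shape[1]
        ok = (gv > 0).all(axis=1)
        hmgv = np.full(len(gv), np.nan)
        hmrpgv = np.full(len(gv), np.nan)
        hmgv[ok] = E / (1.0 / gv[ok]).sum(axis=1)
        rpgv = (gv / mu[None, :]).mean(axis=1)
        hmrpgv[ok] = E / (mu[None, :] / gv[ok]).sum(axis=1)
        out = pd.DataFrame(
            {"HMGV": hmgv, "RPGV": rpgv, "HMRPGV": hmrpgv},
            index=self.gv.index,
        )
        out["positive_domain"] = ok
        for c in ("HMGV", "RPGV", "HMRPGV"):
            out[f"rank_{c}"] = out[c].rank(ascending=False, method="average")
        return out

    def waasb(self) -> pd.DataFrame:
        """Weighted average of absolute scores of the BLUP interaction matrix.

        SVD of (ge)~; WAASB_i = sum_k |s_ik| theta_k / sum theta_k over all
        axes, with s the symmetric-partition scores and theta the per-axis
        share of interaction SS. Smaller = more stable; zero interaction
        gives all-zero WAASB with tied rank 1.
        """
        m = self.ge_blup.to_numpy()
        u, s, vt = np.linalg.svd(m, full_matrices=False)
        p = min(m.shape)
        lam = s[:p]
        total = float((lam**2).sum())
        if total <= 1e-24:
            w = np.zeros(m.shape[0])
        else:
            theta = lam**2 / total
            scores = np.abs(u[:, :p] * np.sqrt(lam))
            w = (scores * theta).sum(axis=1) / theta.sum()
        out = pd.DataFrame({"WAASB": w}, index=self.gv.index)
        out["rank_WAASB"] = out["WAASB"].rank(method="average")
        return out

    def summary(self) -> str:
        vc = self.varcomp
        ind = self.indices()
        best = ind["HMRPGV"].idxmax()
        return (
            f"Mixed-model fit — trait {self.trait!r} ({vc.method} components)\n"
            f"sigma2_g={vc.sigma2_g:.4f}  sigma2_ge={vc.sigma2_ge:.4f}  "
            f"sigma2_e={vc.sigma2_e:.4f}\n"
            f"best genotype by HMRPGV: {best}"
        )


def fit_blup(data: METDataset, trait: str, method: str = "auto") -> BLUPResults:
    """Functional wrapper: fit the MET mixed model and return BLUP results."""
    return METMixedModel(data, trait).fit(method=method)


def blup_indices(fit: BLUPResults) -> pd.DataFrame:
    """Functional wrapper for :meth:`BLUPResults.indices`."""
    return fit.indices()


def waasb(fit: BLUPResults) -> pd.DataFrame:
    """Functional wrapper for :meth:`BLUPResults.waasb`."""
    return fit.waasb()
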