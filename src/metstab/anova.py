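"""RCBD ANOVA, combined ANOVA across environments, variance components and
broad-sense heritability.

Per-environment analysis fits the RCBD model y_ir = mu + g_i + b_r + e_ir and
estimates, by expected mean squares (EMS),

    sigma2_g = (MS_genotype - MS_residual) / R,    sigma2_e = MS_residual.

The combined analysis across L environments partitions

    environment | block-within-environment | genotype | GEI | residual

and, treating the genotype-by-environment interaction as random, estimates

    sigma2_ge = (MS_GEI - MS_residual) / R,
    sigma2_g  = (MS_genotype - MS_GEI) / (R * L).

F tests follow the random-GEI expectation structure: genotype is tested
against the GEI mean square, GEI against the residual, environment against
block-within-environment, blocks against the residual.

Broad-sense heritability on an entry-mean basis:

    single environment:  H2 = s2g / (s2g + s2e / R)
    combined:            H2 = s2g / (s2g + s2ge / L + s2e / (L * R))

A REML alternative (fixed environment and block, random genotype and GEI) is
provided through statsmodels MixedLM; on balanced data EMS and REML agree.
Negative EMS variance estimates are truncated to zero and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import METDataset
from .exceptions import DesignError, ValidationError

_STAR_LEVELS = [(0.001, "***"), (0.01, "**"), (0.05, "*")]


def significance_stars(p: float) -> str:
    for thr, stars in _STAR_LEVELS:
        if p < thr:
            return stars
    return "ns"


@dataclass
class VarianceComponents:
    """Estimated variance components from a single-environment or combined fit.

    Negative method-of-moments estimates are truncated to zero (``truncated``
    set); the untruncated values stay available in ``raw`` for bias-sensitive
    diagnostics such as Monte-Carlo calibration.
    """

    sigma2_g: float
    sigma2_e: float
    sigma2_ge: float | None = None
    n_rep: int = 1
    n_loc: int = 1
    method: str = "ems"
    truncated: bool = False
    raw: dict = None

    def __post_init__(self) -> None:
        self.raw = {name: getattr(self, name)
                    for name in ("sigma2_g", "sigma2_ge", "sigma2_e")}
        for name in ("sigma2_g", "sigma2_ge", "sigma2_e"):
            v = getattr(self, name)
            if v is not None and v < 0:
                setattr(self, name, 0.0)
                self.truncated = True


@dataclass
class AnovaTable:
    """ANOVA table with source, df, SS, MS, F, p and significance stars."""

    table: pd.DataFrame
    trait: str

    def __getitem__(self, source: str) -> pd.Series:
        return self.table.loc[source]

    @property
    def total_ss(self) -> float:
        return float(self.table.loc["total", "SS"])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AnovaTable(trait={self.trait!r})\n{self.table.round(4)}"


def _build_table(rows: list[dict], trait: str) -> AnovaTable:
    df = pd.DataFrame(rows).set_index("source")
    df["MS"] = df["SS"] / df["df"]
    df["stars"] = [significance_stars(p) if np.isfinite(p) else "" for p in df["p"]]
    total = pd.DataFrame(
        {"df": [df["df"].sum()], "SS": [df["SS"].sum()], "MS": [np.nan],
         "F": [np.nan], "p": [np.nan], "stars": [""]},
        index=pd.Index(["total"], name="source"),
    )
    return AnovaTable(pd.concat([df, total]), trait)


def _f_p(ms_num: float, df_num: int, ms_den: float, df_den: int) -> tuple[float, float]:
    if ms_den <= 0:
        # zero denominator mean square: infinite evidence unless numerator is 0 too
        return (np.inf, 0.0) if ms_num > 0 else (np.nan, np.nan)
    f = ms_num / ms_den
    return f, float(stats.f.sf(f, df_num, df_den))


def rcbd_anova(
    data: METDataset, trait: str, environment: str
) -> tuple[AnovaTable, VarianceComponents]:
    """Single-environment RCBD ANOVA with EMS variance components."""
    sub = data.subset_trait(trait)
    sub = sub[sub["environment"] == environment]
    if sub.empty:
        raise ValidationError(f"no observations for environment {environment!r}")
    wide = sub.pivot_table(index="genotype", columns="replicate", values="value")
    if wide.isna().any().any():
        raise ValidationError(f"incomplete RCBD in environment {environment!r}")
    y = wide.to_numpy()
    G, R = y.shape
    if G < 2 or R < 2:
        raise DesignError("RCBD ANOVA needs >=2 genotypes and >=2 replicates")
    grand = y.mean()
    ss_g = R * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_b = G * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_res = ss_tot - ss_g - ss_b
    df_g, df_b, df_res = G - 1, R - 1, (G - 1) * (R - 1)
    ms_res = ss_res / df_res
    f_g, p_g = _f_p(ss_g / df_g, df_g, ms_res, df_res)
    f_b, p_b = _f_p(ss_b / df_b, df_b, ms_res, df_res)
    table = _build_table(
        [
            {"source": "genotype", "df": df_g, "SS": ss_g, "F": f_g, "p": p_g},
            {"source": "block", "df": df_b, "SS": ss_b, "F": f_b, "p": p_b},
            {"source": "residual", "df": df_res, "SS": ss_res, "F": np.nan, "p": np.nan},
        ],
        trait,
    )
    vc = VarianceComponents(
        sigma2_g=(ss_g / df_g - ms_res) / R, sigma2_e=ms_res,
        n_rep=R, n_loc=1, method="ems",
    )
    return table, vc


def _balanced_array(data: METDataset, trait: str) -> np.ndarray:
    arr = data.trait_array(trait)
    if arr.shape[0] < 2 or arr.shape[1] < 2 or arr.shape[2] < 2:
        raise DesignError("combined ANOVA needs >=2 genotypes, environments and replicates")
    return arr


def combined_anova(
    data: METDataset, trait: str, method: str = "ems"
) -> tuple[AnovaTable, VarianceComponents]:
    """Combined ANOVA across environments with random-GEI variance components.

    ``method='ems'`` uses closed-form expected-mean-square estimators and
    requires a balanced design; ``method='reml'`` fits the equivalent mixed
    model by REML (works for mildly unbalanced data too).
    """
    if method not in ("ems", "reml"):
        raise ValueError("method must be 'ems' or 'reml'")
    try:
        y = _balanced_array(data, trait)
    except ValidationError:
        if method == "ems":
            raise ValidationError(
                f"trait {trait!r} is unbalanced; EMS estimation needs a complete "
                "G x E x R design — use method='reml'"
            )
        raise NotImplementedError(
            "REML on unbalanced data requires per-observation model fitting; "
            "drop incomplete traits or complete the design"
        )
    G, E, R = y.shape
    grand = y.mean()
    yi = y.mean(axis=(1, 2))
    yj = y.mean(axis=(0, 2))
    yij = y.mean(axis=2)
    yjr = y.mean(axis=0)  # E x R block means
    ss_env = G * R * ((yj - grand) ** 2).sum()
    ss_blk = G * ((yjr - yj[:, None]) ** 2).sum()
    ss_gen = E * R * ((yi - grand) ** 2).sum()
    ss_gei = R * ((yij - yi[:, None] - yj[None, :] + grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_res = ss_tot - ss_env - ss_blk - ss_gen - ss_gei
    dfs = {
        "environment": E - 1,
        "block(environment)": E * (R - 1),
        "genotype": G - 1,
        "GEI": (G - 1) * (E - 1),
    }
    dfs["residual"] = G * E * R - 1 - sum(dfs.values())
    ms = {
        "environment": ss_env / dfs["environment"],
        "block(environment)": ss_blk / dfs["block(environment)"],
        "genotype": ss_gen / dfs["genotype"],
        "GEI": ss_gei / dfs["GEI"],
        "residual": ss_res / dfs["residual"],
    }
    f_env, p_env = _f_p(ms["environment"], dfs["environment"],
                        ms["block(environment)"], dfs["block(environment)"])
    f_blk, p_blk = _f_p(ms["block(environment)"], dfs["block(environment)"],
                        ms["residual"], dfs["residual"])
    f_gen, p_gen = _f_p(ms["genotype"], dfs["genotype"], ms["GEI"], dfs["GEI"])
    f_gei, p_gei = _f_p(ms["GEI"], dfs["GEI"], ms["residual"], dfs["residual"])
    table = _build_table(
        [
            {"source": "environment", "df": dfs["environment"], "SS": ss_env,
             "F": f_env, "p": p_env},
            {"source": "block(environment)", "df": dfs["block(environment)"],
             "SS": ss_blk, "F": f_blk, "p": p_blk},
            {"source": "genotype", "df": dfs["genotype"], "SS": ss_gen,
             "F": f_gen, "p": p_gen},
            {"source": "GEI", "df": dfs["GEI"], "SS": ss_gei, "F": f_gei, "p": p_gei},
            {"source": "residual", "df": dfs["residual"], "SS": ss_res,
             "F": np.nan, "p": np.nan},
        ],
        trait,
    )
    if method == "ems":
        vc = VarianceComponents(
            sigma2_g=(ms["genotype"] - ms["GEI"]) / (R * E),
            sigma2_ge=(ms["GEI"] - ms["residual"]) / R,
            sigma2_e=ms["residual"],
            n_rep=R, n_loc=E, method="ems",
        )
    else:
        s2g, s2ge, s2e = reml_components(data, trait)
        vc = VarianceComponents(
            sigma2_g=s2g, sigma2_ge=s2ge, sigma2_e=s2e,
            n_rep=R, n_loc=E, method="reml",
        )
    return table, vc


def _met_design(data: METDataset, trait: str):
    """Fixed design X (intercept, env, block-in-env) and random designs Zg, Zge."""
    sub = data.subset_trait(trait)
    gens, envs = data.genotypes, data.environments
    G, E = len(gens), len(envs)
    gi = sub["genotype"].map({g: i for i, g in enumerate(gens)}).to_numpy()
    ej = sub["environment"].map({e: j for j, e in enumerate(envs)}).to_numpy()
    blocks = sorted(set(zip(sub["environment"], sub["replicate"])))
    bmap = {b: k for k, b in enumerate(blocks)}
    bk = np.array([bmap[b] for b in zip(sub["environment"], sub["replicate"])])
    n = len(sub)
    cols = [np.ones(n)]
    cols += [(ej == j).astype(float) for j in range(1, E)]
    first_blocks = {min(k for b, k in bmap.items() if b[0] == env) for env in envs}
    cols += [(bk == k).astype(float) for k in range(len(blocks)) if k not in first_blocks]
    X = np.column_stack(cols)
    Zg = np.zeros((n, G))
    Zg[np.arange(n), gi] = 1.0
    Zge = np.zeros((n, G * E))
    Zge[np.arange(n), gi * E + ej] = 1.0
    y = sub["value"].to_numpy()
    return y, X, Zg, Zge, gi, ej


def _restricted_loglike(theta, y, X, Gram_g, Gram_ge, n):
    """Exact REML log-likelihood at variance components theta = (s2g, s2ge, s2e)."""
    s2g, s2ge, s2e = theta
    V = s2g * Gram_g + s2ge * Gram_ge + s2e * np.eye(n)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * np.log(np.diag(L)).sum()
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    quad = resid @ np.linalg.solve(V, resid)
    return -0.5 * (logdet_v + logdet_x + quad)


def reml_components(data: METDataset, trait: str) -> tuple[float, float, float]:
    """REML variance components (sigma2_g, sigma2_ge, sigma2_e).

    Mixed model: environment and block-within-environment fixed; genotype and
    genotype-by-environment random. A statsmodels MixedLM fit provides the
    starting value and the exact restricted log-likelihood is then maximised
    directly (Nelder-Mead on log variances, tight tolerances), so that on
    balanced data the estimates reproduce the EMS closed forms to high
    precision.
    """
    from scipy import optimize

    y, X, Zg, Zge, _, _ = _met_design(data, trait)
    n = len(y)
    scale = y.var() if y.var() > 0 else 1.0
    start = _mixedlm_start(data, trait)
    if start is None:
        start = np.full(3, scale / 3.0)
    floor = 1e-10 * scale
    Gram_g = Zg @ Zg.T
    Gram_ge = Zge @ Zge.T

    def neg_ll(logtheta):
        return -_restricted_loglike(np.exp(logtheta), y, X, Gram_g, Gram_ge, n)

    x0 = np.log(np.maximum(start, floor))
    res = optimize.minimize(
        neg_ll, x0, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 4000, "maxfev": 6000},
    )
    theta = np.exp(res.x)
    theta[theta <= 2 * floor] = 0.0  # boundary solutions collapse to zero
    return float(theta[0]), float(theta[1]), float(theta[2])


def _mixedlm_start(data: METDataset, trait: str):
    """Starting values from statsmodels MixedLM (None if the fit fails)."""
    import statsmodels.formula.api as smf

    sub = data.subset_trait(trait)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "value ~ C(environment) + C(environment):C(replicate)",
                sub,
                groups=np.ones(len(sub)),
                vc_formula={"g": "0 + C(genotype)",
                            "ge": "0 + C(genotype):C(environment)"},
            )
            result = model.fit(reml=True, method="lbfgs", maxiter=2000)
        comp = dict(zip(model.exog_vc.names, result.vcomp))
        return np.array([comp["g"], comp["ge"], result.scale])
    except Exception:
        return None


def heritability_single(v: VarianceComponents) -> float:
    """Broad-sense heritability in one environment: s2g / (s2g + s2e/R)."""
    if v.sigma2_g <= 0:
        return 0.0
    denom = v.sigma2_g + v.sigma2_e / v.n_rep
    return v.sigma2_g / denom if denom > 0 else 1.0


def heritability_combined(v: VarianceComponents) -> float:
    """Combined broad-sense heritability: s2g / (s2g + s2ge/L + s2e/(L*R))."""
    if v.sigma2_g <= 0:
        return 0.0
    s2ge = v.sigma2_ge or 0.0
    denom = v.sigma2_g + s2ge / v.n_loc + v.sigma2_e / (v.n_loc * v.n_rep)
    return v.sigma2_g / denom if denom > 0 else 1.0
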