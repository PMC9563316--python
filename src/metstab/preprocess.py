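"""Feature-matrix preprocessing and univariate screening for metabolite panels.

A :class:`FeatureMatrix` holds non-negative spectral intensities for samples
(rows) by mass features (columns), with per-sample trial metadata (genotype,
environment, replicate) and per-feature metadata (m/z label, ion mode).

Pipeline steps mirror standard metabolomics practice:

* total-ion-count (TIC) normalisation — each sample row rescaled to sum 100,
  i.e. every intensity becomes a percentage of the sample's total ion count;
* log10 transform followed by Pareto scaling — per feature, centre the log
  intensities and divide by the square root of their standard deviation
  (Pareto scaling damps the dominance of high-variance features without
  flattening the variance structure entirely);
* one-way ANOVA screening per feature with Bonferroni correction over the
  features tested in the call;
* two-way (genotype x environment) fixed-effects ANOVA ranking features by
  the environment main effect, used to shortlist location-responsive
  features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import METDataset
from .exceptions import DesignError, ValidationError

ION_MODES = {"positive", "negative"}


@dataclass
class FeatureMatrix:
    """Samples x features intensity matrix with trial and feature metadata."""

    intensities: pd.DataFrame            # samples x features
    sample_meta: pd.DataFrame            # columns: genotype, environment, replicate
    feature_meta: pd.DataFrame = None    # columns: mz, ion_mode

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame({
                "mz": list(self.intensities.columns),
                "ion_mode": "positive",
            }, index=self.intensities.columns)
        if len(self.sample_meta) != len(self.intensities):
            raise ValidationError("sample_meta length does not match intensity rows")
        if len(self.feature_meta) != self.intensities.shape[1]:
            raise ValidationError("feature_meta length does not match intensity columns")
        bad = set(self.feature_meta["ion_mode"]) - ION_MODES
        if bad:
            raise ValidationError(f"unknown ion mode(s): {sorted(bad)}")
        for col in ("genotype", "environment", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample_meta lacks column {col!r}")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @classmethod
    def from_met(cls, data: METDataset) -> "FeatureMatrix":
        """Pivot a long MET dataset into samples x traits (features)."""
        df = data.observations
        wide = df.pivot_table(
            index=["genotype", "environment", "replicate"],
            columns="trait", values="value",
        ).reindex(columns=data.traits)
        if wide.isna().any().any():
            raise ValidationError("incomplete design cannot be pivoted to a feature matrix")
        meta = wide.index.to_frame(index=False)
        wide = wide.reset_index(drop=True)
        wide.columns.name = None
        return cls(intensities=wide, sample_meta=meta)


def tic_normalize(m: FeatureMatrix) -> FeatureMatrix:
    """Express every intensity as a percentage of its sample's total ion count.

    Each row of the result sums to 100; the operation is idempotent.
    """
    totals = m.intensities.sum(axis=1)
    if (totals <= 0).any():
        sample = m.sample_meta.iloc[int(np.argmax((totals <= 0).to_numpy()))]
        raise ValidationError(
            f"sample (genotype={sample['genotype']}, environment="
            f"{sample['environment']}, replicate={sample['replicate']}) "
            "has non-positive total ion count"
        )
    return replace(m, intensities=100.0 * m.intensities.div(totals, axis=0))


def log_pareto(m: FeatureMatrix, zero_offset: bool = True) -> FeatureMatrix:
    """log10 transform then Pareto scaling per feature column.

    z = (log10 x - mean(log10 x)) / sqrt(sd(log10 x)); zero-variance columns
    map to all-zero. Non-positive intensities are lifted by half the smallest
    positive value in the matrix when ``zero_offset`` is on (the default),
    otherwise they are a domain error.
    """
    x = m.intensities.to_numpy(dtype=float)
    if (x <= 0).any():
        if not zero_offset:
            raise ValidationError(
                "non-positive intensities present and zero_offset disabled"
            )
        positive = x[x > 0]
        if positive.size == 0:
            raise ValidationError("matrix has no positive intensities")
        x = x + 0.5 * positive.min()
        if (x <= 0).any():
            raise ValidationError("offset did not lift all intensities above zero")
    logged = np.log10(x)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (logged - mean) / np.sqrt(sd)
    z[:, sd == 0] = 0.0
    return replace(m, intensities=pd.DataFrame(
        z, index=m.intensities.index, columns=m.intensities.columns
    ))


def _factor_groups(m: FeatureMatrix, factor: str) -> list[np.ndarray]:
    if factor not in ("genotype", "environment"):
        raise DesignError("factor must be 'genotype' or 'environment'")
    labels = m.sample_meta[factor]
    levels = labels.unique()
    if len(levels) < 2:
        raise DesignError(f"factor {factor!r} has a single level")
    groups = [m.intensities.to_numpy()[labels.to_numpy() == lv] for lv in levels]
    if any(len(g) < 2 for g in groups):
        raise DesignError(f"every level of {factor!r} needs >=2 samples")
    return groups


def anova_screen(m: FeatureMatrix, factor: str = "genotype", alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature one-way ANOVA with Bonferroni adjustment.

    Returns a table (feature, F, p, p_adj, significant) where
    ``p_adj = min(1, p * n_features)`` — the family is the set of features
    tested in this call — and ``significant`` flags ``p_adj < alpha``.
    """
    groups = _factor_groups(m, factor)
    f_stat, p_raw = stats.f_oneway(*groups, axis=0)
    p_adj = np.minimum(1.0, p_raw * m.n_features)
    return pd.DataFrame({
        "feature": list(m.intensities.columns),
        "F": f_stat,
        "p": p_raw,
        "p_adj": p_adj,
        "significant": p_adj < alpha,
    }).set_index("feature")


def _twoway_balanced(m: FeatureMatrix) -> pd.DataFrame:
    """Vectorised balanced two-factor fixed-effects ANOVA per feature."""
    meta = m.sample_meta
    gens = meta["genotype"].unique()
    envs = meta["environment"].unique()
    gi = meta["genotype"].map({g: i for i, g in enumerate(gens)}).to_numpy()
    ej = meta["environment"].map({e: j for j, e in enumerate(envs)}).to_numpy()
    G, E = len(gens), len(envs)
    x = m.intensities.to_numpy(dtype=float)  # n x F
    n = len(meta)
    R = n // (G * E)
    counts = np.zeros((G, E))
    np.add.at(counts, (gi, ej), 1)
    if not np.all(counts == R):
        raise DesignError("unbalanced")
    cell = np.zeros((G, E, x.shape[1]))
    np.add.at(cell, (gi, ej), x)
    cell /= R
    grand = x.mean(axis=0)
    mi = cell.mean(axis=1)  # G x F
    mj = cell.mean(axis=0)  # E x F
    ss_g = E * R * ((mi - grand) ** 2).sum(axis=0)
    ss_e = G * R * ((mj - grand) ** 2).sum(axis=0)
    ss_ge = R * ((cell - mi[:, None, :] - mj[None, :, :] + grand) ** 2).sum(axis=(0, 1))
    ss_tot = ((x - grand) ** 2).sum(axis=0)
    ss_res = ss_tot - ss_g - ss_e - ss_ge
    df_g, df_e, df_ge = G - 1, E - 1, (G - 1) * (E - 1)
    df_res = n - G * E
    if df_res <= 0:
        raise DesignError("two-way ANOVA with interaction needs replicates")
    ms_res = ss_res / df_res
    with np.errstate(invalid="ignore", divide="ignore"):
        f_g, f_e, f_ge = (ss_g / df_g) / ms_res, (ss_e / df_e) / ms_res, (ss_ge / df_ge) / ms_res
    return pd.DataFrame({
        "feature": list(m.intensities.columns),
        "F_genotype": f_g, "p_genotype": stats.f.sf(f_g, df_g, df_res),
        "F_environment": f_e, "p_environment": stats.f.sf(f_e, df_e, df_res),
        "F_interaction": f_ge, "p_interaction": stats.f.sf(f_ge, df_ge, df_res),
    }).set_index("feature")


def _twoway_type2(m: FeatureMatrix) -> pd.DataFrame:
    """Per-feature Type-II two-way ANOVA fallback for unbalanced designs."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rows = []
    base = m.sample_meta[["genotype", "environment"]].copy()
    for feat in m.intensities.columns:
        df = base.copy()
        df["y"] = m.intensities[feat].to_numpy()
        fit = smf.ols("y ~ C(genotype) * C(environment)", df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        rows.append({
            "feature": feat,
            "F_genotype": tab.loc["C(genotype)", "F"],
            "p_genotype": tab.loc["C(genotype)", "PR(>F)"],
            "F_environment": tab.loc["C(environment)", "F"],
            "p_environment": tab.loc["C(environment)", "PR(>F)"],
            "F_interaction": tab.loc["C(genotype):C(environment)", "F"],
            "p_interaction": tab.loc["C(genotype):C(environment)", "PR(>F)"],
        })
    return pd.DataFrame(rows).set_index("feature")


def two_way_anova(m: FeatureMatrix) -> pd.DataFrame:
    """Two-factor (genotype, environment, interaction) ANOVA for every feature.

    Uses the fast closed form when the design is balanced and falls back to
    Type-II sums of squares otherwise (with a logged notice).
    """
    for col in ("genotype", "environment"):
        if m.sample_meta[col].nunique() < 2:
            raise DesignError(f"{col} needs >=2 levels")
    try:
        return _twoway_balanced(m)
    except DesignError as err:
        if "unbalanced" not in str(err):
            raise
        import logging

        logging.getLogger(__name__).info(
            "design unbalanced; using Type-II sums of squares"
        )
        return _twoway_type2(m)


def two_way_rank(m: FeatureMatrix, k: int, key: str = "environment") -> pd.DataFrame:
    """Top-``k`` features ranked by the chosen two-way ANOVA term.

    Features sort by ascending p of the ``key`` term (``environment`` by
    default — most variation across locations — or ``interaction``), ties
    broken by larger F. ``k=0`` returns an empty table.
    """
    if key not in ("environment", "interaction", "genotype"):
        raise DesignError("key must be 'environment', 'interaction' or 'genotype'")
    table = two_way_anova(m)
    ranked = table.sort_values(
        [f"p_{key}", f"F_{key}"], ascending=[True, False]
    )
    return ranked.head(int(k))
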