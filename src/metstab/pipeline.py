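"""End-to-end pipeline: trial CSV in, one CSV per result table out.

Per trait: combined ANOVA + variance components + heritability, AMMI fit
with stability indices and biplot coordinates, GGE which-won-where, mixed
model BLUP indices and WAASB. Across traits: the WAASBY matrix and the MTSI
selection. A JSON manifest records the configuration, package version and
seed for reproducibility.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .ammi import AMMI
from .anova import combined_anova, heritability_combined, heritability_single, rcbd_anova
from .blup import METMixedModel
from .dataset import METDataset
from .gge import GGE
from .mtsi import MTSI, waasby
from .stability import stability_indices


@dataclass
class PipelineConfig:
    """Tunable settings of the full pipeline (mirrors the CLI config file)."""

    n_ipca_retained: int | None = None   # None: significant axes, min 2
    svp_exponent: float = 0.5
    waasby_weights: tuple[float, float] = (50.0, 50.0)  # (theta_Y, theta_S)
    bonferroni_alpha: float = 0.05
    selection_fraction: float = 2.0 / 11.0
    varcomp_method: str = "ems"
    seed: int = 0


def run_pipeline(
    data: METDataset,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    traits: list[str] | None = None,
) -> dict:
    """Run every analysis stage and write result CSVs under ``outdir``.

    Returns a summary dict (also written as ``manifest.json``) with the
    per-stage output files and the MTSI-selected genotypes.
    """
    cfg = config or PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    traits = traits or data.traits

    heritability_rows, varcomp_rows, ammi_rows = [], [], []
    waasby_cols, mean_perf = {}, {}
    written: list[str] = []

    def save(frame: pd.DataFrame, name: str, index=True) -> None:
        frame.to_csv(out / name, index=index)
        written.append(name)

    for trait in traits:
        table, vc = combined_anova(data, trait, method=cfg.varcomp_method)
        save(table.table, f"anova_{trait}.csv")
        varcomp_rows.append({
            "trait": trait, "sigma2_g": vc.sigma2_g, "sigma2_ge": vc.sigma2_ge,
            "sigma2_e": vc.sigma2_e, "method": vc.method, "truncated": vc.truncated,
        })
        h_row = {"trait": trait, "H2_combined": heritability_combined(vc)}
        for env in data.environments:
            _, vce = rcbd_anova(data, trait, env)
            h_row[f"H2_{env}"] = heritability_single(vce)
        heritability_rows.append(h_row)

        ammi_fit = AMMI.from_dataset(data, trait).fit(
            n_retained="all" if cfg.n_ipca_retained is None else cfg.n_ipca_retained
        )
        theta = {f"theta{k + 1}": ammi_fit.theta[k] for k in range(min(4, ammi_fit.n_axes))}
        pvals = {}
        if ammi_fit.axis_tests is not None:
            pvals = {f"p_PC{k + 1}": ammi_fit.axis_tests["p"].iloc[k]
                     for k in range(min(4, ammi_fit.n_axes))}
        ammi_rows.append({"trait": trait, **theta, **pvals})
        save(ammi_fit.scores_frame(cfg.svp_exponent), f"ammi_scores_{trait}.csv", index=False)

        stab = stability_indices(ammi_fit, n_retained=cfg.n_ipca_retained)
        save(stab, f"stability_{trait}.csv")

        gge_fit = GGE(data.cell_means(trait)).fit(cfg.svp_exponent)
        save(gge_fit.scores_frame(), f"gge_scores_{trait}.csv", index=False)
        www = gge_fit.which_won_where()
        save(www.mega_environments, f"gge_megaenv_{trait}.csv", index=False)

        blup_fit = METMixedModel(data, trait).fit()
        bi = blup_fit.indices().join(blup_fit.waasb())
        save(bi, f"blup_indices_{trait}.csv")

        waasby_cols[trait] = bi["WAASB"]
        mean_perf[trait] = data.cell_means(trait).values.mean(axis=1)

    save(pd.DataFrame(varcomp_rows).set_index("trait"), "varcomp.csv")
    save(pd.DataFrame(heritability_rows).set_index("trait"), "heritability.csv")
    save(pd.DataFrame(ammi_rows).set_index("trait"), "ammi_summary.csv")

    theta_y, theta_s = cfg.waasby_weights
    waasby_matrix = pd.DataFrame({
        trait: waasby(mean_perf[trait], waasby_cols[trait], theta_y, theta_s)["waasby"]
        for trait in traits
    })
    save(waasby_matrix, "waasby.csv")

    selected: list[str] = []
    if len(traits) >= 2:
        mtsi_res = MTSI(waasby_matrix).fit(selection_fraction=cfg.selection_fraction)
        save(mtsi_res.table(), "mtsi.csv")
        selected = list(mtsi_res.table()[mtsi_res.table()["selected"]].index)

    manifest = {
        "metstab_version": __version__,
        "python": sys.version.split()[0],
        "config": asdict(cfg),
        "n_genotypes": data.n_genotypes,
        "n_environments": data.n_environments,
        "n_replicates": data.n_replicates,
        "n_traits": len(traits),
        "selected": selected,
        "outputs": written,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
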