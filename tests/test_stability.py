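import numpy as np
import pandas as pd
import pytest

import metstab as ms
from metstab.dataset import GEMatrix
from metstab.stability import INDEX_NAMES, default_n_retained


def naive_indices(fit, n):
    """Oracle: every index recomputed with explicit summation loops."""
    lam, gamma, delta = fit.lam[:n], fit.gamma[:, :n], fit.delta[:, :n]
    theta = fit.theta[:n] / 100.0
    G, E = gamma.shape[0], delta.shape[0]
    s = np.array([[np.sqrt(lam[k]) * gamma[i, k] for k in range(n)] for i in range(G)])
    ss = [lam[k] ** 2 for k in range(n)]
    out = {name: np.zeros(G) for name in INDEX_NAMES}
    for i in range(G):
        out["ASTAB"][i] = sum(lam[k] * gamma[i, k] ** 2 for k in range(n))
        out["DA"][i] = np.sqrt(sum((lam[k] * gamma[i, k]) ** 2 for k in range(n)))
        out["DZ"][i] = np.sqrt(sum(gamma[i, k] ** 2 for k in range(n)))
        out["EV"][i] = sum(gamma[i, k] ** 2 for k in range(n)) / n
        out["FA"][i] = sum(lam[k] ** 2 * gamma[i, k] ** 2 for k in range(n))
        out["MASI"][i] = np.sqrt(sum((s[i, k] * theta[k]) ** 2 for k in range(n)))
        out["WAAS"][i] = sum(abs(s[i, k]) * theta[k] for k in range(n)) / sum(theta)
        out["SIPC"][i] = sum(abs(s[i, k]) for k in range(n))
        out["ZA"][i] = sum(theta[k] * abs(s[i, k]) for k in range(n))
        out["AVAMGE"][i] = sum(
            abs(lam[k] * gamma[i, k] * delta[j, k]) for j in range(E) for k in range(n)
        )
        if n >= 2:
            out["ASI"][i] = np.sqrt((s[i, 0] * theta[0]) ** 2 + (s[i, 1] * theta[1]) ** 2)
            out["ASV"][i] = np.sqrt((ss[0] / ss[1] * s[i, 0]) ** 2 + s[i, 1] ** 2)
            out["MASV"][i] = np.sqrt(
                sum((ss[k] / ss[k + 1] * s[i, k]) ** 2 for k in range(n - 1))
                + s[i, n - 1] ** 2
            )
    return pd.DataFrame(out, index=fit.genotypes)


@pytest.mark.parametrize("seed,n", [(0, 2), (1, 3), (2, 4)])
def test_vectorized_matches_naive_loops(seed, n):
    t = ms.random_truth(9, 5, 4, seed=seed)
    fit = ms.fit_ammi(ms.simulate_trait(t).cell_means("trait_001"))
    table = ms.stability_indices(fit, n_retained=n)
    oracle = naive_indices(fit, n)
    for name in INDEX_NAMES:
        np.testing.assert_allclose(table[name], oracle[name], atol=1e-10,
                                   err_msg=name)


def test_zero_interaction_genotype_scores_zero_and_rank_one():
    """A genotype taking no part in the GEI gets every index 0 and rank 1."""
    rng = np.random.default_rng(3)
    G, E = 8, 5
    base = rng.normal(0, 1, (G - 1, E))
    inter = base - base.mean(0) - base.mean(1)[:, None] + base.mean()
    y = np.vstack([inter, np.zeros(E)])  # last genotype: purely additive
    y = y + 50 + rng.normal(0, 2, G)[:, None] + rng.normal(0, 2, E)[None, :]
    # re-centre so the stable genotype's interaction stays exactly zero
    z = y - y.mean(1, keepdims=True) - y.mean(0, keepdims=True) + y.mean()
    assert np.allclose(z[-1], 0, atol=1e-10)
    gm = GEMatrix(values=pd.DataFrame(y, index=[f"G{i}" for i in range(G)],
                                      columns=[f"E{j}" for j in range(E)]), trait="t")
    table = ms.stability_indices(ms.fit_ammi(gm), n_retained=3)
    last = table.loc["G7"]
    for name in INDEX_NAMES:
        assert last[name] == pytest.approx(0.0, abs=1e-8), name
        assert last[f"rank_{name}"] == 1.0, name


def test_single_axis_reductions(noisy_ammi):
    table = ms.stability_indices(noisy_ammi, n_retained=1)
    s1 = np.sqrt(noisy_ammi.lam[0]) * noisy_ammi.gamma[:, 0]
    np.testing.assert_allclose(table["MASI"], np.abs(s1) * noisy_ammi.theta[0] / 100,
                               atol=1e-12)
    np.testing.assert_allclose(table["WAAS"], np.abs(s1), atol=1e-12)
    assert table["ASI"].isna().all()
    assert table["ASV"].isna().all()


def test_ev_equals_dz_squared_over_n(noisy_ammi):
    for n in (2, 3, 4):
        table = ms.stability_indices(noisy_ammi, n_retained=n)
        np.testing.assert_allclose(table["EV"], table["DZ"] ** 2 / n, atol=1e-12)


def test_indices_invariant_to_additive_part():
    t = ms.random_truth(8, 5, 2, seed=7, effect_scales={"block_sd": 0, "error_sd": 0})
    gm = ms.simulate_trait(t).cell_means("trait_001")
    t1 = ms.stability_indices(ms.fit_ammi(gm), n_retained=2)
    rng = np.random.default_rng(8)
    shifted = GEMatrix(
        values=gm.values + 3.3 + rng.normal(0, 5, 8)[:, None] + rng.normal(0, 5, 5)[None, :],
        trait="t",
    )
    t2 = ms.stability_indices(ms.fit_ammi(shifted), n_retained=2)
    for name in INDEX_NAMES:
        np.testing.assert_allclose(t1[name], t2[name].to_numpy(), atol=1e-8, err_msg=name)


@pytest.mark.parametrize("c", [2.0, 0.25])
def test_scaling_behaviour_per_index(c):
    """Scaling data by c scales each index by its stated homogeneity degree."""
    t = ms.random_truth(8, 5, 3, seed=9, effect_scales={"block_sd": 0, "error_sd": 0})
    gm = ms.simulate_trait(t).cell_means("trait_001")
    base = ms.stability_indices(ms.fit_ammi(gm), n_retained=3)
    scaled_gm = GEMatrix(values=gm.values * c, trait="t")
    scaled = ms.stability_indices(ms.fit_ammi(scaled_gm), n_retained=3)
    # lambda scales by c while gamma, delta and theta are invariant, so each
    # index scales by c to the power of its lambda-degree:
    #   sqrt-lambda scores s     -> sqrt(c): ASI, MASI, WAAS, ASV, MASV, SIPC, ZA
    #   one power of lambda      -> c:       ASTAB, DA, AVAMGE
    #   lambda squared           -> c^2:     FA
    #   eigenvectors only        -> 1:       DZ, EV
    factors = {**{n: np.sqrt(c) for n in ("ASI", "MASI", "WAAS", "ASV", "MASV",
                                          "SIPC", "ZA")},
               **{n: c for n in ("ASTAB", "DA", "AVAMGE")},
               "FA": c**2, "DZ": 1.0, "EV": 1.0}
    for name, factor in factors.items():
        np.testing.assert_allclose(scaled[name], base[name] * factor, rtol=1e-8,
                                   err_msg=name)


def test_default_n_retained_minimum_two(noisy_ammi):
    assert default_n_retained(noisy_ammi) >= 2


class TestConcordance:
    def test_symmetric_unit_diagonal(self, noisy_ammi):
        table = ms.stability_indices(noisy_ammi, n_retained=2)
        mat = ms.rank_concordance(table)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        assert ((mat >= -1 - 1e-12) & (mat <= 1 + 1e-12)).all().all()

    def test_duplicate_and_negated_index(self, noisy_ammi):
        table = ms.stability_indices(noisy_ammi, n_retained=2)
        probe = table.copy()
        probe["ASV"] = probe["WAAS"]
        assert ms.rank_concordance(probe).loc["WAAS", "ASV"] == pytest.approx(1.0)
        probe["ASV"] = -probe["WAAS"]
        assert ms.rank_concordance(probe).loc["WAAS", "ASV"] == pytest.approx(-1.0)
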