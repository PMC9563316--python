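import numpy as np
import pandas as pd
import pytest

import metstab as ms
from metstab.dataset import GEMatrix
from metstab.exceptions import DimensionError

from conftest import brute_force_double_center


def random_gematrix(G=6, E=4, seed=0):
    rng = np.random.default_rng(seed)
    return GEMatrix(
        values=pd.DataFrame(rng.normal(10, 3, (G, E)),
                            index=[f"G{i}" for i in range(G)],
                            columns=[f"E{j}" for j in range(E)]),
        trait="t", n_rep=1,
    )


def test_exact_recovery_noise_free(exact_truth, exact_data):
    """On noise-free rank-2 data, mu, alpha, tau and lambda are recovered exactly."""
    fit = ms.AMMI.from_dataset(exact_data, "exact").fit()
    assert fit.mu == pytest.approx(exact_truth.mu, rel=1e-10)
    np.testing.assert_allclose(fit.alpha, exact_truth.alpha, atol=1e-10)
    np.testing.assert_allclose(fit.tau, exact_truth.tau, atol=1e-10)
    np.testing.assert_allclose(fit.lam[:2], exact_truth.lam, rtol=1e-10)
    assert fit.theta[:2].sum() == pytest.approx(100.0, abs=1e-8)
    for k in range(2):
        assert abs(fit.gamma[:, k] @ exact_truth.a[:, k]) == pytest.approx(1.0, abs=1e-8)
        assert abs(fit.delta[:, k] @ exact_truth.t[:, k]) == pytest.approx(1.0, abs=1e-8)


def test_rank1_theta_is_100():
    t = ms.random_truth(7, 4, 1, seed=8, effect_scales={"block_sd": 0, "error_sd": 0})
    fit = ms.fit_ammi(ms.simulate_trait(t).cell_means("trait_001"))
    assert fit.theta[0] == pytest.approx(100.0)
    np.testing.assert_allclose(fit.theta[1:], 0.0, atol=1e-8)


def test_additive_data_all_lambda_zero():
    t = ms.random_truth(6, 5, 0, seed=9, effect_scales={"block_sd": 0, "error_sd": 0})
    fit = ms.fit_ammi(ms.simulate_trait(t).cell_means("trait_001"))
    np.testing.assert_allclose(fit.lam, 0.0, atol=1e-10)
    assert fit.degenerate
    np.testing.assert_allclose(fit.residual, 0.0, atol=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_svd_against_eigendecomposition_oracle(seed):
    """lambda, gamma, delta agree with a brute-force eigendecomposition of Z'Z."""
    gm = random_gematrix(seed=seed)
    fit = ms.fit_ammi(gm)
    z = brute_force_double_center(gm.to_numpy())
    eigval, eigvec = np.linalg.eigh(z.T @ z)
    order = np.argsort(eigval)[::-1]
    lam_oracle = np.sqrt(np.maximum(eigval[order], 0.0))[: fit.n_axes]
    np.testing.assert_allclose(fit.lam, lam_oracle, atol=1e-8)
    for k in range(fit.n_axes):
        if fit.lam[k] > 1e-8:
            v = eigvec[:, order[k]]
            assert abs(v @ fit.delta[:, k]) == pytest.approx(1.0, abs=1e-8)
            u = z @ v / lam_oracle[k]
            assert abs(u @ fit.gamma[:, k]) == pytest.approx(1.0, abs=1e-8)


def test_gei_ss_conservation(noisy_ammi, noisy_data):
    y = noisy_data.cell_means("noisy").to_numpy()
    z = brute_force_double_center(y)
    assert noisy_ammi.gei_ss() == pytest.approx((z**2).sum(), rel=1e-10)


def test_full_reconstruction_identity(noisy_ammi, noisy_data):
    recon = noisy_ammi.reconstruct(noisy_ammi.n_axes)
    np.testing.assert_allclose(recon, noisy_data.cell_means("noisy").to_numpy(),
                               atol=1e-10)


def test_theta_invariant_to_additive_structure():
    gm = random_gematrix(seed=3)
    fit1 = ms.fit_ammi(gm)
    rng = np.random.default_rng(4)
    shifted = gm.values + 7.5 + rng.normal(0, 2, 6)[:, None] + rng.normal(0, 2, 4)[None, :]
    fit2 = ms.fit_ammi(GEMatrix(values=shifted, trait="t", n_rep=1))
    np.testing.assert_allclose(fit1.theta, fit2.theta, atol=1e-8)
    np.testing.assert_allclose(fit1.lam, fit2.lam, atol=1e-8)


def test_gollob_df_and_axis_tests(noisy_data):
    fit = ms.AMMI.from_dataset(noisy_data, "noisy").fit()
    G, E = 11, 5
    expected_df = [G + E - 1 - 2 * k for k in range(1, fit.n_axes + 1)]
    assert fit.axis_tests["df"].tolist() == expected_df
    # axis SS on the replicate scale sums to the ANOVA GEI SS
    table, _ = ms.combined_anova(noisy_data, "noisy")
    assert fit.axis_tests["SS"].sum() == pytest.approx(float(table["GEI"]["SS"]), rel=1e-8)


def test_ss_shares_sum_to_100(noisy_data):
    fit = ms.AMMI.from_dataset(noisy_data, "noisy").fit()
    shares = fit.ss_shares()
    main = shares.loc[["environment", "block(environment)", "genotype", "GEI", "residual"]]
    assert main["percent"].sum() == pytest.approx(100.0, abs=1e-8)
    axes = shares.loc[[s for s in shares.index if s.startswith("GEI:PC")]]
    assert axes["percent"].sum() == pytest.approx(shares.loc["GEI", "percent"], rel=1e-8)


def test_noise_free_additive_shares():
    t = ms.random_truth(6, 4, 0, seed=12, effect_scales={"block_sd": 0, "error_sd": 0})
    data = ms.simulate_trait(t)
    fit = ms.AMMI.from_dataset(data, "trait_001").fit()
    shares = fit.ss_shares()
    env_gen = shares.loc["environment", "percent"] + shares.loc["genotype", "percent"]
    assert env_gen == pytest.approx(100.0, abs=1e-8)
    assert shares.loc["GEI", "percent"] == pytest.approx(0.0, abs=1e-8)


class TestBiplots:
    def test_zero_gei_ammi2_points_at_origin(self):
        t = ms.random_truth(6, 4, 0, seed=13, effect_scales={"block_sd": 0, "error_sd": 0})
        fit = ms.fit_ammi(ms.simulate_trait(t).cell_means("trait_001"))
        coords = fit.biplot_coords("AMMI2")
        # scores scale as sqrt(lambda); lambda ~ 1e-14 numerically -> ~1e-7
        np.testing.assert_allclose(coords[["x", "y"]].to_numpy(), 0.0, atol=1e-6)

    def test_exponent_zero_gives_raw_eigenvectors(self, noisy_ammi):
        coords = noisy_ammi.biplot_coords("AMMI2", svp_exponent=0.0)
        gen = coords[coords["type"] == "genotype"]
        np.testing.assert_allclose(gen["x"], noisy_ammi.gamma[:, 0], atol=1e-12)
        np.testing.assert_allclose(gen["y"], noisy_ammi.gamma[:, 1], atol=1e-12)

    def test_symmetric_scaling_distance_identity(self, noisy_ammi):
        """Sum of squared env AMMI2 distances at f=0.5 equals lambda1 + lambda2."""
        coords = noisy_ammi.biplot_coords("AMMI2", svp_exponent=0.5)
        env = coords[coords["type"] == "environment"]
        total = (env["x"] ** 2 + env["y"] ** 2).sum()
        assert total == pytest.approx(noisy_ammi.lam[0] + noisy_ammi.lam[1], rel=1e-10)

    def test_ammi1_x_axis_is_mean_performance(self, noisy_ammi):
        coords = noisy_ammi.biplot_coords("AMMI1")
        gen = coords[coords["type"] == "genotype"]
        np.testing.assert_allclose(gen["x"], noisy_ammi.mu + noisy_ammi.alpha, atol=1e-12)

    def test_ammi2_needs_two_axes(self):
        rng = np.random.default_rng(5)
        gm = GEMatrix(values=pd.DataFrame(rng.normal(0, 1, (5, 2)),
                                          index=list("abcde"), columns=["E1", "E2"]),
                      trait="t")
        fit = ms.fit_ammi(gm)
        with pytest.raises(DimensionError):
            fit.biplot_coords("AMMI2")
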