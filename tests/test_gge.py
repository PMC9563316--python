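import numpy as np
import pandas as pd
import pytest

import metstab as ms
from metstab.dataset import GEMatrix


def gematrix(values, trait="t"):
    values = np.asarray(values, dtype=float)
    return GEMatrix(
        values=pd.DataFrame(values, index=[f"G{i}" for i in range(values.shape[0])],
                            columns=[f"E{j}" for j in range(values.shape[1])]),
        trait=trait,
    )


def test_frobenius_norm_conserved(noisy_data):
    fit = ms.fit_gge(noisy_data.cell_means("noisy"))
    y = noisy_data.cell_means("noisy").to_numpy()
    centered = y - y.mean(axis=0)
    assert (fit.lam**2).sum() == pytest.approx((centered**2).sum(), rel=1e-10)
    assert fit.explained.sum() == pytest.approx(100.0, abs=1e-8)


def test_no_genotype_effect_no_gei_gives_zero():
    """Environment-only data centres to zero: all singular values vanish."""
    tau = np.array([1.0, 5.0, -2.0, 0.5])
    y = np.tile(10 + tau, (6, 1))
    fit = ms.fit_gge(gematrix(y))
    np.testing.assert_allclose(fit.lam, 0.0, atol=1e-10)


def test_first_two_axes_dominate(noisy_data):
    fit = ms.fit_gge(noisy_data.cell_means("noisy"))
    pairs = [fit.explained[i] + fit.explained[j]
             for i in range(len(fit.lam)) for j in range(i + 1, len(fit.lam))]
    assert fit.explained_first_two() == pytest.approx(max(pairs))


def test_svp_partitioning_product_reconstructs(noisy_data):
    """g-scores (lambda^f) times e-scores (lambda^(1-f)) rebuild the centred matrix."""
    for f in (0.0, 0.5, 1.0):
        fit = ms.fit_gge(noisy_data.cell_means("noisy"), svp_exponent=f)
        recon = fit.genotype_scores @ fit.environment_scores.T
        np.testing.assert_allclose(recon, fit.centered, atol=1e-8)


class TestWhichWonWhere:
    def test_square_example_two_winners(self):
        """4 genotypes at (+-1,+-1); env directions (2,0) and (0,2).

        The perpendicular-ray geometry makes (1,1) win any direction in the
        first quadrant, so both environments fall to vertices adjacent to it.
        """
        pts = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        env = np.array([[2, 0.01], [0.01, 2]], dtype=float)
        fit = _fit_from_scores(pts, env)
        www = fit.which_won_where()
        assert set(www.hull) == {"G0", "G1", "G2", "G3"}
        # both env directions lie (just) inside the sector of vertex (1,1)
        assert www.env_sector["E0"] == "G0"
        assert www.env_sector["E1"] == "G0"
        assert www.n_mega == 1

    def test_assignment_matches_brute_force_grid(self, noisy_data):
        fit = ms.fit_gge(noisy_data.cell_means("noisy"))
        www = fit.which_won_where()
        pts = fit.genotype_scores[:, :2]
        names = fit.genotypes
        for angle in np.linspace(0, 2 * np.pi, 720, endpoint=False):
            d = np.array([np.cos(angle), np.sin(angle)])
            proj = pts @ d
            best = names[int(np.argmax(proj))]
            assert best in www.hull  # winners always on the hull
        for j, envname in enumerate(fit.environments):
            d = fit.environment_scores[j, :2]
            proj = pts @ d
            assert www.env_sector[envname] == names[int(np.argmax(proj))]

    def test_sector_angles_contain_environments(self, noisy_data):
        """The sector angular interval of the assigned winner covers the env angle."""
        fit = ms.fit_gge(noisy_data.cell_means("noisy"))
        www = fit.which_won_where()
        for j, envname in enumerate(fit.environments):
            v = fit.environment_scores[j, :2]
            ang = np.arctan2(v[1], v[0])
            row = www.sectors[www.sectors["vertex"] == www.env_sector[envname]].iloc[0]
            lo, hi = row["angle_from"], row["angle_to"]
            span = (hi - lo) % (2 * np.pi)
            offset = (ang - lo) % (2 * np.pi)
            assert offset <= span + 1e-9

    def test_single_mega_environment(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 1, (6, 2))
        env = np.array([[3.0, 0.1], [2.5, -0.1], [3.2, 0.0]])
        fit = _fit_from_scores(pts, env)
        www = fit.which_won_where()
        if len(set(www.env_sector.values())) == 1:
            assert www.n_mega == 1
        assert sum(len(r) for r in www.mega_environments["environments"]) == 3

    def test_every_environment_assigned_once(self, panel):
        for trait in panel.dataset.traits[:3]:
            fit = ms.fit_gge(panel.dataset.cell_means(trait))
            www = fit.which_won_where()
            assigned = [e for envs in www.mega_environments["environments"] for e in envs]
            assert sorted(assigned) == sorted(fit.environments)

    def test_rotation_equivariance(self, noisy_data):
        """Rotating all scores by a common angle permutes sector assignment consistently."""
        fit = ms.fit_gge(noisy_data.cell_means("noisy"))
        www = fit.which_won_where()
        phi = 0.7
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        fit2 = _fit_from_scores(fit.genotype_scores[:, :2] @ rot.T,
                                fit.environment_scores[:, :2] @ rot.T,
                                gen_names=fit.genotypes, env_names=fit.environments)
        www2 = fit2.which_won_where()
        assert www2.env_sector == www.env_sector

    def test_winner_tops_centred_value_on_rank2_data(self):
        """On rank-2-reconstructible data the winner leads in its own environments."""
        # alpha_sd = 0 keeps the environment-centred matrix exactly rank 2
        t = ms.random_truth(8, 5, 2, seed=31,
                            effect_scales={"block_sd": 0, "error_sd": 0,
                                           "alpha_sd": 0.0, "lambda_scale": 12})
        gm = ms.simulate_trait(t).cell_means("trait_001")
        fit = ms.fit_gge(gm)
        assert fit.explained_first_two() == pytest.approx(100.0, abs=1e-6)
        www = fit.which_won_where()
        centred = gm.to_numpy() - gm.to_numpy().mean(axis=0)
        for _, row in www.mega_environments.iterrows():
            gi = fit.genotypes.index(row["winner"])
            for env in row["environments"]:
                j = fit.environments.index(env)
                assert centred[gi, j] == pytest.approx(centred[:, j].max(), abs=1e-8)


def _fit_from_scores(gen_pts, env_pts, gen_names=None, env_names=None):
    """Build a GGEResults carrying prescribed rank-2 scores (geometry harness)."""
    from metstab.gge import GGE, GGEResults

    gen_names = gen_names or [f"G{i}" for i in range(len(gen_pts))]
    env_names = env_names or [f"E{j}" for j in range(len(env_pts))]
    model = GGE.__new__(GGE)
    model.matrix = GEMatrix(
        values=pd.DataFrame(np.asarray(gen_pts) @ np.asarray(env_pts).T,
                            index=gen_names, columns=env_names),
        trait="synthetic-scores",
    )
    return GGEResults(
        model=model, centered=model.matrix.to_numpy(),
        lam=np.ones(2), genotype_scores=np.asarray(gen_pts, dtype=float),
        environment_scores=np.asarray(env_pts, dtype=float),
        explained=np.array([50.0, 50.0]), svp_exponent=0.5,
        genotype_means=model.matrix.to_numpy().mean(axis=1),
    )


class TestEnvRelations:
    def test_identical_columns_cosine_one(self):
        rng = np.random.default_rng(6)
        col = rng.normal(0, 2, 7)
        y = np.column_stack([col, col, rng.normal(0, 2, 7)]) + 20
        fit = ms.fit_gge(gematrix(y))
        _, cos = fit.env_relations()
        assert cos.loc["E0", "E1"] == pytest.approx(1.0, abs=1e-8)

    def test_cosines_bounded(self, panel):
        for trait in panel.dataset.traits[:3]:
            fit = ms.fit_gge(panel.dataset.cell_means(trait))
            _, cos = fit.env_relations()
            assert ((cos <= 1 + 1e-12) & (cos >= -1 - 1e-12)).all().all()
            np.testing.assert_allclose(np.diag(cos), 1.0, atol=1e-10)

    def test_vector_lengths(self, noisy_data):
        fit = ms.fit_gge(noisy_data.cell_means("noisy"))
        table, _ = fit.env_relations()
        np.testing.assert_allclose(
            table["vector_length"],
            np.linalg.norm(fit.environment_scores[:, :2], axis=1),
        )

    def test_favourable_flag_follows_performance_gradient(self):
        """Environments aligned with high-mean genotypes are favourable."""
        t = ms.random_truth(9, 5, 2, seed=41, effect_scales={"block_sd": 0, "error_sd": 0})
        gm = ms.simulate_trait(t).cell_means("trait_001")
        fit = ms.fit_gge(gm)
        table, _ = fit.env_relations()
        dev = fit.genotype_means - fit.genotype_means.mean()
        grad = fit.genotype_scores[:, :2].T @ dev
        expected = fit.environment_scores[:, :2] @ grad > 0
        assert table["favourable"].tolist() == expected.tolist()
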