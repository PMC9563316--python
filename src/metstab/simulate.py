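"""Synthetic multi-environment trials with known additive + bilinear GEI structure.

Each simulated trait follows the cell-mean model underlying AMMI,

    y_ijr = mu + alpha_i + tau_j + sum_k lambda_k a_ik t_jk + b_jr + e_ijr,

with genotype effects ``alpha`` (sum zero), environment effects ``tau`` (sum
zero), a rank-``k`` bilinear genotype-by-environment interaction whose score
columns are orthonormal and centred (exactly the structure an SVD of the
double-centred cell-mean matrix recovers), RCBD block effects ``b_jr`` shared
by all genotypes within a (environment, replicate) block, and i.i.d. Gaussian
residual noise. Every ingredient is retrievable, so each downstream stage of
the pipeline has a parameter-recovery oracle.

Default effect scales emulate a TIC-normalised metabolite intensity panel in
which environment dominates genotype, as is typical of grain-metabolite METs:
grand mean 100 (arbitrary intensity units), environment effect SD 10,
genotype effect SD 5, interaction singular values of order 8, block SD 2 and
residual SD 3, with 3 replicates. The study shape G=11, E=5, R=3 is the
default throughout the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import METDataset, COLUMNS
from .exceptions import DimensionError, ValidationError

#: default effect scales; see module docstring for rationale
DEFAULT_SCALES = {
    "mu": 100.0,
    "alpha_sd": 5.0,
    "tau_sd": 10.0,
    "lambda_scale": 8.0,
    "block_sd": 2.0,
    "error_sd": 3.0,
}

_ORTHO_TOL = 1e-8


@dataclass
class SimulationTruth:
    """Ground-truth parameter set for one simulated trait.

    Invariants (checked on construction): ``alpha`` and ``tau`` sum to zero;
    the columns of ``a`` (G x k) and ``t`` (E x k) are orthonormal and each
    orthogonal to the all-ones vector; ``lam`` is non-negative and sorted
    non-increasing; ``k <= min(G-1, E-1)``.
    """

    mu: float
    alpha: np.ndarray
    tau: np.ndarray
    lam: np.ndarray
    a: np.ndarray
    t: np.ndarray
    block_sd: float = DEFAULT_SCALES["block_sd"]
    error_sd: float = DEFAULT_SCALES["error_sd"]
    n_rep: int = 3
    seed: int = 0
    noise_df: float | None = None  # scaled-t residuals when set; Gaussian otherwise

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        k = len(self.lam)
        self.a = np.asarray(self.a, dtype=float).reshape(len(self.alpha), k)
        self.t = np.asarray(self.t, dtype=float).reshape(len(self.tau), k)
        G, E = len(self.alpha), len(self.tau)
        if k > min(G - 1, E - 1):
            raise DimensionError(f"rank k={k} exceeds min(G-1, E-1)={min(G - 1, E - 1)}")
        if abs(self.alpha.sum()) > _ORTHO_TOL or abs(self.tau.sum()) > _ORTHO_TOL:
            raise ValidationError("alpha and tau must each sum to zero")
        if np.any(self.lam < 0) or np.any(np.diff(self.lam) > _ORTHO_TOL):
            raise ValidationError("lambda must be non-negative and non-increasing")
        for name, m in [("a", self.a), ("t", self.t)]:
            if k == 0:
                continue
            gram = m.T @ m
            if not np.allclose(gram, np.eye(k), atol=_ORTHO_TOL):
                raise ValidationError(f"columns of {name} are not orthonormal")
            if np.max(np.abs(m.sum(axis=0))) > _ORTHO_TOL:
                raise ValidationError(f"columns of {name} are not centred")

    # -- derived quantities -------------------------------------------------

    @property
    def n_genotypes(self) -> int:
        return len(self.alpha)

    @property
    def n_environments(self) -> int:
        return len(self.tau)

    @property
    def rank(self) -> int:
        return len(self.lam)

    def interaction_matrix(self) -> np.ndarray:
        """G x E bilinear interaction sum_k lambda_k a_k t_k'."""
        return (self.a * self.lam) @ self.t.T

    def cell_mean_matrix(self) -> np.ndarray:
        """Noise-free expected cell means mu + alpha_i + tau_j + GEI_ij."""
        return self.mu + self.alpha[:, None] + self.tau[None, :] + self.interaction_matrix()

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("alpha", "tau", "lam", "a", "t"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(**{k: (np.asarray(v) if k in ("alpha", "tau", "lam", "a", "t") else v)
                      for k, v in d.items()})


def _centered_orthonormal(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """n x k matrix with orthonormal columns, each orthogonal to ones."""
    m = rng.standard_normal((n, k))
    m -= m.mean(axis=0)  # project out the ones vector
    q, r = np.linalg.qr(m)
    # QR of a centred matrix keeps columns in span(centred), hence centred
    q = q[:, :k] * np.sign(np.diag(r))[None, :k]
    # sign convention: first element of each column non-negative
    flip = np.sign(q[0, :])
    flip[flip == 0] = 1.0
    return q * flip


def random_truth(
    n_genotypes: int = 11,
    n_environments: int = 5,
    rank: int = 2,
    seed: int = 0,
    effect_scales: dict | None = None,
    n_rep: int = 3,
    noise_df: float | None = None,
) -> SimulationTruth:
    """Draw a :class:`SimulationTruth` satisfying all invariants exactly.

    Effects are drawn Gaussian then projected: ``alpha`` and ``tau`` are
    centred; score matrices are orthonormalised against the ones vector;
    singular values are |N(0, lambda_scale^2)| draws sorted non-increasing.
    """
    G, E, k = n_genotypes, n_environments, rank
    if k > min(G - 1, E - 1):
        raise DimensionError(f"rank k={k} exceeds min(G-1, E-1)={min(G - 1, E - 1)}")
    scales = dict(DEFAULT_SCALES)
    if effect_scales:
        scales.update(effect_scales)
    rng = np.random.default_rng(seed)
    alpha = rng.normal(0.0, scales["alpha_sd"], G)
    alpha -= alpha.mean()
    tau = rng.normal(0.0, scales["tau_sd"], E)
    tau -= tau.mean()
    lam = np.sort(np.abs(rng.normal(0.0, scales["lambda_scale"], k)))[::-1]
    a = _centered_orthonormal(G, k, rng)
    t = _centered_orthonormal(E, k, rng)
    return SimulationTruth(
        mu=scales["mu"], alpha=alpha, tau=tau, lam=lam, a=a, t=t,
        block_sd=scales["block_sd"], error_sd=scales["error_sd"],
        n_rep=n_rep, seed=seed, noise_df=noise_df,
    )


def simulate_trait(truth: SimulationTruth, trait: str = "trait_001") -> METDataset:
    """Simulate one trait's replicated observations from a truth object.

    Deterministic given ``truth.seed``. Block effects are drawn per
    (environment, replicate) and shared across genotypes (RCBD); residuals
    are i.i.d. Gaussian, or scaled Student-t when ``truth.noise_df`` is set
    (variance still ``error_sd**2``).
    """
    G, E, R = truth.n_genotypes, truth.n_environments, truth.n_rep
    rng = np.random.default_rng(truth.seed)
    cell = truth.cell_mean_matrix()  # G x E
    blocks = rng.normal(0.0, truth.block_sd, (E, R)) if truth.block_sd > 0 else np.zeros((E, R))
    if truth.error_sd > 0:
        if truth.noise_df is not None:
            df = truth.noise_df
            if df <= 2:
                raise ValidationError("noise_df must exceed 2 for finite variance")
            eps = rng.standard_t(df, (G, E, R)) * truth.error_sd / np.sqrt(df / (df - 2))
        else:
            eps = rng.normal(0.0, truth.error_sd, (G, E, R))
    else:
        eps = np.zeros((G, E, R))
    y = cell[:, :, None] + blocks[None, :, :] + eps

    gen = [f"G{i + 1:02d}" for i in range(G)]
    env = [f"E{j + 1}" for j in range(E)]
    rep = [f"R{r + 1}" for r in range(R)]
    gi, ej, rk = np.meshgrid(np.arange(G), np.arange(E), np.arange(R), indexing="ij")
    df = pd.DataFrame({
        "genotype": np.array(gen)[gi.ravel()],
        "environment": np.array(env)[ej.ravel()],
        "replicate": np.array(rep)[rk.ravel()],
        "trait": trait,
        "value": y.ravel(),
    }, columns=COLUMNS)
    return METDataset(df)


@dataclass
class MultiTraitSimulation:
    """A multi-trait simulated MET plus the per-trait ground truths."""

    dataset: METDataset
    truths: dict[str, SimulationTruth] = field(default_factory=dict)

    def truth_for(self, trait: str) -> SimulationTruth:
        return self.truths[trait]

    def write(self, csv_path, truth_path=None) -> None:
        """Write the long CSV and an optional JSON truth sidecar."""
        self.dataset.to_csv(csv_path)
        if truth_path is not None:
            with open(truth_path, "w") as fh:
                json.dump({k: v.to_dict() for k, v in self.truths.items()}, fh, indent=1)


def simulate_multitrait(
    n_traits: int,
    base: SimulationTruth | None = None,
    seed: int = 0,
    n_genotypes: int = 11,
    n_environments: int = 5,
    rank: int = 2,
    n_rep: int = 3,
    effect_scales: dict | None = None,
) -> MultiTraitSimulation:
    """Simulate ``n_traits`` independent traits on a shared trial design.

    When ``base`` is given, its shape, replicate count and noise SDs act as
    the template; fresh effects are drawn per trait. Trait labels are
    ``trait_001`` ... zero-padded to a fixed width.
    """
    if n_traits < 1:
        raise ValidationError("n_traits must be >= 1")
    if base is not None:
        n_genotypes, n_environments = base.n_genotypes, base.n_environments
        rank, n_rep = base.rank, base.n_rep
        effect_scales = dict(effect_scales or {})
        effect_scales.setdefault("mu", base.mu)
        effect_scales.setdefault("block_sd", base.block_sd)
        effect_scales.setdefault("error_sd", base.error_sd)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_traits)
    width = max(3, len(str(n_traits)))
    frames, truths = [], {}
    for i in range(n_traits):
        label = f"trait_{i + 1:0{width}d}"
        truth = random_truth(
            n_genotypes, n_environments, rank, seed=int(sub_seeds[i]),
            effect_scales=effect_scales, n_rep=n_rep,
        )
        truths[label] = truth
        frames.append(simulate_trait(truth, trait=label).observations)
    data = METDataset(pd.concat(frames, ignore_index=True))
    return MultiTraitSimulation(dataset=data, truths=truths)
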