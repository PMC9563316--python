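"""GGE: genotype main effect plus genotype-by-environment interaction.

The GGE model removes only the environment main effect from the cell-mean
table and decomposes the remainder by SVD:

    C_ij = y_ij - ybar_.j = sum_k lambda_k u_ik v_jk,

so axis k explains 100 * lambda_k^2 / sum(lambda^2) percent of the G + GE
sum of squares. Genotype scores are scaled by lambda^f and environment
scores by lambda^(1-f) (singular value partitioning; f = 0.5, the symmetric
default, is used for display).

The which-won-where view takes the rank-2 score plane, draws the convex hull
of the genotype points, and splits the plane into sectors by rays from the
origin perpendicular to the hull edges. Each sector is "won" by its hull
vertex: that genotype has the largest projection onto every direction in the
sector. Environments falling in the same sector form a mega-environment,
with the sector's vertex as its winning genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .dataset import GEMatrix
from .exceptions import DimensionError, ValidationError


class GGE:
    """GGE model for a genotype x environment cell-mean matrix.

    ``fit(svp_exponent=0.5)`` performs the environment-centred SVD ("centering
    2", no column scaling) and returns a :class:`GGEResults`.
    """

    def __init__(self, matrix: GEMatrix):
        if len(matrix.environments) < 2:
            raise DimensionError("GGE needs at least two environments")
        self.matrix = matrix

    def fit(self, svp_exponent: float = 0.5) -> "GGEResults":
        y = self.matrix.to_numpy()
        centered = y - y.mean(axis=0, keepdims=True)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        p = min(y.shape[0], y.shape[1])
        lam, u, v = s[:p], u[:, :p], vt[:p].T
        # sign convention: largest-|.| genotype loading positive per axis
        for k in range(p):
            i = np.argmax(np.abs(u[:, k]))
            if u[i, k] < 0:
                u[:, k] *= -1
                v[:, k] *= -1
        total = float((lam**2).sum())
        explained = 100.0 * lam**2 / total if total > 0 else np.zeros(p)
        f = svp_exponent
        return GGEResults(
            model=self, centered=centered, lam=lam,
            genotype_scores=u * lam**f, environment_scores=v * lam**(1 - f),
            explained=explained, svp_exponent=f,
            genotype_means=y.mean(axis=1),
        )


@dataclass
class WhichWonWhere:
    """Convex hull, sectors and mega-environments of a GGE rank-2 biplot."""

    hull: list[str]                      # hull genotypes, counter-clockwise
    sectors: pd.DataFrame                # vertex, angle_from, angle_to (radians)
    env_sector: dict[str, str]           # environment -> winning hull vertex
    mega_environments: pd.DataFrame      # winner, environments per occupied sector

    @property
    def n_mega(self) -> int:
        return len(self.mega_environments)


@dataclass
class GGEResults:
    """Fitted GGE decomposition for one trait."""

    model: GGE
    centered: np.ndarray
    lam: np.ndarray
    genotype_scores: np.ndarray
    environment_scores: np.ndarray
    explained: np.ndarray
    svp_exponent: float
    genotype_means: np.ndarray

    @property
    def genotypes(self) -> list[str]:
        return self.model.matrix.genotypes

    @property
    def environments(self) -> list[str]:
        return self.model.matrix.environments

    @property
    def trait(self) -> str:
        return self.model.matrix.trait

    def explained_first_two(self) -> float:
        """Percent of G + GE sum of squares on the first two axes."""
        return float(self.explained[:2].sum())

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(len(self.lam))]
        gdf = pd.DataFrame(self.genotype_scores, columns=cols)
        gdf.insert(0, "entity", self.genotypes)
        gdf.insert(1, "type", "genotype")
        edf = pd.DataFrame(self.environment_scores, columns=cols)
        edf.insert(0, "entity", self.environments)
        edf.insert(1, "type", "environment")
        return pd.concat([gdf, edf], ignore_index=True)

    # -- which-won-where ---------------------------------------------------

    def which_won_where(self) -> WhichWonWhere:
        """Convex-hull / sector / mega-environment analysis in the PC1-PC2 plane."""
        pts = self.genotype_scores[:, :2]
        if pts.shape[1] < 2:
            raise DimensionError("which-won-where needs two axes")
        try:
            hull = ConvexHull(pts)
        except QhullError as err:
            raise ValidationError(f"degenerate genotype configuration: {err}") from err
        verts = list(hull.vertices)  # counter-clockwise for 2-D qhull
        names = self.genotypes

        # Sector of vertex v: directions d with d.v >= d.w for every other hull
        # vertex w; its boundaries are the outward normals of the two edges
        # adjacent to v (rays from the origin perpendicular to the hull edges).
        normals = {}
        nv = len(verts)
        for a in range(nv):
            i, j = verts[a], verts[(a + 1) % nv]
            edge = pts[j] - pts[i]
            normals[(i, j)] = np.arctan2(-edge[0], edge[1])  # outward normal angle
        sector_rows = []
        for a in range(nv):
            prev_edge = (verts[(a - 1) % nv], verts[a])
            next_edge = (verts[a], verts[(a + 1) % nv])
            sector_rows.append({
                "vertex": names[verts[a]],
                "angle_from": normals[prev_edge],
                "angle_to": normals[next_edge],
            })
        sectors = pd.DataFrame(sector_rows)

        env_pts = self.environment_scores[:, :2]
        env_sector = {}
        for j, env in enumerate(self.environments):
            proj = pts[verts] @ env_pts[j]
            env_sector[env] = names[verts[int(np.argmax(proj))]]

        groups: dict[str, list[str]] = {}
        for env, winner in env_sector.items():
            groups.setdefault(winner, []).append(env)
        mega = pd.DataFrame(
            [{"winner": w, "environments": tuple(envs)} for w, envs in groups.items()]
        )
        return WhichWonWhere(
            hull=[names[v] for v in verts], sectors=sectors,
            env_sector=env_sector, mega_environments=mega,
        )

    # -- environment relations ---------------------------------------------

    def env_relations(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Environment vector lengths, favourability flags and pairwise cosines.

        The cosine of the angle between two environment vectors in the score
        plane approximates the correlation of genotype performance between
        those environments. An environment is flagged favourable when its
        vector projects positively onto the direction along which genotype
        mean performance increases (the performance gradient in score space).
        """
        ev = self.environment_scores[:, :2]
        lengths = np.linalg.norm(ev, axis=1)
        # direction of increasing genotype mean performance in the score plane
        dev = self.genotype_means - self.genotype_means.mean()
        gradient = self.genotype_scores[:, :2].T @ dev
        favourable = ev @ gradient > 0
        table = pd.DataFrame({
            "environment": self.environments,
            "vector_length": lengths,
            "favourable": favourable,
        }).set_index("environment")
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = ev / np.where(lengths[:, None] > 0, lengths[:, None], np.nan)
            cos = np.clip(unit @ unit.T, -1.0, 1.0)
        cosines = pd.DataFrame(cos, index=self.environments, columns=self.environments)
        return table, cosines

    def summary(self) -> str:
        lines = [
            f"GGE fit — trait {self.trait!r} "
            f"({len(self.genotypes)} genotypes x {len(self.environments)} environments, "
            f"svp f={self.svp_exponent})",
            "axis   lambda      explained%",
        ]
        for k in range(len(self.lam)):
            lines.append(f"PC{k + 1:<4d} {self.lam[k]:<11.4f} {self.explained[k]:.2f}")
        lines.append(f"PC1+PC2 explain {self.explained_first_two():.2f}% of G+GE SS")
        return "\n".join(lines)


def fit_gge(matrix: GEMatrix, svp_exponent: float = 0.5) -> GGEResults:
    """Functional wrapper: fit the GGE model to a cell-mean matrix."""
    return GGE(matrix).fit(svp_exponent)
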