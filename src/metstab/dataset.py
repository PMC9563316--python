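"""Data model for replicated multi-environment trials (METs).

A MET evaluates a set of genotypes in several environments (location-year
combinations) under a randomized complete block design (RCBD): within each
environment every genotype appears once in each of ``R`` blocks (replicates).
The canonical on-disk representation is a long (tidy) CSV with one row per
(genotype, environment, replicate, trait, value) observation; a single file
may hold an arbitrary number of traits, e.g. a full metabolite feature panel.

Two containers are provided:

:class:`METDataset`
    The replicate-level observations for one or more traits, with ordered
    label indexes and structural validation (no duplicate keys, labels
    consistent with the indexes).
:class:`GEMatrix`
    The genotype x environment table of cell means for a single trait — the
    input to the AMMI and GGE bilinear models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParseError, ValidationError

KEY_COLUMNS = ["genotype", "environment", "replicate", "trait"]
COLUMNS = KEY_COLUMNS + ["value"]


def _ordered_unique(values) -> list[str]:
    """Unique labels in order of first appearance."""
    return list(dict.fromkeys(values))


@dataclass
class METDataset:
    """Replicated long-format trial observations for one or more traits.

    Parameters
    ----------
    observations : pandas.DataFrame
        Columns ``genotype, environment, replicate, trait, value``. Label
        columns are stored as stripped strings; ``value`` as float.

    Index lists (``genotypes``, ``environments``, ``replicates``, ``traits``)
    preserve the order of first appearance in the input.
    """

    observations: pd.DataFrame
    genotypes: list[str] = field(default_factory=list)
    environments: list[str] = field(default_factory=list)
    replicates: list[str] = field(default_factory=list)
    traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.observations
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ConfigError(f"observations table lacks column(s): {missing}")
        df = df.loc[:, COLUMNS].copy()
        for c in KEY_COLUMNS:
            df[c] = df[c].astype(str).str.strip()
        df["value"] = pd.to_numeric(df["value"])
        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            first = df.loc[dup.idxmax(), KEY_COLUMNS].tolist()
            raise ValidationError(
                f"duplicate observation key (genotype, environment, replicate, "
                f"trait) = {tuple(first)}"
            )
        df = df.reset_index(drop=True)
        self.observations = df
        if not self.genotypes:
            self.genotypes = _ordered_unique(df["genotype"])
        if not self.environments:
            self.environments = _ordered_unique(df["environment"])
        if not self.replicates:
            self.replicates = _ordered_unique(df["replicate"])
        if not self.traits:
            self.traits = _ordered_unique(df["trait"])
        for col, idx in [
            ("genotype", self.genotypes),
            ("environment", self.environments),
            ("replicate", self.replicates),
            ("trait", self.traits),
        ]:
            extra = set(df[col]) - set(idx)
            if extra:
                raise ValidationError(f"{col} label(s) {sorted(extra)} missing from index list")

    # -- basic queries -----------------------------------------------------

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def is_balanced(self) -> bool:
        """True iff every (genotype, environment, replicate, trait) cell is present."""
        expected = self.n_genotypes * self.n_environments * self.n_replicates * self.n_traits
        return len(self.observations) == expected

    def subset_trait(self, trait: str) -> pd.DataFrame:
        if trait not in self.traits:
            raise ValidationError(f"trait {trait!r} not present (have {self.traits[:5]}...)")
        return self.observations[self.observations["trait"] == trait]

    def trait_array(self, trait: str) -> np.ndarray:
        """Balanced G x E x R value array for one trait.

        Requires the trait's design to be complete; raises otherwise.
        """
        sub = self.subset_trait(trait)
        G, E, R = self.n_genotypes, self.n_environments, self.n_replicates
        arr = np.full((G, E, R), np.nan)
        gi = {g: i for i, g in enumerate(self.genotypes)}
        ei = {e: j for j, e in enumerate(self.environments)}
        ri = {r: k for k, r in enumerate(self.replicates)}
        arr[
            sub["genotype"].map(gi).to_numpy(),
            sub["environment"].map(ei).to_numpy(),
            sub["replicate"].map(ri).to_numpy(),
        ] = sub["value"].to_numpy()
        if np.isnan(arr).any():
            g, e, r = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"trait {trait!r}: missing observation for (genotype={self.genotypes[g]}, "
                f"environment={self.environments[e]}, replicate={self.replicates[r]})"
            )
        return arr

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the canonical long-format CSV (RFC-4180, UTF-8)."""
        self.observations.to_csv(path, index=False)

    def cell_means(self, trait: str) -> "GEMatrix":
        """Genotype x environment cell means for one trait.

        ``n_rep`` records the minimum replicate count across cells. Any empty
        (genotype, environment) cell is an error — imputation is out of scope.
        """
        sub = self.subset_trait(trait)
        counts = sub.pivot_table(
            index="genotype", columns="environment", values="value", aggfunc="count"
        ).reindex(index=self.genotypes, columns=self.environments)
        if counts.isna().any().any():
            g = counts.stack(future_stack=True)
            key = g[g.isna()].index[0]
            raise ValidationError(f"empty cell for (genotype={key[0]}, environment={key[1]})")
        means = sub.pivot_table(
            index="genotype", columns="environment", values="value", aggfunc="mean"
        ).reindex(index=self.genotypes, columns=self.environments)
        return GEMatrix(values=means, trait=trait, n_rep=int(counts.min().min()))


@dataclass
class GEMatrix:
    """Genotype x environment table of cell means for a single trait."""

    values: pd.DataFrame  # index: genotypes, columns: environments
    trait: str
    n_rep: int = 1

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValidationError(
                f"GEMatrix needs >=2 genotypes and >=2 environments, got {v.shape}"
            )
        if v.isna().any().any():
            raise ValidationError("GEMatrix has missing cells")

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def environments(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def read_met_long(path, column_map: dict[str, str] | None = None) -> METDataset:
    """Read a long-format trial CSV into a validated :class:`METDataset`.

    Parameters
    ----------
    path : str or path-like
        Delimited text file with a header row.
    column_map : dict, optional
        Maps canonical names (``genotype``, ``environment``, ``replicate``,
        ``trait``, ``value``) to the column names used in the file. Omitted
        entries default to the canonical name itself.
    """
    raw = pd.read_csv(path, dtype=str)
    cmap = {c: c for c in COLUMNS}
    if column_map:
        unknown = set(column_map) - set(COLUMNS)
        if unknown:
            raise ConfigError(f"column_map keys not recognised: {sorted(unknown)}")
        cmap.update(column_map)
    missing = [src for src in cmap.values() if src not in raw.columns]
    if missing:
        raise ConfigError(f"input file lacks mapped column(s): {missing}")
    df = raw.rename(columns={src: dst for dst, src in cmap.items()})[COLUMNS]
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ParseError(
            f"non-numeric value {df.loc[row, 'value']!r} in data row {row + 1}"
        )
    if values.isna().any():
        row = int(values.isna().idxmax())
        raise ParseError(f"missing value in data row {row + 1}")
    df["value"] = values
    return METDataset(df)


def cell_means(data: METDataset, trait: str) -> GEMatrix:
    """Functional alias for :meth:`METDataset.cell_means`."""
    return data.cell_means(trait)
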