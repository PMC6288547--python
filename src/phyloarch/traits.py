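"""Species-level trait containers: means, within-species variances, sample sizes.

Comparative analyses here never see raw replicates directly; they consume a
:class:`SpeciesTraitObservation` per trait (mean, within-species variance of a
single measurement, number of individuals), so sampling error enters every
likelihood as ``variance / n`` on the diagonal.  The long CSV interchange
format has columns ``species, trait, mean, variance, n``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpeciesTraitObservation", "SpeciesTraitTable"]


@dataclass(frozen=True)
class SpeciesTraitObservation:
    """One trait observed across species, with intraspecific sampling error."""

    species: tuple
    mean: np.ndarray
    variance: np.ndarray        # within-species variance of one measurement
    n: np.ndarray               # individuals per species

    def __post_init__(self):
        m, v, n = map(np.asarray, (self.mean, self.variance, self.n))
        if not (len(self.species) == len(m) == len(v) == len(n)):
            raise ValueError("species, mean, variance, n must align")
        if np.any(v < 0):
            raise ValueError("within-species variance must be >= 0")
        if np.any(n < 1):
            raise ValueError("n must be >= 1")
        object.__setattr__(self, "mean", m.astype(float))
        object.__setattr__(self, "variance", v.astype(float))
        object.__setattr__(self, "n", n.astype(int))

    @property
    def sampling_variance(self) -> np.ndarray:
        """Variance of the species mean: within-species variance / n."""
        return self.variance / self.n

    def reorder(self, species) -> "SpeciesTraitObservation":
        idx = {s: i for i, s in enumerate(self.species)}
        missing = [s for s in species if s not in idx]
        if missing:
            raise KeyError(f"species not observed: {missing}")
        sel = [idx[s] for s in species]
        return SpeciesTraitObservation(tuple(species), self.mean[sel],
                                       self.variance[sel], self.n[sel])

    @classmethod
    def from_replicates(cls, values_by_species: dict) -> "SpeciesTraitObservation":
        """Summarise raw per-individual values into (mean, variance, n)."""
        sp = tuple(values_by_species)
        mean, var, n = [], [], []
        for s in sp:
            x = np.asarray(values_by_species[s], dtype=float)
            mean.append(x.mean())
            var.append(x.var(ddof=1) if len(x) > 1 else 0.0)
            n.append(len(x))
        return cls(sp, np.array(mean), np.array(var), np.array(n))

    @classmethod
    def constant_error(cls, species, mean, variance=0.0, n=1):
        species = tuple(species)
        k = len(species)
        return cls(species, np.asarray(mean, dtype=float),
                   np.full(k, float(variance)), np.full(k, int(n)))


@dataclass
class SpeciesTraitTable:
    """Species x trait matrix of means with aligned variances and sample sizes."""

    means: pd.DataFrame
    variances: pd.DataFrame = None
    n: pd.DataFrame = None

    def __post_init__(self):
        if self.variances is None:
            self.variances = self.means * 0.0
        if self.n is None:
            self.n = self.means.notna().astype(int)
        for other in (self.variances, self.n):
            if not other.index.equals(self.means.index) or \
               not other.columns.equals(self.means.columns):
                raise ValueError("means, variances and n must share index/columns")

    @property
    def species(self) -> list:
        return list(self.means.index)

    @property
    def traits(self) -> list:
        return list(self.means.columns)

    def observation(self, trait: str) -> SpeciesTraitObservation:
        """The named trait restricted to species with a non-missing mean."""
        m = self.means[trait]
        keep = m.notna()
        return SpeciesTraitObservation(
            tuple(m.index[keep]), m[keep].to_numpy(),
            self.variances.loc[keep, trait].fillna(0.0).to_numpy(),
            self.n.loc[keep, trait].fillna(1).to_numpy())

    def to_long(self) -> pd.DataFrame:
        rows = []
        for trait in self.traits:
            for sp in self.species:
                m = self.means.at[sp, trait]
                if pd.isna(m):
                    continue
                rows.append({"species": sp, "trait": trait, "mean": m,
                             "variance": self.variances.at[sp, trait],
                             "n": self.n.at[sp, trait]})
        return pd.DataFrame(rows)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "SpeciesTraitTable":
        means = df.pivot(index="species", columns="trait", values="mean")
        var = df.pivot(index="species", columns="trait", values="variance") \
            if "variance" in df else means * 0.0
        n = df.pivot(index="species", columns="trait", values="n") \
            if "n" in df else means.notna().astype(int)
        var = var.reindex_like(means)
        n = n.reindex_like(means)
        return cls(means, var, n)

    @classmethod
    def from_replicates(cls, df: pd.DataFrame, value: str = "value") -> "SpeciesTraitTable":
        """Build from tidy replicate rows (species, trait, value)."""
        g = df.groupby(["species", "trait"])[value]
        means = g.mean().unstack("trait")
        var = g.var(ddof=1).unstack("trait").fillna(0.0)
        n = g.count().unstack("trait").fillna(0).astype(int)
        return cls(means, var.reindex_like(means), n.reindex_like(means))
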