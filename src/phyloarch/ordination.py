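"""Trait-space ordination (correlation PCA) and PERMANOVA over architectural classes.

The species x trait matrix is z-scored column-wise (correlation PCA), so the
distances underlying PERMANOVA are Euclidean on standardized traits — the
minimal choice consistent with a correlation-matrix PCA of the same table.
Missing trait values drop the species listwise (logged); constant trait
columns are dropped (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["OrdinationResult", "PermanovaResult", "pca_traits", "permanova"]


@dataclass
class OrdinationResult:
    scores: pd.DataFrame          # species x components
    loadings: pd.DataFrame        # traits x components
    explained: np.ndarray         # variance fractions per component
    dropped_species: list = field(default_factory=list)
    dropped_traits: list = field(default_factory=list)


@dataclass
class PermanovaResult:
    pseudo_F: float
    r2: float
    p_value: float
    n_permutations: int
    seed: int
    n: int = 0
    groups: dict = field(default_factory=dict)


def _as_means_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return table.means     # SpeciesTraitTable


def _complete_standardized(table):
    X = _as_means_frame(table).copy()
    dropped_sp = list(X.index[X.isna().any(axis=1)])
    if dropped_sp:
        log.info("listwise-dropped species with missing traits: %s", dropped_sp)
        X = X.dropna()
    sd = X.std(ddof=1)
    dropped_tr = list(sd.index[(sd == 0) | sd.isna()])
    if dropped_tr:
        log.info("dropped constant traits: %s", dropped_tr)
        X = X.drop(columns=dropped_tr)
    Z = (X - X.mean()) / X.std(ddof=1)
    return Z, dropped_sp, dropped_tr


def pca_traits(table) -> OrdinationResult:
    """Correlation-matrix PCA of the species trait means.

    Accepts a :class:`SpeciesTraitTable` or a plain species x trait frame.
    Sign convention: within each component the largest-magnitude loading is
    positive, making outputs deterministic.
    """
    Z, dropped_sp, dropped_tr = _complete_standardized(table)
    if Z.shape[0] < 3 or Z.shape[1] < 2:
        raise ValueError("need >= 3 species and >= 2 non-constant traits")
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = s ** 2 / (Z.shape[0] - 1)
    explained = var / (Z.var(ddof=1).sum())
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return OrdinationResult(
        scores=pd.DataFrame(U * s, index=Z.index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=Z.columns, columns=comp),
        explained=explained,
        dropped_species=dropped_sp, dropped_traits=dropped_tr)


def permanova(table, groups: dict, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances over z-scored traits.

    ``groups`` maps species to a class label; every group needs >= 2 members
    after missing-data drops.  The pseudo-F partitions the squared-distance
    sum into among- and within-group parts; the p-value is the inclusive
    proportion of free label permutations with F >= observed.
    """
    Z, dropped_sp, _ = _complete_standardized(table)
    lab = np.array([groups[s] for s in Z.index])
    uniq, counts = np.unique(lab, return_counts=True)
    small = [str(u) for u, c in zip(uniq, counts) if c < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")

    X = Z.to_numpy()
    n, g = len(X), len(uniq)
    D2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    sst = D2[np.triu_indices(n, 1)].sum() / n

    idx_by_group = {u: np.where(lab == u)[0] for u in uniq}

    def ssw_of(perm):
        tot = 0.0
        for u in uniq:
            ix = perm[idx_by_group[u]]
            sub = D2[np.ix_(ix, ix)]
            tot += sub[np.triu_indices(len(ix), 1)].sum() / len(ix)
        return tot

    identity = np.arange(n)
    ssw = ssw_of(identity)
    ssa = sst - ssw
    F = (ssa / (g - 1)) / (ssw / (n - g))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ssw_p = ssw_of(perm)
        F_p = ((sst - ssw_p) / (g - 1)) / (ssw_p / (n - g))
        if F_p >= F:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermanovaResult(pseudo_F=float(F), r2=float(ssa / sst), p_value=float(p),
                           n_permutations=n_perm, seed=seed, n=n,
                           groups={str(u): int(c) for u, c in zip(uniq, counts)})
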