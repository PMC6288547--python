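"""Functional branching indexes, architectural classes, and derived traits.

A plant's architecture is summarised by two unit-free ratios:

* photosynthetic branching index — leaf area borne by branches over total
  leaf area (branches + trunk);
* exploration branching index — cumulated branch length over total stem
  length (branches + trunk).

Both are 0 for a monocaulous (single-stemmed) plant and approach 1 as
assimilation and exploration are progressively delegated to branches.  A
single integrative index is the first principal component of the two
(correlation-scaled), oriented so that higher scores mean more branched.
Species are segregated into three ordered architectural classes
(Monocaulous < Intermediate < Branched) by locating breaks in the ranked
distribution of individual integrative scores with pairwise two-sample
rank-sum tests and a compact letter display.

When only representative branches were measured, per-branch means are
extrapolated to the censused branch count (the convention the whole-plant
trait formulas also use).
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "Branch",
    "IndividualArchitecture",
    "ArchClass",
    "RawTraitMeasurements",
    "photosynthetic_index",
    "exploration_index",
    "branching_index_table",
    "IntegrativeIndexResult",
    "integrative_index",
    "SegregationResult",
    "segregate_classes",
    "derive_traits",
    "TRAIT_NAMES",
]


@dataclass(frozen=True)
class Branch:
    """One measured branch: cumulated axis length (cm) and its leaf areas (cm^2)."""

    cumulated_length: float
    leaf_areas: tuple

    def __post_init__(self):
        if self.cumulated_length < 0 or any(a < 0 for a in self.leaf_areas):
            raise ValueError("branch lengths and leaf areas must be >= 0")

    @property
    def leaf_area(self) -> float:
        return float(sum(self.leaf_areas))

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_areas)


@dataclass(frozen=True)
class IndividualArchitecture:
    """One plant's trunk and branch measurements.

    ``n_branches`` is the censused branch total; ``branches`` may hold only
    representative branches, in which case per-branch means are extrapolated
    to ``n_branches``.
    """

    species: str
    trunk_length: float                 # cm
    trunk_leaf_areas: tuple             # cm^2 per trunk leaf
    branches: tuple                     # of Branch
    n_branches: int = None              # census; defaults to len(branches)

    def __post_init__(self):
        if self.n_branches is None:
            object.__setattr__(self, "n_branches", len(self.branches))
        if self.trunk_length < 0 or any(a < 0 for a in self.trunk_leaf_areas):
            raise ValueError("lengths and areas must be >= 0")
        if (self.n_branches == 0) != (len(self.branches) == 0):
            raise ValueError("n_branches == 0 iff the branches list is empty")
        if self.n_branches < 0:
            raise ValueError("n_branches must be >= 0")

    @property
    def trunk_leaf_area(self) -> float:
        return float(sum(self.trunk_leaf_areas))

    @property
    def branch_leaf_area(self) -> float:
        """Total branch leaf area, extrapolating representative branches."""
        if not self.branches:
            return 0.0
        mean = np.mean([b.leaf_area for b in self.branches])
        return float(mean * self.n_branches)

    @property
    def branch_cumulated_length(self) -> float:
        if not self.branches:
            return 0.0
        mean = np.mean([b.cumulated_length for b in self.branches])
        return float(mean * self.n_branches)


def photosynthetic_index(ind: IndividualArchitecture) -> float:
    """Branch leaf area / total leaf area (branches + trunk), in [0, 1]."""
    bla = ind.branch_leaf_area
    total = bla + ind.trunk_leaf_area
    if total <= 0:
        raise ValueError(
            f"{ind.species}: total leaf area is zero; photosynthetic index undefined")
    return bla / total


def exploration_index(ind: IndividualArchitecture) -> float:
    """Branch cumulated length / total stem length (branches + trunk), in [0, 1]."""
    bl = ind.branch_cumulated_length
    total = bl + ind.trunk_length
    if total <= 0:
        raise ValueError(
            f"{ind.species}: total stem length is zero; exploration index undefined")
    if ind.trunk_length == 0:
        warnings.warn(f"{ind.species}: zero trunk length; exploration index = 1",
                      stacklevel=2)
    return bl / total


def branching_index_table(individuals) -> pd.DataFrame:
    """Per-individual photosynthetic and exploration indexes (one row each)."""
    rows = [{"species": ind.species,
             "photo": photosynthetic_index(ind),
             "explo": exploration_index(ind)} for ind in individuals]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Integrative index (PC1 of the two raw indexes)
# ---------------------------------------------------------------------------

@dataclass
class IntegrativeIndexResult:
    """PC1 of the z-scored (photo, explo) table, oriented with positive loadings."""

    scores: pd.Series                 # species -> PC1 score
    loadings: np.ndarray              # (2,) loadings on (photo, explo)
    explained: float                  # fraction of variance on PC1
    rho_spearman: float               # Spearman correlation of the raw indexes
    center: np.ndarray = field(default=None)
    scale: np.ndarray = field(default=None)

    def project(self, table: pd.DataFrame) -> pd.Series:
        """Score new (photo, explo) rows on the fitted axis (same centring/scaling)."""
        Z = (table[["photo", "explo"]].to_numpy() - self.center) / self.scale
        return pd.Series(Z @ self.loadings, index=table.index)


def integrative_index(species_means: pd.DataFrame) -> IntegrativeIndexResult:
    """PC1 scores of the correlation-scaled two-index species table.

    The sign is fixed so both loadings are positive (higher score = more
    branched); ties are broken toward a positive photosynthetic loading.
    The Spearman correlation of the two raw indexes is reported alongside.
    """
    X = species_means[["photo", "explo"]].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("at least 3 species required")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale <= 0):
        which = ["photo", "explo"][int(np.argmin(scale))]
        raise ValueError(f"degenerate PCA: column {which!r} is constant")
    Z = (X - center) / scale
    R = np.corrcoef(Z, rowvar=False)
    w, V = np.linalg.eigh(R)
    pc1 = V[:, np.argmax(w)]
    # orient so both loadings are positive; when the raw indexes are
    # negatively correlated that is impossible, so the tie-break makes the
    # photosynthetic loading positive
    if np.sign(pc1[0]) == np.sign(pc1[1]):
        if pc1[0] < 0:
            pc1 = -pc1
    else:
        if pc1[0] < 0:
            pc1 = -pc1
        warnings.warn("raw indexes are negatively correlated; PC1 oriented by "
                      "the photosynthetic loading", stacklevel=2)
    rho = stats.spearmanr(X[:, 0], X[:, 1]).statistic
    return IntegrativeIndexResult(
        scores=pd.Series(Z @ pc1, index=species_means.index),
        loadings=pc1,
        explained=float(np.max(w) / np.sum(w)),
        rho_spearman=float(rho),
        center=center,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# Architectural classes
# ---------------------------------------------------------------------------

class ArchClass(enum.IntEnum):
    """Three-level ordinal architecture category, increasing in branching."""

    Monocaulous = 1
    Intermediate = 2
    Branched = 3


CLASS_NAMES = {1: "Monocaulous", 2: "Intermediate", 3: "Branched"}


@dataclass
class SegregationResult:
    classes: dict                    # species -> int (1..k, increasing score)
    letters: dict                    # species -> compact letter display string
    order: list                      # species sorted by mean score (ascending)
    breaks: list                     # chosen break positions (after rank i)
    pvalues: pd.DataFrame            # pairwise rank-sum p-values
    warning: str = None


def _compact_letter_display(order, disjoint) -> dict:
    """Insert-and-absorb compact letter display.

    ``disjoint[(a, b)]`` is True when species a and b differ significantly;
    species sharing a letter are not significantly different.
    """
    columns = [set(order)]
    for a, b in [(x, y) for i, x in enumerate(order) for y in order[i + 1:]]:
        if not disjoint.get((a, b), disjoint.get((b, a), False)):
            continue
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend([col - {a}, col - {b}])
            else:
                new_cols.append(col)
        # absorb: drop columns contained in another
        columns = [c for c in new_cols
                   if not any(c < d for d in new_cols) and c]
        # drop duplicates while keeping order
        seen, uniq = [], []
        for c in columns:
            if c not in seen:
                seen.append(c)
                uniq.append(c)
        columns = uniq
    rank = {s: i for i, s in enumerate(order)}
    columns.sort(key=lambda c: min(rank[s] for s in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {s: "" for s in order}
    for i, col in enumerate(columns):
        ch = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for s in col:
            letters[s] += ch
    return {s: "".join(sorted(letters[s])) for s in order}


def segregate_classes(scores_by_species: dict, alpha: float = 0.1,
                      k: int = 3) -> SegregationResult:
    """Partition species into ``k`` ordered classes from individual scores.

    Species are ranked by mean score; all pairs are compared with two-sample
    Mann–Whitney rank-sum tests (exact null for small groups, normal
    approximation with tie correction otherwise — scipy's default policy);
    a compact letter display is built at level ``alpha``.  A *break* is an
    adjacent pair (in rank order) sharing no letter; classes are the ``k``
    contiguous runs delimited by the ``k - 1`` strongest significant breaks
    (smallest pairwise p, ties resolved toward the larger mean-score gap).

    Rank-sum tests make the whole procedure invariant under any
    order-preserving transform of the scores.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    species = list(scores_by_species)
    if len(species) < k:
        raise ValueError("need at least k species")
    means = {s: float(np.mean(scores_by_species[s])) for s in species}
    order = sorted(species, key=lambda s: (means[s], s))

    pmat = pd.DataFrame(np.ones((len(order), len(order))),
                        index=order, columns=order)
    disjoint = {}
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            xa, xb = np.asarray(scores_by_species[a]), np.asarray(scores_by_species[b])
            if np.array_equal(xa, xb) or (np.ptp(xa) == 0 and np.ptp(xb) == 0
                                          and xa[0] == xb[0]):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                             method="auto").pvalue)
            pmat.loc[a, b] = pmat.loc[b, a] = p
            disjoint[(a, b)] = p < alpha

    letters = _compact_letter_display(order, disjoint)

    # candidate breaks: adjacent pairs sharing no letter
    candidates = []
    for i in range(len(order) - 1):
        a, b = order[i], order[i + 1]
        if not set(letters[a]) & set(letters[b]):
            gap = means[b] - means[a]
            candidates.append((pmat.loc[a, b], -gap, i))
    candidates.sort()

    warning = None
    breaks = sorted(c[2] for c in candidates[:k - 1])
    if len(candidates) < k - 1:
        # fall back on the largest remaining mean gaps
        warning = (f"only {len(candidates)} significant breaks found for k={k}; "
                   "remaining boundaries placed at the largest mean-score gaps")
        warnings.warn(warning, stacklevel=2)
        taken = set(breaks)
        gaps = sorted(((means[order[i + 1]] - means[order[i]], i)
                       for i in range(len(order) - 1) if i not in taken),
                      reverse=True)
        for g, i in gaps:
            if len(breaks) >= k - 1:
                break
            breaks.append(i)
        breaks = sorted(breaks)

    classes, cls = {}, 1
    for i, s in enumerate(order):
        classes[s] = cls
        if i in breaks:
            cls += 1
    return SegregationResult(classes=classes, letters=letters, order=order,
                             breaks=breaks, pvalues=pmat, warning=warning)


# ---------------------------------------------------------------------------
# Derived functional traits
# ---------------------------------------------------------------------------

TRAIT_NAMES = ["sr", "swd", "ssd", "internode_d", "internode_l", "pct_pith",
               "pct_wood", "pct_cortex", "hv", "mean_la", "sla", "total_la",
               "nb_leaf", "fruit_vol"]


@dataclass(frozen=True)
class RawTraitMeasurements:
    """Per-individual primitives behind the 14 derived functional traits.

    Lengths cm, areas cm^2, masses g, volumes cm^3.  The cross-section
    components (pith + wood + cortex) must not exceed the whole-section area
    by more than 1%.
    """

    plant_height: float = np.nan
    basal_diameter: float = np.nan
    wood_dry_mass: float = np.nan
    wood_fresh_volume: float = np.nan
    stem_dry_mass: float = np.nan
    stem_fresh_volume: float = np.nan
    min_internode_diameter: float = np.nan
    max_internode_diameter: float = np.nan
    internode_length: float = np.nan
    pith_area: float = np.nan
    wood_area: float = np.nan
    cortex_area: float = np.nan
    whole_section_area: float = np.nan
    wood_area_pom: float = np.nan          # wood area at the point of measurement
    leaf_area_above_pom: float = np.nan
    leaf_fresh_area: float = np.nan
    leaf_dry_mass: float = np.nan
    mean_trunk_leaf_area: float = np.nan
    n_trunk_leaves: float = np.nan
    branch_mean_leaf_area: float = np.nan
    branch_mean_leaf_number: float = np.nan
    n_branches: float = np.nan
    fruit_length: float = np.nan
    fruit_width: float = np.nan

    def __post_init__(self):
        for name in ("pith_area", "wood_area", "cortex_area", "whole_section_area",
                     "wood_dry_mass", "wood_fresh_volume", "stem_dry_mass",
                     "stem_fresh_volume", "leaf_fresh_area", "leaf_dry_mass"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0")
        parts = self.pith_area + self.wood_area + self.cortex_area
        if np.isfinite(parts) and np.isfinite(self.whole_section_area):
            if parts > self.whole_section_area * 1.01:
                raise ValueError("pith + wood + cortex exceed whole-section area")


def _ratio(num, den, trait, species=""):
    if not np.isfinite(den) or den == 0 or not np.isfinite(num):
        log.info("trait %s missing%s (zero or missing denominator)",
                 trait, f" for {species}" if species else "")
        return np.nan
    return num / den


def derive_traits(raw: RawTraitMeasurements, species: str = "") -> dict:
    """Derive the 14 functional traits from one individual's raw measurements.

    A zero or missing denominator yields a missing value for that trait only
    (logged), never a global failure.  Internode diameter is the geometric
    mean of the min and max internode diameters.
    """
    t = {}
    t["sr"] = _ratio(raw.plant_height, raw.basal_diameter, "sr", species)
    t["swd"] = _ratio(raw.wood_dry_mass, raw.wood_fresh_volume, "swd", species)
    t["ssd"] = _ratio(raw.stem_dry_mass, raw.stem_fresh_volume, "ssd", species)
    prod = raw.min_internode_diameter * raw.max_internode_diameter
    t["internode_d"] = math.sqrt(prod) if np.isfinite(prod) and prod >= 0 else np.nan
    t["internode_l"] = raw.internode_length
    t["pct_pith"] = _ratio(raw.pith_area, raw.whole_section_area, "pct_pith", species)
    t["pct_wood"] = _ratio(raw.wood_area, raw.whole_section_area, "pct_wood", species)
    t["pct_cortex"] = _ratio(raw.cortex_area, raw.whole_section_area,
                             "pct_cortex", species)
    t["hv"] = _ratio(raw.wood_area_pom, raw.leaf_area_above_pom, "hv", species)
    t["mean_la"] = raw.mean_trunk_leaf_area
    t["sla"] = _ratio(raw.leaf_fresh_area, raw.leaf_dry_mass, "sla", species)
    # an unbranched plant contributes no branch term even if per-branch
    # measurements are missing
    br_la = 0.0 if raw.n_branches == 0 else raw.branch_mean_leaf_area * raw.n_branches
    br_lf = 0.0 if raw.n_branches == 0 else raw.branch_mean_leaf_number * raw.n_branches
    t["total_la"] = br_la + raw.mean_trunk_leaf_area * raw.n_trunk_leaves
    t["nb_leaf"] = raw.n_trunk_leaves + br_lf
    t["fruit_vol"] = raw.fruit_length * raw.fruit_width ** 2
    return t
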