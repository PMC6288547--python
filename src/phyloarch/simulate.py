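"""Seeded generators for every statistical structure the pipeline consumes.

The defaults emulate the study system: a 27-species rainforest crown clade of
age ~2.4 Myr, a three-state architecture (7 monocaulous / 6 intermediate /
14 branched species), per-class branching-index means of 0.03/0.16 (M),
0.36/0.45 (I) and 0.82/0.76 (B) for the photosynthetic/exploration indexes,
five individuals per species, continuous traits under Brownian motion with
tunable phylogenetic signal and within-species replicate noise, and
state-dependent diversification with equal rates (lambda = 1.2/Myr, mu = 0,
q = 0.1/Myr).

Every generator is a pure function of (config, seed): identical seeds give
bit-identical outputs.  Trees are simulated forward in time under a constant
rate (or state-dependent) birth-death process, conditioned on the survivor
count by rejection, with both crown lineages required to survive so the crown
age is the simulation span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .architecture import Branch, IndividualArchitecture
from .sse import MuSSEModel
from .traits import SpeciesTraitObservation
from .tree import PhyloCovariance, PhyloTree, lambda_transform, vcv

__all__ = ["SimulationConfig", "simulate_bd_tree", "simulate_musse",
           "forward_tip_count", "simulate_mk_states", "simulate_bm_traits",
           "simulate_correlated_trait", "generate_architecture_individuals",
           "default_classes"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for every generator (see module docstring)."""

    seed: int = 0
    n_species: int = 27
    crown_age: float = 2.4              # Myr; None keeps simulated depth
    birth: float = 1.2                  # events / Myr
    death: float = 0.0
    q: float = 0.1                      # transition rate, all ordered pairs
    root_state: int = 3                 # Branched ancestor
    k_states: int = 3
    class_sizes: tuple = (7, 6, 14)     # Monocaulous / Intermediate / Branched
    class_photo: tuple = (0.03, 0.36, 0.82)
    class_explo: tuple = (0.16, 0.45, 0.76)
    concentration: float = 60.0         # species-level beta concentration
    ind_concentration: float = 40.0     # individual-level beta concentration
    copula_rho: float = 0.3             # latent correlation photo~explo
    individuals: int = 5                # per species
    measures: int = 5                   # per individual (leaves, internodes...)
    sigma2: float = 1.0                 # BM rate for continuous traits
    lambda_signal: float = 1.0
    slope: float = 2.0                  # trait-vs-index slope for correlated traits
    within_sd: float = 0.1              # replicate noise sd
    max_retries: int = 1000

    def __post_init__(self):
        if self.birth < 0 or self.death < 0 or self.q < 0:
            raise ValueError("rates must be >= 0")
        for m in self.class_photo + self.class_explo:
            if not 0 <= m <= 1:
                raise ValueError("class index means must be in [0, 1]")

    def mussemodel(self) -> MuSSEModel:
        k = self.k_states
        q = np.full((k, k), self.q)
        np.fill_diagonal(q, 0.0)
        return MuSSEModel(np.full(k, self.birth), np.full(k, self.death), q)


# ---------------------------------------------------------------------------
# Forward birth-death / state-dependent simulation
# ---------------------------------------------------------------------------

def _forward(model: MuSSEModel, root_state: int, rng, n_target=None,
             max_time=None):
    """Forward Gillespie simulation from two crown lineages.

    Stops at a uniform time between the event that first reaches ``n_target``
    extant lineages and the next event (avoiding zero-length tip branches), or
    at ``max_time``.  Returns (records, states, t_stop, n_extant) where each
    record is [parent, t_start, t_end, extinct]; extant records have
    t_end = t_stop.
    """
    lam, mu, q = model.lam, model.mu, model.q
    qs = q.sum(axis=1)
    total = lam + mu + qs
    s0 = root_state - 1
    recs = [[-1, 0.0, None, False], [-1, 0.0, None, False]]
    state = [s0, s0]
    extant = [0, 1]
    t = 0.0
    while True:
        if not extant:
            return recs, state, t, 0
        rates = np.array([total[state[i]] for i in extant])
        R = rates.sum()
        dt = rng.exponential(1.0 / R) if R > 0 else np.inf
        if n_target is not None and len(extant) >= n_target:
            t_stop = t + rng.uniform() * dt
            break
        if max_time is not None and (t + dt >= max_time or not np.isfinite(dt)):
            t_stop = max_time
            break
        if not np.isfinite(dt):
            return recs, state, t, len(extant)   # frozen: no events possible
        t += dt
        i = extant[rng.choice(len(extant), p=rates / R)]
        s = state[i]
        u = rng.uniform() * total[s]
        if u < lam[s]:                               # speciation
            recs[i][2] = t
            for _ in range(2):
                recs.append([i, t, None, False])
                state.append(s)
            extant.remove(i)
            extant.extend([len(recs) - 2, len(recs) - 1])
        elif u < lam[s] + mu[s]:                     # extinction
            recs[i][2] = t
            recs[i][3] = True
            extant.remove(i)
        else:                                        # state transition
            u -= lam[s] + mu[s]
            for j in range(model.k):
                if j == s:
                    continue
                if u < q[s, j]:
                    state[i] = j
                    break
                u -= q[s, j]
    for i in extant:
        recs[i][2] = t_stop
    return recs, state, t_stop, len(extant)


def _assemble(recs, state, t_stop):
    """Build a PhyloTree from surviving forward-simulation records."""
    children_of = {}
    for i, r in enumerate(recs):
        children_of.setdefault(r[0], []).append(i)

    def survives(i):
        r = recs[i]
        if r[3]:
            return False
        kids = children_of.get(i, [])
        if not kids:
            return r[2] == t_stop
        return any(survives(c) for c in kids)

    crown = [i for i in children_of.get(-1, []) if survives(i)]
    if len(crown) != 2:
        return None, None

    tip_counter = [0]
    tip_states = {}

    def build(i, acc):
        r = recs[i]
        length = acc + (r[2] - r[1])
        kids = [c for c in children_of.get(i, []) if survives(c)]
        if not kids:
            tip_counter[0] += 1
            lab = f"sp{tip_counter[0]:02d}"
            tip_states[lab] = state[i] + 1
            return ("tip", lab, length)
        if len(kids) == 1:
            kind, payload, l = build(kids[0], 0.0)
            return (kind, payload, l + length)
        return ("node", (None, [build(c, 0.0) for c in kids]), length)

    spec = ("node", (None, [build(c, 0.0) for c in crown]), 0.0)
    parent_l, length_l, children_l, labels_l = [], [], [], []

    def emit(node, parent_idx):
        kind, payload, l = node
        idx = len(parent_l)
        parent_l.append(parent_idx)
        length_l.append(l if parent_idx >= 0 else 0.0)
        children_l.append([])
        if parent_idx >= 0:
            children_l[parent_idx].append(idx)
        if kind == "tip":
            labels_l.append(payload)
        else:
            labels_l.append(payload[0])
            for s in payload[1]:
                emit(s, idx)

    emit(spec, -1)
    tree = PhyloTree(np.array(parent_l, dtype=np.int64), np.array(length_l),
                     tuple(tuple(c) for c in children_l), tuple(labels_l))
    return tree, tip_states


def simulate_musse(model: MuSSEModel, n_species: int, root_state: int = 1,
                   seed=0, crown_age=None, max_retries: int = 1000):
    """Joint forward simulation of tree and states, conditioned on the
    survivor count (rejection; both crown lineages must survive).

    Returns (tree, tip_states) with states coded 1..k.  ``crown_age`` rescales
    the tree depth exactly (rates then refer to the original time scale).
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        recs, state, t_stop, n_ext = _forward(model, root_state, rng,
                                              n_target=n_species)
        if n_ext != n_species or t_stop <= 0:
            continue
        tree, tip_states = _assemble(recs, state, t_stop)
        if tree is None or tree.n_tips != n_species:
            continue
        if crown_age is not None:
            tree = tree.rescale(crown_age)
        return tree, tip_states
    raise RuntimeError(f"no surviving clade of {n_species} tips in "
                       f"{max_retries} attempts")


def simulate_bd_tree(cfg: SimulationConfig = None, seed=None, **kw) -> PhyloTree:
    """Constant-rate birth-death tree conditioned on ``n_species`` survivors."""
    cfg = replace(cfg or SimulationConfig(), **kw)
    tree, _ = simulate_musse(
        MuSSEModel([cfg.birth], [cfg.death], np.zeros((1, 1))),
        cfg.n_species, root_state=1,
        seed=cfg.seed if seed is None else seed,
        crown_age=cfg.crown_age, max_retries=cfg.max_retries)
    return tree


def forward_tip_count(birth: float, death: float, t: float, seed=0) -> int:
    """Extant lineages of one unconditioned crown simulation run to time t."""
    rng = np.random.default_rng(seed)
    model = MuSSEModel([birth], [death], np.zeros((1, 1)))
    _, _, _, n = _forward(model, 1, rng, max_time=t)
    return n


# ---------------------------------------------------------------------------
# Discrete character simulation on a fixed tree
# ---------------------------------------------------------------------------

def simulate_mk_states(tree: PhyloTree, Q: np.ndarray, root_state: int = 1,
                       seed=0):
    """CTMC simulation along branches by exponential waiting times.

    Returns (tip_states, node_states): tip labels -> 1..k, plus the true
    state (1..k) at every node, indexed like the tree's nodes.
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    if np.any(Q - np.diag(np.diag(Q)) < 0):
        raise ValueError("off-diagonal rates must be >= 0")
    rng = np.random.default_rng(seed)
    node_states = np.zeros(tree.n_nodes, dtype=int)
    node_states[tree.root] = root_state - 1
    for v in tree.postorder[::-1]:       # preorder
        p = tree.parent[v]
        if p < 0:
            continue
        s = node_states[p]
        rem = tree.lengths[v]
        while True:
            out = -Q[s, s]
            if out <= 0:
                break
            w = rng.exponential(1.0 / out)
            if w > rem:
                break
            rem -= w
            probs = Q[s].copy()
            probs[s] = 0.0
            s = rng.choice(k, p=probs / probs.sum())
        node_states[v] = s
    tip_states = {tree.labels[i]: int(node_states[i]) + 1
                  for i in tree.tip_indices}
    return tip_states, node_states + 1


# ---------------------------------------------------------------------------
# Continuous traits
# ---------------------------------------------------------------------------

def simulate_bm_traits(tree: PhyloTree, sigma2: float = 1.0,
                       lambda_signal: float = 1.0, within_sd: float = 0.1,
                       n_individuals: int = 5, seed=0, root_value: float = 0.0):
    """Brownian species values on the lambda-transformed tree plus iid
    within-species replicate noise.

    Returns (obs, replicates, true_values): the species-level summary used by
    the signal/PGLS machinery, the raw replicate frame (species, individual,
    value), and the noiseless species values (sorted-label order).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = np.random.default_rng(seed)
    species = sorted(tree.tip_labels)
    C = lambda_transform(vcv(tree, order=species), lambda_signal).matrix
    L = np.linalg.cholesky(C * sigma2 + 1e-12 * np.eye(len(species)))
    true = root_value + L @ rng.standard_normal(len(species))
    rows = []
    for s, v in zip(species, true):
        for j in range(n_individuals):
            rows.append({"species": s, "individual": j + 1,
                         "value": v + rng.normal(0.0, within_sd)})
    reps = pd.DataFrame(rows)
    if within_sd == 0:
        obs = SpeciesTraitObservation(tuple(species), true,
                                      np.zeros(len(species)),
                                      np.full(len(species), n_individuals))
    else:
        obs = SpeciesTraitObservation.from_replicates(
            {s: reps.loc[reps.species == s, "value"].to_numpy()
             for s in species})
    return obs, reps, true


def simulate_correlated_trait(tree: PhyloTree, x: SpeciesTraitObservation,
                              slope: float, sigma2: float = 1.0,
                              within_sd: float = 0.1, n_individuals: int = 5,
                              seed=0):
    """A trait y = slope * x + Brownian noise, with replicate-level error."""
    obs, reps, noise = simulate_bm_traits(tree, sigma2, 1.0, 0.0, 1, seed)
    species = list(obs.species)
    xv = x.reorder(species).mean
    rng = np.random.default_rng(None if seed is None else seed + 1)
    true = slope * xv + noise
    rows = []
    for s, v in zip(species, true):
        for j in range(n_individuals):
            rows.append({"species": s, "individual": j + 1,
                         "value": v + rng.normal(0.0, within_sd)})
    reps = pd.DataFrame(rows)
    y = SpeciesTraitObservation.from_replicates(
        {s: reps.loc[reps.species == s, "value"].to_numpy() for s in species}) \
        if within_sd > 0 else SpeciesTraitObservation(
            tuple(species), true, np.zeros(len(species)),
            np.full(len(species), n_individuals))
    return y, reps, true


# ---------------------------------------------------------------------------
# Individual architecture measurements
# ---------------------------------------------------------------------------

def _beta_draw(rng_uniform, mean, conc):
    a = max(mean * conc, 1e-6)
    b = max((1.0 - mean) * conc, 1e-6)
    return float(stats.beta.ppf(rng_uniform, a, b))


def generate_architecture_individuals(classes: dict,
                                      cfg: SimulationConfig = None,
                                      seed=None):
    """Per-individual trunk/branch measurements calibrated to class means.

    Species-level (photosynthetic, exploration) index targets are drawn from
    beta distributions around the class means (concentration
    ``cfg.concentration``), coupled through a Gaussian copula
    (``cfg.copula_rho``) so the two indexes correlate across species as in
    the emulated data; individual indexes are beta-distributed around the
    species target (``cfg.ind_concentration``).  Measurements (trunk length,
    leaf areas, two representative branches plus a branch census) are
    constructed so the computed indexes reproduce the drawn targets exactly.
    Individuals whose drawn indexes fall below 1e-3 are emitted unbranched.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out = []
    for sp in classes:
        c = int(classes[sp]) - 1
        if not 0 <= c < len(cfg.class_photo):
            raise ValueError(f"unknown class {classes[sp]} for {sp}")
        z = rng.multivariate_normal([0, 0], [[1, cfg.copula_rho],
                                             [cfg.copula_rho, 1]])
        u = stats.norm.cdf(z)
        p_sp = _beta_draw(u[0], cfg.class_photo[c], cfg.concentration)
        e_sp = _beta_draw(u[1], cfg.class_explo[c], cfg.concentration)
        for j in range(cfg.individuals):
            p = _beta_draw(rng.uniform(), p_sp, cfg.ind_concentration)
            e = _beta_draw(rng.uniform(), e_sp, cfg.ind_concentration)
            out.append(_build_individual(sp, p, e, cfg, rng))
    return out


def _split(total, n, rng, jitter=0.3):
    w = rng.gamma(1.0 / max(jitter, 1e-3) ** 2, size=n)
    return tuple(total * w / w.sum())


def _build_individual(sp, p, e, cfg, rng):
    trunk_length = float(rng.lognormal(np.log(150.0), 0.2))
    total_la = float(rng.lognormal(np.log(3000.0), 0.3))
    n_trunk_leaves = int(12 + rng.poisson(6))
    trunk_la = (1.0 - p) * total_la
    trunk_leaf_areas = _split(trunk_la, n_trunk_leaves, rng)
    if p < 1e-3 and e < 1e-3:
        return IndividualArchitecture(sp, trunk_length,
                                      _split(total_la, n_trunk_leaves, rng),
                                      (), 0)
    e = min(e, 0.99)
    branch_la_total = p * total_la
    branch_len_total = e / (1.0 - e) * trunk_length
    n_branches = int(max(1, rng.poisson(3 + 30 * e)))
    la_mean = branch_la_total / n_branches
    len_mean = branch_len_total / n_branches
    n_measured = min(2, n_branches)
    if n_measured == 1:
        factors = [1.0]
    else:
        d = rng.uniform(0.0, 0.2)
        factors = [1.0 + d, 1.0 - d]
    branches = []
    for f in factors:
        n_leaves = int(max(1, rng.poisson(cfg.measures)))
        branches.append(Branch(len_mean * f, _split(la_mean * f, n_leaves, rng)))
    return IndividualArchitecture(sp, trunk_length, trunk_leaf_areas,
                                  tuple(branches), n_branches)


def default_classes(cfg: SimulationConfig = None) -> dict:
    """Species sp01..spNN mapped to classes with the configured class sizes."""
    cfg = cfg or SimulationConfig()
    n = sum(cfg.class_sizes)
    labels = [f"sp{i + 1:02d}" for i in range(n)]
    classes, i = {}, 0
    for c, size in enumerate(cfg.class_sizes, start=1):
        for _ in range(size):
            classes[labels[i]] = c
            i += 1
    return classes
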