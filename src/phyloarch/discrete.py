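"""Mk models of discrete character evolution: likelihood, ML fitting, ACE.

A k-state character evolves by a continuous-time Markov chain with generator
Q (off-diagonal rates >= 0, rows summing to zero).  Three standard equality
constraints are supported:

* ER  — equal rates, one parameter;
* SYM — symmetric rates, k(k-1)/2 parameters;
* ARD — all rates different, k(k-1) parameters.

The likelihood is Felsenstein's pruning algorithm with per-edge transition
matrices exp(Q t) (eigendecomposition, scaling-and-squaring fallback for
ill-conditioned Q), per-node rescaling against underflow, and a uniform root
prior by default (a stationary-distribution prior is available).  Polytomies
are handled natively by the pruning product over all children.  Marginal
ancestral state probabilities come from a combined downward/upward pass,
equivalent to rerooting at every node.  Model choice is by AICc with
n = number of tips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .modelsel import FitResult, select_model
from .tree import PhyloTree

__all__ = ["MkModel", "mk_loglik", "fit_mk", "fit_mk_all", "marginal_ace",
           "select_model", "CONSTRAINTS"]

CONSTRAINTS = ("ER", "SYM", "ARD")
_RATE_BOUNDS = (1e-8, 1e3)


def _pair_index(k):
    """Off-diagonal (i, j) orderings used by the SYM/ARD parameter vectors."""
    sym = [(i, j) for i in range(k) for j in range(i + 1, k)]
    ard = [(i, j) for i in range(k) for j in range(k) if i != j]
    return sym, ard


@dataclass(frozen=True)
class MkModel:
    """A constrained Mk rate model; ``rates`` follows the constraint's ordering."""

    k: int
    constraint: str
    rates: np.ndarray

    def __post_init__(self):
        if self.constraint not in CONSTRAINTS:
            raise ValueError(f"constraint must be one of {CONSTRAINTS}")
        r = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if len(r) != self.n_params:
            raise ValueError(f"{self.constraint} with k={self.k} needs "
                             f"{self.n_params} rates, got {len(r)}")
        if np.any(r < 0):
            raise ValueError("rates must be >= 0")
        object.__setattr__(self, "rates", r)

    @property
    def n_params(self) -> int:
        k = self.k
        return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[self.constraint]

    @property
    def Q(self) -> np.ndarray:
        k = self.k
        Q = np.zeros((k, k))
        sym, ard = _pair_index(k)
        if self.constraint == "ER":
            Q[:] = self.rates[0]
            np.fill_diagonal(Q, 0.0)
        elif self.constraint == "SYM":
            for r, (i, j) in zip(self.rates, sym):
                Q[i, j] = Q[j, i] = r
        else:
            for r, (i, j) in zip(self.rates, ard):
                Q[i, j] = r
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def stationary(self) -> np.ndarray:
        w, V = linalg.eig(self.Q.T)
        pi = np.real(V[:, np.argmin(np.abs(w))])
        pi = np.abs(pi)
        return pi / pi.sum()


def transition_matrices(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """exp(Q t) for a batch of branch lengths.

    Eigendecomposition (one per Q, reused across branches); falls back to
    scaling-and-squaring per branch when Q is defective or ill-conditioned.
    """
    k = Q.shape[0]
    ts = np.asarray(ts, dtype=float)
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        E = np.exp(np.multiply.outer(ts, w))              # (m, k)
        P = np.einsum("ij,tj,jl->til", V, E, Vinv).real
    else:
        P = np.stack([linalg.expm(Q * t) for t in ts])
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


def _root_prior(prior, k, model=None):
    if isinstance(prior, str):
        if prior == "uniform":
            return np.full(k, 1.0 / k)
        if prior == "stationary":
            if model is None:
                raise ValueError("stationary prior needs the model")
            return model.stationary()
        raise ValueError(f"unknown root prior {prior!r}")
    pi = np.asarray(prior, dtype=float)
    if len(pi) != k or abs(pi.sum() - 1) > 1e-9 or np.any(pi < 0):
        raise ValueError("root prior must be a length-k probability vector")
    return pi


def _tip_partials(tree: PhyloTree, tip_states: dict, k: int) -> dict:
    out = {}
    for v in tree.tip_indices:
        lab = tree.labels[v]
        s = tip_states.get(lab)
        L = np.ones(k)
        if s is not None and s != 0:
            s = int(s)
            if not 1 <= s <= k:
                raise ValueError(f"state {s} for {lab} outside 1..{k}")
            L = np.zeros(k)
            L[s - 1] = 1.0
        out[v] = L
    return out


def _downward(tree, tip_states, Q, k):
    """Pruning pass: per-node partial likelihoods and per-node rescaling logs."""
    if np.any(tree.lengths < 0):
        raise ValueError("negative branch length")
    P = transition_matrices(Q, tree.lengths)
    tipL = _tip_partials(tree, tip_states, k)
    Ld = np.zeros((tree.n_nodes, k))
    logscale = 0.0
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            L = tipL[v]
        else:
            L = np.ones(k)
            for c in kids:
                L = L * (P[c] @ Ld[c])
        s = L.sum()
        if s <= 0:
            return Ld, -np.inf, P
        Ld[v] = L / s
        logscale += np.log(s)
    return Ld, logscale, P


def mk_loglik(tree: PhyloTree, tip_states: dict, model,
              root_prior="uniform") -> float:
    """Pruning log-likelihood of the tip states under an Mk model.

    ``model`` may be an :class:`MkModel` or a raw generator matrix.  Unknown
    tips (missing / None / 0) contribute a uniform partial likelihood.
    """
    Q = model.Q if isinstance(model, MkModel) else np.asarray(model, dtype=float)
    k = Q.shape[0]
    pi = _root_prior(root_prior, k, model if isinstance(model, MkModel) else None)
    Ld, logscale, _ = _downward(tree, tip_states, Q, k)
    if not np.isfinite(logscale):
        return -np.inf
    return float(np.log(pi @ Ld[tree.root]) + logscale)


def fit_mk(tree: PhyloTree, tip_states: dict, constraint: str = "ER",
           k: int = 3, root_prior="uniform", n_starts: int = 3, seed: int = 0,
           extra_starts=()) -> FitResult:
    """ML rates under an equality constraint, by bounded multi-start L-BFGS-B.

    ``extra_starts`` accepts rate vectors used as additional starting points
    (e.g. the expanded optimum of a nested constraint); the returned optimum
    never falls below the likelihood of any start, so ER <= SYM <= ARD
    monotonicity holds whenever fits are chained through
    :func:`fit_mk_all`.  AICc uses n = number of tips.
    """
    observed = {int(s) for s in tip_states.values() if s}
    if len(observed) < 2:
        warnings.warn("single observed state: rate likelihood is flat toward 0; "
                      "boundary estimate returned", stacklevel=2)
    npar = _n_constraint(k, constraint)

    def nll(logr):
        mod = MkModel(k, constraint, np.exp(logr))
        ll = mk_loglik(tree, tip_states, mod, root_prior)
        return -ll if np.isfinite(ll) else 1e10

    depth = tree.depths()[tree.tip_indices].mean()
    r0 = 1.0 / max(depth, 1e-9)
    rng = np.random.default_rng(seed)
    starts = [np.full(npar, r0 * f) for f in (0.3, 1.0, 3.0)[:max(1, n_starts)]]
    starts += [np.full(npar, r0) * np.exp(rng.normal(0, 1, npar))
               for _ in range(max(0, n_starts - 3))]
    starts += [np.asarray(s, dtype=float) for s in extra_starts]

    lb, ub = np.log(_RATE_BOUNDS[0]), np.log(_RATE_BOUNDS[1])
    scored = []
    for s in starts:
        x0 = np.clip(np.log(np.maximum(s, _RATE_BOUNDS[0])), lb, ub)
        scored.append((nll(x0), tuple(x0)))
    scored.sort(key=lambda t: t[0])
    best_f, bx = scored[0]
    best_x, ok = np.array(bx), True
    for f0, x0 in scored[:max(2, n_starts)]:
        if f0 >= 1e10:
            continue
        res = optimize.minimize(nll, np.array(x0), method="L-BFGS-B",
                                bounds=[(lb, ub)] * npar,
                                options={"ftol": 1e-10, "gtol": 1e-8})
        if res.fun < best_f:
            best_x, best_f, ok = res.x, float(res.fun), bool(res.success)

    rates = np.exp(best_x)
    model = MkModel(k, constraint, rates)
    boundary = bool(np.any(np.isclose(best_x, lb)) or np.any(np.isclose(best_x, ub)))
    return FitResult(model=constraint,
                     params={"rates": rates, "Q": model.Q,
                             "constraint": constraint},
                     loglik=-best_f, k_params=npar, n=tree.n_tips,
                     converged=ok and not boundary,
                     message="boundary estimate" if boundary else "",
                     settings={"root_prior": root_prior, "seed": seed})


def _n_constraint(k, constraint):
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[constraint]


def fit_mk_all(tree: PhyloTree, tip_states: dict, k: int = 3,
               root_prior="uniform", seed: int = 0) -> list:
    """Fit ER, SYM and ARD with nested seeding (ER feeds SYM feeds ARD)."""
    sym_pairs, ard_pairs = _pair_index(k)
    er = fit_mk(tree, tip_states, "ER", k, root_prior, seed=seed)
    er_rate = er.params["rates"][0]
    sym = fit_mk(tree, tip_states, "SYM", k, root_prior, seed=seed,
                 extra_starts=[np.full(len(sym_pairs), er_rate)])
    Qs = sym.params["Q"]
    ard_start = np.array([Qs[i, j] for i, j in ard_pairs])
    ard = fit_mk(tree, tip_states, "ARD", k, root_prior, seed=seed,
                 extra_starts=[np.full(len(ard_pairs), er_rate), ard_start])
    return [er, sym, ard]


def marginal_ace(tree: PhyloTree, tip_states: dict, model,
                 root_prior="uniform"):
    """Marginal ancestral state probabilities at every internal node.

    Combined downward/upward pass (rerooting-equivalent): the downward pass
    gives each node's subtree partial likelihood, the upward pass the
    likelihood of the rest of the tree conditional on the node's state; their
    normalized product is the marginal.  Node ids are positions in the tree's
    postorder sequence.  Returns (probs, node_ids) where ``probs`` is a dict
    postorder-id -> length-k probability vector.
    """
    Q = model.Q if isinstance(model, MkModel) else np.asarray(model, dtype=float)
    k = Q.shape[0]
    pi = _root_prior(root_prior, k, model if isinstance(model, MkModel) else None)
    Ld, logscale, P = _downward(tree, tip_states, Q, k)
    if not np.isfinite(logscale):
        raise ValueError("zero likelihood: tip states impossible under model")

    G = np.zeros((tree.n_nodes, k))
    G[tree.root] = pi
    post = tree.postorder
    for v in post[::-1]:                      # preorder
        for c in tree.children[v]:
            # everything except c's subtree, seen from c's state
            other = G[v].copy()
            for w in tree.children[v]:
                if w != c:
                    other = other * (P[w] @ Ld[w])
            G[c] = P[c].T @ other
            s = G[c].sum()
            if s > 0:
                G[c] /= s

    probs = {}
    order = {int(v): i for i, v in enumerate(post)}
    for v in post:
        if tree.children[v]:
            m = G[v] * Ld[v]
            probs[order[v]] = m / m.sum()
    return probs, order
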