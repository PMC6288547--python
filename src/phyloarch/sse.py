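"""Multi-state speciation–extinction (MuSSE) likelihood, model family, fitting.

Each lineage carries one of k character states; state i speciates at rate
lambda_i, goes extinct at rate mu_i, and transitions to state j at rate q_ij.
Along each branch two coupled quantities are integrated backward in time
(t = 0 at the tips, increasing toward the root):

    dE_i/dt = mu_i - (lambda_i + mu_i + sum_j q_ij) E_i
              + lambda_i E_i^2 + sum_j q_ij E_j
    dD_i/dt = -(lambda_i + mu_i + sum_j q_ij) D_i
              + 2 lambda_i E_i D_i + sum_j q_ij D_j

E_i(t) is the probability that a lineage in state i at time t leaves no
sampled descendant; D_i(t) is the density of the observed subtree.  At each
internal node (the root included) D_i <- D_i(left) * D_i(right) * lambda_i,
with per-node renormalization on the log scale.  The root is handled by
state weighting: "obs" weights each state by its relative D (FitzJohn
weighting, the default of the standard implementation), "flat" averages;
optional survival conditioning divides by sum_i w_i lambda_i (1 - E_i)^2.
Complete sampling is assumed (E_i(0) = 0); a sampling-fraction hook exists
via ``sampling_f`` but defaults to 1.

Branches are integrated with an embedded Dormand–Prince 5(4) adaptive
stepper, JIT-compiled with numba when available (pure-Python fallback
otherwise); a scipy ``solve_ivp`` path is kept as an independent cross-check.

The model family covers the standard 15 constraint patterns used for
three-state (Monocaulous / Intermediate / Branched) diversification
analysis: free vs shared speciation, extinction (including fixed at zero)
and transition rates, plus the three two-class speciation patterns with and
without extinction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .modelsel import FitResult, select_model
from .tree import PhyloTree

__all__ = ["MuSSEModel", "MuSSEPattern", "sse_ode", "musse_loglik",
           "build_model_family", "fit_musse", "fit_family", "family_table",
           "select_model"]

_RATE_BOUNDS = (1e-8, 1e3)


@dataclass(frozen=True)
class MuSSEModel:
    """Concrete rates: speciation, extinction (events / Myr) and transitions."""

    lam: np.ndarray          # (k,)
    mu: np.ndarray           # (k,)
    q: np.ndarray            # (k, k), off-diagonal transition rates, diag 0

    def __post_init__(self):
        lam = np.asarray(self.lam, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        q = np.asarray(self.q, dtype=float).copy()
        np.fill_diagonal(q, 0.0)
        if np.any(lam < 0) or np.any(mu < 0) or np.any(q < 0):
            raise ValueError("all rates must be >= 0")
        if not (len(lam) == len(mu) == q.shape[0] == q.shape[1]):
            raise ValueError("rate dimensions disagree")
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "q", q)

    @property
    def k(self) -> int:
        return len(self.lam)


def sse_ode(t: float, D: np.ndarray, E: np.ndarray, model: MuSSEModel):
    """Time derivatives (dD, dE) of the D/E system; pure function of the state."""
    lam, mu, q = model.lam, model.mu, model.q
    qs = q.sum(axis=1)
    tot = lam + mu + qs
    dE = mu - tot * E + lam * E ** 2 + q @ E
    dD = -tot * D + 2.0 * lam * E * D + q @ D
    return dD, dE


# ---------------------------------------------------------------------------
# Branch integrator (Dormand-Prince 5(4), numba-compiled when available)
# ---------------------------------------------------------------------------

def _deriv(y, lam, mu, q, out):
    k = lam.shape[0]
    for i in range(k):
        E = y[i]
        D = y[k + i]
        qs = 0.0
        qE = 0.0
        qD = 0.0
        for j in range(k):
            if j != i:
                qs += q[i, j]
                qE += q[i, j] * y[j]
                qD += q[i, j] * y[k + j]
        tot = lam[i] + mu[i] + qs
        out[i] = mu[i] - tot * E + lam[i] * E * E + qE
        out[k + i] = -tot * D + 2.0 * lam[i] * E * D + qD


def _integrate_branch(y0, t0, t1, lam, mu, q, rtol, atol):
    """Adaptive DP5(4) from t0 to t1; returns (y, ok)."""
    n = y0.shape[0]
    y = y0.copy()
    span = t1 - t0
    if span <= 0.0:
        return y, True
    t = 0.0
    h = span * 0.1
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    k5 = np.empty(n); k6 = np.empty(n); k7 = np.empty(n)
    ytmp = np.empty(n)
    y5 = np.empty(n)
    steps = 0
    while t < span:
        # cap effort: rate regimes needing more steps than this are treated
        # as infeasible by the caller (the fitter scores them -inf)
        if steps > 1500:
            return y, False
        steps += 1
        if t + h > span:
            h = span - t
        _deriv(y, lam, mu, q, k1)
        for i in range(n):
            ytmp[i] = y[i] + h * 0.2 * k1[i]
        _deriv(ytmp, lam, mu, q, k2)
        for i in range(n):
            ytmp[i] = y[i] + h * (0.075 * k1[i] + 0.225 * k2[i])
        _deriv(ytmp, lam, mu, q, k3)
        for i in range(n):
            ytmp[i] = y[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i]
                                  + 32.0 / 9.0 * k3[i])
        _deriv(ytmp, lam, mu, q, k4)
        for i in range(n):
            ytmp[i] = y[i] + h * (19372.0 / 6561.0 * k1[i]
                                  - 25360.0 / 2187.0 * k2[i]
                                  + 64448.0 / 6561.0 * k3[i]
                                  - 212.0 / 729.0 * k4[i])
        _deriv(ytmp, lam, mu, q, k5)
        for i in range(n):
            ytmp[i] = y[i] + h * (9017.0 / 3168.0 * k1[i] - 355.0 / 33.0 * k2[i]
                                  + 46732.0 / 5247.0 * k3[i]
                                  + 49.0 / 176.0 * k4[i]
                                  - 5103.0 / 18656.0 * k5[i])
        _deriv(ytmp, lam, mu, q, k6)
        for i in range(n):
            y5[i] = y[i] + h * (35.0 / 384.0 * k1[i] + 500.0 / 1113.0 * k3[i]
                                + 125.0 / 192.0 * k4[i]
                                - 2187.0 / 6784.0 * k5[i] + 11.0 / 84.0 * k6[i])
        _deriv(y5, lam, mu, q, k7)
        errnorm = 0.0
        for i in range(n):
            y4i = y[i] + h * (5179.0 / 57600.0 * k1[i]
                              + 7571.0 / 16695.0 * k3[i]
                              + 393.0 / 640.0 * k4[i]
                              - 92097.0 / 339200.0 * k5[i]
                              + 187.0 / 2100.0 * k6[i] + 0.025 * k7[i])
            ay = abs(y[i])
            ay5 = abs(y5[i])
            sc = atol + rtol * (ay if ay > ay5 else ay5)
            e = (y5[i] - y4i) / sc
            errnorm += e * e
        errnorm = (errnorm / n) ** 0.5
        if errnorm <= 1.0:
            t += h
            for i in range(n):
                y[i] = y5[i]
        fac = 0.9 * (errnorm + 1e-300) ** -0.2
        if fac < 0.2:
            fac = 0.2
        elif fac > 5.0:
            fac = 5.0
        h *= fac
        if h < 1e-14 * span:
            return y, False
    return y, True


_deriv_py = _deriv
_integrate_branch_py = _integrate_branch
try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _deriv = njit(cache=False)(_deriv)
    _integrate_branch = njit(cache=False)(_integrate_branch)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def _integrate_scipy(y0, t0, t1, lam, mu, q, rtol, atol):
    """Independent solve_ivp (LSODA) path, used as a cross-check in tests."""
    from scipy.integrate import solve_ivp

    k = len(lam)

    def f(t, y):
        model = MuSSEModel(lam, mu, q)
        dD, dE = sse_ode(t, y[k:], y[:k], model)
        return np.concatenate([dE, dD])

    sol = solve_ivp(f, (t0, t1), y0, method="LSODA", rtol=rtol, atol=atol)
    return sol.y[:, -1], sol.success


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def musse_loglik(tree: PhyloTree, tip_states: dict, model: MuSSEModel,
                 root_mode="obs", condition_on_survival: bool = False,
                 rtol: float = 1e-8, atol: float = 1e-10,
                 renorm: str = "node", method: str = "auto",
                 sampling_f: float = 1.0) -> float:
    """MuSSE log-likelihood of the tree and tip states.

    Requires a strictly bifurcating tree (polytomies are rejected) and warns
    when the tree is not ultrametric to tolerance.  ``root_mode`` is "obs"
    (FitzJohn D-proportional weighting, default), "flat", or an explicit
    probability vector; survival conditioning is off by default, matching the
    reference implementation's defaults.  ``renorm`` ("node" or "never")
    controls the underflow bookkeeping schedule and never changes the result.
    """
    if not tree.is_bifurcating():
        bad = [v for v in range(tree.n_nodes) if len(tree.children[v]) > 2]
        raise ValueError(f"MuSSE requires a bifurcating tree; polytomy at "
                         f"node(s) {bad}")
    if not tree.is_ultrametric(1e-6):
        warnings.warn("tree is not ultrametric to 1e-6; tip times taken as 0",
                      stacklevel=2)
    lam, mu, q = model.lam, model.mu, model.q
    k = model.k
    if not 0 < sampling_f <= 1:
        raise ValueError("sampling_f must be in (0, 1]")
    times = np.maximum(tree.node_times(), 0.0)
    integrate = _integrate_branch if method in ("auto", "numba") else \
        (_integrate_branch_py if method == "python" else _integrate_scipy)

    ED = np.zeros((tree.n_nodes, 2 * k))
    logcomp = 0.0
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            lab = tree.labels[v]
            s = tip_states.get(lab)
            y = np.zeros(2 * k)
            y[:k] = 1.0 - sampling_f
            if s is None or s == 0:
                y[k:] = sampling_f
            else:
                s = int(s)
                if not 1 <= s <= k:
                    raise ValueError(f"state {s} for {lab} outside 1..{k}")
                y[k + s - 1] = sampling_f
        else:
            c1, c2 = kids
            y = np.zeros(2 * k)
            y[:k] = 0.5 * (ED[c1, :k] + ED[c2, :k])
            y[k:] = ED[c1, k:] * ED[c2, k:] * lam
            if renorm == "node":
                ssum = y[k:].sum()
                if ssum <= 0:
                    return -np.inf
                y[k:] /= ssum
                logcomp += np.log(ssum)
        if tree.parent[v] >= 0:
            t0, t1 = times[v], times[tree.parent[v]]
            y, ok = integrate(y, t0, t1, lam, mu, q, rtol, atol)
            if not ok:
                raise RuntimeError(
                    f"branch integration failed above node {v} "
                    f"(t {t0:.4g} -> {t1:.4g})")
        ED[v] = y

    Droot = ED[tree.root, k:]
    Eroot = np.clip(ED[tree.root, :k], 0.0, 1.0)
    if isinstance(root_mode, str):
        if root_mode == "obs":
            tot = Droot.sum()
            if tot <= 0:
                return -np.inf
            w = Droot / tot
        elif root_mode == "flat":
            w = np.full(k, 1.0 / k)
        else:
            raise ValueError(f"unknown root mode {root_mode!r}")
    else:
        w = np.asarray(root_mode, dtype=float)
        if len(w) != k or abs(w.sum() - 1) > 1e-9 or np.any(w < 0):
            raise ValueError("root weights must be a probability vector")
    val = float(w @ Droot)
    if val <= 0:
        return -np.inf
    ll = np.log(val) + logcomp
    if condition_on_survival:
        denom = float(w @ (lam * (1.0 - Eroot) ** 2))
        if denom <= 0:
            return -np.inf
        ll -= np.log(denom)
    return float(ll)


# ---------------------------------------------------------------------------
# Constraint patterns and the 15-model family
# ---------------------------------------------------------------------------

def _coarser(a, b) -> bool:
    """True if partition ``a`` is a coarsening of ``b`` (a's classes are unions)."""
    for i in range(len(a)):
        for j in range(len(a)):
            if b[i] == b[j] and a[i] != a[j]:
                return False
    return True


@dataclass(frozen=True)
class MuSSEPattern:
    """Equality-class constraint over (lambda, mu, q) for k = 3 states.

    ``lam_classes``/``mu_classes`` assign each state to a free-parameter
    class; ``mu_classes=None`` fixes all extinction rates at zero (zero
    parameters).  ``q_equal`` shares one transition rate across all ordered
    state pairs.
    """

    name: str
    lam_classes: tuple
    mu_classes: tuple = None        # None => mu fixed at 0
    q_equal: bool = True
    labels: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.lam_classes)

    @property
    def n_params(self) -> int:
        n = len(set(self.lam_classes))
        if self.mu_classes is not None:
            n += len(set(self.mu_classes))
        n += 1 if self.q_equal else self.k * (self.k - 1)
        return n

    def _blocks(self):
        nl = len(set(self.lam_classes))
        nm = 0 if self.mu_classes is None else len(set(self.mu_classes))
        nq = 1 if self.q_equal else self.k * (self.k - 1)
        return nl, nm, nq

    def to_model(self, theta) -> MuSSEModel:
        """Expand a free-parameter vector (natural scale) into full rates."""
        theta = np.asarray(theta, dtype=float)
        nl, nm, nq = self._blocks()
        if len(theta) != nl + nm + nq:
            raise ValueError(f"{self.name}: expected {nl + nm + nq} parameters")
        lam = theta[:nl][np.asarray(self.lam_classes)]
        if self.mu_classes is None:
            mu = np.zeros(self.k)
        else:
            mu = theta[nl:nl + nm][np.asarray(self.mu_classes)]
        qv = theta[nl + nm:]
        q = np.zeros((self.k, self.k))
        if self.q_equal:
            q[:] = qv[0]
        else:
            idx = 0
            for i in range(self.k):
                for j in range(self.k):
                    if i != j:
                        q[i, j] = qv[idx]
                        idx += 1
        np.fill_diagonal(q, 0.0)
        return MuSSEModel(lam, mu, q)

    def start_from(self, model: MuSSEModel, floor: float = _RATE_BOUNDS[0]):
        """Project a concrete model onto this pattern (class means); a start
        vector for nested-seeded optimization."""
        nl, nm, nq = self._blocks()
        lam_cls = np.asarray(self.lam_classes)
        lam = np.array([model.lam[lam_cls == c].mean() for c in range(nl)])
        parts = [lam]
        if self.mu_classes is not None:
            mu_cls = np.asarray(self.mu_classes)
            parts.append(np.array([model.mu[mu_cls == c].mean()
                                   for c in range(nm)]))
        off = model.q[~np.eye(self.k, dtype=bool)]
        parts.append(np.array([off.mean()]) if self.q_equal else off)
        return np.maximum(np.concatenate(parts), floor)

    def nests_in(self, other: "MuSSEPattern") -> bool:
        """True when every rate configuration of self is expressible in other
        (mu = 0 counts as the boundary of any estimated-mu pattern)."""
        if not _coarser(self.lam_classes, other.lam_classes):
            return False
        if self.mu_classes is not None:
            if other.mu_classes is None:
                return False
            if not _coarser(self.mu_classes, other.mu_classes):
                return False
        if not self.q_equal and other.q_equal:
            return False
        return True


def build_model_family() -> list:
    """The 15 standard three-state diversification models.

    State order is (Monocaulous, Intermediate, Branched) = states 1, 2, 3.
    Parameter counts: model 1 has 12 (3 lambda + 3 mu + 6 q) down to model 10
    with 2 (shared lambda, mu = 0, shared q).
    """
    F, M, E = (0, 1, 2), (0, 0, 0), None
    mk = MuSSEPattern
    lab = lambda l, m, q: {"speciation": l, "extinction": m, "transition": q}
    return [
        mk("1", F, F, False, lab("free", "free", "free")),
        mk("2", M, M, True, lab("equal", "equal", "equal")),
        mk("3", F, M, True, lab("free", "equal", "equal")),
        mk("4", F, F, True, lab("free", "free", "equal")),
        mk("5", F, M, False, lab("free", "equal", "free")),
        mk("6", M, M, False, lab("equal", "equal", "free")),
        mk("7", M, F, False, lab("equal", "free", "free")),
        mk("8a", (0, 0, 1), M, True, lab("M=I; B free", "equal", "equal")),
        mk("8b", (1, 0, 0), M, True, lab("I=B; M free", "equal", "equal")),
        mk("8c", (0, 1, 0), M, True, lab("M=B; I free", "equal", "equal")),
        mk("9a", (0, 0, 1), E, True, lab("M=I; B free", "zero", "equal")),
        mk("9b", (1, 0, 0), E, True, lab("I=B; M free", "zero", "equal")),
        mk("9c", (0, 1, 0), E, True, lab("M=B; I free", "zero", "equal")),
        mk("10", M, E, True, lab("equal", "zero", "equal")),
        mk("11", F, E, True, lab("free", "zero", "equal")),
    ]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _default_start(tree: PhyloTree, pattern: MuSSEPattern):
    """Birth-death moment start: Yule-ish speciation, small mu and q."""
    n, age = tree.n_tips, max(tree.crown_age(), 1e-6)
    lam0 = max((np.log(n) - np.log(2.0)) / age, 0.05)
    nl, nm, nq = pattern._blocks()
    return np.concatenate([np.full(nl, lam0), np.full(nm, 0.25 * lam0),
                           np.full(nq, 0.1 * lam0)])


def fit_musse(tree: PhyloTree, tip_states: dict, pattern: MuSSEPattern,
              seed: int = 0, n_starts: int = 2, extra_starts=(),
              root_mode="obs", condition_on_survival: bool = False,
              rtol: float = 1e-7, atol: float = 1e-10) -> FitResult:
    """ML fit of one constraint pattern, in log-rate space with box bounds.

    ``extra_starts`` take natural-scale parameter vectors (typically nested
    optima projected by :meth:`MuSSEPattern.start_from`); the returned optimum
    is never below the likelihood at any start, which makes family-wide
    nesting monotonicity structural.  AICc uses n = number of tips.
    """
    if tree.n_tips < 10:
        warnings.warn("fewer than 10 tips: state-dependent rates are weakly "
                      "identifiable", stacklevel=2)

    def nll(logtheta):
        try:
            ll = musse_loglik(tree, tip_states, pattern.to_model(np.exp(logtheta)),
                              root_mode=root_mode,
                              condition_on_survival=condition_on_survival,
                              rtol=rtol, atol=atol)
        except RuntimeError:
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    rng = np.random.default_rng(seed)
    base = _default_start(tree, pattern)
    starts = [base] + [base * np.exp(rng.normal(0, 0.7, len(base)))
                       for _ in range(max(0, n_starts - 1))]
    starts += [np.asarray(s, dtype=float) for s in extra_starts]
    lb, ub = np.log(_RATE_BOUNDS[0]), np.log(_RATE_BOUNDS[1])

    # score every start; optimize only from the most promising few (the best
    # start is always retained, so the fit never falls below any start)
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
                                bounds=[(lb, ub)] * len(x0),
                                options={"ftol": 1e-10, "gtol": 1e-8,
                                         "maxiter": 200, "maxfun": 2000})
        if res.fun < best_f:
            best_x, best_f, ok = res.x, float(res.fun), bool(res.success)

    theta = np.exp(best_x)
    model = pattern.to_model(theta)
    return FitResult(model=pattern.name,
                     params={"theta": theta, "lam": model.lam, "mu": model.mu,
                             "q": model.q},
                     loglik=-best_f, k_params=pattern.n_params, n=tree.n_tips,
                     converged=ok,
                     settings={"root_mode": root_mode,
                               "condition_on_survival": condition_on_survival,
                               "seed": seed, "rtol": rtol})


def fit_family(tree: PhyloTree, tip_states: dict, family=None, seed: int = 0,
               n_starts: int = 2, root_mode="obs",
               condition_on_survival: bool = False) -> list:
    """Fit all family models with nested seeding; failures are recorded, not fatal.

    Models are fitted in increasing parameter count, each seeded with the
    projected optimum of every already-fitted nested pattern, so
    lnL(model 1) >= lnL(any constrained model) on every dataset.
    """
    family = list(family) if family is not None else build_model_family()
    order = sorted(range(len(family)), key=lambda i: family[i].n_params)
    fitted: dict = {}
    for i in order:
        pat = family[i]
        extra = [pat.start_from(fitted[j].params["theta_model"])
                 for j in fitted
                 if family[j].nests_in(pat) and "theta_model" in fitted[j].params]
        try:
            fit = fit_musse(tree, tip_states, pat, seed=seed, n_starts=n_starts,
                            extra_starts=extra, root_mode=root_mode,
                            condition_on_survival=condition_on_survival)
            fit.params["theta_model"] = MuSSEModel(fit.params["lam"],
                                                   fit.params["mu"],
                                                   fit.params["q"])
        except Exception as exc:  # single-model failure: record and continue
            warnings.warn(f"model {pat.name} failed: {exc}", stacklevel=2)
            fit = FitResult(model=pat.name, params={}, loglik=-np.inf,
                            k_params=pat.n_params, n=tree.n_tips,
                            aicc=np.inf, converged=False, message=str(exc))
        fitted[i] = fit
    return [fitted[i] for i in range(len(family))]


def family_table(fits, family=None) -> pd.DataFrame:
    """Family comparison in the conventional layout: model, rate patterns,
    k, lnL, AICc, delta-AICc."""
    family = list(family) if family is not None else build_model_family()
    pat = {p.name: p for p in family}
    best = min(f.aicc for f in fits)
    rows = []
    for f in fits:
        p = pat.get(f.model)
        rows.append({
            "model": f.model,
            "speciation": p.labels.get("speciation", "") if p else "",
            "extinction": p.labels.get("extinction", "") if p else "",
            "transition": p.labels.get("transition", "") if p else "",
            "k": f.k_params, "lnL": f.loglik, "AICc": f.aicc,
            "delta_AICc": f.aicc - best,
        })
    return pd.DataFrame(rows)
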