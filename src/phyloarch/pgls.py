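"""Bivariate phylogenetic regression with intraspecific variation.

The estimator is maximum likelihood on the joint 2n-dimensional normal of the
stacked species means (x, y): both traits evolve by correlated Brownian
motion on the shared tree, and each species mean additionally carries its own
sampling variance (within-species variance / n) on the diagonal,

    Cov = [[sx2 C + Dx,  r sx sy C],
           [r sx sy C,   sy2 C + Dy]].

The evolutionary regression slope is beta = r * sy / sx.  Significance is a
likelihood-ratio test against the same model with the correlation r (hence
the slope) constrained to zero, referred to chi2 with 1 df.

The fit is direct ML on the joint normal (no EM): with at most a few hundred
species a dense Cholesky per likelihood evaluation is robust and testable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .traits import SpeciesTraitObservation, SpeciesTraitTable
from .tree import PhyloTree, vcv_subset

log = logging.getLogger(__name__)

__all__ = ["PglsFit", "fit_pgls_ives", "lrt_slope_zero", "correlation_table"]


@dataclass
class PglsFit:
    """A fitted bivariate phylogenetic regression."""

    slope: float                 # beta = r * sy / sx (y units per x unit)
    intercept: float
    sigma2_x: float
    sigma2_y: float
    correlation: float           # evolutionary correlation r
    mu_x: float
    mu_y: float
    loglik: float
    n_species: int
    species: tuple
    constrained: bool = False
    converged: bool = True
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


def _joint_nll_factory(C, Dx, Dy, x, y):
    n = len(x)
    w = np.concatenate([x, y])
    X = np.zeros((2 * n, 2))
    X[:n, 0] = 1.0
    X[n:, 1] = 1.0

    def nll(theta):
        sx2, sy2 = np.exp(theta[0]), np.exp(theta[1])
        r = theta[2]
        S = np.empty((2 * n, 2 * n))
        S[:n, :n] = sx2 * C + Dx
        S[n:, n:] = sy2 * C + Dy
        S[:n, n:] = r * np.sqrt(sx2 * sy2) * C
        S[n:, :n] = S[:n, n:]
        try:
            L = linalg.cholesky(S, lower=True)
        except linalg.LinAlgError:
            return 1e10, (np.nan, np.nan)
        Z = linalg.solve_triangular(L, np.column_stack([w, X[:, 0], X[:, 1]]),
                                    lower=True)
        zw, zx = Z[:, 0], Z[:, 1:]
        beta, *_ = np.linalg.lstsq(zx, zw, rcond=None)
        resid = zw - zx @ beta
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        ll = -0.5 * (2 * n * np.log(2 * np.pi) + logdet + resid @ resid)
        return -ll, (beta[0], beta[1])

    return nll


def fit_pgls_ives(tree: PhyloTree, x_obs: SpeciesTraitObservation,
                  y_obs: SpeciesTraitObservation,
                  constrain_slope_zero: bool = False,
                  n_restarts: int = 5, seed: int = 0) -> PglsFit:
    """ML fit of the bivariate Brownian model with sampling error.

    Species are matched by label (sorted intersection); at least 5 shared
    species are required.  ``constrain_slope_zero`` fixes the evolutionary
    correlation r at 0, giving the null model for :func:`lrt_slope_zero`.
    Multi-start bounded quasi-Newton optimization (moment-based start plus
    ``n_restarts`` seeded perturbations); the best point always dominates
    every start evaluated.
    """
    common = sorted(set(x_obs.species) & set(y_obs.species))
    if len(common) < 5:
        raise ValueError(f"need >= 5 shared species, got {len(common)}")
    xo, yo = x_obs.reorder(common), y_obs.reorder(common)
    missing = set(common) - set(tree.tip_labels)
    if missing:
        raise KeyError(f"species not on tree: {sorted(missing)}")
    C = vcv_subset(tree, common)
    Dx, Dy = np.diag(xo.sampling_variance), np.diag(yo.sampling_variance)
    x, y = xo.mean, yo.mean
    n = len(common)

    nll = _joint_nll_factory(C, Dx, Dy, x, y)
    dbar = np.mean(np.diag(C))
    sx2_0 = max(np.var(x, ddof=0), 1e-10) / dbar
    sy2_0 = max(np.var(y, ddof=0), 1e-10) / dbar
    sx = np.std(x)
    r0 = 0.0 if constrain_slope_zero or sx == 0 or np.std(y) == 0 else \
        float(np.clip(np.corrcoef(x, y)[0, 1], -0.95, 0.95))

    rng = np.random.default_rng(seed)
    starts = [[np.log(sx2_0), np.log(sy2_0), r0]]
    for _ in range(n_restarts):
        starts.append([np.log(sx2_0) + rng.normal(0, 1),
                       np.log(sy2_0) + rng.normal(0, 1),
                       0.0 if constrain_slope_zero else rng.uniform(-0.8, 0.8)])
    rb = (0.0, 0.0) if constrain_slope_zero else (-0.9999, 0.9999)
    bounds = [(-25, 25), (-25, 25), rb]

    best_x, best_f, ok = None, np.inf, False
    for s in starts:
        s[2] = min(max(s[2], rb[0]), rb[1])
        f0, _ = nll(s)
        if f0 < best_f:
            best_x, best_f = list(s), f0
        res = optimize.minimize(lambda t: nll(t)[0], s, method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": 1e-14, "gtol": 1e-10})
        if res.fun < best_f:
            best_x, best_f, ok = list(res.x), float(res.fun), bool(res.success)

    sx2, sy2 = float(np.exp(best_x[0])), float(np.exp(best_x[1]))
    r = float(best_x[2])
    _, (mu_x, mu_y) = nll(best_x)
    slope = r * np.sqrt(sy2 / sx2)
    if not ok:
        warnings.warn("PGLS optimizer did not report convergence; "
                      "best point of all starts returned", stacklevel=2)
    return PglsFit(slope=float(slope), intercept=float(mu_y - slope * mu_x),
                   sigma2_x=sx2, sigma2_y=sy2, correlation=r,
                   mu_x=float(mu_x), mu_y=float(mu_y), loglik=-best_f,
                   n_species=n, species=tuple(common),
                   constrained=constrain_slope_zero, converged=ok,
                   settings={"n_restarts": n_restarts, "seed": seed})


def lrt_slope_zero(full: PglsFit, constrained: PglsFit) -> float:
    """Likelihood-ratio p-value for slope = 0 (chi2, 1 df).

    The constrained fit must be the r = 0 model on the same species; a
    slightly negative statistic (optimizer noise) is clipped to zero with a
    warning.
    """
    if full.species != constrained.species:
        raise ValueError("fits are not on the same species set")
    if full.constrained or not constrained.constrained:
        raise ValueError("pass (full, constrained) in that order")
    stat = 2.0 * (full.loglik - constrained.loglik)
    if stat < 0:
        if stat < -1e-6:
            warnings.warn(f"negative LRT statistic {stat:.3g} clipped to 0",
                          stacklevel=2)
        stat = 0.0
    return float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0


def correlation_table(tree: PhyloTree, index: SpeciesTraitObservation,
                      traits: SpeciesTraitTable, seed: int = 0,
                      holm: bool = False) -> pd.DataFrame:
    """One regression of each trait on the branching index, with its LRT.

    Layout: trait, log(L), beta, p-value, n.  The response is the index;
    species missing a trait are dropped for that trait only (logged).  Raw
    p-values by default; ``holm=True`` adds a Holm-adjusted column.
    """
    rows = []
    for j, trait in enumerate(traits.traits):
        x_obs = traits.observation(trait)
        dropped = set(index.species) ^ set(x_obs.species)
        if dropped:
            log.info("trait %s: %d species without both variables dropped",
                     trait, len(dropped))
        try:
            full = fit_pgls_ives(tree, x_obs, index, seed=seed + j)
            null = fit_pgls_ives(tree, x_obs, index, constrain_slope_zero=True,
                                 seed=seed + j)
            rows.append({"trait": trait, "logL": full.loglik,
                         "beta": full.slope, "p_value": lrt_slope_zero(full, null),
                         "n": full.n_species})
        except ValueError as exc:
            log.warning("trait %s skipped: %s", trait, exc)
            rows.append({"trait": trait, "logL": np.nan, "beta": np.nan,
                         "p_value": np.nan, "n": 0})
    out = pd.DataFrame(rows)
    if holm and len(out):
        p = out["p_value"].to_numpy()
        order = np.argsort(p)
        adj = np.empty_like(p)
        m = np.sum(np.isfinite(p))
        running = 0.0
        for rank, i in enumerate(order):
            if not np.isfinite(p[i]):
                adj[i] = np.nan
                continue
            running = max(running, (m - rank) * p[i])
            adj[i] = min(1.0, running)
        out["p_holm"] = adj
    return out
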