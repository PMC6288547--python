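"""Phylogenetic signal with intraspecific variation: Pagel's lambda, Blomberg's K.

Both statistics are computed from species means whose sampling error
(within-species variance / n) is carried on the diagonal of the Brownian
covariance, so poorly replicated species are automatically down-weighted.

* Pagel's lambda multiplies the off-diagonal (shared-history) part of the
  Brownian covariance by lambda in [0, 1]; lambda and the Brownian rate are
  jointly ML-estimated, and the p-value is a likelihood-ratio test against
  lambda = 0 using the 50:50 chi2_0 / chi2_1 boundary mixture.
* Blomberg's K compares the observed ratio of the ordinary to the
  phylogenetically whitened mean squared error with its Brownian expectation;
  K ~ 1 under Brownian motion, < 1 when close relatives resemble each other
  less than expected.  Its p-value is a seeded tip-permutation test
  (inclusive, +1-corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .traits import SpeciesTraitObservation
from .tree import PhyloTree, vcv_subset

__all__ = ["SignalResult", "bm_loglik", "fit_bm", "pagel_lambda",
           "blomberg_k", "signal_table"]

_LOG_S2_BOUNDS = (-25.0, 25.0)


@dataclass
class SignalResult:
    """One signal statistic for one trait."""

    statistic: str
    estimate: float
    p_value: float
    n_species: int
    loglik: float = np.nan          # lambda only
    sigma2: float = np.nan
    settings: dict = field(default_factory=dict)
    converged: bool = True
    message: str = ""


def _aligned_cov(tree: PhyloTree, obs: SpeciesTraitObservation):
    missing = set(obs.species) - set(tree.tip_labels)
    if missing:
        raise KeyError(f"observed species not on tree: {sorted(missing)}")
    C = vcv_subset(tree, list(obs.species))
    return C, obs.mean, obs.sampling_variance


def _gls_loglik(y, V):
    """Log-likelihood of y ~ N(mu 1, V) with mu profiled by GLS."""
    n = len(y)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf, np.nan
    z = linalg.solve_triangular(L, y, lower=True)
    u = linalg.solve_triangular(L, np.ones(n), lower=True)
    mu = (u @ z) / (u @ u)
    r = z - mu * u
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet + r @ r)
    return ll, mu


def bm_loglik(tree: PhyloTree, obs: SpeciesTraitObservation,
              sigma2: float, lam: float = 1.0) -> float:
    """Brownian log-likelihood with measurement error.

    Covariance is ``sigma2 * lambda_transform(C, lam) + diag(variance / n)``;
    the phylogenetic mean is profiled out by GLS.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    C, y, se = _aligned_cov(tree, obs)
    Cl = C.copy()
    if lam != 1.0:
        off = ~np.eye(len(y), dtype=bool)
        Cl[off] *= lam
    V = sigma2 * Cl + np.diag(se)
    ll, _ = _gls_loglik(y, V)
    if not np.isfinite(ll):
        raise linalg.LinAlgError("singular covariance")
    return float(ll)


def fit_bm(tree: PhyloTree, obs: SpeciesTraitObservation, lam=None):
    """ML fit of (sigma2, lambda); ``lam`` fixes lambda when given.

    Returns (sigma2_hat, lambda_hat, loglik, converged).
    """
    C, y, se = _aligned_cov(tree, obs)
    Cd = np.diag(np.diag(C))
    off = C - Cd

    def nll(theta):
        s2 = np.exp(theta[0])
        l = theta[1] if lam is None else lam
        V = s2 * (Cd + l * off) + np.diag(se)
        ll, _ = _gls_loglik(y, V)
        return -ll if np.isfinite(ll) else 1e10

    s2_0 = max(np.var(y, ddof=1), 1e-12) / np.mean(np.diag(C))
    best = None
    lam_starts = [0.25, 0.75, 1.0] if lam is None else [lam]
    for l0 in lam_starts:
        x0 = [np.log(s2_0), l0]
        bounds = [_LOG_S2_BOUNDS, (0.0, 1.0)]
        if lam is not None:
            x0, bounds = x0[:1], bounds[:1]
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-12, "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    s2 = float(np.exp(best.x[0]))
    lhat = float(best.x[1]) if lam is None else float(lam)
    return s2, lhat, -float(best.fun), bool(best.success)


def pagel_lambda(tree: PhyloTree, obs: SpeciesTraitObservation,
                 unbounded: bool = False) -> SignalResult:
    """ML Pagel's lambda with a boundary-mixture LRT against lambda = 0.

    The search is bounded to [0, 1] by default; ``unbounded=True`` extends the
    upper bound to the matrix-feasible maximum (min diag / max off-diag), for
    comparability with software that reports lambda slightly above 1.
    """
    if len(obs.species) < 4:
        raise ValueError("at least 4 species required")
    if np.ptp(obs.mean) == 0:
        return SignalResult("lambda", np.nan, np.nan, len(obs.species),
                            converged=False, message="constant trait")
    C, y, se = _aligned_cov(tree, obs)
    Cd, off = np.diag(np.diag(C)), C - np.diag(np.diag(C))
    lam_max = 1.0
    if unbounded:
        m = off.max()
        lam_max = float(np.diag(C).min() / m) if m > 0 else 1.0

    def nll(theta):
        V = np.exp(theta[0]) * (Cd + theta[1] * off) + np.diag(se)
        ll, _ = _gls_loglik(y, V)
        return -ll if np.isfinite(ll) else 1e10

    s2_0 = max(np.var(y, ddof=1), 1e-12) / np.mean(np.diag(C))
    best = None
    for l0 in (0.05, 0.5, min(1.0, lam_max), lam_max):
        res = optimize.minimize(nll, [np.log(s2_0), l0], method="L-BFGS-B",
                                bounds=[_LOG_S2_BOUNDS, (0.0, lam_max)],
                                options={"ftol": 1e-12, "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    ll1 = -float(best.fun)
    _, _, ll0, _ = fit_bm(tree, obs, lam=0.0)
    stat = max(0.0, 2.0 * (ll1 - ll0))
    # lambda = 0 sits on the parameter boundary: 50:50 chi2_0/chi2_1 mixture
    p = 1.0 if stat == 0.0 else 0.5 * stats.chi2.sf(stat, df=1)
    return SignalResult("lambda", float(best.x[1]), float(max(p, 1e-300)),
                        len(obs.species), loglik=ll1,
                        sigma2=float(np.exp(best.x[0])),
                        settings={"bounds": (0.0, lam_max)},
                        converged=bool(best.success))


def blomberg_k(tree: PhyloTree, obs: SpeciesTraitObservation,
               n_perm: int = 999, seed: int = 0) -> SignalResult:
    """Blomberg's K with a seeded tip-permutation p-value.

    K = (MSE0/MSE)_observed / (MSE0/MSE)_expected, where MSE0 uses deviations
    from the phylogenetic (GLS) mean, MSE the C-whitened deviations, and the
    Brownian expectation of the ratio is (tr C - n / 1'C^-1 1) / (n - 1).
    With intraspecific variation, C is replaced by the error-adjusted ML
    covariance C + diag(variance / n) / sigma2_hat.  The p-value is the
    inclusive proportion of tip permutations whose whitened MSE is <= the
    observed one (strong signal gives a small whitened MSE).
    """
    if len(obs.species) < 4:
        raise ValueError("at least 4 species required")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    C, y, se = _aligned_cov(tree, obs)
    n = len(y)
    if np.any(se > 0):
        s2, _, _, _ = fit_bm(tree, obs, lam=1.0)
        C = C + np.diag(se) / s2
    L = linalg.cholesky(C, lower=True)
    u = linalg.solve_triangular(L, np.ones(n), lower=True)
    uu = u @ u

    def mse_pair(yv):
        z = linalg.solve_triangular(L, yv, lower=True)
        mu = (u @ z) / uu
        mse = (z @ z - uu * mu ** 2) / (n - 1)
        mse0 = float((yv - mu) @ (yv - mu)) / (n - 1)
        return mse0, mse

    mse0_obs, mse_obs = mse_pair(y)
    expected = (np.trace(C) - n / np.sum(linalg.cho_solve((L, True), np.ones(n)))) \
        / (n - 1)
    K = (mse0_obs / mse_obs) / expected

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(y) for _ in range(n_perm)]).T   # (n, m)
    Z = linalg.solve_triangular(L, perms, lower=True)
    mu_p = (u @ Z) / uu
    mse_p = (np.einsum("ij,ij->j", Z, Z) - uu * mu_p ** 2) / (n - 1)
    p = (1.0 + np.sum(mse_p <= mse_obs)) / (1.0 + n_perm)
    return SignalResult("K", float(K), float(p), n,
                        settings={"n_perm": n_perm, "seed": seed,
                                  "error_adjusted": bool(np.any(se > 0))})


def signal_table(tree: PhyloTree, table, n_perm: int = 999, seed: int = 0):
    """Both statistics for every trait of a :class:`SpeciesTraitTable`.

    Returns a data frame with columns (trait, lambda, lambda_p, K, K_p, n) —
    the conventional signal-table layout.
    """
    import pandas as pd

    rows = []
    for j, trait in enumerate(table.traits):
        obs = table.observation(trait)
        obs = obs.reorder([s for s in obs.species if s in set(tree.tip_labels)])
        try:
            lam = pagel_lambda(tree, obs)
        except ValueError as exc:
            lam = SignalResult("lambda", np.nan, np.nan, len(obs.species),
                               converged=False, message=str(exc))
        kk = blomberg_k(tree, obs, n_perm=n_perm, seed=seed + j)
        rows.append({"trait": trait, "lambda": lam.estimate,
                     "lambda_p": lam.p_value, "K": kk.estimate,
                     "K_p": kk.p_value, "n": kk.n_species})
    return pd.DataFrame(rows)
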