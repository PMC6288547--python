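"""Fit results and small-sample AIC model selection shared by Mk and MuSSE fits."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FitResult", "aicc", "select_model", "delta_table"]


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1); +inf when n <= k + 1."""
    if n - k - 1 <= 0:
        warnings.warn(f"AICc undefined for k={k}, n={n}; returning inf",
                      stacklevel=2)
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class FitResult:
    """One fitted model: estimates, log-likelihood, parameter count, AICc."""

    model: str
    params: dict
    loglik: float
    k_params: int
    n: int
    aicc: float = None
    converged: bool = True
    message: str = ""
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.aicc is None:
            self.aicc = aicc(self.loglik, self.k_params, self.n)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params


def select_model(fits) -> FitResult:
    """Minimum-AICc fit; AICc ties are broken toward fewer parameters."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (f.aicc, f.k_params))


def delta_table(fits) -> pd.DataFrame:
    """Model comparison table: lnL, k, AICc and delta-AICc, sorted by AICc."""
    fits = list(fits)
    best = select_model(fits)
    df = pd.DataFrame([{"model": f.model, "lnL": f.loglik, "k": f.k_params,
                        "AICc": f.aicc, "delta_AICc": f.aicc - best.aicc}
                       for f in fits])
    return df.sort_values(["AICc", "k"], kind="stable").reset_index(drop=True)
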