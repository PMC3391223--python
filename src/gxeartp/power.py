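"""Power of the 1-df SNP-by-environment interaction Wald test.

Power is parameterized by the fraction ``f`` of total outcome variance the
interaction term explains: the Wald statistic is asymptotically noncentral
chi-square with 1 degree of freedom and noncentrality n*f/(1-f), so

    power = P( chi2_1(lambda) > chi2_1 quantile at 1 - alpha ).

A Monte-Carlo cross-check simulates cohorts in which the (partialled)
interaction contrast carries exactly that variance share, fits the interaction
regression with robust standard errors, and counts rejections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PowerQuery", "interaction_power", "simulated_power", "power_table"]


@dataclass(frozen=True)
class PowerQuery:
    n: int
    alpha: float = 0.05
    variance_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.variance_fraction < 1.0:
            raise ValueError("variance_fraction must be in [0, 1)")


def interaction_power(n: int, variance_fraction: float, alpha: float = 0.05) -> float:
    """Analytic power of the two-sided 1-df interaction Wald test.

    ``variance_fraction`` is the interaction's share of total outcome variance;
    at 0 the power equals alpha exactly.
    """
    q = PowerQuery(n=n, alpha=alpha, variance_fraction=variance_fraction)
    lam = q.n * q.variance_fraction / (1.0 - q.variance_fraction)
    crit = stats.chi2.ppf(1.0 - q.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=lam))


def simulated_power(
    n: int,
    variance_fraction: float,
    alpha: float = 0.05,
    n_reps: int = 2000,
    maf: float = 0.3,
    seed: int = 0,
) -> float:
    """Monte-Carlo power estimate agreeing with :func:`interaction_power`.

    Each replicate draws a HWE genotype, a standard-normal exposure and an
    outcome whose interaction contrast (the G x E column partialled for
    intercept and main effects) explains ``variance_fraction`` of total
    variance, fits OLS with HC0 sandwich errors, and tests the interaction at
    ``alpha`` (normal reference).  All replicates are solved in one batched
    linear-algebra pass.
    """
    PowerQuery(n=n, alpha=alpha, variance_fraction=variance_fraction)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
    f = variance_fraction
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    rejections = 0
    chunk = 250
    done = 0
    while done < n_reps:
        R = min(chunk, n_reps - done)
        g = (rng.random((R, n, 2)) < maf).sum(axis=2).astype(float)
        e = rng.standard_normal((R, n))
        w = g * e
        X = np.stack([np.ones((R, n)), g, e, w], axis=2)  # (R, n, 4)
        # partial the interaction column for intercept and main effects, then
        # scale the partialled contrast so it explains f of total variance
        XtX3 = np.einsum("rni,rnj->rij", X[:, :, :3], X[:, :, :3])
        Xtw = np.einsum("rni,rn->ri", X[:, :, :3], w)
        gamma = np.linalg.solve(XtX3, Xtw[:, :, None])[:, :, 0]
        u = w - np.einsum("rni,ri->rn", X[:, :, :3], gamma)
        var_u = (u**2).mean(axis=1)
        beta = np.sqrt(f / (1.0 - f) / np.maximum(var_u, 1e-12))
        y = beta[:, None] * u + rng.standard_normal((R, n))
        XtX = np.einsum("rni,rnj->rij", X, X)
        Xty = np.einsum("rni,rn->ri", X, y)
        A = np.linalg.inv(XtX)
        betas = np.einsum("rij,rj->ri", A, Xty)
        resid = y - np.einsum("rni,ri->rn", X, betas)
        meat = np.einsum("rni,rn,rnj->rij", X, resid**2, X)
        V = np.einsum("rij,rjk,rkl->ril", A, meat, A)
        z = np.abs(betas[:, 3]) / np.sqrt(V[:, 3, 3])
        rejections += int((z > crit).sum())
        done += R
    return rejections / n_reps


def power_table(
    ns: list[int],
    fractions: list[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Analytic power over a grid of sample sizes and variance fractions."""
    rows = [
        {
            "n": n,
            "variance_fraction": f,
            "alpha": alpha,
            "power": interaction_power(n, f, alpha),
        }
        for n in ns
        for f in fractions
    ]
    return pd.DataFrame(rows)
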