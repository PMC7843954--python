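"""Shared fixtures: small synthetic cohorts and independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, poisson

from jiatraj import CohortTable, GbtmParameters
from jiatraj.likelihoods import polynomial_eta
from jiatraj.synthetic import GeneratorConfig, GroupSpec


# ---------------------------------------------------------------------------
# configs

def three_group_config(n: int, seed: int) -> GeneratorConfig:
    """Three well-separated trajectory groups (linear shapes)."""
    groups = [
        GroupSpec("low", 0.40, (0.0, -0.5), 0.30, (1.5, -0.4), (1.0, -0.2)),
        GroupSpec("mid", 0.35, (1.5, -0.3), 0.10, (5.0, -1.0), (5.0, -0.8)),
        GroupSpec("high", 0.25, (2.2, 0.0), 0.02, (8.0, -0.5), (8.0, -0.3)),
    ]
    return GeneratorConfig(n_individuals=n, groups=groups, seed=seed)


def two_group_config(n: int, seed: int) -> GeneratorConfig:
    """Two very well separated groups for near-perfect recovery checks."""
    groups = [
        GroupSpec("low", 0.6, (0.0, -0.5), 0.30, (1.0, -0.2), (1.0, -0.2)),
        GroupSpec("high", 0.4, (2.2, 0.0), 0.02, (8.5, -0.3), (8.5, -0.3)),
    ]
    return GeneratorConfig(n_individuals=n, groups=groups, seed=seed)


def one_group_config(n: int, seed: int) -> GeneratorConfig:
    groups = [GroupSpec("only", 1.0, (1.0, -0.3), 0.20, (4.0, -0.5), (3.0, -0.3))]
    return GeneratorConfig(n_individuals=n, groups=groups, seed=seed)


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Six individuals, hand-written visits, with some missing components."""
    rows = [
        ("a", 0.0, 2, 3.0, 2.5), ("a", 1.0, 1, 2.0, 2.0), ("a", 3.0, 0, 1.0, 1.5),
        ("b", 0.0, 8, 6.0, 5.5), ("b", 2.0, 5, np.nan, 4.0),
        ("c", 0.0, 0, 0.0, 0.5), ("c", 1.0, 0, 0.5, np.nan),
        ("d", 0.0, 10, 9.0, 10.0), ("d", 3.0, 4, 5.0, 6.0),
        ("e", 0.5, np.nan, 2.0, 3.0),
        ("f", 0.0, 3, np.nan, np.nan), ("f", 2.0, 1, 1.0, 1.0),
    ]
    df = pd.DataFrame(rows, columns=["individual_id", "time_years",
                                     "ajc", "pga_cm", "pge_cm"])
    return CohortTable(data=df)


def hand_params(k: int = 2, order: int = 1) -> GbtmParameters:
    """Small fixed parameter set for oracle comparisons."""
    rng = np.random.default_rng(42)

    def coeffs(intercept_mu, intercept_sd):
        b = rng.normal(0.0, 0.4, (k, order + 1))
        b[:, 0] = rng.normal(intercept_mu, intercept_sd, k)
        return b

    beta = {
        "ajc": coeffs(0.5, 0.4),
        "pga_cm": coeffs(4.0, 1.5),
        "pge_cm": coeffs(3.0, 1.5),
    }
    pi = rng.dirichlet(np.ones(k) * 5)
    return GbtmParameters(pi=pi, beta=beta,
                          sigma={"pga_cm": 1.3, "pge_cm": 1.6},
                          p_zero=rng.uniform(0.05, 0.5, k))


# ---------------------------------------------------------------------------
# independent oracles (plain probability space, scipy/math only)

def oracle_gbtm_loglik(params: GbtmParameters, visits: pd.DataFrame) -> float:
    """Brute-force enumeration over groups, multiplying plain densities."""
    total = 0.0
    for g in range(params.n_groups):
        p = params.pi[g]
        for _, row in visits.iterrows():
            t = row["time_years"]
            if not np.isnan(row.get("ajc", np.nan)):
                lam = math.exp(polynomial_eta(params.beta["ajc"][g], t))
                rho = params.p_zero[g]
                f = (1 - rho) * poisson.pmf(row["ajc"], lam)
                if row["ajc"] == 0:
                    f += rho
                p *= f
            for j in ("pga_cm", "pge_cm"):
                y = row.get(j, np.nan)
                if np.isnan(y):
                    continue
                mu = polynomial_eta(params.beta[j][g], t)
                s = params.sigma[j]
                lo, hi = params.bounds
                if y == lo:
                    p *= norm.cdf((lo - mu) / s)
                elif y == hi:
                    p *= norm.sf((hi - mu) / s)
                else:
                    p *= norm.pdf(y, mu, s)
        total += p
    return math.log(total)


def oracle_ari(a, b) -> float:
    """Adjusted Rand index from the pair-counting formula, via exact combs."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    cats_a, cats_b = np.unique(a), np.unique(b)
    table = np.array([[np.sum((a == x) & (b == y)) for y in cats_b]
                      for x in cats_a])
    comb2 = lambda x: x * (x - 1) // 2
    sum_ij = sum(comb2(int(v)) for v in table.ravel())
    sum_a = sum(comb2(int(v)) for v in table.sum(axis=1))
    sum_b = sum(comb2(int(v)) for v in table.sum(axis=0))
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def oracle_kruskal(values, groups):
    """Tie-corrected Kruskal–Wallis H from the explicit rank formula."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n)
    i = 0
    sv = values[order]
    while i < n:
        j = i
        while j < n and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0   # average rank, 1-based
        i = j
    h = 0.0
    for g in np.unique(groups):
        r = ranks[groups == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


def oracle_fisher_2x2(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def pmf(k):
        return math.comb(r1, k) * math.comb(r2, c1 - k) / denom

    p_obs = pmf(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))
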