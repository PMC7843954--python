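"""Cross-sectional latent profile analysis of the baseline cJADAS-10 components.

A K-class finite mixture of a Poisson (capped active joint count) and two
normals (the 0–10 cm global scores), fit by EM with closed-form M-steps.
Normal residual SDs are shared across classes (the generalised-SEM default;
configurable to class-specific).  Missing components are omitted from an
individual's likelihood; individuals missing all three baseline components
are excluded from this analysis only.

Baseline clustering is fully independent of the longitudinal trajectory
model — no inheritance of classes in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from sklearn.cluster import KMeans

from .cohort import CohortTable
from .gbtm import (assign_groups, average_posterior_probability, bic,
                   relative_entropy)

__all__ = ["LpaParameters", "LpaResult", "fit_lpa", "lpa_scan",
           "baseline_components"]


@dataclass
class LpaParameters:
    pi: np.ndarray
    ajc_rate: np.ndarray          # per-class Poisson mean
    pga_mu: np.ndarray
    pge_mu: np.ndarray
    pga_sigma: np.ndarray         # shared -> identical entries per class
    pge_sigma: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.pi)

    def n_free_params(self, shared_sigma: bool = True) -> int:
        k = self.n_classes
        n_sigma = 2 if shared_sigma else 2 * k
        return (k - 1) + 3 * k + n_sigma

    def permuted(self, idx) -> "LpaParameters":
        idx = np.asarray(idx)
        return LpaParameters(self.pi[idx], self.ajc_rate[idx], self.pga_mu[idx],
                             self.pge_mu[idx], self.pga_sigma[idx],
                             self.pge_sigma[idx])

    def to_dict(self) -> dict:
        return {k: np.asarray(v).tolist() for k, v in self.__dict__.items()}


@dataclass
class LpaResult:
    params: LpaParameters
    loglik: float
    n_params: int
    bic: float
    posteriors: np.ndarray
    assignment: np.ndarray
    entropy: float
    app: np.ndarray
    app_overall: float
    converged: bool
    n_iter: int
    loglik_history: np.ndarray = None
    individual_ids: np.ndarray = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loglik": float(self.loglik), "n_params": int(self.n_params),
            "bic": float(self.bic), "entropy": float(self.entropy),
            "app": self.app.tolist(), "app_overall": float(self.app_overall),
            "converged": bool(self.converged), "n_iter": int(self.n_iter),
            "assignment": self.assignment.tolist(),
            "individual_ids": (None if self.individual_ids is None
                               else [str(i) for i in self.individual_ids]),
        }


def baseline_components(cohort: CohortTable, ajc_cap: int = 10) -> pd.DataFrame:
    """Per-individual baseline (t = 0) components for LPA.

    The joint count is capped at ten, consistent with the cJADAS-10 scale.
    Individuals with no baseline visit or all three components missing at
    baseline are excluded (from this analysis only).
    """
    base = cohort.baseline()
    out = base[["individual_id", "ajc", "pga_cm", "pge_cm"]].copy()
    out["ajc"] = np.minimum(out["ajc"], ajc_cap)
    keep = out[["ajc", "pga_cm", "pge_cm"]].notna().any(axis=1)
    return out.loc[keep].reset_index(drop=True)


def _loglik_matrix(params: LpaParameters, Y: np.ndarray) -> np.ndarray:
    """(N, K) log-likelihood matrix; NaN components contribute nothing."""
    n = Y.shape[0]
    L = np.zeros((n, params.n_classes))
    ajc, pga, pge = Y[:, 0], Y[:, 1], Y[:, 2]

    m = ~np.isnan(ajc)
    if m.any():
        lam = params.ajc_rate[None, :]
        y = ajc[m, None]
        L[m] += y * np.log(lam) - lam - special.gammaln(y + 1.0)
    for vals, mu, sd in ((pga, params.pga_mu, params.pga_sigma),
                         (pge, params.pge_mu, params.pge_sigma)):
        m = ~np.isnan(vals)
        if m.any():
            z = (vals[m, None] - mu[None, :]) / sd[None, :]
            L[m] += -0.5 * z * z - np.log(sd)[None, :] - 0.5 * np.log(2 * np.pi)
    return L


def _m_step(Y: np.ndarray, post: np.ndarray, shared_sigma: bool) -> LpaParameters:
    k = post.shape[1]
    pi = np.clip(post.mean(axis=0), 1e-10, None)
    pi /= pi.sum()

    def weighted_means(vals):
        m = ~np.isnan(vals)
        w = post[m]
        tot = np.maximum(w.sum(axis=0), 1e-9)
        return (w * vals[m, None]).sum(axis=0) / tot, m, w, tot

    lam, _, _, _ = weighted_means(Y[:, 0])
    lam = np.maximum(lam, 1e-3)

    def normal_updates(vals):
        mu, m, w, tot = weighted_means(vals)
        resid2 = (vals[m, None] - mu[None, :]) ** 2
        if shared_sigma:
            var = (w * resid2).sum() / w.sum()
            sd = np.full(k, np.sqrt(max(var, 1e-6)))
        else:
            sd = np.sqrt(np.maximum((w * resid2).sum(axis=0) / tot, 1e-6))
        return mu, sd

    pga_mu, pga_sd = normal_updates(Y[:, 1])
    pge_mu, pge_sd = normal_updates(Y[:, 2])
    return LpaParameters(pi, lam, pga_mu, pge_mu, pga_sd, pge_sd)


def fit_lpa(baseline, K: int, n_starts: int = 10, seed: int = 0,
            tol: float = 1e-8, max_iter: int = 500,
            shared_sigma: bool = True) -> LpaResult:
    """EM maximum likelihood for the K-class baseline profile mixture.

    ``baseline`` is a DataFrame with columns ``ajc``, ``pga_cm``, ``pge_cm``
    (and optionally ``individual_id``), one row per individual; NaN marks a
    missing component.  Classes are reported in canonical ascending order of
    λ_g + μ_PGA,g + μ_PGE,g.
    """
    df = pd.DataFrame(baseline)
    ids = df["individual_id"].to_numpy() if "individual_id" in df else None
    Y = df[["ajc", "pga_cm", "pge_cm"]].to_numpy(dtype=float)
    if not (~np.isnan(Y)).any(axis=1).all():
        raise ValueError("every individual needs >= 1 non-missing baseline component")
    n = Y.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")

    col_mean = np.nanmean(Y, axis=0)
    filled = np.where(np.isnan(Y), col_mean, Y)
    sd = filled.std(axis=0)
    Z = (filled - filled.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    best = None
    degenerate = K > len(np.unique(filled, axis=0))
    for s in range(n_starts):
        rng = np.random.default_rng(seed + s)
        S = Z if s == 0 else Z + rng.normal(0, 0.5, Z.shape)
        labels = KMeans(n_clusters=min(K, n), n_init=3,
                        random_state=int(rng.integers(2**31 - 1))).fit_predict(S)
        post = np.full((n, K), 0.05 / max(K - 1, 1))
        post[np.arange(n), labels % K] = 0.95
        post /= post.sum(axis=1, keepdims=True)
        params = _m_step(Y, post, shared_sigma)

        history = []
        converged = False
        for _ in range(max_iter):
            logp = np.log(params.pi) + _loglik_matrix(params, Y)
            lse = special.logsumexp(logp, axis=1)
            ll = float(lse.sum())
            post = np.exp(logp - lse[:, None])
            history.append(ll)
            if len(history) > 1 and ll - history[-2] < tol * (abs(history[-2]) + 1):
                converged = True
                break
            params = _m_step(Y, post, shared_sigma)
        if best is None or history[-1] > best[2][-1]:
            best = (params, post, history, converged)
        if K == 1:
            break

    params, post, history, converged = best
    order = np.argsort(params.ajc_rate + params.pga_mu + params.pge_mu,
                       kind="stable")
    params = params.permuted(order)
    post = post[:, order]
    assignment = assign_groups(post)
    app, app_overall = average_posterior_probability(post, assignment)
    n_params = params.n_free_params(shared_sigma)
    ll = float(history[-1])
    return LpaResult(params=params, loglik=ll, n_params=n_params,
                     bic=bic(ll, n_params, n), posteriors=post,
                     assignment=assignment, entropy=relative_entropy(post),
                     app=app, app_overall=app_overall,
                     converged=converged and not degenerate,
                     n_iter=len(history), loglik_history=np.array(history),
                     individual_ids=ids)


def lpa_scan(baseline, k_max: int = 10, n_starts: int = 10, seed: int = 0,
             tol: float = 1e-8, max_iter: int = 500):
    """Fit K = 1…k_max and select the lowest-BIC converged model.

    Returns ``(best_result, table)`` where ``table`` is a DataFrame with one
    row per K (BIC, log-likelihood, entropy, converged flag).  Non-converged
    fits are recorded but excluded from selection.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    rows = []
    fits = {}
    for k in range(1, k_max + 1):
        res = fit_lpa(baseline, k, n_starts=n_starts, seed=seed,
                      tol=tol, max_iter=max_iter)
        fits[k] = res
        rows.append({"K": k, "bic": res.bic, "loglik": res.loglik,
                     "entropy": res.entropy, "app_overall": res.app_overall,
                     "converged": res.converged})
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    pool = ok if len(ok) else table
    best_k = int(pool.loc[pool["bic"].idxmin(), "K"])
    return fits[best_k], table
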