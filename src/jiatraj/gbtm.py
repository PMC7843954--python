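"""Multivariate group-based trajectory model (latent class growth analysis).

The model: each individual belongs to one of K latent groups with prior
probabilities π.  Conditional on group g, the three disease-activity
components evolve along group-specific polynomial trajectories in time t
(years from first presentation):

* active joint count (capped at 10):  AJC ~ ZIP(λ = exp(η_g(t)), ρ_g),
  with an intercept-only zero-inflation probability ρ_g per group;
* physician's global assessment and patient/parent global evaluation:
  censored normal on [0, 10] cm with latent mean η_g(t) and a residual SD
  shared across groups within each outcome (the standard identifying
  assumption for this model family).

Outcomes and visits are conditionally independent given group, and missing
components are simply omitted from the likelihood, which is the
maximum-likelihood handling of data missing at random — no imputation.

Estimation is EM: the E-step computes posterior group memberships by Bayes'
rule on the individual log-likelihoods (log-sum-exp throughout); the M-step
re-estimates π in closed form and the trajectory/dispersion parameters by
warm-started quasi-Newton ascent of the posterior-weighted ZIP and Tobit
log-likelihoods (a generalised M-step — any ascent of the weighted
complete-data objective preserves EM monotonicity).  Multiple starts use
k-means on per-individual outcome summaries with jitter; the best final
log-likelihood wins, and groups are relabelled by ascending model-implied
baseline cJADAS-10 so labels are canonical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, special
from sklearn.cluster import KMeans

from .cohort import CohortTable, OUTCOME_COLUMNS
from .likelihoods import censnorm_mean, zip_mean

__all__ = [
    "TrajectorySpec",
    "GbtmParameters",
    "FitResult",
    "fit_gbtm",
    "individual_log_likelihood",
    "posterior_probabilities",
    "assign_groups",
    "bic",
    "relative_entropy",
    "average_posterior_probability",
    "predicted_trajectories",
]

_LOG_2PI = np.log(2.0 * np.pi)
_VAS_OUTCOMES = ("pga_cm", "pge_cm")
_ETA_CLIP = 30.0
_ALPHA_BOUND = 8.0         # logit bound for the zero-inflation probability
_LOG_SIGMA_BOUNDS = (np.log(1e-2), np.log(50.0))


@dataclass(frozen=True)
class TrajectorySpec:
    """Model size: number of groups K (1–10) and polynomial order (1–3)."""

    n_groups: int
    polynomial_order: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.n_groups <= 10:
            raise ValueError("n_groups must be between 1 and 10")
        if self.polynomial_order not in (1, 2, 3):
            raise ValueError("polynomial_order must be 1, 2 or 3")


@dataclass
class GbtmParameters:
    """Fitted parameters of the multivariate trajectory mixture.

    ``beta`` maps outcome name -> (K, order+1) coefficient array; for the
    joint count the polynomial acts on the log rate.  ``sigma`` holds one
    residual SD per censored-normal outcome, shared across groups;
    ``p_zero`` is the per-group structural-zero probability.
    """

    pi: np.ndarray
    beta: dict
    sigma: dict
    p_zero: np.ndarray
    bounds: tuple = (0.0, 10.0)

    @property
    def n_groups(self) -> int:
        return len(self.pi)

    @property
    def order(self) -> int:
        return self.beta["ajc"].shape[1] - 1

    def n_free_params(self) -> int:
        k, q = self.n_groups, self.order + 1
        return (k - 1) + 3 * k * q + k + len(self.sigma)

    def permuted(self, order_idx) -> "GbtmParameters":
        idx = np.asarray(order_idx)
        return GbtmParameters(
            pi=self.pi[idx],
            beta={j: b[idx] for j, b in self.beta.items()},
            sigma=dict(self.sigma),
            p_zero=self.p_zero[idx],
            bounds=self.bounds,
        )

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "beta": {j: b.tolist() for j, b in self.beta.items()},
            "sigma": {j: float(s) for j, s in self.sigma.items()},
            "p_zero": self.p_zero.tolist(),
            "bounds": list(self.bounds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GbtmParameters":
        return cls(
            pi=np.asarray(d["pi"], dtype=float),
            beta={j: np.asarray(b, dtype=float) for j, b in d["beta"].items()},
            sigma={j: float(s) for j, s in d["sigma"].items()},
            p_zero=np.asarray(d["p_zero"], dtype=float),
            bounds=tuple(d.get("bounds", (0.0, 10.0))),
        )


@dataclass
class FitResult:
    params: GbtmParameters
    loglik: float
    n_params: int
    bic: float
    posteriors: np.ndarray
    assignment: np.ndarray
    entropy: float
    app: np.ndarray                      # per-group average posterior probability
    app_overall: float
    converged: bool
    n_starts: int
    best_start_seed: int
    n_iter: int
    loglik_history: np.ndarray
    individual_ids: np.ndarray = field(default=None)

    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.params.n_groups)

    def to_dict(self, include_posteriors: bool = False) -> dict:
        out = {
            "params": self.params.to_dict(),
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "bic": float(self.bic),
            "entropy": float(self.entropy),
            "app": self.app.tolist(),
            "app_overall": float(self.app_overall),
            "converged": bool(self.converged),
            "n_starts": int(self.n_starts),
            "best_start_seed": int(self.best_start_seed),
            "n_iter": int(self.n_iter),
            "assignment": self.assignment.tolist(),
            "group_sizes": self.group_sizes().tolist(),
        }
        if self.individual_ids is not None:
            out["individual_ids"] = [str(i) for i in self.individual_ids]
        if include_posteriors:
            out["posteriors"] = self.posteriors.tolist()
        return out


# ---------------------------------------------------------------------------
# data preparation

class _FitData:
    """Cohort flattened to per-outcome observation arrays.

    For each outcome: ``obs_i`` (individual index per observed row), ``y``,
    and the time design matrix ``X`` (powers of t up to the requested
    order).  ``agg`` is a sparse indicator used to sum per-observation log
    densities into per-individual totals.
    """

    def __init__(self, cohort: CohortTable, order: int, ajc_cap: int = 10):
        df = cohort.data
        ids, idx = np.unique(df["individual_id"].to_numpy(), return_inverse=True)
        self.ids = ids
        self.n = len(ids)
        self.order = order
        self.outcomes = {}
        for j in OUTCOME_COLUMNS:
            y = df[j].to_numpy(dtype=float)
            m = ~np.isnan(y)
            t = df["time_years"].to_numpy(dtype=float)[m]
            yv = y[m]
            if j == "ajc":
                if np.any(yv < 0) or np.any(yv % 1 != 0):
                    raise ValueError("active joint count must be a non-negative integer")
                yv = np.minimum(yv, ajc_cap)
            else:
                if np.any((yv < 0) | (yv > 10)):
                    raise ValueError(f"{j} outside [0, 10] cm")
            X = np.vander(t, N=order + 1, increasing=True)
            oi = idx[m]
            agg = sparse.csr_matrix(
                (np.ones(oi.size), (oi, np.arange(oi.size))),
                shape=(self.n, oi.size))
            self.outcomes[j] = {"obs_i": oi, "t": t, "y": yv, "X": X, "agg": agg}
        observed_any = np.zeros(self.n, dtype=bool)
        for j in OUTCOME_COLUMNS:
            observed_any[self.outcomes[j]["obs_i"]] = True
        if not observed_any.all():
            bad = ids[~observed_any][:5]
            raise ValueError(f"individuals with no observed outcome: {bad}")


# ---------------------------------------------------------------------------
# log-likelihood kernels on prepared data (vectorised over groups)

def _zip_ll_matrix(y, eta, log_p0, log_1mp0):
    """(n_obs, K) ZIP log pmf; ``eta`` is the log-rate matrix."""
    lam = np.exp(eta)
    ycol = y[:, None]
    pois = ycol * eta - lam - special.gammaln(ycol + 1.0)
    ll = log_1mp0[None, :] + pois
    zero = y == 0
    if zero.any():
        ll[zero] = np.logaddexp(log_p0[None, :], log_1mp0[None, :] - lam[zero])
    return ll


def _censnorm_ll_matrix(y, mu, sigma, lower, upper):
    """(n_obs, K) censored-normal log density/mass."""
    z = (y[:, None] - mu) / sigma
    ll = -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI
    at_l = y == lower
    at_u = y == upper
    if at_l.any():
        ll[at_l] = special.log_ndtr((lower - mu[at_l]) / sigma)
    if at_u.any():
        ll[at_u] = special.log_ndtr(-(upper - mu[at_u]) / sigma)
    return ll


def _component_loglik(params: GbtmParameters, data: _FitData) -> np.ndarray:
    """(N, K) matrix of log L_ig = log f(individual i's data | group g)."""
    L = np.zeros((data.n, params.n_groups))
    o = data.outcomes["ajc"]
    with np.errstate(divide="ignore"):
        log_p0 = np.log(params.p_zero)
        log_1mp0 = np.log1p(-params.p_zero)
    eta = np.clip(o["X"] @ params.beta["ajc"].T, -_ETA_CLIP, _ETA_CLIP)
    L += o["agg"] @ _zip_ll_matrix(o["y"], eta, log_p0, log_1mp0)
    lower, upper = params.bounds
    for j in _VAS_OUTCOMES:
        o = data.outcomes[j]
        mu = o["X"] @ params.beta[j].T
        L += o["agg"] @ _censnorm_ll_matrix(o["y"], mu, params.sigma[j], lower, upper)
    return L


# ---------------------------------------------------------------------------
# public likelihood / posterior utilities

def individual_log_likelihood(params: GbtmParameters, visits) -> float:
    """Marginal log-likelihood of one individual's visit records.

    ``visits`` is a DataFrame (or dict of columns) with ``time_years`` and
    the outcome columns; missing components are omitted (MAR likelihood):
    log Σ_g π_g · Π_{t,j observed} f_j(y_jt | group g).
    """
    df = pd.DataFrame(visits).copy()
    df["individual_id"] = "one"
    table = CohortTable(data=df[["individual_id", "time_years", *OUTCOME_COLUMNS]])
    data = _FitData(table, order=params.order)
    L = _component_loglik(params, data)
    return float(special.logsumexp(np.log(params.pi) + L[0]))


def posterior_probabilities(params: GbtmParameters, cohort) -> np.ndarray:
    """N×K posterior membership matrix, p_ig = π_g L_ig / Σ_h π_h L_ih."""
    data = cohort if isinstance(cohort, _FitData) else _FitData(cohort, params.order)
    with np.errstate(divide="ignore"):
        logp = np.log(params.pi) + _component_loglik(params, data)
    lse = special.logsumexp(logp, axis=1)
    if np.any(~np.isfinite(lse)):
        bad = data.ids[~np.isfinite(lse)][:5]
        raise FloatingPointError(
            f"zero total likelihood (underflow) for individuals {bad}")
    return np.exp(logp - lse[:, None])


def assign_groups(posteriors) -> np.ndarray:
    """Modal (highest-posterior) assignment; exact ties break to the lowest index."""
    return np.argmax(posteriors, axis=1)


def bic(loglik: float, n_params: int, n_individuals: int) -> float:
    """Bayesian information criterion, −2·logL + k·ln N; lower is better."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_individuals)


def relative_entropy(posteriors) -> float:
    """Normalised classification certainty in [0, 1].

    1 − Σ_i Σ_g (−p_ig ln p_ig) / (N ln K): 1 for one-hot posteriors,
    0 for uniform ones.  Defined as 1 for K = 1 (degenerate, perfectly
    classified).
    """
    p = np.asarray(posteriors, dtype=float)
    n, k = p.shape
    if k == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return float(1.0 - terms.sum() / (n * np.log(k)))


def average_posterior_probability(posteriors, assignment):
    """Per-group and overall average posterior probability of assigned group.

    Returns ``(app, overall)`` where ``app[g]`` is the mean of p_ig over
    individuals assigned to g (NaN for empty groups) and ``overall`` is the
    mean assigned-group posterior across all individuals.
    """
    p = np.asarray(posteriors, dtype=float)
    a = np.asarray(assignment)
    k = p.shape[1]
    assigned = p[np.arange(p.shape[0]), a]
    app = np.full(k, np.nan)
    for g in range(k):
        m = a == g
        if m.any():
            app[g] = assigned[m].mean()
    return app, float(assigned.mean())


def predicted_trajectories(params: GbtmParameters, time_grid) -> dict:
    """Expected observed-value curves per group: dict outcome -> (K, T) array.

    Joint counts: (1 − ρ_g)·exp(η_g(t)), shown capped at 10; global scores:
    the censored-normal mean, which accounts for the mass at 0 and 10 cm.
    """
    t = np.asarray(time_grid, dtype=float)
    X = np.vander(t, N=params.order + 1, increasing=True)
    out = {}
    lam = np.exp(np.clip(X @ params.beta["ajc"].T, -_ETA_CLIP, _ETA_CLIP))
    out["ajc"] = np.minimum(zip_mean(lam, params.p_zero[None, :]), 10.0).T
    lower, upper = params.bounds
    for j in _VAS_OUTCOMES:
        mu = X @ params.beta[j].T
        out[j] = censnorm_mean(mu, params.sigma[j], lower, upper).T
    return out


# ---------------------------------------------------------------------------
# M-step: weighted ZIP and Tobit maximum likelihood

def _zip_objective(theta, X, y, w):
    """Negative weighted ZIP log-likelihood and gradient for one group.

    theta = (beta, alpha) with rate λ = exp(Xβ) and ρ = sigmoid(α).
    """
    beta, alpha = theta[:-1], theta[-1]
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    lam = np.exp(eta)
    rho = special.expit(alpha)
    log_p0 = np.log(rho)
    log_1mp0 = np.log1p(-rho)

    zero = y == 0
    ll = np.empty_like(eta)
    deta = np.empty_like(eta)
    dalpha = np.empty_like(eta)

    pos = ~zero
    ll[pos] = log_1mp0 + y[pos] * eta[pos] - lam[pos] - special.gammaln(y[pos] + 1.0)
    deta[pos] = y[pos] - lam[pos]
    dalpha[pos] = -rho
    if zero.any():
        lz = lam[zero]
        logD = np.logaddexp(log_p0, log_1mp0 - lz)
        ll[zero] = logD
        deta[zero] = -lz * np.exp(log_1mp0 - lz - logD)
        dalpha[zero] = np.exp(log_p0 + log_1mp0 - logD) * (-np.expm1(-lz))

    f = -np.dot(w, ll)
    g = np.empty_like(theta)
    g[:-1] = -(X.T @ (w * deta))
    g[-1] = -np.dot(w, dalpha)
    return f, g


def _tobit_objective(theta, X, y, W, lower, upper, at_l, at_u):
    """Negative posterior-weighted censored-normal log-likelihood + gradient.

    theta = (β_1, …, β_K, log σ); W is the (n_obs, K) weight matrix.
    """
    k = W.shape[1]
    q = X.shape[1]
    beta = theta[: k * q].reshape(k, q)
    s = theta[-1]
    sigma = np.exp(s)

    mu = X @ beta.T                       # (n_obs, K)
    z = (y[:, None] - mu) / sigma
    ll = -0.5 * z * z - s - 0.5 * _LOG_2PI
    dmu = z / sigma
    ds = z * z - 1.0
    if at_l.any():
        a = (lower - mu[at_l]) / sigma
        r = np.exp(-0.5 * a * a - 0.5 * _LOG_2PI - special.log_ndtr(a))
        ll[at_l] = special.log_ndtr(a)
        dmu[at_l] = -r / sigma
        ds[at_l] = -a * r
    if at_u.any():
        b = (upper - mu[at_u]) / sigma
        r = np.exp(-0.5 * b * b - 0.5 * _LOG_2PI - special.log_ndtr(-b))
        ll[at_u] = special.log_ndtr(-b)
        dmu[at_u] = r / sigma
        ds[at_u] = b * r

    f = -np.sum(W * ll)
    g = np.empty_like(theta)
    g[: k * q] = -(X.T @ (W * dmu)).T.ravel()
    g[-1] = -np.sum(W * ds)
    return f, g


def _m_step(params: GbtmParameters, data: _FitData, post: np.ndarray,
            maxiter: int = 40) -> GbtmParameters:
    k = params.n_groups
    pi = np.clip(post.mean(axis=0), 1e-10, None)
    pi = pi / pi.sum()

    # ZIP outcome: one warm-started quasi-Newton fit per group
    o = data.outcomes["ajc"]
    W = post[o["obs_i"]]                   # (n_obs, K)
    beta_ajc = params.beta["ajc"].copy()
    alpha = special.logit(np.clip(params.p_zero, 1e-6, 1 - 1e-6))
    new_alpha = alpha.copy()
    bnds = ([(None, None)] * beta_ajc.shape[1]
            + [(-_ALPHA_BOUND, _ALPHA_BOUND)])
    for g in range(k):
        theta0 = np.append(beta_ajc[g], np.clip(alpha[g], -_ALPHA_BOUND, _ALPHA_BOUND))
        res = optimize.minimize(
            _zip_objective, theta0, args=(o["X"], o["y"], W[:, g]),
            method="L-BFGS-B", jac=True, bounds=bnds,
            options={"maxiter": maxiter, "ftol": 1e-12})
        f0, _ = _zip_objective(theta0, o["X"], o["y"], W[:, g])
        if res.fun <= f0:                  # generalised M-step: never go downhill
            beta_ajc[g] = res.x[:-1]
            new_alpha[g] = res.x[-1]
    p_zero = special.expit(new_alpha)

    # Tobit outcomes: joint fit over all groups' betas and the shared sigma
    beta = {"ajc": beta_ajc}
    sigma = {}
    lower, upper = params.bounds
    for j in _VAS_OUTCOMES:
        o = data.outcomes[j]
        Wj = post[o["obs_i"]]
        at_l = o["y"] == lower
        at_u = o["y"] == upper
        theta0 = np.append(params.beta[j].ravel(), np.log(params.sigma[j]))
        bounds_j = [(None, None)] * (theta0.size - 1) + [_LOG_SIGMA_BOUNDS]
        res = optimize.minimize(
            _tobit_objective, theta0,
            args=(o["X"], o["y"], Wj, lower, upper, at_l, at_u),
            method="L-BFGS-B", jac=True, bounds=bounds_j,
            options={"maxiter": maxiter, "ftol": 1e-12})
        f0, _ = _tobit_objective(theta0, o["X"], o["y"], Wj, lower, upper,
                                 at_l, at_u)
        if res.fun <= f0:
            q = params.beta[j].shape[1]
            beta[j] = res.x[: k * q].reshape(k, q)
            sigma[j] = float(np.exp(res.x[-1]))
        else:
            beta[j] = params.beta[j].copy()
            sigma[j] = params.sigma[j]

    return GbtmParameters(pi=pi, beta=beta, sigma=sigma, p_zero=p_zero,
                          bounds=params.bounds)


# ---------------------------------------------------------------------------
# initialisation and the EM driver

class _EmptyGroupError(RuntimeError):
    pass


def _initial_posteriors(data: _FitData, k: int, rng: np.random.Generator,
                        jitter: float) -> np.ndarray:
    """Soft one-hot posteriors from k-means on per-individual outcome means."""
    S = np.full((data.n, 3), np.nan)
    for c, j in enumerate(OUTCOME_COLUMNS):
        o = data.outcomes[j]
        sums = np.bincount(o["obs_i"], weights=o["y"], minlength=data.n)
        cnt = np.bincount(o["obs_i"], minlength=data.n)
        with np.errstate(invalid="ignore"):
            S[:, c] = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
    col_mean = np.nanmean(S, axis=0)
    S = np.where(np.isnan(S), col_mean, S)
    sd = S.std(axis=0)
    S = (S - S.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if jitter > 0:
        S = S + rng.normal(0.0, jitter, S.shape)
    km = KMeans(n_clusters=min(k, data.n), n_init=3,
                random_state=int(rng.integers(2**31 - 1)))
    labels = km.fit_predict(S)
    post = np.full((data.n, k), 0.05 / max(k - 1, 1))
    post[np.arange(data.n), labels % k] = 0.95
    return post / post.sum(axis=1, keepdims=True)


def _initial_params(data: _FitData, post: np.ndarray, spec: TrajectorySpec,
                    bounds=(0.0, 10.0)) -> GbtmParameters:
    k = spec.n_groups
    q = spec.polynomial_order + 1
    beta = {}
    sigma = {}
    o = data.outcomes["ajc"]
    W = post[o["obs_i"]]
    means = (W * o["y"][:, None]).sum(axis=0) / np.maximum(W.sum(axis=0), 1e-9)
    b = np.zeros((k, q))
    b[:, 0] = np.log(np.maximum(means, 0.05))
    beta["ajc"] = b
    for j in _VAS_OUTCOMES:
        o = data.outcomes[j]
        W = post[o["obs_i"]]
        means = (W * o["y"][:, None]).sum(axis=0) / np.maximum(W.sum(axis=0), 1e-9)
        b = np.zeros((k, q))
        b[:, 0] = means
        beta[j] = b
        resid = o["y"][:, None] - means[None, :]
        sigma[j] = float(np.sqrt((W * resid**2).sum() / max(W.sum(), 1e-9)))
        sigma[j] = float(np.clip(sigma[j], 0.3, 5.0))
    pi = np.clip(post.mean(axis=0), 1e-6, None)
    return GbtmParameters(pi=pi / pi.sum(), beta=beta, sigma=sigma,
                          p_zero=np.full(k, 0.2), bounds=bounds)


def _run_em(data: _FitData, params: GbtmParameters, tol: float,
            max_iter: int, m_maxiter: int):
    history = []
    converged = False
    post = None
    for it in range(max_iter):
        logp = np.log(params.pi) + _component_loglik(params, data)
        lse = special.logsumexp(logp, axis=1)
        ll = float(lse.sum())
        post = np.exp(logp - lse[:, None])
        history.append(ll)
        if len(history) > 1:
            prev = history[-2]
            if ll - prev < tol * (abs(prev) + 1.0):
                converged = True
                break
        if post.sum(axis=0).min() < 1.0 and params.n_groups > 1:
            raise _EmptyGroupError(
                f"group collapsed (posterior mass {post.sum(axis=0).min():.3f})")
        params = _m_step(params, data, post, maxiter=m_maxiter)
    return params, post, np.array(history), converged


def _canonical_order(params: GbtmParameters) -> np.ndarray:
    """Group order by ascending model-implied baseline cJADAS-10."""
    lam0 = np.exp(np.clip(params.beta["ajc"][:, 0], -_ETA_CLIP, _ETA_CLIP))
    total = np.minimum(zip_mean(lam0, params.p_zero), 10.0)
    lower, upper = params.bounds
    for j in _VAS_OUTCOMES:
        total = total + censnorm_mean(params.beta[j][:, 0], params.sigma[j],
                                      lower, upper)
    return np.argsort(total, kind="stable")


def fit_gbtm(cohort: CohortTable, spec: TrajectorySpec, n_starts: int = 20,
             seed: int = 0, tol: float = 1e-7, max_iter: int = 500,
             m_maxiter: int = 40, init_params: GbtmParameters | None = None) -> FitResult:
    """Fit the multivariate trajectory model by multi-start EM.

    Parameters
    ----------
    cohort
        Validated long-format cohort; individuals contribute whichever
        components they have observed.
    spec
        Number of groups and polynomial order (shared across outcomes).
    n_starts
        Independent k-means(+jitter) initialisations; the best final
        log-likelihood is returned.
    seed
        Master seed; start s uses a child generator seeded with seed + s.
    tol
        Relative log-likelihood convergence tolerance.
    init_params
        Optional warm start (e.g. a fit of the unperturbed cohort when
        re-fitting noisy copies); run as one extra deterministic start.
    """
    data = _FitData(cohort, order=spec.polynomial_order)
    k = spec.n_groups
    best = None

    starts: list = list(range(n_starts))
    if init_params is not None:
        starts = ["warm"] + starts
    for s in starts:
        if s == "warm":
            if init_params.n_groups != k or init_params.order != spec.polynomial_order:
                raise ValueError("init_params shape does not match spec")
            attempt_results = []
            try:
                attempt_results.append(
                    _run_em(data, init_params, tol, max_iter, m_maxiter))
            except _EmptyGroupError:
                pass
            results = attempt_results
            start_seed = -1
        else:
            start_seed = seed + s
            results = []
            for retry in range(3):       # re-seed if a group empties out
                rng = np.random.default_rng(start_seed + 10_000 * retry)
                jitter = 0.0 if s == 0 else 0.5
                post0 = _initial_posteriors(data, k, rng, jitter)
                params0 = _initial_params(data, post0, spec)
                params0 = _m_step(params0, data, post0, maxiter=m_maxiter)
                try:
                    results.append(_run_em(data, params0, tol, max_iter, m_maxiter))
                    break
                except _EmptyGroupError:
                    continue
        for params, post, history, converged in results:
            ll = history[-1]
            if best is None or ll > best[2][-1]:
                best = (params, post, history, converged, start_seed)

    if best is None:
        raise RuntimeError("all EM starts collapsed to empty groups")
    params, post, history, converged, start_seed = best

    order_idx = _canonical_order(params)
    params = params.permuted(order_idx)
    post = post[:, order_idx]
    assignment = assign_groups(post)
    app, app_overall = average_posterior_probability(post, assignment)
    n_params = params.n_free_params()
    ll = float(history[-1])
    return FitResult(
        params=params, loglik=ll, n_params=n_params,
        bic=bic(ll, n_params, data.n),
        posteriors=post, assignment=assignment,
        entropy=relative_entropy(post), app=app, app_overall=app_overall,
        converged=converged, n_starts=len(starts), best_start_seed=start_seed,
        n_iter=len(history), loglik_history=history, individual_ids=data.ids)
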