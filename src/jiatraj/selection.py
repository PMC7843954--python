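"""Model-adequacy filtering and BIC ranking over the trajectory-model grid.

A fitted model is excluded if it has a group representing less than 1% of
the cohort (by modal assignment), any group whose average posterior
probability falls below 0.70, or relative entropy below 0.5.  Surviving
models are ranked by BIC (lower is better), overall and within each
polynomial form.  The final choice between close candidates is a human
judgement of clinical plausibility, so near-ties (BIC within a configurable
margin) are reported, never resolved silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .gbtm import FitResult, TrajectorySpec, fit_gbtm

__all__ = ["AdequacyThresholds", "SelectionReport", "adequacy_filter", "run_grid"]


@dataclass(frozen=True)
class AdequacyThresholds:
    min_group_share: float = 0.01
    min_app: float = 0.70
    min_entropy: float = 0.5

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class SelectionReport:
    """Grid of fitted models with adequacy verdicts and BIC rankings."""

    grid: pd.DataFrame                  # one row per (order, K)
    best_per_order: dict                # order -> (order, K) of lowest-BIC adequate fit
    overall_ranking: list               # [(order, K), ...] adequate fits by ascending BIC
    tie_margin: float
    ties: list = field(default_factory=list)   # candidates within tie_margin of the best
    fits: dict = field(default_factory=dict)   # (order, K) -> FitResult

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(orient="records"),
            "best_per_order": {str(o): list(v) for o, v in self.best_per_order.items()},
            "overall_ranking": [list(v) for v in self.overall_ranking],
            "tie_margin": self.tie_margin,
            "ties": [list(v) for v in self.ties],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def adequacy_filter(fit: FitResult, n_individuals: int,
                    thresholds: AdequacyThresholds = AdequacyThresholds()):
    """Apply the three adequacy thresholds; returns ``(passes, reasons)``.

    Reasons are machine-readable: ``min_group_share`` (an assigned group has
    fewer than min_group_share·N members), ``low_app`` (some group's average
    posterior probability is below min_app), ``low_entropy`` (relative
    entropy below min_entropy).  Group share is computed from hard
    assignments — the criterion describes members of the cohort.
    """
    reasons = []
    sizes = fit.group_sizes()
    if sizes.min() < thresholds.min_group_share * n_individuals:
        reasons.append("min_group_share")
    app = fit.app[~np.isnan(fit.app)]
    if np.isnan(fit.app).any() or (app < thresholds.min_app).any():
        reasons.append("low_app")
    if fit.entropy < thresholds.min_entropy:
        reasons.append("low_entropy")
    return len(reasons) == 0, reasons


def run_grid(cohort: CohortTable, orders=(1, 2, 3), k_values=range(1, 11),
             thresholds: AdequacyThresholds = AdequacyThresholds(),
             n_starts: int = 5, seed: int = 0, tol: float = 1e-7,
             max_iter: int = 500, tie_margin: float = 10.0,
             cache_dir=None, keep_fits: bool = True) -> SelectionReport:
    """Fit every (polynomial order, K) combination and assemble the report.

    Individual fit failures are recorded in the grid, not fatal.  With
    ``cache_dir`` set, each fit's diagnostics are cached to JSON keyed by
    (order, K, seed) and reused on re-runs, making the grid resumable.
    """
    rows = []
    fits = {}
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    for order in orders:
        for k in k_values:
            key = (int(order), int(k))
            cache_file = (cache / f"fit_o{order}_k{k}_s{seed}.json"
                          if cache is not None else None)
            row = {"order": order, "K": k, "seed": seed}
            fit = None
            if cache_file is not None and cache_file.exists():
                cached = json.loads(cache_file.read_text())
                row.update(cached)
            else:
                try:
                    fit = fit_gbtm(cohort, TrajectorySpec(k, order),
                                   n_starts=n_starts, seed=seed, tol=tol,
                                   max_iter=max_iter)
                    ok, reasons = adequacy_filter(fit, fit.posteriors.shape[0],
                                                  thresholds)
                    row.update({
                        "bic": fit.bic, "loglik": fit.loglik,
                        "entropy": fit.entropy,
                        "min_app": float(np.nanmin(fit.app)),
                        "min_group_share": float(fit.group_sizes().min()
                                                 / fit.posteriors.shape[0]),
                        "converged": fit.converged,
                        "adequate": ok, "reasons": reasons, "error": None,
                    })
                except Exception as exc:  # a failed cell must not sink the grid
                    row.update({"bic": np.nan, "loglik": np.nan,
                                "entropy": np.nan, "min_app": np.nan,
                                "min_group_share": np.nan, "converged": False,
                                "adequate": False, "reasons": ["fit_error"],
                                "error": str(exc)})
                if cache_file is not None:
                    cache_file.write_text(json.dumps(
                        {k_: v for k_, v in row.items()
                         if k_ not in ("order", "K", "seed")}, default=str))
            if fit is not None and keep_fits:
                fits[key] = fit
            rows.append(row)

    grid = pd.DataFrame(rows)
    adequate = grid[grid["adequate"] & grid["bic"].notna()]
    ranking = [(int(r.order), int(r.K))
               for r in adequate.sort_values("bic").itertuples()]
    best_per_order = {}
    for order in orders:
        sub = adequate[adequate["order"] == order]
        if len(sub):
            r = sub.loc[sub["bic"].idxmin()]
            best_per_order[int(order)] = (int(r["order"]), int(r["K"]))
    ties = []
    if ranking:
        best_bic = adequate["bic"].min()
        ties = [(int(r.order), int(r.K)) for r in adequate.itertuples()
                if r.bic - best_bic <= tie_margin]
    return SelectionReport(grid=grid, best_per_order=best_per_order,
                           overall_ranking=ranking, tie_margin=tie_margin,
                           ties=ties, fits=fits)
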