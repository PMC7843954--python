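"""Post-hoc characterisation of clusters and trajectory groups.

Per-group descriptive summaries (median/IQR for continuous variables,
n (%) for categorical, with percentages over available data per variable),
univariable group comparisons (Kruskal–Wallis for continuous, Pearson χ² or
Fisher's exact for categorical), and the baseline-cluster × trajectory-group
mapping matrix that underlies the chord-diagram comparison of the two
clustering solutions.

No multiple-testing adjustment is applied: per-variable p-values are
reported as-is, descriptive convention for this kind of cohort table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupSummaryTable", "MappingMatrix", "group_summaries",
           "compare_continuous", "compare_categorical", "cross_tabulate"]


@dataclass
class GroupSummaryTable:
    table: pd.DataFrame            # one row per variable (or category)
    tests: pd.DataFrame            # variable, test_used, statistic, p_value


@dataclass
class MappingMatrix:
    counts: pd.DataFrame           # baseline clusters (rows) x trajectory groups
    row_percent: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def compare_continuous(values, groups):
    """Kruskal–Wallis H (tie-corrected) across groups; χ² p with K−1 df.

    Degenerate input — every value identical — returns (0.0, 1.0) rather
    than failing.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    samples = [values[groups == g] for g in pd.unique(groups)]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    stat, p = stats.kruskal(*samples)
    return float(stat), float(p)


def compare_categorical(table):
    """Group comparison for a contingency table of counts.

    Pearson χ² by default; Fisher's exact for 2×2 tables whenever any
    expected cell count is below 5 (Cochran's criterion) or any observed
    cell is empty (where the χ² approximation is unreliable).  Larger
    sparse tables keep the χ² with ``test_used = "chi2_low_expected"``
    flagging the approximation.  Zero-margin rows/columns are dropped first.

    Returns ``(statistic, p_value, test_used)``; Fisher's statistic is the
    conditional odds ratio.
    """
    t = np.asarray(table, dtype=float)
    if t.size == 0 or t.sum() == 0:
        raise ValueError("empty contingency table")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        # association is undefined with a single observed row/column
        return 0.0, 1.0, "degenerate"
    chi2, p, _, expected = stats.chi2_contingency(t, correction=False)
    if (expected < 5).any() or (t.shape == (2, 2) and (t == 0).any()):
        if t.shape == (2, 2):
            orat, p = stats.fisher_exact(t, alternative="two-sided")
            return float(orat), float(p), "fisher"
        return float(chi2), float(p), "chi2_low_expected"
    return float(chi2), float(p), "chi2"


def _is_categorical(series: pd.Series) -> bool:
    return (series.dtype == object or series.dtype == bool
            or isinstance(series.dtype, pd.CategoricalDtype))


def group_summaries(cohort, assignment, variables, group_names=None,
                    categorical=()) -> GroupSummaryTable:
    """Per-group baseline summaries and univariable tests.

    ``assignment`` maps individual_id -> group (a Series, or an array
    aligned with ``cohort.covariates``).  Continuous variables get median
    (IQR, linear-interpolation quantiles) and a Kruskal–Wallis test;
    categorical ones get n (%) per level — percentages over available data —
    and a χ²/Fisher test.  Numeric codes that should be treated as
    categories (e.g. deprivation quintiles) can be listed in ``categorical``.
    """
    cov = cohort.covariates if hasattr(cohort, "covariates") else pd.DataFrame(cohort)
    if isinstance(assignment, pd.Series):
        assign = assignment.reindex(cov.index)
    else:
        assign = pd.Series(np.asarray(assignment), index=cov.index)
    keep = assign.notna()
    cov, assign = cov.loc[keep], assign.loc[keep].astype(int)
    group_ids = np.sort(assign.unique())
    names = (list(group_names) if group_names is not None
             else [f"group{g}" for g in group_ids])

    rows, tests = [], []
    for var in variables:
        if var not in cov.columns:
            raise KeyError(f"unknown variable: {var}")
        col = cov[var]
        avail = col.notna()
        if avail.sum() == 0:
            rows.append({"variable": var, "level": None, "n_available": 0,
                         **{nm: None for nm in names}})
            continue
        if var in categorical or _is_categorical(col):
            ct = pd.crosstab(col[avail], assign[avail])
            ct = ct.reindex(columns=group_ids, fill_value=0)
            denom = ct.sum(axis=0)
            for level in ct.index:
                row = {"variable": var, "level": level,
                       "n_available": int(avail.sum())}
                for g, nm in zip(group_ids, names):
                    n = int(ct.loc[level, g])
                    pct = 100.0 * n / denom[g] if denom[g] else np.nan
                    row[nm] = f"{n} ({pct:.0f}%)"
                rows.append(row)
            stat, p, used = compare_categorical(ct.to_numpy().T)
            tests.append({"variable": var, "test_used": used,
                          "statistic": stat, "p_value": p})
        else:
            vals = col[avail].astype(float)
            row = {"variable": var, "level": None,
                   "n_available": int(avail.sum())}
            for g, nm in zip(group_ids, names):
                v = vals[assign[avail] == g]
                if len(v) == 0:
                    row[nm] = None
                else:
                    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
                    row[nm] = f"{med:.1f} ({q1:.1f}-{q3:.1f})"
            rows.append(row)
            if len(pd.unique(assign[avail])) >= 2:
                stat, p = compare_continuous(vals.to_numpy(),
                                             assign[avail].to_numpy())
                tests.append({"variable": var, "test_used": "kruskal",
                              "statistic": stat, "p_value": p})
    test_cols = ["variable", "test_used", "statistic", "p_value"]
    return GroupSummaryTable(table=pd.DataFrame(rows),
                             tests=pd.DataFrame(tests, columns=test_cols))


def cross_tabulate(baseline_assignment: pd.Series,
                   trajectory_assignment: pd.Series,
                   baseline_names=None, trajectory_names=None) -> MappingMatrix:
    """Count matrix mapping baseline clusters to trajectory groups.

    Both arguments are Series indexed by individual_id; counts are over the
    intersection of the two index sets.  Row percentages are also emitted
    (share of each baseline cluster landing in each trajectory group).
    """
    common = baseline_assignment.index.intersection(trajectory_assignment.index)
    if len(common) == 0:
        raise ValueError("assignments share no individuals")
    b = baseline_assignment.loc[common]
    t = trajectory_assignment.loc[common]
    counts = pd.crosstab(b, t)
    if baseline_names is not None:
        counts.index = [baseline_names[i] for i in counts.index]
    if trajectory_names is not None:
        counts.columns = [trajectory_names[i] for i in counts.columns]
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return MappingMatrix(counts=counts, row_percent=row_pct)
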