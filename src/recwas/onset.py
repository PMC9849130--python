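"""Age-at-first-diagnosis comparisons across genotype groups.

Wilcoxon rank-sum for pairwise group comparisons (exact enumeration for
small tie-free samples, normal approximation with continuity correction
otherwise), Cox proportional hazards (Efron ties) with the standard GWAS
covariates, and Kaplan-Meier curves with Greenwood confidence intervals.
Individuals never diagnosed are right-censored at their last observed age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 25  # exact rank-sum enumeration up to this per-group size (no ties)


@dataclass
class GroupComparison:
    statistic: float
    p: float
    summaries: dict  # group label -> {n, mean, sd, median}


def group_compare(a, b, labels: tuple[str, str] = ("group1", "group2"),
                  test: str = "wilcoxon") -> GroupComparison:
    """Two-sided rank-sum comparison of two value groups.

    Uses exact enumeration when both groups have <= 25 observations and the
    pooled values are tie-free, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    if test != "wilcoxon":
        raise ValueError(f"unsupported test {test!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    summaries = {lab: {"n": len(g), "mean": float(np.mean(g)), "sd": float(np.std(g, ddof=1)) if len(g) > 1 else 0.0,
                       "median": float(np.median(g))}
                 for lab, g in zip(labels, (a, b))}
    if np.all(pooled == pooled[0]):  # fully tied: no evidence either way
        return GroupComparison(statistic=len(a) * len(b) / 2.0, p=1.0, summaries=summaries)
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and max(len(a), len(b)) <= EXACT_MAX_N:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
    return GroupComparison(statistic=float(res.statistic), p=float(min(res.pvalue, 1.0)),
                           summaries=summaries)


def cox_onset(time, event, group, covariates: pd.DataFrame | None = None,
              reference: str = "wildtype") -> pd.DataFrame:
    """Cox proportional-hazards fit of onset age on genotype group.

    ``group`` holds labels (e.g. wildtype/het/hom); each non-reference
    level gets an indicator column.  Ties use the Efron approximation
    (lifelines default).  Returns a frame indexed by genotype level with
    columns ``hr``, ``ci_low``, ``ci_high``, ``p``, ``coef``, ``se``.
    """
    from lifelines import CoxPHFitter

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=object)
    if event.sum() == 0:
        raise ValueError("no events observed; cannot fit a Cox model")
    df = pd.DataFrame({"time": time, "event": event})
    levels = [g for g in pd.unique(group) if g != reference]
    for lev in levels:
        df[f"g_{lev}"] = (group == lev).astype(float)
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        if np.linalg.matrix_rank(cov.to_numpy(dtype=float)) < cov.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        df = pd.concat([df, cov], axis=1)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    rows = []
    for lev in levels:
        name = f"g_{lev}"
        coef = float(cph.params_[name])
        se = float(cph.standard_errors_[name])
        rows.append({"group": lev, "hr": float(np.exp(coef)),
                     "ci_low": float(np.exp(coef - 1.959963984540054 * se)),
                     "ci_high": float(np.exp(coef + 1.959963984540054 * se)),
                     "p": float(cph.summary.loc[name, "p"]), "coef": coef, "se": se})
    return pd.DataFrame(rows).set_index("group")


def km_curves(time, event, group) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier survival table per genotype group.

    Product-limit estimates with plain Greenwood 95% confidence intervals
    (linear scale, clipped to [0, 1]).  Each frame has columns ``time``,
    ``survival``, ``ci_low``, ``ci_high``, ``n_at_risk``, ``n_events``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=object)
    if len(time) == 0:
        raise ValueError("empty input; every group must be non-empty")
    out: dict[str, pd.DataFrame] = {}
    for lev in pd.unique(group):
        t = time[group == lev]
        e = event[group == lev]
        if len(t) == 0:
            raise ValueError(f"group {lev!r} is empty")
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        event_times = np.unique(t[e == 1])
        s = 1.0
        greenwood = 0.0
        rows = [{"time": 0.0, "survival": 1.0, "ci_low": 1.0, "ci_high": 1.0,
                 "n_at_risk": len(t), "n_events": 0}]
        for et in event_times:
            n_risk = int((t >= et).sum())
            d = int(((t == et) & (e == 1)).sum())
            s *= 1.0 - d / n_risk
            if n_risk > d:
                greenwood += d / (n_risk * (n_risk - d))
            var = s * s * greenwood
            half = 1.959963984540054 * np.sqrt(var)
            rows.append({"time": float(et), "survival": s,
                         "ci_low": max(0.0, s - half), "ci_high": min(1.0, s + half),
                         "n_at_risk": n_risk, "n_events": d})
        out[str(lev)] = pd.DataFrame(rows)
    return out
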