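"""Condition-level statistics: t tests, one-way ANOVA, bootstrap CIs, stars.

Group summaries are reported as the median with a seeded percentile
bootstrap confidence interval, and group differences with two-sided
one-sample/two-sample t tests or one-way ANOVA, mirroring the standard
presentation of high-content phenotype comparisons.  Significance stars
follow the usual four-level map (p < 0.05 / 0.01 / 0.001 / 0.0001).

Test statistics are computed from the closed-form expressions with
p-values from the corresponding scipy.stats distributions; the scipy
one-call equivalents serve as independent cross-checks in the test suite.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import StatsParams
from .errors import InputError, StatisticsError

__all__ = [
    "ConditionComparison",
    "one_sample_t",
    "two_sample_t",
    "one_way_anova",
    "anova_vs_control",
    "bootstrap_median_ci",
    "p_to_stars",
    "compare_conditions",
]


def _as_array(values, min_n: int, what: str) -> np.ndarray:
    x = np.asarray(list(values), dtype=np.float64)
    if x.ndim != 1:
        raise StatisticsError(f"{what}: expected a 1-D sample")
    if not np.all(np.isfinite(x)):
        raise StatisticsError(f"{what}: sample contains non-finite values")
    if x.size < min_n:
        raise StatisticsError(f"{what}: need at least {min_n} observations, got {x.size}")
    return x


def one_sample_t(values: Sequence[float], mu0: float) -> Tuple[float, int, float]:
    """Two-sided one-sample t test of mean == mu0.

    t = (mean - mu0) / (s / sqrt(n)), df = n - 1.
    """
    x = _as_array(values, 2, "one_sample_t")
    s = x.std(ddof=1)
    if s == 0:
        raise StatisticsError("one_sample_t: zero sample variance")
    n = x.size
    t = (x.mean() - mu0) / (s / math.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> Tuple[float, float, float]:
    """Two-sided two-sample t test (Welch by default).

    With ``equal_var`` the classical pooled-variance t is used; otherwise
    Welch's statistic with the Welch–Satterthwaite degrees of freedom.
    """
    xa = _as_array(a, 2, "two_sample_t")
    xb = _as_array(b, 2, "two_sample_t")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    na, nb = xa.size, xb.size
    if va + vb == 0:
        raise StatisticsError("two_sample_t: both samples have zero variance")
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df: float = na + nb - 2
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = (xa.mean() - xb.mean()) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def one_way_anova(groups: Sequence[Sequence[float]]) -> Tuple[float, int, int, float]:
    """Classical one-way ANOVA: F = MS_between / MS_within.

    Returns (F, df1, df2, p) with df1 = k - 1, df2 = N - k.
    """
    if len(groups) < 2:
        raise StatisticsError("one_way_anova: need at least 2 groups")
    xs = [_as_array(g, 2, "one_way_anova group") for g in groups]
    k = len(xs)
    ns = np.array([x.size for x in xs])
    N = int(ns.sum())
    grand = np.concatenate(xs).mean()
    ss_between = float(sum(n * (x.mean() - grand) ** 2 for n, x in zip(ns, xs)))
    ss_within = float(sum(((x - x.mean()) ** 2).sum() for x in xs))
    df1, df2 = k - 1, N - k
    if ss_within == 0:
        raise StatisticsError("one_way_anova: zero within-group variance")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def anova_vs_control(
    groups: Dict[str, Sequence[float]], control: str
) -> List[Tuple[str, float, float, float, float]]:
    """Each-treatment-vs-control t tests with the pooled ANOVA MS_within
    and Bonferroni correction over the k-1 comparisons.

    Returns rows (group, t, df, p_raw, p_bonferroni).
    """
    if control not in groups:
        raise StatisticsError(f"control group {control!r} not among groups")
    xs = {name: _as_array(g, 2, "anova_vs_control group") for name, g in groups.items()}
    ns = {name: x.size for name, x in xs.items()}
    N = sum(ns.values())
    k = len(xs)
    ms_within = sum(((x - x.mean()) ** 2).sum() for x in xs.values()) / (N - k)
    if ms_within == 0:
        raise StatisticsError("anova_vs_control: zero within-group variance")
    df = N - k
    out = []
    xc, nc = xs[control], ns[control]
    n_comp = k - 1
    for name, x in xs.items():
        if name == control:
            continue
        se = math.sqrt(ms_within * (1 / ns[name] + 1 / nc))
        t = (x.mean() - xc.mean()) / se
        p_raw = 2.0 * sps.t.sf(abs(t), df)
        out.append((name, float(t), float(df), float(p_raw), float(min(1.0, p_raw * n_comp))))
    return out


def bootstrap_median_ci(
    values: Sequence[float],
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> Tuple[float, float]:
    """Seeded percentile bootstrap CI for the median at level 1 - alpha."""
    x = _as_array(values, 3, "bootstrap_median_ci")
    if n_boot < 1000:
        raise StatisticsError("bootstrap_median_ci: n_boot must be >= 1000")
    if not 0 < alpha < 1:
        raise StatisticsError("bootstrap_median_ci: alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    medians = np.median(x[idx], axis=1)
    lo, hi = np.quantile(medians, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def p_to_stars(p: float) -> str:
    """Map a p-value to significance stars.

    p < 0.0001 -> "****", < 0.001 -> "***", < 0.01 -> "**", < 0.05 -> "*",
    otherwise "ns".
    """
    if not (isinstance(p, (int, float)) and 0.0 <= p <= 1.0):
        raise InputError(f"p-value must be in [0, 1], got {p!r}")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ConditionComparison:
    """One row of the condition-comparison table."""

    metric_name: str
    group: str
    n: int
    median: float
    ci_lo: float
    ci_hi: float
    test_name: str
    statistic: float
    df: float
    p_value: float
    stars: str

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "group": self.group,
            "n": self.n,
            "median": self.median,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "test": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p_value,
            "stars": self.stars,
        }


def compare_conditions(
    metrics: pd.DataFrame,
    metric: str,
    params: StatsParams = StatsParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Compare one metric across conditions.

    Excluded fields (zero nuclei) are dropped.  Two conditions are compared
    with a two-sample t test (Welch unless ``equal_var``); more than two
    with one-way ANOVA plus each-vs-control t tests (pooled MS_within,
    Bonferroni) when a control condition is named.  Every group row carries
    its median and seeded percentile-bootstrap CI.
    """
    if metric not in metrics.columns:
        raise InputError(f"metric {metric!r} not in metrics table")
    df = metrics
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    df = df.dropna(subset=[metric])
    groups = {str(c): sub[metric].to_numpy(dtype=float) for c, sub in df.groupby("condition", sort=True)}
    if len(groups) < 2:
        raise StatisticsError("compare_conditions: need at least 2 conditions")

    names = sorted(groups)
    control = params.control if params.control in groups else names[0]
    rows: List[ConditionComparison] = []

    if len(groups) == 2:
        other = [n for n in names if n != control][0]
        t, dof, p = two_sample_t(groups[other], groups[control], equal_var=params.equal_var)
        test = "two_sample_t"
        per_group = {other: (t, dof, p)}
        overall = (t, dof, p)
    else:
        f, df1, df2, p = one_way_anova([groups[n] for n in names])
        test = "one_way_anova"
        overall = (f, float(df1), p)
        per_group = {
            name: (t, dof, p_adj)
            for name, t, dof, _p_raw, p_adj in anova_vs_control(groups, control)
        }

    for i, name in enumerate(names):
        x = groups[name]
        lo, hi = bootstrap_median_ci(x, n_boot=params.n_boot, alpha=params.alpha, seed=seed + i)
        if name == control:
            stat, dof, p = overall
            label = test if len(groups) == 2 else "one_way_anova"
        else:
            stat, dof, p = per_group[name]
            label = test if len(groups) == 2 else "t_vs_control_bonferroni"
        rows.append(
            ConditionComparison(
                metric_name=metric,
                group=name,
                n=x.size,
                median=float(np.median(x)),
                ci_lo=lo,
                ci_hi=hi,
                test_name=label,
                statistic=stat,
                df=dof,
                p_value=p,
                stars=p_to_stars(min(1.0, p)),
            )
        )
    return pd.DataFrame([r.to_dict() for r in rows])
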