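"""Group statistics and significance reporting for figure-style tables.

Input is a tidy long-format table (a pandas ``DataFrame``) with one row per
measured cell or replicate: a ``group`` label, an optional second-factor
``condition`` label, and a numeric ``value``.  Outputs are per-group
means ± SEM and one- or two-way ANOVA with per-group significance flags
against a reference group at a stated alpha.

Pairwise flags use Welch t-tests without multiplicity correction by
default, matching the single-threshold reporting style common in figure
captions (e.g. ``* p < 0.01`` vs wild type); a Bonferroni option is
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    degenerate: bool = False
    # per-group Welch p-values and significance flags vs the reference group
    pairwise_p: Dict[str, float] = field(default_factory=dict)
    significant: Dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class TwoWayAnovaResult:
    F: Dict[str, float]   # keys: factor names and "interaction"
    p: Dict[str, float]
    significant: Dict[str, bool]


def _validate(table: pd.DataFrame, value: str, group: str) -> None:
    for col in (group, value):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    if table[group].nunique() < 2:
        raise ValueError("need >= 2 groups")


def summarize(table: pd.DataFrame, value: str = "value",
              group: str = "group") -> pd.DataFrame:
    """Per-group mean, SEM (sd/sqrt(n), ddof=1) and n.

    SEM is NaN (undefined) for singleton groups; the ``sem_defined`` column
    flags this.
    """
    if group not in table.columns or value not in table.columns:
        raise ValueError("table lacks required columns")
    rows = []
    for g, sub in table.groupby(group, sort=False):
        vals = sub[value].to_numpy(dtype=float)
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        rows.append({group: g, "mean": float(vals.mean()), "sem": sem,
                     "n": n, "sem_defined": n >= 2})
    return pd.DataFrame(rows)


def _oneway_F(groups) -> Tuple[float, int, int, bool]:
    """Classical one-way ANOVA F from explicit between/within sums of squares."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    N = int(ns.sum())
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(n * (g.mean() - grand) ** 2
                           for n, g in zip(ns, groups)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = k - 1, N - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, df_b, df_w, True   # all values identical
        return float("inf"), df_b, df_w, True
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, df_b, df_w, False


def anova_oneway(
    table: pd.DataFrame,
    alpha: float = 0.05,
    reference: Optional[str] = None,
    value: str = "value",
    group: str = "group",
    bonferroni: bool = False,
) -> AnovaResult:
    """One-way ANOVA with per-group flags against a reference.

    The omnibus F and p come from the classical between/within
    sums-of-squares decomposition.  If ``reference`` is given (e.g. the
    wild-type group), each other group is compared to it with a Welch
    t-test and flagged significant at ``alpha`` (optionally
    Bonferroni-corrected across the comparisons).
    """
    _validate(table, value, group)
    labels = list(table[group].unique())
    groups = [table.loc[table[group] == g, value].to_numpy(dtype=float)
              for g in labels]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2 for ANOVA")

    F, df_b, df_w, degenerate = _oneway_F(groups)
    if degenerate:
        p = 1.0 if F == 0.0 else 0.0
    else:
        p = float(sps.f.sf(F, df_b, df_w))

    pairwise_p: Dict[str, float] = {}
    significant: Dict[str, bool] = {}
    if reference is not None:
        if reference not in labels:
            raise ValueError(f"reference group {reference!r} not in table")
        ref_vals = groups[labels.index(reference)]
        others = [g for g in labels if g != reference]
        m = len(others)
        for g in others:
            vals = groups[labels.index(g)]
            if np.ptp(vals) == 0 and np.ptp(ref_vals) == 0:
                pw = 1.0 if vals[0] == ref_vals[0] else 0.0
            else:
                pw = float(sps.ttest_ind(vals, ref_vals, equal_var=False).pvalue)
            pairwise_p[g] = pw
            thresh = alpha / m if bonferroni else alpha
            significant[g] = pw < thresh

    return AnovaResult(F=F, p=p, df_between=df_b, df_within=df_w,
                       degenerate=degenerate, pairwise_p=pairwise_p,
                       significant=significant)


def anova_twoway(
    table: pd.DataFrame,
    alpha: float = 0.05,
    value: str = "value",
    factors: Tuple[str, str] = ("group", "condition"),
) -> TwoWayAnovaResult:
    """Two-way ANOVA (type II) with interaction for a (near-)balanced table.

    Returns main-effect and interaction F and p, with significance flags at
    ``alpha``.  Effects whose sum of squares is numerically zero relative to
    the total are reported as F = 0, p = 1 (covers noiseless additive or
    constant data where the F ratio is formally 0/0).  Raises ``ValueError``
    naming any empty factor-level cell.
    """
    fa, fb = factors
    for col in (fa, fb, value):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    la = list(table[fa].unique())
    lb = list(table[fb].unique())
    if len(la) < 2 or len(lb) < 2:
        raise ValueError("both factors need >= 2 levels")
    for a in la:
        for b in lb:
            if ((table[fa] == a) & (table[fb] == b)).sum() == 0:
                raise ValueError(f"missing cell: {fa}={a!r}, {fb}={b!r}")

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.rename(columns={fa: "_A", fb: "_B", value: "_y"})
    total_ss = float(((df["_y"] - df["_y"].mean()) ** 2).sum())
    model = smf.ols("_y ~ C(_A) * C(_B)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)

    key_map = {"C(_A)": fa, "C(_B)": fb, "C(_A):C(_B)": "interaction"}
    Fs: Dict[str, float] = {}
    ps: Dict[str, float] = {}
    sig: Dict[str, bool] = {}
    tol = 1e-12 * max(total_ss, 1.0)
    for row_key, name in key_map.items():
        ss = float(tab.loc[row_key, "sum_sq"])
        F = tab.loc[row_key, "F"]
        p = tab.loc[row_key, "PR(>F)"]
        if ss <= tol:
            F, p = 0.0, 1.0
        elif not np.isfinite(F):
            F, p = float("inf"), 0.0
        Fs[name] = float(F)
        ps[name] = float(p)
        sig[name] = ps[name] < alpha
    return TwoWayAnovaResult(F=Fs, p=ps, significant=sig)
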