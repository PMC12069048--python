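"""Group inference: ANOVA with the field's post-hoc conventions.

Dose-dependence designs use one-way fixed-effects ANOVA followed by the
Newman–Keuls (SNK) step-down studentized-range procedure; time-course
designs use two-way ANOVA (time × treatment, complete balanced design)
followed by Bonferroni-adjusted treated-vs-time-matched-control contrasts.
Significance is declared at α = 0.05 and rendered as asterisks in report
tables.  Fish are treated as independent units throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, ValidationError


@dataclass
class AnovaResult:
    """One effect row (one-way) or several (two-way: main effects +
    interaction), plus descriptive group statistics."""

    table: pd.DataFrame  # columns: effect, F, df1, df2, p
    group_means: dict
    group_sems: dict
    ms_within: float
    df_within: int
    group_ns: dict

    @property
    def F(self) -> float:
        return float(self.table["F"].iloc[0])

    @property
    def p(self) -> float:
        return float(self.table["p"].iloc[0])


@dataclass
class PosthocResult:
    """Pairwise decisions; ``table`` has one row per comparison."""

    method: str
    alpha: float
    table: pd.DataFrame

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.table[self.table["significant"]]
        return [(r.group1, r.group2) for r in sig.itertuples()]


def _group_arrays(groups: dict) -> tuple[list[str], list[np.ndarray]]:
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float).ravel() for g in labels]
    if len(arrays) < 2:
        raise DesignError("ANOVA needs at least 2 groups")
    for g, a in zip(labels, arrays):
        if len(a) < 2:
            raise DesignError(f"group {g!r} has fewer than 2 values")
    return labels, arrays


def one_way_anova(groups: dict) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    ``groups`` maps label → values.  F = MS_between / MS_within with the
    F-distribution p-value.
    """
    labels, arrays = _group_arrays(groups)
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    ms_within = ss_within / df_w
    f_res = sps.f_oneway(*arrays)
    table = pd.DataFrame(
        [{"effect": "group", "F": float(f_res.statistic), "df1": df_b,
          "df2": df_w, "p": float(f_res.pvalue)}]
    )
    return AnovaResult(
        table=table,
        group_means={g: float(a.mean()) for g, a in zip(labels, arrays)},
        group_sems={
            g: float(np.std(a, ddof=1) / np.sqrt(len(a)))
            for g, a in zip(labels, arrays)
        },
        ms_within=float(ms_within),
        df_within=df_w,
        group_ns={g: len(a) for g, a in zip(labels, arrays)},
    )


def newman_keuls(groups: dict, alpha: float = 0.05) -> PosthocResult:
    """Student–Newman–Keuls step-down studentized-range procedure.

    Means are sorted; the widest range is tested first and a pair is only
    tested when every enclosing range was rejected (step-down protection).
    The q statistic for a pair spanning r ordered means is referred to the
    studentized-range distribution with range parameter r.  Unbalanced
    groups use the harmonic mean of the pair's sizes (Tukey–Kramer-style).
    """
    anova = one_way_anova(groups)
    if anova.ms_within == 0:
        raise DesignError("MS_within is 0; Newman–Keuls is degenerate")
    labels = sorted(anova.group_means, key=anova.group_means.get)
    means = np.array([anova.group_means[g] for g in labels])
    ns = np.array([anova.group_ns[g] for g in labels])
    k = len(labels)

    sig = {}
    blocked = {}
    rows = []
    for span in range(k, 1, -1):  # widest ranges first
        for i in range(0, k - span + 1):
            j = i + span - 1
            n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
            se = np.sqrt(anova.ms_within / n_h)
            q = (means[j] - means[i]) / se
            p = float(sps.studentized_range.sf(q, span, anova.df_within))
            enclosing_retained = any(
                not sig[(a, b)]
                for (a, b) in sig
                if a <= i and b >= j and (a, b) != (i, j)
            )
            blocked[(i, j)] = enclosing_retained
            sig[(i, j)] = (p < alpha) and not enclosing_retained
            rows.append(
                {"group1": labels[i], "group2": labels[j], "span": span,
                 "q": float(q), "p": p, "blocked": enclosing_retained,
                 "significant": sig[(i, j)]}
            )
    return PosthocResult(method="newman-keuls", alpha=alpha,
                         table=pd.DataFrame(rows))


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    factor_a: str = "time_point",
    factor_b: str = "group",
) -> AnovaResult:
    """Two-way fixed-effects ANOVA on a complete balanced crossed design.

    Main effects and the interaction are computed from the balanced-design
    sums of squares via an OLS fit with interaction.  Incomplete or
    unbalanced designs are rejected rather than silently approximated.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ValidationError(f"column {col!r} missing from data")
    cells = data.groupby([factor_a, factor_b], observed=True).size()
    n_a = data[factor_a].nunique()
    n_b = data[factor_b].nunique()
    if len(cells) != n_a * n_b:
        raise DesignError("incomplete design: at least one time×treatment "
                          "cell is empty")
    if cells.nunique() != 1:
        raise DesignError("unbalanced design: cell sizes differ; "
                          "two_way_anova requires equal cell counts")
    df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = ols("_y ~ C(_a) * C(_b)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    effect_names = {
        "C(_a)": factor_a,
        "C(_b)": factor_b,
        "C(_a):C(_b)": f"{factor_a}:{factor_b}",
    }
    df_resid = int(aov.loc["Residual", "df"])
    rows = [
        {"effect": effect_names[idx], "F": float(aov.loc[idx, "F"]),
         "df1": int(aov.loc[idx, "df"]), "df2": df_resid,
         "p": float(aov.loc[idx, "PR(>F)"])}
        for idx in effect_names
    ]
    cell_means = data.groupby([factor_a, factor_b], observed=True)[value]
    return AnovaResult(
        table=pd.DataFrame(rows),
        group_means=cell_means.mean().to_dict(),
        group_sems=(cell_means.sem()).to_dict(),
        ms_within=float(aov.loc["Residual", "sum_sq"] / df_resid),
        df_within=df_resid,
        group_ns=cell_means.size().to_dict(),
    )


def _cellwise_anova(
    data: pd.DataFrame, value: str, factor_time: str, factor_group: str
) -> AnovaResult:
    """Cell means and pooled within-cell mean square for contrast tests.

    Equivalent to the two-way model's residual MS on a balanced design but
    also defined when a factor has a single level.
    """
    for col in (value, factor_time, factor_group):
        if col not in data.columns:
            raise ValidationError(f"column {col!r} missing from data")
    cells = data.groupby([factor_time, factor_group], observed=True)[value]
    sizes = cells.size()
    if (sizes < 2).any():
        raise DesignError("every time×treatment cell needs >= 2 values")
    ss_e = float(sum(((v - v.mean()) ** 2).sum() for _, v in cells))
    df_e = int(len(data) - len(sizes))
    return AnovaResult(
        table=pd.DataFrame(
            [{"effect": "cells", "F": float("nan"), "df1": len(sizes) - 1,
              "df2": df_e, "p": float("nan")}]),
        group_means=cells.mean().to_dict(),
        group_sems=cells.sem().to_dict(),
        ms_within=ss_e / df_e,
        df_within=df_e,
        group_ns=sizes.to_dict(),
    )


def bonferroni_vs_control(
    data: pd.DataFrame,
    value: str,
    control_label: str,
    factor_time: str = "time_point",
    factor_group: str = "group",
    alpha: float = 0.05,
) -> PosthocResult:
    """Treated-vs-time-matched-control contrasts with Bonferroni adjustment.

    Each treated cell is compared with the control cell at the same time
    point via a t contrast on the pooled within-cell mean square (the
    residual MS of the balanced two-way model); raw p-values are
    multiplied by the number of comparisons (capped at 1).
    """
    anova = _cellwise_anova(data, value, factor_time, factor_group)
    groups = [g for g in data[factor_group].unique() if g != control_label]
    if not groups:
        raise DesignError(f"no non-control groups to compare against "
                          f"{control_label!r}")
    times = list(data[factor_time].unique())
    comparisons = [(t, g) for t in times for g in groups]
    m = len(comparisons)
    rows = []
    for t, g in comparisons:
        key_c, key_t = (t, control_label), (t, g)
        if key_c not in anova.group_means:
            raise DesignError(f"missing control cell at time point {t!r}")
        diff = anova.group_means[key_t] - anova.group_means[key_c]
        se = np.sqrt(
            anova.ms_within
            * (1.0 / anova.group_ns[key_t] + 1.0 / anova.group_ns[key_c])
        )
        tstat = diff / se
        p_raw = float(2.0 * sps.t.sf(abs(tstat), anova.df_within))
        p_adj = min(1.0, p_raw * m)
        rows.append(
            {"time_point": t, "group1": control_label, "group2": g,
             "diff": float(diff), "t": float(tstat), "p_raw": p_raw,
             "p_adj": p_adj, "significant": p_adj < alpha}
        )
    return PosthocResult(method="bonferroni-vs-control", alpha=alpha,
                         table=pd.DataFrame(rows))


def asterisks(p: float, alpha: float = 0.05) -> str:
    """Figure-legend style significance marker: '*' when p < alpha."""
    return "*" if p < alpha else ""
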