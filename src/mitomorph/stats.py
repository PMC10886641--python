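"""Group statistics for per-cell morphometric and kinetic metrics.

The workflow mirrors a common bioimage-statistics protocol: a
Shapiro–Wilk normality gate per group, one- or two-way ANOVA with Tukey
pairwise comparisons judged against a Bonferroni-adjusted alpha
(alpha = 0.05 / number of pairwise comparisons — note this *stacks*
Bonferroni on top of Tukey, an unusually conservative double control
that is kept deliberately because it is the protocol being reproduced),
an unpaired two-sided Student's t-test for before/after-stress
contrasts, ANCOVA with donor age and sex as covariates, and fold-change
reporting rounded half-up to one decimal.

Array-level primitives (``shapiro_wilk``, ``one_way_anova``,
``unpaired_t``) are exposed for calibration studies; the record-level
functions operate on a tidy per-cell table with ``line`` and
``condition`` columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

ALPHA = 0.05

CELL_LINES = ("Control", "LRRK2", "PINK1", "PinkParkin", "A53T")
CONDITIONS = ("normal", "H2O2")


class CollinearityWarning(UserWarning):
    """Covariates confounded with the group factor (e.g. one donor/line)."""


# ---------------------------------------------------------------------------
# array-level primitives
# ---------------------------------------------------------------------------

def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p for one sample (n >= 3, non-degenerate)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError(f"Shapiro-Wilk needs >= 3 values, got {len(x)}")
    if np.ptp(x) == 0.0:
        raise ValueError("sample is degenerate (all values identical)")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p over >= 2 groups."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("one-way ANOVA needs >= 2 groups with >= 2 values each")
    res = sps.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def unpaired_t(a, b) -> tuple[float, float]:
    """Two-sided unpaired Student's t-test (equal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test needs >= 2 values per sample")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni_alpha(n_groups: int, alpha: float = ALPHA,
                     n_comparisons: int | None = None) -> float:
    """Per-comparison alpha for all pairwise comparisons among k groups.

    The comparison family defaults to all C(k, 2) pairs; a different
    family size can be passed explicitly (it is never inferred from the
    data).
    """
    m = n_comparisons if n_comparisons is not None else comb(n_groups, 2)
    if m < 1:
        raise ValueError("need at least one comparison")
    return alpha / m


# ---------------------------------------------------------------------------
# record-level workflow
# ---------------------------------------------------------------------------

def _require_columns(records: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"records table missing columns: {missing}")


def normality_gate(
    records: pd.DataFrame, metric: str, group_cols: list[str] | str = "line"
) -> pd.DataFrame:
    """Shapiro–Wilk per group; flags whether a parametric path is safe.

    Returns one row per group with W, p and ``normal`` (p > 0.05).  If
    any group fails, a warning is raised but the pipeline may proceed —
    the decision is surfaced, not enforced.
    """
    if isinstance(group_cols, str):
        group_cols = [group_cols]
    _require_columns(records, group_cols + [metric])
    rows = []
    for key, sub in records.groupby(group_cols, sort=True):
        vals = sub[metric].dropna().to_numpy()
        if len(vals) < 3:
            raise ValueError(
                f"group {key} has {len(vals)} values for {metric!r}; "
                "Shapiro-Wilk needs >= 3"
            )
        w, p = shapiro_wilk(vals)
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(group_cols, key))
            | {"metric": metric, "test": "ShapiroWilk", "n": len(vals),
               "statistic": w, "p_value": p, "normal": p > ALPHA}
        )
    report = pd.DataFrame(rows)
    if not report["normal"].all():
        bad = report.loc[~report["normal"], group_cols].to_records(index=False)
        warnings.warn(
            f"non-normal groups for {metric!r}: {list(bad)}; "
            "parametric tests may be inappropriate",
            UserWarning,
            stacklevel=2,
        )
    return report


def compare_groups(
    records: pd.DataFrame,
    metric: str,
    design: str = "one_way",
    group_col: str = "line",
    condition_col: str = "condition",
    alpha: float = ALPHA,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Omnibus ANOVA plus Tukey pairwise rows against a Bonferroni alpha.

    ``design="one_way"`` runs line-only ANOVA; ``design="two_way"`` fits
    ``metric ~ line * condition`` (type-II ANOVA) and errors on empty
    design cells.  Tukey comparisons are made between the levels of
    ``group_col`` and declared significant when the Tukey-adjusted
    p-value falls below alpha / (number of pairwise comparisons).
    """
    _require_columns(records, [group_col, metric])
    data = records.dropna(subset=[metric])
    levels = sorted(data[group_col].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups to compare")
    groups = [data.loc[data[group_col] == g, metric].to_numpy() for g in levels]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 values")
    adj_alpha = bonferroni_alpha(len(levels), alpha, n_comparisons)

    rows = []
    if design == "one_way":
        f, p = one_way_anova(groups)
        rows.append(
            {"metric": metric, "test": "ANOVA1", "groups": "|".join(map(str, levels)),
             "statistic": f, "p_value": p, "adjusted_alpha": alpha,
             "significant": p < alpha}
        )
    elif design == "two_way":
        _require_columns(records, [condition_col])
        cell_counts = data.groupby([group_col, condition_col], observed=True)[metric].count()
        full = len(levels) * data[condition_col].nunique()
        if (cell_counts < 2).any() or len(cell_counts) < full:
            raise ValueError(
                "two-way design has empty or singleton cells; "
                f"cell counts:\n{cell_counts}"
            )
        d = data.rename(columns={metric: "_y", group_col: "_g", condition_col: "_c"})
        model = smf.ols("_y ~ C(_g) * C(_c)", data=d).fit()
        table = sm.stats.anova_lm(model, typ=2)
        for term, label in [("C(_g)", group_col), ("C(_c)", condition_col),
                            ("C(_g):C(_c)", f"{group_col}x{condition_col}")]:
            rows.append(
                {"metric": metric, "test": "ANOVA2", "groups": label,
                 "statistic": float(table.loc[term, "F"]),
                 "p_value": float(table.loc[term, "PR(>F)"]),
                 "adjusted_alpha": alpha,
                 "significant": float(table.loc[term, "PR(>F)"]) < alpha}
            )
    else:
        raise ValueError(f"unknown design {design!r}")

    tukey = sps.tukey_hsd(*groups)
    ref_mean = float(np.mean(groups[0]))
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            p_ij = float(tukey.pvalue[i, j])
            rows.append(
                {"metric": metric, "test": "Tukey",
                 "groups": f"{levels[i]}|{levels[j]}",
                 "statistic": float(np.mean(groups[j]) - np.mean(groups[i])),
                 "p_value": p_ij, "adjusted_alpha": adj_alpha,
                 "significant": p_ij < adj_alpha}
            )
    report = pd.DataFrame(rows)
    if ref_mean > 0:
        means = {g: float(np.mean(v)) for g, v in zip(levels, groups)}
        report.attrs["group_means"] = means
    return report


def paired_condition_test(
    records: pd.DataFrame,
    metric: str,
    line: str,
    group_col: str = "line",
    condition_col: str = "condition",
    conditions: tuple[str, str] = CONDITIONS,
) -> pd.DataFrame:
    """Unpaired two-sided t-test between conditions within one cell line."""
    _require_columns(records, [group_col, condition_col, metric])
    sub = records[records[group_col] == line].dropna(subset=[metric])
    samples = []
    for cond in conditions:
        vals = sub.loc[sub[condition_col] == cond, metric].to_numpy()
        if len(vals) < 2:
            raise ValueError(
                f"line {line!r} is missing condition {cond!r} "
                f"(found {len(vals)} values)"
            )
        samples.append(vals)
    t, p = unpaired_t(*samples)
    return pd.DataFrame(
        [{"metric": metric, "test": "t_test",
          "groups": f"{line}:{conditions[0]}|{conditions[1]}",
          "statistic": t, "p_value": p, "adjusted_alpha": ALPHA,
          "significant": p < ALPHA}]
    )


def ancova_covariates(
    records: pd.DataFrame,
    metric: str,
    group_col: str = "line",
    age_col: str = "donor_age",
    sex_col: str = "donor_sex",
) -> pd.DataFrame:
    """ANCOVA: metric ~ line + age + sex + age:sex (type-II table).

    When donor age is constant within every line (one donor per line),
    age and line are perfectly confounded; the fit still runs on the
    reduced-rank design but a :class:`CollinearityWarning` is emitted
    and the report carries a ``confounded`` flag — a silent answer here
    would be misleading.
    """
    _require_columns(records, [group_col, age_col, sex_col, metric])
    data = records.dropna(subset=[metric]).rename(
        columns={metric: "_y", group_col: "_g", age_col: "_age", sex_col: "_sex"}
    )
    if data["_age"].isna().any() or data["_sex"].isna().any():
        raise ValueError("age and sex must be present for every record")
    per_line_ages = data.groupby("_g")["_age"].nunique()
    confounded = bool((per_line_ages == 1).any())
    if confounded:
        warnings.warn(
            "donor age is constant within at least one line "
            f"({list(per_line_ages[per_line_ages == 1].index)}): the age "
            "covariate is (partially) confounded with the line factor",
            CollinearityWarning,
            stacklevel=2,
        )
    model = smf.ols("_y ~ C(_g) + _age + C(_sex) + _age:C(_sex)", data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank-deficient designs warn internally
        table = sm.stats.anova_lm(model, typ=2)
    rows = []
    for term, label in [
        ("C(_g)", group_col), ("_age", age_col), ("C(_sex)", sex_col),
        ("_age:C(_sex)", f"{age_col}x{sex_col}"),
    ]:
        if term not in table.index:
            continue
        f = float(table.loc[term, "F"])
        p = float(table.loc[term, "PR(>F)"])
        rows.append(
            {"metric": metric, "test": "ANCOVA", "groups": label,
             "statistic": f, "p_value": p, "adjusted_alpha": ALPHA,
             "significant": (p < ALPHA) if np.isfinite(p) else False,
             "confounded": confounded}
        )
    report = pd.DataFrame(rows)
    report.attrs["params"] = dict(model.params)
    report.attrs["bse"] = dict(model.bse)
    return report


def fold_change(
    means: dict[str, float] | pd.Series, reference: str, decimals: int = 1
) -> pd.DataFrame:
    """Group mean / reference mean, rounded half-up to ``decimals``."""
    means = dict(means)
    if reference not in means:
        raise ValueError(f"reference group {reference!r} not in means")
    ref = means[reference]
    if ref == 0:
        raise ValueError("reference mean is zero")
    q = Decimal(1).scaleb(-decimals)
    rows = []
    for g, m in means.items():
        fc = m / ref
        rows.append(
            {"group": g, "mean": m, "reference": reference,
             "fold_change": float(Decimal(repr(fc)).quantize(q, ROUND_HALF_UP))}
        )
    return pd.DataFrame(rows)


def boxplot_metric(records: pd.DataFrame, metric: str, out_path,
                   group_col: str = "line", condition_col: str | None = None):
    """Basic box-plot export of one metric by group (and condition)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if condition_col and condition_col in records:
        keys = sorted(
            records.groupby([group_col, condition_col], observed=True).groups
        )
        data = [
            records[(records[group_col] == g) & (records[condition_col] == c)][metric].dropna()
            for g, c in keys
        ]
        labels = [f"{g}\n{c}" for g, c in keys]
    else:
        keys = sorted(records[group_col].unique())
        data = [records[records[group_col] == g][metric].dropna() for g in keys]
        labels = list(keys)
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
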