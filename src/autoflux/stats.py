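"""Statistical decision pipeline for LC3 turnover experiments.

The pipeline mirrors common practice for factorial blot designs: raw
LC3-II values are first screened with a two-way ANOVA (treatment x
inhibitor); when the interaction is significant the global treatment effect
is re-examined with one-way ANOVAs within each inhibitor level.  Flux,
formation and degradation are then compared between conditions with
one-tailed Student t-tests (two conditions) or a one-way ANOVA followed by
a Holm-Sidak post-hoc (three or more), and the formation/degradation/net
turnover ratios are compared to the basal reference value of 1 with
one-tailed one-sample t-tests.  Every p-value is labelled with a tier:
significant (p < 0.05), tendency (p < 0.1), or ns.

One-tailed directions are always supplied explicitly by the caller —
inferring the direction from the data after the fact doubles the type-I
error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "AnovaTable",
    "tier_label",
    "t_one_sample_vs_one",
    "t_two_sample",
    "anova_one_way",
    "anova_two_way",
    "holm_sidak",
    "normality_homoscedasticity",
    "decision_pipeline",
]

ALPHA_SIGNIFICANT = 0.05
ALPHA_TENDENCY = 0.1


class InsufficientDataError(ValueError):
    """Fewer observations, or less variance, than the test requires."""


class StatsValidationError(ValueError):
    """Malformed statistical input."""


def tier_label(p: float, alpha: float = ALPHA_SIGNIFICANT, tendency: float = ALPHA_TENDENCY) -> str:
    if p < alpha:
        return "significant"
    if p < tendency:
        return "tendency"
    return "ns"


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    tail: str  # "one" or "two"
    tier: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise StatsValidationError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class AnovaTable:
    """Per-effect decomposition: sum of squares, df, F and p per row."""

    table: pd.DataFrame  # index: effect names incl. "Residual"; cols: sum_sq, df, F, p

    @property
    def total_ss(self) -> float:
        return float(self.table["sum_sq"].sum())

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _result(name: str, t: float, df: tuple[float, ...], p: float, tail: str) -> StatResult:
    return StatResult(
        test_name=name,
        statistic=float(t),
        df=df,
        p_value=float(p),
        tail=tail,
        tier=tier_label(p),
    )


def t_one_sample_vs_one(values: Sequence[float], direction: str = "greater") -> StatResult:
    """One-tailed one-sample Student t-test of the mean against 1.

    Used for ratio-vs-basal comparisons: under the equilibrium assumption
    the basal value of every turnover ratio is 1.  ``direction="greater"``
    tests mean > 1, ``"less"`` tests mean < 1.
    """
    x = np.asarray(values, dtype=float)
    if direction not in ("greater", "less"):
        raise StatsValidationError(f"direction must be 'greater' or 'less', got {direction!r}")
    if len(x) < 2:
        raise InsufficientDataError(f"need >= 2 values, got {len(x)}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise InsufficientDataError(
            "zero variance: the t statistic is undefined (degenerate input)"
        )
    n = len(x)
    t = (x.mean() - 1.0) / (sd / np.sqrt(n))
    df = n - 1
    p = sps.t.sf(t, df) if direction == "greater" else sps.t.cdf(t, df)
    return _result("one-sample t vs 1", t, (float(df),), p, "one")


def t_two_sample(
    a: Sequence[float],
    b: Sequence[float],
    direction: str = "greater",
    paired: bool = False,
    welch: bool = False,
) -> StatResult:
    """One-tailed two-sample Student t-test of group b against group a.

    ``direction="greater"`` tests mean(b) > mean(a); ``"less"`` the reverse.
    Unpaired tests pool the variances (classic Student); Welch's unequal-
    variance form is available behind the ``welch`` flag.  Paired tests use
    the within-replicate difference scores.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if direction not in ("greater", "less"):
        raise StatsValidationError(f"direction must be 'greater' or 'less', got {direction!r}")
    if paired and len(a) != len(b):
        raise StatsValidationError(
            f"paired test needs equal lengths, got {len(a)} and {len(b)}"
        )
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 observations")
    if paired:
        diffs = b - a
        if np.std(diffs, ddof=1) == 0:
            raise InsufficientDataError("zero variance of paired differences")
        res = sps.ttest_rel(b, a, alternative=direction)
        df = (float(len(a) - 1),)
        name = "paired t"
    else:
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            raise InsufficientDataError("zero variance in both groups")
        res = sps.ttest_ind(b, a, equal_var=not welch, alternative=direction)
        if welch:
            df = (float(res.df),)
            name = "Welch t"
        else:
            df = (float(len(a) + len(b) - 2),)
            name = "two-sample t"
    return _result(name, res.statistic, df, res.pvalue, "one")


def anova_one_way(groups: Sequence[Sequence[float]]) -> AnovaTable:
    """One-way ANOVA with the standard between/within decomposition."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise StatsValidationError("need >= 2 groups")
    for i, g in enumerate(gs):
        if len(g) == 0:
            raise StatsValidationError(f"group {i} is empty")
    ns = [len(g) for g in gs]
    k, n = len(gs), sum(ns)
    if n < k + 1:
        raise InsufficientDataError(f"need > {k} total observations, got {n}")
    allx = np.concatenate(gs)
    grand = allx.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        raise InsufficientDataError(
            "zero within-group variance: F is undefined (degenerate input)"
        )
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    F = ms_b / ms_w
    p = sps.f.sf(F, df_b, df_w)
    table = pd.DataFrame(
        {
            "sum_sq": [ss_between, ss_within],
            "df": [df_b, df_w],
            "F": [F, np.nan],
            "p": [p, np.nan],
        },
        index=["Between", "Residual"],
    )
    return AnovaTable(table=table)


def anova_two_way(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "condition",
    factor_b: str = "inhibitor",
) -> AnovaTable:
    """Two-way factorial ANOVA with interaction (type-I SS; balanced designs).

    The interaction row is the screen for inhibitor-dependent treatment
    effects: a significant interaction means the treatment effect differs
    between BAF- and BAF+, and the factorial mean comparison should be
    replaced by per-level one-way analyses.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise StatsValidationError(f"column {col!r} missing from data")
    d = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"}).copy()
    d["_a"] = d["_a"].astype(str)
    d["_b"] = d["_b"].astype(str)
    la, lb = d["_a"].unique(), d["_b"].unique()
    if len(la) < 2 or len(lb) < 2:
        raise StatsValidationError("each factor needs >= 2 levels")
    counts = d.groupby(["_a", "_b"]).size()
    for a in la:
        for b in lb:
            if (a, b) not in counts.index:
                raise StatsValidationError(f"empty design cell ({a!r}, {b!r})")
    if (counts < 2).all() :
        raise InsufficientDataError(
            "interaction term needs replicate observations within cells"
        )
    model = ols("_y ~ C(_a) * C(_b)", data=d).fit()
    tab = sm.stats.anova_lm(model, typ=1)
    total = ((d["_y"] - d["_y"].mean()) ** 2).sum()
    if tab.loc["Residual", "sum_sq"] <= 1e-12 * max(total, 1.0):
        raise InsufficientDataError(
            "zero residual variance: the factorial model fits exactly (degenerate input)"
        )
    tab = tab.rename(
        index={"C(_a)": factor_a, "C(_b)": factor_b, "C(_a):C(_b)": f"{factor_a}:{factor_b}"},
        columns={"PR(>F)": "p"},
    )[["sum_sq", "df", "F", "p"]]
    return AnovaTable(table=tab)


def holm_sidak(p_values: Sequence[float], alpha: float = ALPHA_SIGNIFICANT) -> pd.DataFrame:
    """Holm's step-down procedure with Sidak-adjusted thresholds.

    With m hypotheses sorted by ascending raw p, the i-th adjusted value is
    ``1 - (1 - p_(i)) ** (m - i + 1)`` with a running maximum enforcing
    monotonicity; hypotheses are rejected while the adjusted p stays below
    alpha.  Returns a frame in the original input order with columns
    ``p_raw``, ``p_adjusted``, ``reject``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise StatsValidationError("no p-values supplied")
    if np.any((p < 0) | (p > 1)):
        raise StatsValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj_sorted = np.minimum(adj_sorted, 1.0)
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if adj_sorted[i] < alpha:
            reject_sorted[i] = True
        else:
            break
    adjusted = np.empty(m)
    reject = np.empty(m, dtype=bool)
    adjusted[order] = adj_sorted
    reject[order] = reject_sorted
    return pd.DataFrame({"p_raw": p, "p_adjusted": adjusted, "reject": reject})


def normality_homoscedasticity(groups: Sequence[Sequence[float]]) -> dict:
    """Advisory Shapiro-Wilk (per group, pooled residuals) and Levene checks.

    Reported for inspection only; no automatic nonparametric fallback is
    applied.
    """
    gs = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    resid = np.concatenate([g - g.mean() for g in gs])
    out: dict = {}
    if len(resid) >= 3 and np.std(resid) > 0:
        w, p = sps.shapiro(resid)
        out["shapiro"] = {"statistic": float(w), "p": float(p)}
    else:
        out["shapiro"] = None
    if len(gs) >= 2 and all(len(g) >= 2 for g in gs):
        w, p = sps.levene(*gs)
        out["levene"] = {"statistic": float(w), "p": float(p)}
    else:
        out["levene"] = None
    return out


@dataclass
class PipelineReport:
    """Structured output of :func:`decision_pipeline`."""

    two_way: AnovaTable
    interaction: StatResult
    one_way_by_inhibitor: dict[str, AnovaTable] = field(default_factory=dict)
    rate_tests: dict[str, object] = field(default_factory=dict)
    ratio_tests: dict[str, dict[str, StatResult]] = field(default_factory=dict)
    screening: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def all_tiers(self) -> dict[str, str]:
        tiers = {"interaction": self.interaction.tier}
        for name, res in self.rate_tests.items():
            if isinstance(res, StatResult):
                tiers[name] = res.tier
        for cond, tests in self.ratio_tests.items():
            for name, res in tests.items():
                tiers[f"{cond}:{name}"] = res.tier
        return tiers


def decision_pipeline(
    design_data: pd.DataFrame,
    estimates: pd.DataFrame,
    ratios: pd.DataFrame,
    reference: str = "EXP-",
    directions: dict[str, str] | None = None,
    paired: bool = False,
    alpha: float = ALPHA_SIGNIFICANT,
    posthoc: str = "vs_control",
) -> PipelineReport:
    """Run the full decision cascade on one experiment.

    Stage 1: two-way ANOVA on the raw normalised LC3-II table
    (treatment x inhibitor).  If the interaction is significant at
    ``alpha``, stage 2 re-tests the treatment effect with a one-way ANOVA
    within each inhibitor level.  Stage 3 compares flux/formation/
    degradation between conditions: a one-tailed two-sample t-test when
    there is a single treatment level, otherwise a one-way ANOVA followed
    by a Holm-Sidak post-hoc over per-condition comparisons
    (each-treatment-vs-control by default; ``posthoc="all_pairs"`` for all
    pairwise).  Stage 4 tests each condition's formation, degradation and
    net ratios against 1 with one-tailed one-sample t-tests.

    ``directions`` maps a quantity name (``"flux"``, ``"formation"``,
    ``"degradation"``, ``"formation_ratio"``, ``"degradation_ratio"``,
    ``"net_ratio"``) to ``"greater"``/``"less"``; unlisted quantities
    default to ``"greater"`` (stimulus expected to raise them), a choice
    the report records in its notes.
    """
    directions = dict(directions or {})
    report_notes: list[str] = []
    for q in ("flux", "formation", "degradation", "formation_ratio", "degradation_ratio", "net_ratio"):
        if q not in directions:
            directions[q] = "greater"
            report_notes.append(f"direction for {q!r} not configured; defaulted to 'greater'")

    # stage 1: factorial screen on raw values
    two_way = anova_two_way(design_data, value="value", factor_a="condition", factor_b="inhibitor")
    inter_row = two_way.table.loc["condition:inhibitor"]
    interaction = _result(
        "two-way ANOVA interaction",
        inter_row["F"],
        (float(inter_row["df"]), float(two_way.table.loc["Residual", "df"])),
        inter_row["p"],
        "two",
    )

    # stage 2: one-way treatment effect within inhibitor levels
    one_way_by_inh: dict[str, AnovaTable] = {}
    if interaction.p_value < alpha:
        for inh, sub in design_data.groupby("inhibitor"):
            groups = [g["value"].to_numpy() for _, g in sub.groupby("condition")]
            label = "BAF+" if inh else "BAF-"
            one_way_by_inh[label] = anova_one_way(groups)
    else:
        report_notes.append("interaction ns; one-way ANOVA branch skipped")

    conditions = [c for c in estimates["condition"].unique() if c != reference]
    est_by_cond = {c: estimates[estimates["condition"] == c] for c in estimates["condition"].unique()}
    basal = est_by_cond[reference]

    rate_tests: dict[str, object] = {}
    quantities = {"flux": "degradation", "formation": "formation", "degradation": "degradation"}
    if len(conditions) == 1:
        cond = conditions[0]
        for qname, col in quantities.items():
            a = basal.sort_values("replicate_id")[col].to_numpy()
            b = est_by_cond[cond].sort_values("replicate_id")[col].to_numpy()
            rate_tests[qname] = t_two_sample(a, b, direction=directions[qname], paired=paired)
    else:
        for qname, col in quantities.items():
            groups = [basal[col].to_numpy()] + [est_by_cond[c][col].to_numpy() for c in conditions]
            table = anova_one_way(groups)
            if posthoc == "vs_control":
                comparisons = [(reference, c) for c in conditions]
            else:
                labels = [reference] + conditions
                comparisons = [
                    (labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))
                ]
            raw_p = []
            for lo, hi in comparisons:
                res = t_two_sample(
                    est_by_cond[lo][col].to_numpy(),
                    est_by_cond[hi][col].to_numpy(),
                    direction=directions[qname],
                    paired=paired,
                )
                raw_p.append(res.p_value)
            hs = holm_sidak(raw_p, alpha=alpha)
            hs.index = [f"{lo} vs {hi}" for lo, hi in comparisons]
            hs["tier"] = [tier_label(p) for p in hs["p_adjusted"]]
            rate_tests[qname] = {"anova": table, "posthoc": hs}

    # stage 4: ratios vs the basal reference value of 1
    ratio_tests: dict[str, dict[str, StatResult]] = {}
    for cond in conditions:
        sub = ratios[ratios["condition"] == cond]
        tests: dict[str, StatResult] = {}
        for rname in ("formation_ratio", "degradation_ratio", "net_ratio"):
            vals = sub[rname].dropna().to_numpy()
            dropped = len(sub) - len(vals)
            if dropped:
                report_notes.append(
                    f"{cond}: {dropped} undefined {rname} value(s) excluded from the vs-1 test"
                )
            try:
                tests[rname] = t_one_sample_vs_one(vals, direction=directions[rname])
            except InsufficientDataError as e:
                report_notes.append(f"{cond}: {rname} vs 1 not testable ({e})")
        ratio_tests[cond] = tests

    screening = normality_homoscedasticity(
        [g["value"].to_numpy() for _, g in design_data.groupby(["condition", "inhibitor"])]
    )
    return PipelineReport(
        two_way=two_way,
        interaction=interaction,
        one_way_by_inhibitor=one_way_by_inh,
        rate_tests=rate_tests,
        ratio_tests=ratio_tests,
        screening=screening,
        notes=report_notes,
    )
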