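"""Group-comparison layer: normality gating, two-group tests, factorial ANOVA.

Mirrors the statistical workflow of small-cohort electrophysiology studies:
Shapiro–Wilk decides between parametric and non-parametric two-group tests
(unpaired two-tailed t vs Mann–Whitney, exact for n <= 8 per group without
ties); factorial comparisons use fixed-effects ANOVA (type-II sums of
squares) with Šídák or Tukey multiple-comparison adjustment.  α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st

from .errors import DesignError, InsufficientDataError, ParameterError

ALPHA = 0.05


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    adjusted: dict = field(default_factory=dict)      # comparison -> adjusted p
    adjust_method: str = ""
    group_stats: pd.DataFrame | None = None           # mean, sem, n per group
    table: pd.DataFrame | None = None                 # ANOVA table when applicable

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _group_summary(groups: dict) -> pd.DataFrame:
    rows = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        rows.append({"group": name, "n": v.size, "mean": v.mean(),
                     "sem": v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan})
    return pd.DataFrame(rows)


def normality_gate(*groups) -> str:
    """``"parametric"`` iff Shapiro–Wilk p >= 0.05 in every group."""
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 3:
            raise InsufficientDataError("normality gate needs >= 3 values per group")
        if np.ptp(g) == 0:
            continue  # constant data: SW undefined; treat as non-informative
        if st.shapiro(g).pvalue < ALPHA:
            return "nonparametric"
    return "parametric"


def compare_two_groups(values_a, values_b, label_a: str = "a",
                       label_b: str = "b") -> TestResult:
    """Two-tailed unpaired comparison, gated by Shapiro–Wilk normality."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    gate = normality_gate(a, b)
    if gate == "parametric":
        stat, p = st.ttest_ind(a, b)
        if np.isnan(p):  # zero pooled variance, identical groups
            stat, p = 0.0, 1.0
        name = "Student t (unpaired, two-tailed)"
    else:
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (max(a.size, b.size) <= 8 and not ties) else "auto"
        stat, p = st.mannwhitneyu(a, b, alternative="two-sided", method=method)
        name = "Mann-Whitney U"
    return TestResult(test=name, statistic=float(stat), p_value=float(p),
                      group_stats=_group_summary({label_a: a, label_b: b}))


def sidak_adjust(p_values) -> np.ndarray:
    """Šídák adjustment: p_adj = 1 − (1 − p)^m over m comparisons."""
    p = np.asarray(p_values, dtype=float)
    return 1.0 - (1.0 - p) ** p.size


def factorial_anova(table: pd.DataFrame, factors, value: str = "value",
                    posthoc: str = "sidak") -> TestResult:
    """Fixed-effects ANOVA (type II) with Šídák or Tukey post hoc tests.

    ``table`` holds one row per (animal, cell) with a ``value`` column and
    one column per factor.  A single factor routes to one-way ANOVA; the
    post hoc set is all pairwise comparisons of the first factor's levels
    within each cell of the remaining factors.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    factors = list(factors)
    if posthoc not in ("sidak", "tukey"):
        raise ParameterError(f"unknown posthoc {posthoc!r}")
    for f in factors:
        if table[f].nunique() < 2:
            raise DesignError(f"factor {f!r} needs >= 2 levels")
    sizes = table.groupby(factors, observed=True).size()
    full = 1
    for f in factors:
        full *= table[f].nunique()
    if len(sizes) < full:
        present = set(sizes.index if len(factors) > 1 else [(i,) for i in sizes.index])
        raise DesignError(f"design has empty cells; present cells: {sorted(present)}")

    df = table.rename(columns={value: "_y"})
    formula = "_y ~ " + " * ".join(f"C({f})" for f in factors)
    model = ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    main = anova.iloc[0]
    result = TestResult(
        test=f"{len(factors)}-way ANOVA (type II)",
        statistic=float(main["F"]), p_value=float(main["PR(>F)"]),
        adjust_method=posthoc, table=anova,
        group_stats=_group_summary(
            {str(k): g["_y"].values for k, g in df.groupby(factors[0], observed=True)}),
    )

    # Post hoc: pairwise comparisons of factor[0] within cells of the others.
    prim = factors[0]
    rest = factors[1:]
    cells = [(None, df)] if not rest else list(df.groupby(rest, observed=True))
    if posthoc == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        adjusted = {}
        for cell_key, cell in cells:
            if cell[prim].nunique() < 2:
                continue
            tk = pairwise_tukeyhsd(cell["_y"].values, cell[prim].astype(str).values)
            summary = pd.DataFrame(tk.summary().data[1:],
                                   columns=tk.summary().data[0])
            for _, row in summary.iterrows():
                tag = f"{row['group1']} vs {row['group2']}"
                if cell_key is not None:
                    tag += f" | {cell_key}"
                adjusted[tag] = float(row["p-adj"])
        result.adjusted = adjusted
    else:
        raw, names = [], []
        for cell_key, cell in cells:
            levels = sorted(cell[prim].unique(), key=str)
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    ga = cell.loc[cell[prim] == levels[i], "_y"].values
                    gb = cell.loc[cell[prim] == levels[j], "_y"].values
                    if min(ga.size, gb.size) < 2:
                        continue
                    _, p = st.ttest_ind(ga, gb)
                    raw.append(1.0 if np.isnan(p) else p)
                    tag = f"{levels[i]} vs {levels[j]}"
                    if cell_key is not None:
                        tag += f" | {cell_key}"
                    names.append(tag)
        adj = sidak_adjust(raw) if raw else []
        result.adjusted = {n: float(max(a, r))  # adjusted p >= raw p
                           for n, a, r in zip(names, adj, raw)}
    return result
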