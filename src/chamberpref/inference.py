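"""Treatment comparisons: ANOVA, Tukey HSD, and compact letter displays.

Responses (window-level unrest means or per-replicate permanence totals)
are compared across light and temperature treatments with one-way and
balanced two-factor ANOVA, followed by Tukey's honestly-significant-
difference test at alpha = 0.05.  Pairwise p-values come from the
studentized range distribution (Tukey-Kramer adjustment for unequal n),
and the results are summarised as a compact letter display: groups sharing
a letter are not significantly different.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "GroupedMeasurements",
    "AnovaResult",
    "FactorialAnovaResult",
    "PairwiseResult",
    "one_way_anova",
    "two_way_anova",
    "tukey_hsd",
    "letter_display",
]


@dataclass
class GroupedMeasurements:
    """Replicate measurements per (light, temperature) treatment cell."""

    cells: dict[tuple[str, str], list[float]]
    response: str = "response"
    units: str = ""

    def __post_init__(self) -> None:
        for key, vals in self.cells.items():
            arr = np.asarray(vals, dtype=float)
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite values in cell {key}")
            if len(arr) < 2:
                raise ValueError(f"cell {key} needs >= 2 values for a variance")

    @property
    def lights(self) -> list[str]:
        return sorted({k[0] for k in self.cells})

    @property
    def temperatures(self) -> list[str]:
        return sorted({k[1] for k in self.cells})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"light": l, "temperature": t, self.response: v}
            for (l, t), vals in self.cells.items()
            for v in vals
        ]
        return pd.DataFrame(rows)

    def by_factor(self, factor: str) -> dict[str, list[float]]:
        """Pool cells over the other factor: groups keyed by one factor's levels."""
        idx = {"light": 0, "temperature": 1}[factor]
        out: dict[str, list[float]] = {}
        for key, vals in self.cells.items():
            out.setdefault(key[idx], []).extend(vals)
        return out


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within


def one_way_anova(groups: Mapping[Hashable, Sequence[float]] | Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA over >= 2 groups of >= 2 values each.

    Returns the F statistic, its p-value from the F distribution, and the
    between/within sums of squares.  Degenerate data with zero variance
    both between and within groups yields NaN F (flagged, not an error).
    """
    vals = list(groups.values()) if isinstance(groups, Mapping) else list(groups)
    if len(vals) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(v, dtype=float) for v in vals]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs at least two values")
    grand = np.concatenate(arrs).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_between = len(arrs) - 1
    df_within = sum(len(a) for a in arrs) - len(arrs)
    if ss_within == 0 and ss_between == 0:
        return AnovaResult(np.nan, np.nan, df_between, df_within, 0.0, 0.0)
    if ss_within == 0:
        return AnovaResult(np.inf, 0.0, df_between, df_within, float(ss_between), 0.0)
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(float(F), p, df_between, df_within, float(ss_between), float(ss_within))


@dataclass
class FactorialAnovaResult:
    """Balanced two-factor ANOVA table: light, temperature, interaction."""

    table: pd.DataFrame  # index: light, temperature, interaction, residual; cols: ss, df, F, p
    ss_total: float

    def F(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def ss(self, term: str) -> float:
        return float(self.table.loc[term, "ss"])


def two_way_anova(data: GroupedMeasurements) -> FactorialAnovaResult:
    """Balanced two-factor ANOVA with interaction, via an OLS fit.

    Requires a complete, balanced light x temperature table (the study's
    3 x 3 design with equal replicates); unbalanced or incomplete data is
    rejected rather than silently switching sums-of-squares types — in the
    balanced case all SS types coincide.
    """
    lights, temps = data.lights, data.temperatures
    expected = set(itertools.product(lights, temps))
    if set(data.cells) != expected:
        missing = sorted(expected - set(data.cells))
        raise ValueError(f"missing treatment cells: {missing}")
    sizes = {len(v) for v in data.cells.values()}
    if len(sizes) != 1:
        raise ValueError(f"unbalanced design: cell sizes {sorted(sizes)}")
    df = data.to_frame().rename(columns={data.response: "y"})
    model = ols("y ~ C(light) * C(temperature)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    table = pd.DataFrame(
        {
            "ss": [
                aov.loc["C(light)", "sum_sq"],
                aov.loc["C(temperature)", "sum_sq"],
                aov.loc["C(light):C(temperature)", "sum_sq"],
                aov.loc["Residual", "sum_sq"],
            ],
            "df": [
                aov.loc["C(light)", "df"],
                aov.loc["C(temperature)", "df"],
                aov.loc["C(light):C(temperature)", "df"],
                aov.loc["Residual", "df"],
            ],
            "F": [
                aov.loc["C(light)", "F"],
                aov.loc["C(temperature)", "F"],
                aov.loc["C(light):C(temperature)", "F"],
                np.nan,
            ],
            "p": [
                aov.loc["C(light)", "PR(>F)"],
                aov.loc["C(temperature)", "PR(>F)"],
                aov.loc["C(light):C(temperature)", "PR(>F)"],
                np.nan,
            ],
        },
        index=["light", "temperature", "interaction", "residual"],
    )
    y = df["y"].to_numpy()
    ss_total = float(((y - y.mean()) ** 2).sum())
    return FactorialAnovaResult(table=table, ss_total=ss_total)


@dataclass(frozen=True)
class PairwiseResult:
    """One Tukey HSD comparison between two groups."""

    group_i: Hashable
    group_j: Hashable
    mean_diff: float  # mean_i - mean_j
    q: float  # studentized range statistic
    p_adj: float
    significant: bool
    alpha: float = 0.05


def tukey_hsd(
    groups: Mapping[Hashable, Sequence[float]],
    alpha: float = 0.05,
) -> list[PairwiseResult]:
    """Tukey HSD over all group pairs at familywise level ``alpha``.

    q = |mean_i - mean_j| / sqrt( MSW/2 * (1/n_i + 1/n_j) ) with MSW the
    pooled within-group mean square; p-values come from the studentized
    range distribution with (k, N-k) parameters.  Unequal group sizes use
    the Tukey-Kramer form above.  With MSW = 0 every pair of distinct
    means is significant with p -> 0 (degenerate but well-defined).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrs = {g: np.asarray(groups[g], dtype=float) for g in names}
    if any(len(a) < 2 for a in arrs.values()):
        raise ValueError("each group needs at least two values")
    k = len(names)
    N = sum(len(a) for a in arrs.values())
    df_w = N - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrs.values()) / df_w
    out: list[PairwiseResult] = []
    for gi, gj in itertools.combinations(names, 2):
        ai, aj = arrs[gi], arrs[gj]
        diff = float(ai.mean() - aj.mean())
        if msw == 0:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt(msw / 2 * (1 / len(ai) + 1 / len(aj)))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_w))
            p = min(max(p, 0.0), 1.0)
        out.append(
            PairwiseResult(
                group_i=gi,
                group_j=gj,
                mean_diff=diff,
                q=float(q),
                p_adj=p,
                significant=bool(p < alpha),
                alpha=alpha,
            )
        )
    return out


def pairwise_to_frame(results: Sequence[PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_i": r.group_i,
                "group_j": r.group_j,
                "mean_diff": r.mean_diff,
                "q": r.q,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def letter_display(
    results: Sequence[PairwiseResult],
    letters: str = string.ascii_lowercase,
) -> dict[Hashable, str]:
    """Compact letter display: groups share a letter iff not significantly different.

    Uses the insert-and-absorb algorithm: start with one letter column per
    significant pair's separation, then merge redundant columns, yielding a
    minimal (or near-minimal) set of letters consistent with the
    non-significance graph.
    """
    groups: list[Hashable] = []
    for r in results:
        for g in (r.group_i, r.group_j):
            if g not in groups:
                groups.append(g)
    sig = {frozenset((r.group_i, r.group_j)) for r in results if r.significant}

    # columns: sets of groups allowed to share a letter
    columns: list[set[Hashable]] = [set(groups)]
    for pair in sig:
        a, b = tuple(pair)
        new_cols: list[set[Hashable]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop columns contained in another
        columns = [
            c for i, c in enumerate(new_cols)
            if not any(i != j and c < d or (c == d and i > j) for j, d in enumerate(new_cols))
        ]
    # a column is only useful if it is maximal w.r.t. the non-significance graph;
    # ensure every group appears in at least one column
    for g in groups:
        if not any(g in c for c in columns):
            columns.append({g})
    columns.sort(key=lambda c: [groups.index(g) for g in sorted(c, key=groups.index)])
    display = {g: "" for g in groups}
    for letter, col in zip(letters, columns):
        for g in groups:
            if g in col:
                display[g] += letter
    return display
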