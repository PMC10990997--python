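"""Group statistics for the blood-flow study.

Reproduces the study's analysis: mean ± SEM group summaries, one-way
ANOVA for hemodynamic-style comparisons, a per-region 2×2
strain × treatment ANOVA with Tukey HSD over the four cell means for
the flow data, percent differences between group means, and the
phospho/total normalization + testing branch for Western-blot
densitometry.

The two-way ANOVA table comes from an OLS fit with type-II sums of
squares (identical to type I/III on balanced layouts; type II is the
documented choice when cells are unbalanced).  Tukey HSD p-values use
the exact studentized-range distribution via :func:`scipy.stats.tukey_hsd`,
with Tukey–Kramer standard errors for unequal cell sizes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ValidationError

__all__ = [
    "GroupSummary",
    "FactorEffect",
    "GroupComparisonResult",
    "summarize",
    "one_way_anova",
    "two_way_anova_tukey",
    "tukey_hsd",
    "percent_difference",
    "blot_normalize_and_test",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SEM for one group; SEM = sample SD (n−1 denominator) / √n."""

    group: str
    n: int
    mean: float
    sem: float
    units: str = ""


@dataclass(frozen=True)
class FactorEffect:
    """One line of an ANOVA table."""

    name: str
    F: float
    df_num: float
    df_den: float
    p: float


@dataclass
class GroupComparisonResult:
    """ANOVA effects plus a Tukey pairwise table at significance level α."""

    effects: list[FactorEffect]
    tukey: Optional[pd.DataFrame]  # group1, group2, meandiff, p_adj, significant
    alpha: float = DEFAULT_ALPHA
    summaries: list[GroupSummary] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def effect(self, name: str) -> FactorEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def pair(self, group1: str, group2: str) -> pd.Series:
        """Tukey row for an unordered pair of group labels."""
        if self.tukey is None:
            raise ValidationError("no Tukey table in this result")
        t = self.tukey
        m = ((t.group1 == group1) & (t.group2 == group2)) | (
            (t.group1 == group2) & (t.group2 == group1)
        )
        if not m.any():
            raise KeyError((group1, group2))
        return t[m].iloc[0]

    def pair_significant(self, group1: str, group2: str) -> bool:
        return bool(self.pair(group1, group2).significant)


def summarize(
    values_by_group: Mapping[str, Sequence[float]], units: str = ""
) -> list[GroupSummary]:
    """Per-group mean and standard error of the mean."""
    out = []
    for name, values in values_by_group.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValidationError(f"group {name!r} is empty")
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        out.append(GroupSummary(group=str(name), n=int(v.size), mean=float(v.mean()),
                                sem=sem, units=units))
    return out


@lru_cache(maxsize=256)
def _q_critical(alpha: float, k: int, df: int) -> float:
    """Upper-α studentized-range quantile (cached: the ppf is expensive)."""
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_hsd(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Tukey HSD over all group pairs, exact studentized-range p-values.

    Uses the pooled within-group mean square with N−k degrees of freedom
    and Tukey–Kramer standard errors ``sqrt(MSE/2·(1/nᵢ + 1/nⱼ))`` when
    group sizes differ.  Returns a table with columns ``group1, group2,
    meandiff, p_adj, ci_lower, ci_upper, significant``
    (significant ⇔ p_adj < α).
    """
    names = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(names) < 2 or any(a.size < 2 for a in arrays):
        raise ValidationError("Tukey HSD needs >= 2 groups with >= 2 values each")
    k = len(arrays)
    df = sum(a.size for a in arrays) - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
    pairs = list(itertools.combinations(range(k), 2))
    diffs = np.array([arrays[i].mean() - arrays[j].mean() for i, j in pairs])
    ses = np.array([
        np.sqrt(mse / 2.0 * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        for i, j in pairs
    ])
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.abs(diffs) / ses
    q = np.where(np.isfinite(q), q, np.inf)
    p_adj = np.where(np.isinf(q) & (np.abs(diffs) > 0), 0.0,
                     np.clip(sps.studentized_range.sf(np.where(np.isfinite(q), q, 0.0),
                                                      k, df), 0.0, 1.0))
    p_adj = np.where(np.isinf(q) & (np.abs(diffs) == 0), 1.0, p_adj)
    q_crit = _q_critical(alpha, k, df)
    half = q_crit * ses
    table = pd.DataFrame({
        "group1": [names[i] for i, _ in pairs],
        "group2": [names[j] for _, j in pairs],
        "meandiff": diffs,
        "p_adj": p_adj,
        "ci_lower": diffs - half,
        "ci_upper": diffs + half,
    })
    table["significant"] = table.p_adj < alpha
    return table


def one_way_anova(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
    *,
    tukey: bool = True,
) -> GroupComparisonResult:
    """Classical one-way ANOVA (between/within decomposition) with optional Tukey."""
    names = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValidationError("one-way ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every group needs at least 2 values")
    notes: list[str] = []
    if all(a.std() == 0 for a in arrays):
        # zero within-group variance: F degenerates; p -> 0 iff means differ
        means = [a.mean() for a in arrays]
        if np.ptp(means) > 0:
            F, p = float("inf"), 0.0
            notes.append("degenerate data: zero within-group variance with "
                         "unequal means; p reported as the 0 limit")
        else:
            F, p = 0.0, 1.0
            notes.append("degenerate data: all values identical")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", sps.ConstantInputWarning)
            F, p = sps.f_oneway(*arrays)
    k = len(arrays)
    N = sum(a.size for a in arrays)
    result = GroupComparisonResult(
        effects=[FactorEffect("group", float(F), k - 1, N - k, float(p))],
        tukey=None,
        alpha=alpha,
        summaries=summarize(values_by_group),
        warnings=notes,
    )
    if tukey and all(np.asarray(a).std() > 0 for a in arrays):
        try:
            result.tukey = tukey_hsd(values_by_group, alpha)
        except ValidationError:
            pass
    return result


def _cell_label(strain: str, treatment: str) -> str:
    return f"{strain}:{treatment}"


def two_way_anova_tukey(
    data: pd.DataFrame,
    value_col: str,
    alpha: float = DEFAULT_ALPHA,
    factors: tuple[str, str] = ("strain", "treatment"),
) -> GroupComparisonResult:
    """2×2 factorial ANOVA with Tukey HSD over the four cell means.

    ``data`` is a tidy table with one row per animal carrying both factor
    columns and the response.  Main effects and the interaction come from
    an OLS fit with type-II sums of squares; the Tukey table compares all
    six pairs of strain:treatment cells.
    """
    fa, fb = factors
    for col in (fa, fb, value_col):
        if col not in data.columns:
            raise ValidationError(f"column {col!r} missing from input table")
    levels_a = sorted(data[fa].unique())
    levels_b = sorted(data[fb].unique())
    cells = {
        (a, b): data.loc[(data[fa] == a) & (data[fb] == b), value_col].to_numpy(float)
        for a in levels_a for b in levels_b
    }
    missing = [c for c, v in cells.items() if v.size == 0]
    if missing:
        raise ValidationError(f"missing design cells: {missing}")
    if any(v.size < 2 for v in cells.values()):
        raise ValidationError("every design cell needs at least 2 animals")
    notes: list[str] = []
    sizes = {v.size for v in cells.values()}
    if len(sizes) > 1:
        notes.append("unbalanced cells: type-II sums of squares used")

    df = data[[fa, fb, value_col]].rename(columns={fa: "A", fb: "B", value_col: "y"})
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_den = float(table.loc["Residual", "df"])
    effects = []
    for label, name in (("C(A)", fa), ("C(B)", fb), ("C(A):C(B)", f"{fa}:{fb}")):
        row = table.loc[label]
        effects.append(FactorEffect(name=name, F=float(row.F), df_num=float(row.df),
                                    df_den=df_den, p=float(row["PR(>F)"])))

    by_cell = {_cell_label(a, b): v for (a, b), v in cells.items()}
    return GroupComparisonResult(
        effects=effects,
        tukey=tukey_hsd(by_cell, alpha),
        alpha=alpha,
        summaries=summarize(by_cell),
        warnings=notes,
    )


def percent_difference(reference_mean: float, comparison_mean: float) -> float:
    """100·(comparison − reference)/reference."""
    if reference_mean <= 0:
        raise ValidationError("reference mean must be > 0")
    return 100.0 * (comparison_mean - reference_mean) / reference_mean


def blot_normalize_and_test(
    blots: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> dict[str, GroupComparisonResult]:
    """Phospho/total normalization followed by 2×2 ANOVA + Tukey, per marker.

    ``blots`` is a tidy table with columns ``animal_id, strain, treatment,
    marker, phospho, total``.  Each animal's phosphorylation signal is
    normalized to its total-protein signal, and the ratios are tested in
    the same strain × treatment layout as the flow data (n = 3 per group
    in the study's design).
    """
    required = {"strain", "treatment", "marker", "phospho", "total"}
    missing = required - set(blots.columns)
    if missing:
        raise ValidationError(f"blot table missing columns: {sorted(missing)}")
    if (blots.total <= 0).any():
        raise ValidationError("all total-protein signals must be > 0")
    work = blots.copy()
    work["ratio"] = work.phospho / work.total
    return {
        str(marker): two_way_anova_tukey(sub, "ratio", alpha)
        for marker, sub in work.groupby("marker")
    }
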