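"""Treatment-effect statistics.

One-way ANOVA is available through two equivalent routes: from raw
plot-level data and from printed group summaries (means, standard
deviations, equal n).  The summary route exists because agronomy papers
print exactly those summaries; for a balanced design the two routes agree
identically, since the between-group mean square depends only on the group
means and the within-group mean square is the average group variance.

Also here: fixed-effects two-way ANOVA (treatment x depth with
interaction), compact-letter multiple-comparison displays, percent change
vs a reference treatment, and Shapiro-Wilk normality checks.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "anova_from_summary",
    "anova_from_raw",
    "two_way_anova",
    "pairwise_significant",
    "tukey_letters",
    "percent_change",
    "percent_change_range",
    "normality_check",
    "format_p",
]


@dataclass(frozen=True)
class GroupSummary:
    """Equal-n group summaries: labels, means, SDs, replicate count."""

    labels: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    n: int

    def __post_init__(self):
        k = len(self.labels)
        if k < 2:
            raise ValueError("need at least 2 groups")
        if len(self.means) != k or len(self.sds) != k:
            raise ValueError("labels, means and sds must have equal length")
        if self.n < 2:
            raise ValueError("need at least 2 replicates per group")
        if any(s < 0 for s in self.sds):
            raise ValueError("standard deviations must be >= 0")

    @classmethod
    def from_raw(cls, groups: dict[str, np.ndarray]) -> "GroupSummary":
        sizes = {len(v) for v in groups.values()}
        if len(sizes) != 1:
            raise ValueError("groups must have equal n")
        (n,) = sizes
        labels = tuple(groups)
        return cls(
            labels=labels,
            means=tuple(float(np.mean(groups[g])) for g in labels),
            sds=tuple(float(np.std(groups[g], ddof=1)) for g in labels),
            n=n,
        )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    MSB: float
    MSW: float

    def __str__(self) -> str:
        return (
            f"F({self.df_between},{self.df_within}) = {self.F:.3f}, "
            f"p = {format_p(self.p)}"
        )


def format_p(p: float, decimals: int = 3) -> str:
    """Format a p-value to ``decimals`` places, '<0.001'-style below range."""
    floor = 10.0 ** (-decimals)
    if p < floor:
        return f"<{floor:.{decimals}f}"
    return f"{p:.{decimals}f}"


def anova_from_summary(summary: GroupSummary) -> AnovaResult:
    """One-way ANOVA reconstructed from group means, SDs and equal n.

    MSB = n * sum((m_i - m_bar)^2) / (k - 1); MSW = mean(SD_i^2);
    F = MSB / MSW with (k-1, k(n-1)) degrees of freedom.
    """
    means = np.asarray(summary.means, dtype=float)
    sds = np.asarray(summary.sds, dtype=float)
    k, n = len(means), summary.n
    df_b, df_w = k - 1, k * (n - 1)
    msb = n * float(np.sum((means - means.mean()) ** 2)) / df_b
    msw = float(np.mean(sds**2))
    if msw == 0.0:
        if msb == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0, 0.0, 0.0)
        return AnovaResult(math.inf, df_b, df_w, 0.0, msb, 0.0)
    f = msb / msw
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(f, df_b, df_w, p, msb, msw)


def _groups_from_dataset(dataset, variable: str, depth: str | None):
    table = dataset.records
    sel = table[table["variable"] == variable]
    if depth is not None:
        sel = sel[sel["depth"] == depth]
    if sel.empty:
        raise KeyError(f"no observations for variable {variable!r} at depth {depth!r}")
    return {t: g["value"].to_numpy(float) for t, g in sel.groupby("treatment", sort=False)}


def anova_from_raw(dataset, variable: str, depth: str | None = None) -> AnovaResult:
    """One-way ANOVA on plot-level values of one variable (one depth).

    For balanced groups this equals :func:`anova_from_summary` applied to
    the empirical group means and SDs.
    """
    groups = _groups_from_dataset(dataset, variable, depth)
    return anova_from_summary(GroupSummary.from_raw(groups))


def two_way_anova(dataset, variable: str) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA: treatment, depth and interaction.

    Requires a balanced treatment x depth design.  Returns a table with
    sum_sq, df, F and p for each term plus the residual row.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    table = dataset.records
    sel = table[table["variable"] == variable][["treatment", "depth", "value"]].copy()
    if sel.empty:
        raise KeyError(f"no observations for variable {variable!r}")
    counts = sel.groupby(["treatment", "depth"], sort=False).size()
    if counts.nunique() != 1:
        raise ValueError("two-way ANOVA requires a balanced treatment x depth design")
    if sel["depth"].nunique() == 1:
        # degenerate design: the model collapses to one-way in treatment
        groups = {t: g["value"].to_numpy(float) for t, g in sel.groupby("treatment", sort=False)}
        one = anova_from_summary(GroupSummary.from_raw(groups))
        return pd.DataFrame(
            {"sum_sq": [one.MSB * one.df_between, one.MSW * one.df_within],
             "df": [float(one.df_between), float(one.df_within)],
             "F": [one.F, np.nan], "p": [one.p, np.nan]},
            index=["treatment", "residual"],
        )
    model = ols("value ~ C(treatment) * C(depth)", data=sel).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(
        index={
            "C(treatment)": "treatment",
            "C(depth)": "depth",
            "C(treatment):C(depth)": "treatment:depth",
            "Residual": "residual",
        },
        columns={"PR(>F)": "p"},
    )
    return anova


def pairwise_significant(
    summary: GroupSummary, alpha: float = 0.05, method: str = "tukey"
) -> np.ndarray:
    """Boolean k x k matrix: True where a pair differs significantly.

    ``method`` is ``"tukey"`` (studentized-range HSD, the default),
    ``"lsd"`` (Fisher's least significant difference, unprotected
    pairwise t) or ``"duncan"`` (multiple range test with span-dependent
    protection levels).  All use the pooled within-group mean square.
    """
    means = np.asarray(summary.means, dtype=float)
    k, n = len(means), summary.n
    df_w = k * (n - 1)
    msw = anova_from_summary(summary).MSW
    se_pair = math.sqrt(2.0 * msw / n) if msw > 0 else 0.0
    diff = np.abs(means[:, None] - means[None, :])
    if msw == 0.0:
        sig = diff > 0
    elif method == "tukey":
        # studentized range statistic q = |diff| / sqrt(MSW/n)
        q = diff / math.sqrt(msw / n)
        p = stats.studentized_range.sf(q, k, df_w)
        sig = p < alpha
    elif method == "lsd":
        t = diff / se_pair
        p = 2.0 * stats.t.sf(t, df_w)
        sig = p < alpha
    elif method == "duncan":
        # span r = number of means covered (inclusive) in the sorted order;
        # protection level 1-(1-alpha)^(r-1)
        order = np.argsort(means)
        rank = np.empty(k, dtype=int)
        rank[order] = np.arange(k)
        span = np.abs(rank[:, None] - rank[None, :]) + 1
        q = diff / math.sqrt(msw / n)
        sig = np.zeros((k, k), dtype=bool)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                r = int(span[i, j])
                alpha_r = 1.0 - (1.0 - alpha) ** (r - 1)
                crit = stats.studentized_range.ppf(1.0 - alpha_r, r, df_w)
                sig[i, j] = q[i, j] > crit
    else:
        raise ValueError(f"unknown multiple-comparison method {method!r}")
    np.fill_diagonal(sig, False)
    return sig


def tukey_letters(
    summary: GroupSummary, alpha: float = 0.05, method: str = "tukey"
) -> dict[str, str]:
    """Compact letter display: groups sharing a letter do not differ.

    Letters are assigned by insert-and-absorb over the pairwise
    significance matrix of :func:`pairwise_significant`: groups are sorted
    by descending mean, each starts in the letter class of every group it
    is *not* significantly different from, and redundant classes are
    absorbed.  Two groups share a letter iff their pairwise comparison is
    non-significant.
    """
    sig = pairwise_significant(summary, alpha=alpha, method=method)
    k = len(summary.labels)
    # insert-and-absorb: start from the all-inclusive class and split it
    # on every significant pair, keeping the invariant that every
    # non-significant pair still shares at least one class
    classes: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            next_classes: list[set[int]] = []
            for cls in classes:
                if i in cls and j in cls:
                    next_classes.append(cls - {i})
                    next_classes.append(cls - {j})
                else:
                    next_classes.append(cls)
            # absorb duplicates and subsets
            next_classes.sort(key=len, reverse=True)
            kept: list[set[int]] = []
            for cls in next_classes:
                if not any(cls <= other for other in kept):
                    kept.append(cls)
            classes = kept
    # order classes by the largest mean they contain, for conventional
    # 'a' = best-group lettering
    classes.sort(key=lambda c: -max(summary.means[i] for i in c))
    letters = {label: "" for label in summary.labels}
    for letter, cls in zip(string.ascii_lowercase, classes):
        for i in sorted(cls):
            letters[summary.labels[i]] += letter
    return letters


def percent_change(reference_mean: float, treatment_mean: float) -> float:
    """Signed percent change of a treatment mean vs the reference mean."""
    if reference_mean == 0:
        raise ZeroDivisionError("reference mean must be non-zero")
    return (treatment_mean - reference_mean) / reference_mean * 100.0


def percent_change_range(
    reference_mean: float, treatment_means
) -> tuple[float, float]:
    """(min, max) of |percent change| across a subset of treatments."""
    changes = [abs(percent_change(reference_mean, m)) for m in treatment_means]
    return min(changes), max(changes)


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value for one sample."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate constant sample: normality undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)
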