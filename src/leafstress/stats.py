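"""Factorial statistics: one-way ANOVA, Duncan's multiple range test,
compact letter displays, Pearson correlation, percent-change summaries.

The factorial design is annotated with two independent one-way families,
exactly as drought-trait tables are conventionally lettered: lowercase
letters compare treatments within a sampling period, uppercase letters
compare periods within a treatment.  No two-way model and no cross-trait
multiplicity correction are applied (none are used in this style of
analysis); reports should state this.

Duncan's critical ranges are computed from the studentized-range
distribution at Duncan's protection levels alpha_p = 1 - (1-alpha)^(p-1)
for a comparison spanning p ranked means, rather than from shipped lookup
tables.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: label, mean, SE of the mean, n."""

    label: str
    mean: float
    se: float
    n: int = 3

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.se < 0:
            raise ValueError("SE must be non-negative")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_between: float
    ms_within: float


@dataclass(frozen=True)
class DuncanResult:
    """Ranked means plus the pairwise significance set at level alpha."""

    labels: tuple[str, ...]  # descending mean order
    means: tuple[float, ...]
    significant: frozenset[frozenset[str]]
    alpha: float
    ms_within: float
    df_within: int
    n: float  # per-group n (harmonic mean when unequal)

    def letters(self) -> dict[str, str]:
        return compact_letters(self.labels, self.significant)


def _anova_from_stats(
    means: np.ndarray, variances: np.ndarray, ns: np.ndarray
) -> AnovaResult:
    """Classical between/within decomposition from group sufficient stats."""
    k = means.size
    n_total = int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * variances).sum())
    df_b, df_w = k - 1, n_total - k
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0.0:
        if msb == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0, msb, msw)
        # unequal means with no within-group spread: report the limit case
        return AnovaResult(math.inf, df_b, df_w, 0.0, msb, msw)
    f = msb / msw
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p, msb, msw)


def anova_oneway(groups: dict[str, "np.ndarray | list[float]"]) -> AnovaResult:
    """One-way ANOVA on raw per-group values.

    Requires >= 2 groups with >= 2 values each.  A zero within-group
    variance with unequal means is reported explicitly as F = inf, p = 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for label, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
    means = np.array([a.mean() for a in arrays.values()])
    variances = np.array([a.var(ddof=1) for a in arrays.values()])
    ns = np.array([a.size for a in arrays.values()])
    return _anova_from_stats(means, variances, ns)


def anova_from_summary(groups: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA from (mean, SE, n) summaries.

    The within-group variance of each group is recovered as n * SE^2, so
    the result is identical to :func:`anova_oneway` applied to any raw
    data sharing these sufficient statistics.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    means = np.array([g.mean for g in groups], dtype=float)
    variances = np.array([g.n * g.se**2 for g in groups], dtype=float)
    ns = np.array([g.n for g in groups], dtype=float)
    return _anova_from_stats(means, variances, ns)


# ---------------------------------------------------------------------------
# Duncan's multiple range test


def _as_summaries(groups) -> list[GroupSummary]:
    if isinstance(groups, dict):
        out = []
        for label, values in groups.items():
            arr = np.asarray(values, dtype=float)
            if arr.size < 2:
                raise ValueError(f"group {label!r} has fewer than 2 values")
            out.append(
                GroupSummary(
                    label=str(label),
                    mean=float(arr.mean()),
                    se=float(arr.std(ddof=1) / math.sqrt(arr.size)),
                    n=int(arr.size),
                )
            )
        return out
    return list(groups)


def duncan_mrt(groups, alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test at level ``alpha``.

    ``groups`` is either a mapping label -> raw values or a list of
    :class:`GroupSummary`.  Means are ranked; a pair spanning p ranks is
    significant when its difference exceeds the critical range
    q_{1-alpha_p}(p, df_w) * sqrt(MSW/n) with Duncan's protection level
    alpha_p = 1 - (1-alpha)^(p-1), under the standard step-down constraint
    that pairs inside a non-significant span are never declared
    significant.  Unequal group sizes fall back to the harmonic mean n
    with a warning.
    """
    summaries = _as_summaries(groups)
    if len(summaries) < 2:
        raise ValueError("need at least two groups")
    anova = anova_from_summary(summaries)
    ns = np.array([g.n for g in summaries], dtype=float)
    if np.unique(ns).size > 1:
        warnings.warn("unequal group sizes: using harmonic-mean n", stacklevel=2)
        n_eff = ns.size / (1.0 / ns).sum()
    else:
        n_eff = float(ns[0])
    order = sorted(range(len(summaries)), key=lambda i: -summaries[i].mean)
    labels = tuple(summaries[i].label for i in order)
    means = tuple(float(summaries[i].mean) for i in order)
    k = len(labels)
    df_w = anova.df_within
    se_term = math.sqrt(anova.ms_within / n_eff)

    crit = {
        p: float(sps.studentized_range.ppf(1.0 - (1.0 - (1.0 - alpha) ** (p - 1)), p, df_w))
        * se_term
        for p in range(2, k + 1)
    }

    ns_windows: list[tuple[int, int]] = []
    significant: set[frozenset[str]] = set()
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(a <= i and j <= b for a, b in ns_windows):
                continue
            if means[i] - means[j] > crit[span]:
                significant.add(frozenset({labels[i], labels[j]}))
            else:
                ns_windows.append((i, j))
    return DuncanResult(
        labels=labels,
        means=means,
        significant=frozenset(significant),
        alpha=alpha,
        ms_within=anova.ms_within,
        df_within=df_w,
        n=n_eff,
    )


def compact_letters(
    labels_desc: tuple[str, ...], significant: frozenset[frozenset[str]]
) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    ``labels_desc`` must be in descending-mean order; groups sharing any
    letter are pairwise non-significant, and letters are assigned 'a',
    'b', ... down the ranking.  The letter set is minimal in the
    insert-and-absorb sense.
    """
    letters: list[set[str]] = [set(labels_desc)]
    for pair in sorted(significant, key=sorted):
        expanded: list[set[str]] = []
        a, b = sorted(pair)
        for cls in letters:
            if a in cls and b in cls:
                expanded.extend([cls - {a}, cls - {b}])
            else:
                expanded.append(cls)
        # absorb duplicates and proper subsets
        letters = []
        for i, cls in enumerate(expanded):
            absorbed = any(
                cls < other or (cls == other and i > j) for j, other in enumerate(expanded)
            )
            if cls and not absorbed:
                letters.append(cls)
    rank = {label: i for i, label in enumerate(labels_desc)}
    letters.sort(key=lambda cls: min(rank[m] for m in cls))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment: dict[str, list[str]] = {label: [] for label in labels_desc}
    for idx, cls in enumerate(letters):
        for member in cls:
            assignment[member].append(alphabet[idx])
    return {label: "".join(sorted(chars)) for label, chars in assignment.items()}


# ---------------------------------------------------------------------------
# factorial letter grid


def letter_matrix(table: pd.DataFrame, trait: str, alpha: float = 0.05) -> pd.DataFrame:
    """Two-family letter grid for one trait of a long-format table.

    Lowercase letters compare treatments within each period; uppercase
    letters compare periods within each treatment.  Returns a tidy frame
    with one row per design cell: mean, SE, n, upper, lower.
    """
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in table")
    treatments = list(dict.fromkeys(sub["treatment"]))
    periods = list(dict.fromkeys(sub["period"]))
    missing = [
        (t, p)
        for t in treatments
        for p in periods
        if sub[(sub["treatment"] == t) & (sub["period"] == p)].empty
    ]
    if missing:
        raise ValueError(f"missing design cells for {trait!r}: {missing}")

    def cell_values(t: str, p: str) -> np.ndarray:
        return sub[(sub["treatment"] == t) & (sub["period"] == p)]["value"].to_numpy()

    lower: dict[tuple[str, str], str] = {}
    for p in periods:
        res = duncan_mrt({t: cell_values(t, p) for t in treatments}, alpha=alpha)
        for t, letter in res.letters().items():
            lower[(t, p)] = letter
    upper: dict[tuple[str, str], str] = {}
    for t in treatments:
        res = duncan_mrt({p: cell_values(t, p) for p in periods}, alpha=alpha)
        for p, letter in res.letters().items():
            upper[(t, p)] = letter.upper()

    rows = []
    for t in treatments:
        for p in periods:
            vals = cell_values(t, p)
            rows.append(
                {
                    "trait": trait,
                    "treatment": t,
                    "period": p,
                    "mean": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / math.sqrt(vals.size)),
                    "n": int(vals.size),
                    "upper": upper[(t, p)],
                    "lower": lower[(t, p)],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations and percent change


def pearson_matrix(
    table: pd.DataFrame, traits: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between traits of a long-format table.

    Observations are (treatment, period, replicate) rows; pairs use
    pairwise-complete observations (>= 3 required).  Returns (r, p) frames
    with unit diagonal; constant traits yield NaN markers.
    """
    wide = table.pivot_table(
        index=["treatment", "period", "replicate"], columns="trait", values="value"
    )
    traits = traits or list(wide.columns)
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for t1, t2 in itertools.combinations(traits, 2):
        paired = wide[[t1, t2]].dropna()
        if len(paired) < 3:
            raise ValueError(f"fewer than 3 paired observations for ({t1}, {t2})")
        x, y = paired[t1].to_numpy(), paired[t2].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rv, pv = np.nan, np.nan
        else:
            rv, pv = sps.pearsonr(x, y)
        r.loc[t1, t2] = r.loc[t2, t1] = rv
        p.loc[t1, t2] = p.loc[t2, t1] = pv
    return r, p


def percent_change(reference: float, treated: float, direction: str = "decrease") -> float:
    """Percent change of ``treated`` relative to ``reference``.

    ``direction='decrease'`` reports (reference - treated)/reference * 100
    (the "decreased by x%" convention); ``'increase'`` reports the signed
    opposite ("x% higher than the control").
    """
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    if direction == "decrease":
        return (reference - treated) / reference * 100.0
    if direction == "increase":
        return (treated - reference) / reference * 100.0
    raise ValueError("direction must be 'decrease' or 'increase'")
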