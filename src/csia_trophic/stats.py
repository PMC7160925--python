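"""Group-comparison statistics computable from summary statistics.

Published isotope tables report only per-group n, mean and SD, so the
comparison layer works from those summaries: Welch t-tests, one-way
ANOVA, and Tukey–Kramer post hoc comparisons with a compact letter
display. The summary-statistic forms are algebraically identical to their
raw-data counterparts when the summaries are computed (unrounded) from
the raw data. Raw-data diagnostics (Levene/Brown–Forsythe, Shapiro–Wilk)
and the duplicate-measurement repeatability (one-way intraclass
correlation) are also provided.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateVarianceError, InsufficientDataError, ValidationError

SIDEDNESS = ("two_sided", "less", "greater")


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and SD of one group for one variable (SD absent if n = 1)."""

    label: str
    n: int
    mean: float
    sd: float | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError(f"group {self.label!r}: n must be >= 1")
        if self.sd is not None and self.sd < 0:
            raise ValidationError(f"group {self.label!r}: sd must be >= 0")

    @classmethod
    def from_values(cls, label: str, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else None
        return cls(label=label, n=int(arr.size), mean=float(arr.mean()), sd=sd)


@dataclass(frozen=True)
class TestReport:
    """Outcome of one hypothesis test; df is a float, or (between, within) for ANOVA."""

    statistic: float
    df: float | tuple
    p_value: float
    test: str
    sidedness: str = "two_sided"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value outside [0, 1]: {self.p_value!r}")


@dataclass(frozen=True)
class CLDResult:
    """Compact letter display: groups sharing a letter are not significantly different."""

    letters: Mapping[str, str]
    pairwise_p: Mapping[tuple, float] = field(default_factory=dict)
    alpha: float = 0.05

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def _check_sidedness(sidedness: str) -> None:
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}, got {sidedness!r}")


def _t_pvalue(t: float, df: float, sidedness: str) -> float:
    if sidedness == "two_sided":
        return float(2.0 * sps.t.sf(abs(t), df))
    if sidedness == "greater":
        return float(sps.t.sf(t, df))
    return float(sps.t.cdf(t, df))


def welch_t_from_summaries(a: GroupSummary, b: GroupSummary,
                           sidedness: str = "two_sided") -> TestReport:
    """Welch's unequal-variance t-test from group summaries.

    t = (m_a − m_b)/sqrt(s_a²/n_a + s_b²/n_b) with the Welch–Satterthwaite
    approximation for the degrees of freedom.
    """
    _check_sidedness(sidedness)
    for g in (a, b):
        if g.n < 2 or g.sd is None:
            raise InsufficientDataError(
                f"group {g.label!r} needs n >= 2 and an SD for a Welch test"
            )
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0:
        raise DegenerateVarianceError("both group variances are zero")
    t = (a.mean - b.mean) / math.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TestReport(t, df, _t_pvalue(t, df, sidedness), "welch_t", sidedness)


def paired_t(differences: Sequence[float], sidedness: str = "two_sided") -> TestReport:
    """One-sample t-test on paired differences: t = mean(d)/(sd(d)/√n), df = n−1."""
    _check_sidedness(sidedness)
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise InsufficientDataError("paired t-test needs at least 2 differences")
    if not np.all(np.isfinite(d)):
        raise ValidationError("differences must be finite")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("all paired differences are identical")
    n = d.size
    t = float(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    return TestReport(t, float(df), _t_pvalue(t, df, sidedness), "paired_t", sidedness)


def _pooled_within(groups: Sequence[GroupSummary]) -> tuple:
    """Within-group mean square and its df: MSW = Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1)."""
    df_within = sum(g.n - 1 for g in groups)
    ssw = sum((g.n - 1) * g.sd**2 for g in groups)
    return ssw / df_within, df_within


def anova_from_summaries(groups: Sequence[GroupSummary]) -> TestReport:
    """One-way fixed-effects ANOVA from group summaries.

    Exactly equal to the raw-data ANOVA when the summaries are unrounded:
    the between-group sum of squares is Σnᵢ(mᵢ − m̄)² around the weighted
    grand mean, and the within-group mean square pools the group variances.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs at least 2 groups")
    for g in groups:
        if g.n < 2 or g.sd is None:
            raise InsufficientDataError(
                f"group {g.label!r} needs n >= 2 and an SD for an ANOVA"
            )
    n_total = sum(g.n for g in groups)
    grand = sum(g.n * g.mean for g in groups) / n_total
    ssb = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    df_between = len(groups) - 1
    msw, df_within = _pooled_within(groups)
    if msw == 0:
        raise DegenerateVarianceError("all within-group variances are zero")
    f = (ssb / df_between) / msw
    p = float(sps.f.sf(f, df_between, df_within))
    return TestReport(float(f), (float(df_between), float(df_within)), p, "anova")


def tukey_pairwise_p(groups: Sequence[GroupSummary]) -> dict:
    """Tukey–Kramer adjusted p-value for every pair of groups.

    q = |mᵢ − mⱼ| / sqrt((MSW/2)(1/nᵢ + 1/nⱼ)), referred to the
    studentized-range distribution with k groups and the pooled within df.
    The Kramer correction handles unequal group sizes.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise InsufficientDataError("post hoc comparison needs at least 2 groups")
    for g in groups:
        if g.n < 2 or g.sd is None:
            raise InsufficientDataError(
                f"group {g.label!r} needs n >= 2 and an SD for Tukey comparisons"
            )
    msw, df_within = _pooled_within(groups)
    if msw == 0:
        raise DegenerateVarianceError("all within-group variances are zero")
    k = len(groups)
    pvals = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            se = math.sqrt(msw / 2.0 * (1.0 / a.n + 1.0 / b.n))
            q = abs(a.mean - b.mean) / se
            pvals[(a.label, b.label)] = float(sps.studentized_range.sf(q, k, df_within))
    return pvals


def _letters_from_columns(labels: Sequence[str], columns: Sequence[frozenset]) -> dict:
    # deterministic letter order: columns sorted by first member's label order
    order = {lab: i for i, lab in enumerate(labels)}
    cols = sorted(columns, key=lambda c: sorted(order[m] for m in c))
    alphabet = list(string.ascii_lowercase)
    while len(alphabet) < len(cols):
        alphabet.append(f"z{len(alphabet)}")
    assigned = {lab: [] for lab in labels}
    for letter, col in zip(alphabet, cols):
        for member in col:
            assigned[member].append(letter)
    return {lab: ",".join(sorted(ls)) for lab, ls in assigned.items()}


def cld_from_significance(labels: Sequence[str], significant: Mapping[tuple, bool]) -> dict:
    """Insert-and-absorb compact letter display from a pairwise significance map.

    Starts from a single column holding every group; each significant pair
    splits every column containing both members; columns that become
    subsets of another are absorbed. The result guarantees that two groups
    share a letter iff no significant difference separates them.
    """
    labels = list(labels)
    columns = [frozenset(labels)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend((col - {a}, col - {b}))
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another
        columns = [
            c for c in set(new_cols)
            if c and not any(c < other for other in set(new_cols))
        ]
    return _letters_from_columns(labels, columns)


def tukey_cld(groups: Sequence[GroupSummary], alpha: float = 0.05) -> CLDResult:
    """Tukey–Kramer homogeneous subgroups as a compact letter display."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    groups = list(groups)
    pvals = tukey_pairwise_p(groups)
    significant = {pair: p < alpha for pair, p in pvals.items()}
    letters = cld_from_significance([g.label for g in groups], significant)
    return CLDResult(letters=letters, pairwise_p=pvals, alpha=alpha)


def levene_test(values_by_group: Mapping[str, Sequence[float]]) -> TestReport:
    """Brown–Forsythe homogeneity-of-variance test (Levene on deviations
    from group medians)."""
    samples = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise InsufficientDataError("Levene's test needs >= 2 groups of >= 2 values")
    stat, p = sps.levene(*samples, center="median")
    k = len(samples)
    n_total = sum(s.size for s in samples)
    return TestReport(float(stat), (float(k - 1), float(n_total - k)), float(p), "levene")


def shapiro_wilk(values: Sequence[float]) -> TestReport:
    """Shapiro–Wilk normality test (3 <= n <= 5000)."""
    arr = np.asarray(values, dtype=float)
    if not (3 <= arr.size <= 5000):
        raise InsufficientDataError("Shapiro-Wilk requires 3 <= n <= 5000")
    stat, p = sps.shapiro(arr)
    return TestReport(float(stat), float(arr.size), float(p), "shapiro")


def repeatability(duplicates: Sequence[tuple]) -> float:
    """Repeatability (intraclass correlation) of duplicate measurements, in percent.

    One-way ANOVA with samples as groups and the two measurements as
    replicates: ICC = (MS_between − MS_within)/(MS_between + MS_within)
    for duplicate pairs, i.e. the share of total variance attributable to
    true between-sample differences. Exact duplicates give 100%; the
    estimate can be slightly negative when within-pair noise dominates.
    """
    pairs = np.asarray(list(duplicates), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise InsufficientDataError("repeatability needs >= 3 duplicate pairs")
    n = pairs.shape[0]
    sample_means = pairs.mean(axis=1)
    grand = pairs.mean()
    msb = 2.0 * np.sum((sample_means - grand) ** 2) / (n - 1)
    msw = np.sum((pairs - sample_means[:, None]) ** 2) / n
    if msb + msw == 0:
        raise DegenerateVarianceError("all measurements are identical")
    icc = (msb - msw) / (msb + msw)
    return float(100.0 * icc)
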