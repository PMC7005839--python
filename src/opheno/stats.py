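"""Statistical layer applied to criterion scores and classification outcomes.

Two-group score comparisons use the Mann-Whitney U test (U reported with the
min-U convention), classification frequencies are compared against the
control group's addicted proportion with a 1-df goodness-of-fit chi-square,
and the relation between each criterion's score and the number of criteria
met is summarised by Pearson correlation.  No multiple-testing correction is
applied by default; a Bonferroni helper is available.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "chi_square_vs_control",
    "pearson_correlation",
    "significance_stars",
    "bonferroni",
]


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    direction: str = ""  # e.g. "group1 > group2" by location

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be >= 1")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stars"] = self.stars
        return d


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> GroupComparison:
    """Mann-Whitney U test; exact p for small tie-free samples, otherwise the
    normal approximation with tie correction.  Reports U = min(U1, U2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="auto")
    u1 = float(res.statistic)
    u_min = min(u1, x.size * y.size - u1)
    direction = "x > y" if np.median(x) > np.median(y) else "x < y"
    return GroupComparison(
        test="mann_whitney_u",
        statistic=u_min,
        p_value=float(res.pvalue),
        n1=int(x.size),
        n2=int(y.size),
        direction=direction,
    )


def chi_square_vs_control(
    labels: Sequence[str] | Sequence[bool],
    control_proportion: float,
    *,
    yates: bool = False,
) -> GroupComparison:
    """1-df goodness-of-fit chi-square of a test group's addicted/non-addicted
    counts against the frequencies expected under the control group's addicted
    proportion.

    ``labels`` may be booleans (True = addicted) or the strings
    'addicted'/'non_addicted'.
    """
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        addicted = arr == "addicted"
    else:
        addicted = arr.astype(bool)
    n = int(addicted.size)
    if n < 1:
        raise ValueError("test group must be nonempty")
    p = float(control_proportion)
    if not 0.0 < p < 1.0:
        raise ValueError(
            "control proportion must lie strictly in (0, 1); "
            "degenerate expected counts"
        )
    observed = np.array([addicted.sum(), n - addicted.sum()], dtype=float)
    expected = np.array([n * p, n * (1.0 - p)])
    dev = np.abs(observed - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / expected))
    p_value = float(sps.chi2.sf(stat, df=1))
    direction = "above control" if observed[0] > expected[0] else "below control"
    return GroupComparison(
        test="chi_square_gof" + ("_yates" if yates else ""),
        statistic=stat,
        p_value=p_value,
        n1=n,
        n2=n,
        direction=direction,
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Pearson r between criterion scores and the number of criteria met,
    with the p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return GroupComparison(
        test="pearson_r",
        statistic=r,
        p_value=float(res.pvalue),
        n1=int(x.size),
        n2=int(x.size),
        direction="positive" if r >= 0 else "negative",
    )


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-adjusted p-values (off by default everywhere)."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0)
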