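"""Two-group comparison protocol: Shapiro–Wilk gate, Student's t, asterisk tiers.

Normality is assessed per group with a Shapiro–Wilk test and recorded; a
rejection is logged as a warning but does not block the t-test (the reporting
convention these experiments follow).  The default two-sample test assumes
equal variances; ``equal_var=False`` switches to Welch's t.  Significance
tiers follow the asterisk convention: ns for p >= 0.05, * for p < 0.05,
** for p < 0.01, *** for p < 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientSampleError

__all__ = ["ComparisonResult", "significance_tier", "two_sample_compare"]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-group comparison."""

    statistic: float
    p_value: float
    tier: str
    normality_ok: tuple[bool, bool]
    group_means: tuple[float, float]
    group_sems: tuple[float, float]
    n: tuple[int, int]
    df: float
    equal_var: bool = True

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "tier": self.tier,
            "normality_ok": list(self.normality_ok),
            "group_means": list(self.group_means),
            "group_sems": list(self.group_sems),
            "n": list(self.n),
            "df": self.df,
            "equal_var": self.equal_var,
        }


def significance_tier(p_value: float) -> str:
    """Asterisk tier for a p-value (pure function; boundaries are half-open)."""
    if not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p-value must lie in [0, 1], got {p_value!r}")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def two_sample_compare(a, b, equal_var: bool = True, normality_alpha: float = 0.05) -> ComparisonResult:
    """Two-sided two-sample t comparison with a recorded normality gate.

    Each sample needs at least 3 observations.  Two zero-variance samples
    with equal means return statistic 0 and p = 1 by convention (and an
    infinite statistic with p = 0 when the means differ).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientSampleError(
            f"each group needs n >= 3 observations (got {len(a)} and {len(b)})"
        )
    normality = []
    for name, x in (("a", a), ("b", b)):
        if np.ptp(x) == 0.0:
            ok = True  # Shapiro-Wilk is undefined for constant samples
        else:
            ok = bool(sps.shapiro(x).pvalue >= normality_alpha)
        if not ok:
            warnings.warn(
                f"sample {name} fails the Shapiro-Wilk normality check; "
                "proceeding with the t-test per protocol",
                stacklevel=2,
            )
        normality.append(ok)
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    if var_a == 0.0 and var_b == 0.0:
        if np.mean(a) == np.mean(b):
            statistic, p_value = 0.0, 1.0
        else:
            statistic = float(np.inf) if np.mean(a) > np.mean(b) else float(-np.inf)
            p_value = 0.0
        df = float(len(a) + len(b) - 2)
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        statistic, p_value = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return ComparisonResult(
        statistic=statistic,
        p_value=p_value,
        tier=significance_tier(p_value),
        normality_ok=(normality[0], normality[1]),
        group_means=(float(np.mean(a)), float(np.mean(b))),
        group_sems=(_sem(a), _sem(b)),
        n=(len(a), len(b)),
        df=df,
        equal_var=equal_var,
    )
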