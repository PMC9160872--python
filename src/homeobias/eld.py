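"""Expression-level-dominance classification of hybrid expression patterns.

For every homeolog pair and condition, the hybrid's total expression
(sum of the two homeologs, per hybrid replicate) is compared with each
parent's expression by two-sample Student's t-tests.  The three verdicts
(hybrid vs P1, hybrid vs P2, P1 vs P2) place the pair in one of thirteen
patterns, conventionally labelled with Roman numerals I–XII plus a "no
change" class, which collapse into six operational bins:

========================  ==========================================
bin                       patterns
========================  ==========================================
no_change                 hybrid indistinguishable from both parents
additivity                I, XII   (hybrid at the parental midpoint)
ELD_P1                    IV, IX   (hybrid mimics parent P1)
ELD_P2                    II, XI   (hybrid mimics parent P2)
transgressive_up          V, VI, VIII  (hybrid above both parents)
transgressive_down        III, VII, X  (hybrid below both parents)
========================  ==========================================

"Indistinguishable" means the t-test fails to reject at ``alpha``; no
multiple-testing correction is applied within the classification.
Combinations that fit none of the thirteen geometries (e.g. the
intransitive hybrid≈P1, hybrid≈P2 but P1≠P2) fall back to ``no_change``
with ``conflict_flag`` set.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PatternCall",
    "PatternSummary",
    "students_t_test",
    "classify_pattern",
    "bin_patterns",
    "PATTERN_TO_BIN",
    "BINS",
    "PATTERNS",
]

#: Fixed pattern → bin mapping.
PATTERN_TO_BIN: dict[str, str] = {
    "I": "additivity",
    "XII": "additivity",
    "IV": "ELD_P1",
    "IX": "ELD_P1",
    "II": "ELD_P2",
    "XI": "ELD_P2",
    "V": "transgressive_up",
    "VI": "transgressive_up",
    "VIII": "transgressive_up",
    "III": "transgressive_down",
    "VII": "transgressive_down",
    "X": "transgressive_down",
    "NO_CHANGE": "no_change",
}

BINS: tuple[str, ...] = (
    "no_change",
    "additivity",
    "ELD_P1",
    "ELD_P2",
    "transgressive_up",
    "transgressive_down",
)

PATTERNS: tuple[str, ...] = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII",
    "NO_CHANGE",
)


@dataclass(frozen=True)
class PatternCall:
    """Classification of one homeolog pair at one condition."""

    pattern: str
    bin: str
    conflict_flag: bool
    p_h_vs_p1: float
    p_h_vs_p2: float
    p_p1_vs_p2: float
    mean_h: float
    mean_p1: float
    mean_p2: float

    def __post_init__(self) -> None:
        if PATTERN_TO_BIN.get(self.pattern) != self.bin:
            raise ValueError(
                f"pattern {self.pattern!r} does not map to bin {self.bin!r}"
            )


def students_t_test(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, str]:
    """Classic pooled-variance two-sample t-test.

    Returns ``(p_value, direction)`` where direction is the sign of
    ``mean(x) - mean(y)``: ``greater``, ``less`` or ``equal_means``.
    Degenerate inputs: two identical constant vectors give ``p = 1``;
    zero pooled variance with unequal means gives ``p = 0`` (warned), the
    limit of the t statistic as variance vanishes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    mx, my = x.mean(), y.mean()
    if mx > my:
        direction = "greater"
    elif mx < my:
        direction = "less"
    else:
        direction = "equal_means"
    if x.var(ddof=0) == 0.0 and y.var(ddof=0) == 0.0:
        if mx == my:
            return 1.0, direction
        warnings.warn(
            "zero pooled variance with unequal means; p set to 0", stacklevel=2
        )
        return 0.0, direction
    t, p = stats.ttest_ind(x, y, equal_var=True)
    if math.isnan(p):  # pragma: no cover - guarded above
        return 1.0, direction
    return float(p), direction


def classify_pattern(
    hybrid_total: Sequence[float],
    p1_expr: Sequence[float],
    p2_expr: Sequence[float],
    alpha: float = 0.05,
    log_transform: bool = False,
) -> PatternCall:
    """Assign one of the thirteen expression patterns.

    Parameters
    ----------
    hybrid_total
        Per-replicate hybrid expression (sum of the two homeologs' RPKM).
    p1_expr, p2_expr
        Per-replicate parental expression of the matching transcripts.
    alpha
        Per-test significance level; "different" means ``p < alpha``.
    log_transform
        Run the t-tests on ``log2(x + 1)`` instead of raw values.
    """
    h = np.asarray(hybrid_total, dtype=float)
    p1 = np.asarray(p1_expr, dtype=float)
    p2 = np.asarray(p2_expr, dtype=float)
    if (h < 0).any() or (p1 < 0).any() or (p2 < 0).any():
        raise ValueError("expression values must be non-negative")
    th, tp1, tp2 = (np.log2(v + 1.0) for v in (h, p1, p2)) if log_transform else (h, p1, p2)

    p_h1, _ = students_t_test(th, tp1)
    p_h2, _ = students_t_test(th, tp2)
    p_12, _ = students_t_test(tp1, tp2)

    h_ne_p1 = p_h1 < alpha
    h_ne_p2 = p_h2 < alpha
    p1_ne_p2 = p_12 < alpha
    mh, m1, m2 = h.mean(), p1.mean(), p2.mean()

    def call(pattern: str, conflict: bool = False) -> PatternCall:
        return PatternCall(
            pattern=pattern,
            bin=PATTERN_TO_BIN[pattern],
            conflict_flag=conflict,
            p_h_vs_p1=p_h1,
            p_h_vs_p2=p_h2,
            p_p1_vs_p2=p_12,
            mean_h=mh,
            mean_p1=m1,
            mean_p2=m2,
        )

    if not h_ne_p1 and not h_ne_p2:
        # hybrid matches both parents; flag the intransitive case P1 != P2
        return call("NO_CHANGE", conflict=p1_ne_p2)
    if not h_ne_p1 and h_ne_p2:
        return call("IV" if m1 > m2 else "IX")
    if h_ne_p1 and not h_ne_p2:
        return call("II" if m2 > m1 else "XI")
    # hybrid differs from both parents
    if mh > m1 and mh > m2:
        if not p1_ne_p2:
            return call("VI")
        return call("V" if m1 < m2 else "VIII")
    if mh < m1 and mh < m2:
        if not p1_ne_p2:
            return call("VII")
        return call("III" if m1 < m2 else "X")
    if p1_ne_p2 and min(m1, m2) < mh < max(m1, m2):
        return call("XII" if m1 < m2 else "I")
    # residual geometry (e.g. hybrid between equal-looking parents)
    return call("NO_CHANGE", conflict=True)


@dataclass
class PatternSummary:
    """Counts and proportions of pattern calls."""

    n: int
    pattern_counts: pd.Series
    pattern_proportions: pd.Series
    bin_counts: pd.Series
    bin_proportions: pd.Series


def bin_patterns(calls: Iterable[PatternCall]) -> PatternSummary:
    """Tabulate calls over the 13 patterns and the operational bins."""
    calls = list(calls)
    if not calls:
        raise ValueError("bin_patterns requires at least one call")
    n = len(calls)
    pat = Counter(c.pattern for c in calls)
    bn = Counter(c.bin for c in calls)
    pattern_counts = pd.Series(
        [pat.get(p, 0) for p in PATTERNS], index=list(PATTERNS), dtype=int
    )
    bin_counts = pd.Series([bn.get(b, 0) for b in BINS], index=list(BINS), dtype=int)
    return PatternSummary(
        n=n,
        pattern_counts=pattern_counts,
        pattern_proportions=pattern_counts / n,
        bin_counts=bin_counts,
        bin_proportions=bin_counts / n,
    )
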