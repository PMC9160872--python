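"""Homeolog expression bias (HEB), its likelihood-ratio test, and ΔHEB.

Within each hybrid library both homeologs of a pair are quantified, so
their relative expression can be compared directly.  The bias statistic
is the base-2 log ratio of replicate-mean RPKM,

    B = log2( mean(RPKM_P1-homeolog) / mean(RPKM_P2-homeolog) ),

so B = 0 means balanced expression, B = 3 an 8-fold bias toward the
P1-derived copy, B = -3 an 8-fold bias toward the P2-derived copy.

Significance is assessed on the summed read counts with a binomial
likelihood-ratio test.  Under the null of equal underlying expression
the P1 homeolog's share of the pair's reads is the length-expected
proportion pi0 = len_P1 / (len_P1 + len_P2) (a longer transcript draws
proportionally more reads); under the alternative it is the observed
proportion.  Twice the log-likelihood ratio is referred to chi-square
with 1 df.  Per-condition p-values are corrected by Benjamini–Hochberg.

ΔHEB between two conditions is the difference of the two B values; its
test is the likelihood-ratio (G) test of homogeneity of the homeolog
proportion across the 2×2 table of summed counts — transcript-length
offsets cancel within a pair, so no length term appears.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from homeobias.errors import ExcludedPairError

__all__ = [
    "HomeologCounts",
    "HEBResult",
    "DeltaHEBResult",
    "BiasSummary",
    "heb_statistic",
    "fold_change",
    "heb_lrt",
    "bh_fdr",
    "delta_heb",
    "delta_heb_lrt",
    "heb_test",
    "apply_fdr",
    "summarize_bias",
]


@dataclass
class HomeologCounts:
    """Replicate-level data for one homeolog pair at one condition.

    ``spt``/``spc`` name the P1- and P2-derived homeologs respectively
    (paternal and maternal subgenomes in the motivating system).
    """

    pair_id: str
    condition: str
    spt_counts: np.ndarray
    spc_counts: np.ndarray
    spt_rpkm: np.ndarray
    spc_rpkm: np.ndarray
    len_spt: float
    len_spc: float

    def __post_init__(self) -> None:
        for name in ("spt_counts", "spc_counts", "spt_rpkm", "spc_rpkm"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.spt_counts) != len(self.spt_rpkm):
            raise ValueError("spt count and RPKM vectors differ in length")
        if len(self.spc_counts) != len(self.spc_rpkm):
            raise ValueError("spc count and RPKM vectors differ in length")
        if (self.spt_counts < 0).any() or (self.spc_counts < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def m(self) -> int:
        """Replicates carrying the P1 homeolog."""
        return len(self.spt_counts)

    @property
    def n(self) -> int:
        """Replicates carrying the P2 homeolog."""
        return len(self.spc_counts)


@dataclass
class HEBResult:
    pair_id: str
    condition: str
    b: float
    lrt_stat: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    direction: str = "none"


@dataclass
class DeltaHEBResult:
    pair_id: str
    condition_pair: tuple[str, str]
    b1: float
    b2: float
    delta: float
    lrt_stat: float
    p_value: float
    significant: bool
    direction: str


def heb_statistic(
    spt_rpkm: Sequence[float], spc_rpkm: Sequence[float]
) -> float:
    """Base-2 log ratio of replicate-mean RPKM (P1 over P2 homeolog).

    With equal replicate numbers this equals ``log2(sum(spt)/sum(spc))``.
    A zero mean on either side raises :class:`ExcludedPairError`: such
    pairs fail the non-zero expression requirement and carry no finite
    bias.
    """
    spt = np.asarray(spt_rpkm, dtype=float)
    spc = np.asarray(spc_rpkm, dtype=float)
    ms, mc = spt.mean(), spc.mean()
    if ms <= 0.0 or mc <= 0.0:
        raise ExcludedPairError(
            "bias undefined: zero mean expression on one side "
            f"(P1 mean {ms}, P2 mean {mc})"
        )
    return float(np.log2(ms / mc))


def fold_change(b: float) -> float:
    """Fold change implied by a bias value: ``2**|b|`` (>= 1)."""
    b = np.asarray(b, dtype=float)
    if not np.isfinite(b).all():
        raise ValueError("bias must be finite")
    out = np.exp2(np.abs(b))
    return float(out) if out.ndim == 0 else out


def _binom_loglik(x: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel with the 0*log(0) = 0 convention."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(x > 0, x * np.log(p), 0.0)
        t2 = np.where(n - x > 0, (n - x) * np.log1p(-p), 0.0)
    return t1 + t2


def heb_lrt(
    x_spt,
    x_spc,
    len_spt: float = 1.0,
    len_spc: float = 1.0,
):
    """Likelihood-ratio test of expression bias on summed counts.

    Parameters are the total read counts of the two homeologs (summed
    over hybrid replicates) and the transcript lengths that set the null
    proportion.  Scalars or equally-shaped arrays are accepted; arrays
    are tested element-wise.

    Returns ``(lrt_stat, p_value)`` with the p-value from the upper tail
    of chi-square with 1 df.
    """
    xs = np.asarray(x_spt, dtype=float)
    xc = np.asarray(x_spc, dtype=float)
    ls = np.asarray(len_spt, dtype=float)
    lc = np.asarray(len_spc, dtype=float)
    if (xs < 0).any() or (xc < 0).any():
        raise ValueError("read counts must be non-negative")
    n = xs + xc
    if (n < 1).any():
        raise ExcludedPairError(
            "bias test requires at least one read across the homeolog pair"
        )
    pi0 = ls / (ls + lc)
    pi1 = xs / n
    lrt = 2.0 * (_binom_loglik(xs, n, pi1) - _binom_loglik(xs, n, pi0))
    lrt = np.maximum(lrt, 0.0)
    p = stats.chi2.sf(lrt, df=1)
    if lrt.ndim == 0:
        return float(lrt), float(p)
    return lrt, p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def delta_heb(b1: float, b2: float) -> float:
    """Change in bias between two conditions: exactly ``b2 - b1``."""
    return b2 - b1


def delta_heb_lrt(
    x1_spt,
    x1_spc,
    x2_spt,
    x2_spc,
):
    """G-test of homogeneity of the homeolog proportion across conditions.

    The 2×2 table of summed counts ({condition 1, condition 2} ×
    {P1 homeolog, P2 homeolog}) is tested for a common P1 proportion
    (H0) against condition-specific proportions (H1).  Transcript-length
    offsets are shared by both conditions and cancel.  Scalars or
    equally-shaped arrays accepted.

    Returns ``(lrt_stat, p_value)`` with 1 df.
    """
    cells = [np.asarray(v, dtype=float) for v in (x1_spt, x1_spc, x2_spt, x2_spc)]
    a, b, c, d = np.broadcast_arrays(*cells)
    if any((v < 0).any() for v in (a, b, c, d)):
        raise ValueError("read counts must be non-negative")
    n1 = a + b
    n2 = c + d
    if (n1 < 1).any() or (n2 < 1).any():
        raise ExcludedPairError(
            "homogeneity test requires non-zero totals in both conditions"
        )
    total = n1 + n2
    p_common = (a + c) / total
    l0 = _binom_loglik(a, n1, p_common) + _binom_loglik(c, n2, p_common)
    l1 = _binom_loglik(a, n1, a / n1) + _binom_loglik(c, n2, c / n2)
    lrt = np.maximum(2.0 * (l1 - l0), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    if lrt.ndim == 0:
        return float(lrt), float(p)
    return lrt, p


def heb_test(h: HomeologCounts) -> HEBResult:
    """Bias statistic plus LRT for one pair at one condition.

    The returned result has no q-value yet; run :func:`apply_fdr` on the
    full per-condition collection.
    """
    b = heb_statistic(h.spt_rpkm, h.spc_rpkm)
    lrt, p = heb_lrt(
        h.spt_counts.sum(), h.spc_counts.sum(), h.len_spt, h.len_spc
    )
    return HEBResult(
        pair_id=h.pair_id, condition=h.condition, b=b, lrt_stat=lrt, p_value=p
    )


def apply_fdr(
    results: Iterable[HEBResult], fdr_threshold: float = 0.05
) -> list[HEBResult]:
    """Fill q-values, significance and direction for one condition's results."""
    results = list(results)
    if not results:
        return results
    q = bh_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.significant = bool(qv < fdr_threshold)
        if r.significant:
            r.direction = "toward_P1" if r.b > 0 else "toward_P2"
        else:
            r.direction = "none"
    return results


@dataclass
class BiasSummary:
    """Per-condition reduction of HEB results."""

    condition: str
    n_testable: int
    n_significant: int
    n_toward_p1: int
    n_toward_p2: int
    mean_b_toward_p1: float | None
    fold_toward_p1: float | None
    mean_b_toward_p2: float | None
    fold_toward_p2: float | None
    overall_mean_b: float
    pct_biased: float


def summarize_bias(
    results: Sequence[HEBResult], fdr_threshold: float = 0.05
) -> BiasSummary:
    """Counts, direction means, fold changes and biased percentage.

    All results must share one condition.  Direction means are reported
    only when at least one pair is significant in that direction.
    """
    results = list(results)
    if not results:
        raise ValueError("summarize_bias requires at least one result")
    conditions = {r.condition for r in results}
    if len(conditions) > 1:
        raise ValueError(f"results span multiple conditions: {sorted(conditions)}")
    sig = [r for r in results if r.q_value < fdr_threshold]
    toward_p1 = [r.b for r in sig if r.b > 0]
    toward_p2 = [r.b for r in sig if r.b < 0]
    mean_p1 = float(np.mean(toward_p1)) if toward_p1 else None
    mean_p2 = float(np.mean(toward_p2)) if toward_p2 else None
    n = len(results)
    return BiasSummary(
        condition=conditions.pop(),
        n_testable=n,
        n_significant=len(sig),
        n_toward_p1=len(toward_p1),
        n_toward_p2=len(toward_p2),
        mean_b_toward_p1=mean_p1,
        fold_toward_p1=fold_change(mean_p1) if mean_p1 is not None else None,
        mean_b_toward_p2=mean_p2,
        fold_toward_p2=fold_change(mean_p2) if mean_p2 is not None else None,
        overall_mean_b=float(np.mean([r.b for r in results])),
        pct_biased=100.0 * len(sig) / n,
    )
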