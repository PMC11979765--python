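"""Shared statistical primitives.

Every stage of the pipeline funnels its inference through the small set of
procedures here: an exact hypergeometric upper-tail probability (the
``phyper(q = x - 1, ..., lower.tail = FALSE)`` convention), Benjamini-Hochberg
step-up adjustment, unpaired two-sample t-tests on log-transformed values, and
the field-trait decision rules (log-scale trait t-test; the plus/minus 3 day
flowering-time flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HypergeomParams",
    "TestResult",
    "hypergeom_tail",
    "bh_adjust",
    "log_ttest",
    "compare_trait_to_control",
    "flowering_time_flag",
]


@dataclass(frozen=True)
class HypergeomParams:
    """Parameters of an upper-tail hypergeometric test.

    x: observed successes (e.g. DEGs that are predicted targets)
    m: marked genes in the universe (e.g. expressed predicted targets)
    N: universe size (e.g. expressed, nonredundant predicted targets genome-wide)
    k: drawn genes (e.g. DEGs)

    The corresponding R call is ``phyper(q = x - 1, m, n = N - m, k,
    lower.tail = FALSE)``.
    """

    x: int
    m: int
    N: int
    k: int

    def __post_init__(self) -> None:
        for name in ("x", "m", "N", "k"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.m > self.N:
            raise ValueError(f"m={self.m} exceeds universe N={self.N}")
        if self.k > self.N:
            raise ValueError(f"k={self.k} exceeds universe N={self.N}")
        if self.x > min(self.m, self.k):
            raise ValueError(
                f"x={self.x} exceeds min(m, k)={min(self.m, self.k)}; "
                "upstream bookkeeping is inconsistent"
            )


@dataclass
class TestResult:
    """Outcome of a two-sample location test on the log scale.

    ``effect`` is the difference of group means on the log scale (group A
    minus group B). ``fdr`` is filled only after a batch BH adjustment.
    """

    statistic: float
    pvalue: float
    effect: float
    fdr: float | None = None
    df: float = field(default=float("nan"), repr=False)


def hypergeom_tail(params: HypergeomParams) -> float:
    """Exact P(X >= x) for X ~ Hypergeometric(N, m, k).

    Computed as a log-space sum of PMF terms from x to min(m, k) via
    log-gamma, so universes of tens of thousands of genes with p-values near
    1e-300 neither overflow nor lose the tail. No normal approximation.
    """
    x, m, N, k = params.x, params.m, params.N, params.k
    hi = min(m, k)
    if x == 0:
        return 1.0
    lo_support = max(0, m + k - N)
    xs = np.arange(max(x, lo_support), hi + 1)
    if xs.size == 0:
        return 0.0
    logpmf = (
        gammaln(m + 1) - gammaln(xs + 1) - gammaln(m - xs + 1)
        + gammaln(N - m + 1) - gammaln(k - xs + 1) - gammaln(N - m - k + xs + 1)
        - (gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1))
    )
    return float(min(1.0, math.exp(logsumexp(logpmf))))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_adjust requires a non-empty p-value list")
    if np.isnan(p).any():
        raise ValueError("bh_adjust received NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_LOG_FNS = {2: np.log2, 10: np.log10, math.e: np.log, "e": np.log}


def log_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    base: float | str = 2,
    equal_var: bool = False,
) -> TestResult:
    """Unpaired two-sample t-test on log-transformed values.

    Welch (unequal variances) by default; set ``equal_var=True`` for the
    pooled-variance Student flavor. ``effect`` = mean(log a) - mean(log b).
    """
    try:
        logfn = _LOG_FNS[base]
    except KeyError:
        raise ValueError(f"base must be one of 2, e, 10; got {base!r}") from None
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for name, g in (("group_a", a), ("group_b", b)):
        if g.size < 2:
            raise ValueError(f"{name} needs at least 2 values, got {g.size}")
        if (g <= 0).any():
            bad = int(np.flatnonzero(g <= 0)[0])
            raise ValueError(
                f"{name}[{bad}] = {g[bad]} is not strictly positive; "
                "log-scale tests need positive values"
            )
    la, lb = logfn(a), logfn(b)
    res = sps.ttest_ind(la, lb, equal_var=equal_var)
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        effect=float(la.mean() - lb.mean()),
        df=float(res.df),
    )


def compare_trait_to_control(
    mutant_values: Sequence[float],
    control_values: Sequence[float],
    base: float | str = 2,
) -> TestResult:
    """Trait comparison of one mutant row against the pooled control rows.

    Log-transform then unpaired t-test; the caller applies :func:`bh_adjust`
    across all mutant rows within one field and calls fdr < 0.05 significant.
    Comparisons are only meaningful within a single field environment.
    """
    return log_ttest(mutant_values, control_values, base=base)


def flowering_time_flag(
    mutant_days: float, control_mean_days: float, max_days: float = 3.0
) -> Literal["flagged", "not_flagged"]:
    """Flag a possible flowering-time shift.

    A single value per mutant row precludes a significance test, so the rule
    is a strict threshold: flagged iff |mutant - control mean| > 3 days,
    applied separately per field environment.
    """
    if mutant_days <= 0 or control_mean_days <= 0:
        raise ValueError("flowering times must be positive day counts")
    return (
        "flagged"
        if abs(mutant_days - control_mean_days) > max_days
        else "not_flagged"
    )
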