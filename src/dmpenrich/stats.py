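"""Per-sample significance machinery.

The enrichment test is a one-sided binomial upper tail: the test set's overlap
count ``k`` out of ``n`` probes is referred to Binomial(n, p0), where ``p0``
is the pooled overlap proportion across the matched background sets.  p-values
are computed entirely in log space (log-gamma binomial coefficients combined
with log-sum-exp over the tail), which keeps extreme enrichments finite and
fast where linear-scale arithmetic underflows.  Multiple testing across the
samples of a panel is corrected with Benjamini-Yekutieli (valid under the
dependence expected between related cell types), with Benjamini-Hochberg
co-reported as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests


@dataclass
class SampleCounts:
    """Overlap bookkeeping for one reference sample."""

    sample_id: str
    k: int                      # test-set overlap count
    n: int                      # test-set size
    background_counts: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def binom_upper_tail_log(k: int, n: int, p0: float) -> float:
    """Natural log of P(X >= k) for X ~ Binomial(n, p0), in log space throughout.

    Uses log-gamma binomial coefficients and log-sum-exp over the tail terms,
    so the result never underflows to -inf for ``p0 > 0`` and ``k <= n``.
    Returns 0.0 (= ln 1) for ``k <= 0`` or ``p0 >= 1``; ``p0 == 0`` with
    ``k > 0`` is the one genuinely impossible event and yields ``-inf``
    (callers floor p0 before getting here).
    """
    k, n = int(k), int(n)
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"require 0 <= p0 <= 1, got p0={p0}")
    if k == 0 or p0 == 1.0:
        return 0.0
    if p0 == 0.0:
        return -np.inf
    i = np.arange(k, n + 1, dtype=np.float64)
    log_pmf = (gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
               + i * np.log(p0) + (n - i) * np.log1p(-p0))
    return float(min(logsumexp(log_pmf), 0.0))


def zscore(k: float, background_counts) -> float:
    """Standardized test count against the background distribution.

    ``(k - mean) / sd`` with the sample standard deviation (ddof=1).  A
    degenerate background (sd = 0) gives 0 when ``k`` equals the common value
    and a signed infinity sentinel otherwise, which downstream reporting flags
    as an extreme rather than a number.
    """
    counts = np.asarray(background_counts, dtype=np.float64)
    if counts.size == 0:
        raise ValueError("background_counts must be non-empty")
    mean = counts.mean()
    sd = counts.std(ddof=1) if counts.size > 1 else 0.0
    if sd == 0.0:
        if k == mean:
            return 0.0
        return np.inf if k > mean else -np.inf
    return float((k - mean) / sd)


def _checked(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size and (np.any(p <= 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = _checked(pvalues)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def by_adjust(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli step-up q-values (BH inflated by c(m) = sum 1/i)."""
    p = _checked(pvalues)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


def p_threshold_for_q(pvalues, q_threshold: float, *, method: str = "by") -> float:
    """Largest raw p rejected at FDR level ``q_threshold`` for this family.

    Inverts the step-up rule: with m tests the j-th smallest p is rejected iff
    ``p_(j) <= j * q / (m * c)`` (c = harmonic sum for BY, 1 for BH); the
    boundary is that bound at the largest rejected rank (rank 1 if none).
    Used to draw the q-tier threshold lines on the significance plot.
    """
    p = np.sort(_checked(pvalues))
    m = p.size
    if m == 0:
        return float(q_threshold)
    c = float(np.sum(1.0 / np.arange(1, m + 1))) if method == "by" else 1.0
    bounds = np.arange(1, m + 1) * q_threshold / (m * c)
    rejected = np.flatnonzero(p <= bounds)
    rank = int(rejected.max()) + 1 if rejected.size else 1
    return float(rank * q_threshold / (m * c))
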