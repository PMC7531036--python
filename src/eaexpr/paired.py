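"""Transcript-paired exact binomial comparisons between contrasts.

Two questions about a pair of contrast tables sharing a probe universe:

* magnitude: is |log fold change| systematically larger in one contrast than
  the other?  Each probe is a paired observation; exact ties are excluded;
  the count of pairs favouring table A is referred to an exact two-sided
  binomial test against 1/2.
* direction consistency: among probes significant in both contrasts, how
  often do the fold changes agree in sign?  Reported with the exact
  two-sided binomial p and the 95% Clopper-Pearson interval.

The two-sided p-value uses the minimum-likelihood convention (the sum of
outcome probabilities no larger than the observed outcome's), which for the
symmetric 1/2 null equals the doubled symmetric tail.  Tail sums are
computed in log space (log-sum-exp of log binomial pmf terms), so p-values
far below the double-precision underflow threshold are still reported with
full relative accuracy through their logarithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ValidationError

logger = logging.getLogger("eaexpr")


@dataclass
class PairedTestResult:
    n: int                 # informative pairs
    k: int                 # successes (pairs favouring table A / agreeing)
    p: float               # two-sided exact binomial p vs 0.5
    log10_p: float         # accurate even when p underflows
    ci_low: float          # 95% Clopper-Pearson
    ci_high: float
    restriction: str       # "all" or "de_in_both"
    n_ties: int = 0


def _log_binom_tail(n: int, k_from: int) -> float:
    """log of P(X >= k_from) for X ~ Binomial(n, 1/2), via log-sum-exp."""
    ks = np.arange(k_from, n + 1)
    logpmf = special.gammaln(n + 1) - special.gammaln(ks + 1) \
        - special.gammaln(n - ks + 1) - n * np.log(2.0)
    return float(special.logsumexp(logpmf))


def binom_two_sided_log(n: int, k: int) -> tuple[float, float]:
    """Exact two-sided binomial p vs 0.5; returns (p, log10 p).

    By symmetry of the null, the minimum-likelihood two-sided p equals
    P(X >= max(k, n-k)) + P(X <= min(k, n-k)) = 2 P(X >= k') for k' > n/2.
    """
    if not (0 <= k <= n):
        raise ValidationError("need 0 <= k <= n")
    k_hi = max(k, n - k)
    if 2 * k_hi == n:
        return 1.0, 0.0
    logp = np.log(2.0) + _log_binom_tail(n, k_hi)
    logp = min(logp, 0.0)
    return float(np.exp(logp)), float(logp / np.log(10.0))


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval from beta
    quantiles; at k = n the upper bound is exactly 1 and the lower bound is
    (alpha/2)^(1/n)."""
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def _common(tableA: pd.DataFrame, tableB: pd.DataFrame) -> pd.Index:
    common = tableA.index.intersection(tableB.index)
    if len(common) == 0:
        raise ValidationError("tables share no probes")
    return common


def magnitude_binomial(
    tableA: pd.DataFrame,
    tableB: pd.DataFrame,
    restrict: str = "all",
) -> PairedTestResult:
    """Paired test of |logFC| magnitude between two contrast tables.

    ``restrict="de_in_both"`` keeps only probes significant in both tables.
    Exact |logFC| ties are excluded (count logged).  Success = |logFC_A| >
    |logFC_B|.
    """
    if restrict not in ("all", "de_in_both"):
        raise ValidationError(f"unknown restriction {restrict!r}")
    common = _common(tableA, tableB)
    a, b = tableA.loc[common], tableB.loc[common]
    if restrict == "de_in_both":
        keep = a["significant"] & b["significant"]
        a, b = a[keep], b[keep]
    absA, absB = a["logFC"].abs(), b["logFC"].abs()
    ties = absA == absB
    n_ties = int(ties.sum())
    if n_ties:
        logger.info("magnitude_binomial: %d exact tie(s) excluded", n_ties)
    absA, absB = absA[~ties], absB[~ties]
    n = len(absA)
    if n == 0:
        raise ValidationError("no informative pairs after restriction")
    k = int((absA > absB).sum())
    p, log10p = binom_two_sided_log(n, k)
    lo, hi = clopper_pearson(k, n)
    return PairedTestResult(
        n=n, k=k, p=p, log10_p=log10p, ci_low=lo, ci_high=hi,
        restriction=restrict, n_ties=n_ties,
    )


def direction_consistency(
    tableA: pd.DataFrame, tableB: pd.DataFrame
) -> PairedTestResult:
    """Agreement in sign of regulation among probes significant in both
    tables, with exact binomial p and 95% Clopper-Pearson interval."""
    common = _common(tableA, tableB)
    a, b = tableA.loc[common], tableB.loc[common]
    keep = a["significant"] & b["significant"]
    a, b = a[keep], b[keep]
    n = len(a)
    if n == 0:
        raise ValidationError("no probes significant in both tables")
    k = int((np.sign(a["logFC"]) == np.sign(b["logFC"])).sum())
    p, log10p = binom_two_sided_log(n, k)
    lo, hi = clopper_pearson(k, n)
    return PairedTestResult(
        n=n, k=k, p=p, log10_p=log10p, ci_low=lo, ci_high=hi,
        restriction="de_in_both",
    )
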