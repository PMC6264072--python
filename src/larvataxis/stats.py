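"""Shared statistics: exact binomial intervals, the two-proportion Z-test
and rank-based group comparisons with Bonferroni correction.

The Clopper-Pearson interval and the pooled Z-test are implemented here
because they carry the study's headline quantifications; rank tests are
delegated to scipy.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["BinomialCI", "clopper_pearson", "two_proportion_ztest", "group_compare"]


@dataclass(frozen=True)
class BinomialCI:
    k: int
    n: int
    level: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (0 <= self.lower <= self.k / self.n <= self.upper <= 1):
            raise ValueError("interval must bracket the point estimate")


def clopper_pearson(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact (Clopper-Pearson) binomial confidence interval.

    Beta-quantile formulation: ``lower = BetaInv(alpha/2; k, n-k+1)`` (0 for
    k = 0) and ``upper = BetaInv(1 - alpha/2; k+1, n-k)`` (1 for k = n),
    equivalent to inverting the binomial CDF at both tails.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n and n >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return BinomialCI(k=int(k), n=int(n), level=level, lower=lower, upper=upper)


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> dict:
    """Pooled two-proportion Z-test with a two-sided normal p-value."""
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        logger.warning("pooled proportion is %g; z undefined", pooled)
        return {"z": float("nan"), "p_two_sided": float("nan"), "pooled": pooled}
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return {"z": float(z), "p_two_sided": float(p), "pooled": float(pooled)}


def group_compare(
    samples: dict,
    design: str = "independent",
    correction: str = "bonferroni",
    exact_threshold: int = 25,
) -> pd.DataFrame:
    """Pairwise rank tests across groups with Bonferroni correction.

    Independent design uses the Wilcoxon rank-sum (Mann-Whitney) test,
    paired design the Wilcoxon signed-rank test; the exact null
    distribution is used when every group is smaller than
    ``exact_threshold``, the normal approximation otherwise.  Adjusted
    p-values are ``min(1, p * m)`` over the ``m`` pairwise comparisons.
    """
    if design not in ("independent", "paired"):
        raise ValueError("design must be 'independent' or 'paired'")
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, float) for k, v in samples.items()}
    for name, arr in arrays.items():
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
    pairs = list(itertools.combinations(arrays, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        xa, xb = arrays[a], arrays[b]
        method = "wilcoxon-ranksum" if design == "independent" else "wilcoxon-signed-rank"
        degenerate = (design == "paired" and np.array_equal(xa, xb)) or (
            len(set(np.r_[xa, xb])) == 1
        )
        if degenerate:
            rows.append({"group_a": a, "group_b": b, "stat": 0.0, "p": 1.0,
                         "p_adjusted": 1.0, "method": method, "family_size": m})
            continue
        exact = max(len(xa), len(xb)) < exact_threshold
        if design == "independent":
            res = sps.mannwhitneyu(xa, xb, alternative="two-sided",
                                   method="exact" if exact else "asymptotic")
        else:
            if len(xa) != len(xb):
                raise ValueError("paired design requires equal group sizes")
            res = sps.wilcoxon(xa, xb, method="exact" if exact else "approx")
        p = float(res.pvalue)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "stat": float(res.statistic),
                "p": p,
                "p_adjusted": min(1.0, p * m) if correction == "bonferroni" else p,
                "method": "wilcoxon-ranksum" if design == "independent" else "wilcoxon-signed-rank",
                "family_size": m,
            }
        )
    return pd.DataFrame(rows)
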