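"""Statistical procedures applied to pipeline outputs.

Two-sample Kolmogorov-Smirnov with the asymptotic two-sided p-value,
per-category exact 2x2 tests with Benjamini-Hochberg correction, and
Pearson correlation with a Fisher-z confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided two-sample KS test, asymptotic p-value.

    D = sup_x |ECDF_a(x) - ECDF_b(x)|.  The asymptotic (not exact) null
    distribution is used, matching common practice at genomic sample sizes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires non-empty samples")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method="ks_2samp_asymp",
        n1=a.size,
        n2=b.size,
    )


def category_fdr_test(
    counts_a: Dict[str, int], counts_b: Dict[str, int]
) -> pd.DataFrame:
    """Per-category two-sided exact 2x2 tests with BH q-values.

    For each category a Fisher exact test on the 2x2 table (category vs
    rest, condition A vs B); q-values by Benjamini-Hochberg across
    categories.  Returns a frame with category, counts, odds ratio, p, q.
    """
    if set(counts_a) != set(counts_b):
        raise ValueError("category sets differ")
    cats = sorted(counts_a)
    tot_a = sum(counts_a.values())
    tot_b = sum(counts_b.values())
    if tot_a <= 0 or tot_b <= 0:
        raise ValueError("totals must be positive")
    rows = []
    for cat in cats:
        na, nb = counts_a[cat], counts_b[cat]
        if na < 0 or nb < 0:
            raise ValueError(f"negative count for {cat!r}")
        table = [[na, tot_a - na], [nb, tot_b - nb]]
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        rows.append({"category": cat, "count_a": na, "count_b": nb,
                     "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def pearson_ci(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> Tuple[float, float, float]:
    """Pearson r with a Fisher-z confidence interval.

    z = atanh(r), se = 1/sqrt(n - 3); the interval is tanh(z -+ z_crit*se).
    Degenerate r = +-1 returns a point interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4 or y.size != n:
        raise ValueError("need matched samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(sps.pearsonr(x, y).statistic)
    # collinear data can land a few ulp inside +-1; the Fisher z transform
    # diverges there, so report the degenerate point interval
    if abs(r) >= 1.0 - 1e-12:
        r = math.copysign(1.0, r)
        return r, r, r
    zcrit = float(sps.norm.ppf(0.5 + confidence / 2))
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    return r, math.tanh(z - zcrit * se), math.tanh(z + zcrit * se)
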