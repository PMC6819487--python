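"""Paired two-sample comparison of localization-percentage vectors.

A deliberately small validation surface: given two equal-length vectors of
per-category localization percentages (for example, the same protein's
genic-localization breakdown computed with and without mock-control
filtering), report the spreadsheet-style "paired two sample for means"
panel — means, sample variances, Pearson correlation, the paired t
statistic with df = n - 1, one- and two-tailed p-values, and the critical
t values at the chosen significance level.

With d = a - b, the statistic is t = mean(d) / (sd(d) / sqrt(n)) where
sd uses the n-1 denominator.  When sd(d) = 0 the statistic is 0 for a
zero mean difference and signed infinity otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DataError


@dataclass(frozen=True)
class PairedComparison:
    mean_a: float
    mean_b: float
    var_a: float          # sample variance (n-1 denominator)
    var_b: float
    n: int
    pearson_r: float
    hypothesized_mean_difference: float
    df: int
    t_stat: float
    p_one_tail: float
    p_two_tail: float
    t_crit_one_tail: float
    t_crit_two_tail: float
    alpha: float

    def as_rows(self) -> list[tuple[str, object]]:
        """Ordered (label, value) rows mirroring the spreadsheet panel."""
        return [
            ("Mean", (self.mean_a, self.mean_b)),
            ("Variance", (self.var_a, self.var_b)),
            ("Observations", (self.n, self.n)),
            ("Pearson Correlation", self.pearson_r),
            ("Hypothesized Mean Difference", self.hypothesized_mean_difference),
            ("df", self.df),
            ("t Stat", self.t_stat),
            ("P(T<=t) one-tail", self.p_one_tail),
            ("t Critical one-tail", self.t_crit_one_tail),
            ("P(T<=t) two-tail", self.p_two_tail),
            ("t Critical two-tail", self.t_crit_two_tail),
        ]


def paired_comparison(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    hypothesized_mean_difference: float = 0.0,
) -> PairedComparison:
    """Paired t-test and Pearson correlation for two matched vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError(
            f"paired_comparison needs two equal-length vectors, "
            f"got shapes {a.shape} and {b.shape}"
        )
    n = a.size
    if n < 2:
        raise DataError(f"paired_comparison needs n >= 2 observations, got {n}")
    df = n - 1

    d = a - b - hypothesized_mean_difference
    mean_d = d.mean()
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        t_stat = 0.0 if mean_d == 0 else math.copysign(math.inf, mean_d)
    else:
        t_stat = mean_d / (sd_d / math.sqrt(n))

    if math.isinf(t_stat):
        p_one = 0.0
    else:
        p_one = float(sps.t.sf(abs(t_stat), df))
    p_two = 2.0 * p_one

    if a.std() == 0 or b.std() == 0:
        pearson_r = float("nan")
    else:
        pearson_r = float(np.corrcoef(a, b)[0, 1])

    return PairedComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        var_a=float(a.var(ddof=1)),
        var_b=float(b.var(ddof=1)),
        n=n,
        pearson_r=pearson_r,
        hypothesized_mean_difference=hypothesized_mean_difference,
        df=df,
        t_stat=float(t_stat),
        p_one_tail=p_one,
        p_two_tail=p_two,
        t_crit_one_tail=float(sps.t.ppf(1 - alpha, df)),
        t_crit_two_tail=float(sps.t.ppf(1 - alpha / 2, df)),
        alpha=alpha,
    )
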