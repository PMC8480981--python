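"""Age-standardized incidence rates and generic two-sample tests.

Direct standardization weights stratum-specific rates by a standard
population's age distribution (e.g. the 2010 US standard population),
reporting rates per 100,000.  The module also exposes the pooled
two-proportion z test and the Welch t test used for spectrum and
proportion comparisons elsewhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgeStratum",
    "AdjustedRateResult",
    "age_adjusted_rate",
    "rate_ratio",
    "two_proportion_ztest",
    "welch_t_test",
    "read_strata",
]

_WEIGHT_TOL = 1e-6


@dataclass(frozen=True)
class AgeStratum:
    label: str
    cases: int
    person_base: int
    weight: float

    def __post_init__(self) -> None:
        if self.cases < 0:
            raise ValueError("cases must be >= 0")
        if self.person_base <= 0:
            raise ValueError("person_base must be > 0")


@dataclass(frozen=True)
class AdjustedRateResult:
    rate_per_100k: float
    stratum_rates: tuple[float, ...]


def age_adjusted_rate(strata: Sequence[AgeStratum]) -> AdjustedRateResult:
    """Directly age-standardized rate per 100,000.

    rate = sum over age groups of (cases / person_base) * 100000 * weight,
    with the weights required to sum to 1 (within 1e-6).
    """
    if not strata:
        raise ValueError("need >= 1 stratum")
    wsum = sum(s.weight for s in strata)
    if abs(wsum - 1.0) > _WEIGHT_TOL:
        raise ValueError(f"stratum weights must sum to 1, got {wsum}")
    stratum_rates = tuple(s.cases / s.person_base * 100_000 for s in strata)
    rate = float(sum(r * s.weight for r, s in zip(stratum_rates, strata)))
    return AdjustedRateResult(rate_per_100k=rate, stratum_rates=stratum_rates)


def rate_ratio(rate_a: float, rate_b: float, decimals: int = 1) -> float:
    """Ratio of two incidence rates, reported to one decimal by default."""
    if rate_b <= 0:
        raise ValueError("reference rate must be > 0")
    return round(rate_a / rate_b, decimals)


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> dict:
    """Pooled-variance two-proportion z test (two-sided).

    Degenerate pooled proportions (0 or 1) give z = 0, p = 1 with a
    ``degenerate`` flag.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("require 0 <= x <= n, n >= 1")
    p_pool = (x1 + x2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return {"z": 0.0, "p_two_sided": 1.0, "degenerate": True}
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2 * stats.norm.sf(abs(z))
    return {"z": float(z), "p_two_sided": float(p), "degenerate": False}


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> dict:
    """Welch two-sample t test with Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return {"t": 0.0, "df": float(len(a) + len(b) - 2), "p_two_sided": 1.0}
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return {"t": float(res.statistic), "df": float(df), "p_two_sided": float(res.pvalue)}


def read_strata(path: str | Path) -> list[AgeStratum]:
    """Read an age-strata CSV with columns label,cases,person_base,weight."""
    df = pd.read_csv(path)
    return [
        AgeStratum(
            label=str(r.label),
            cases=int(r.cases),
            person_base=int(r.person_base),
            weight=float(r.weight),
        )
        for r in df.itertuples(index=False)
    ]
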