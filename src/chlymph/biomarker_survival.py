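"""Multiple-hit TET2 biomarker and CHN-free survival analysis.

The biomarker calls a patient positive when the clonal hematopoiesis in
their bone marrow / peripheral blood harbors two or more pathogenic
(tier 1/2) TET2 variants, each with VAF >= 15%.  CHN-free survival —
time from lymphoma diagnosis to occurrence of a concomitant hematologic
neoplasm, censored at death or last follow-up without CHN — is compared
between biomarker groups with Kaplan-Meier curves, the log-rank test,
and a binary-covariate Cox proportional-hazards model (Efron ties).
Diagnostic accuracy of the biomarker against observed CHN is summarised
as sensitivity/specificity/PPV/NPV, and a brute-force reconstruction
oracle recovers the unique 2x2 confusion table consistent with printed
(rounded) metrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .cohort_io import Variant

__all__ = [
    "BiomarkerCall",
    "SurvivalRecord",
    "KMCurve",
    "ConfusionTable",
    "CoxResult",
    "call_multihit_tet2",
    "km_estimate",
    "logrank_test",
    "cox_hr_binary",
    "diagnostic_metrics",
    "reconstruct_confusion",
    "chn_free_analysis",
]

PATHOGENIC_TIERS = frozenset({1, 2})


@dataclass(frozen=True)
class BiomarkerCall:
    patient_id: str
    positive: bool
    n_qualifying_tet2: int
    qualifying_vafs: tuple[float, ...]


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time_months: float
    event: int  # CHN occurrence
    group: str  # {"high_burden", "low_or_absent"}

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ValueError("time_months must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("KM survival must be non-increasing")


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    monotone_likelihood: bool = False


def call_multihit_tet2(
    ch_variants: Iterable[Variant],
    vaf_min: float = 0.15,
    min_hits: int = 2,
    vaf_inclusive: bool = True,
) -> BiomarkerCall:
    """Multiple-hit TET2 biomarker call from a patient's CH variants.

    Counts TET2 variants that are pathogenic (tier 1 or 2) and carry
    VAF >= ``vaf_min`` (inclusive by default; the comparison operator is
    configurable).  Positive iff at least ``min_hits`` qualify.
    """
    variants = list(ch_variants)
    pid = variants[0].patient_id if variants else ""
    qualifying = [
        v.vaf
        for v in variants
        if v.gene == "TET2"
        and v.tier in PATHOGENIC_TIERS
        and (v.vaf >= vaf_min if vaf_inclusive else v.vaf > vaf_min)
    ]
    return BiomarkerCall(
        patient_id=pid,
        positive=len(qualifying) >= min_hits,
        n_qualifying_tet2=len(qualifying),
        qualifying_vafs=tuple(sorted(qualifying, reverse=True)),
    )


def _to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [r.time_months for r in records],
            "event": [r.event for r in records],
            "group": [r.group for r in records],
        }
    )


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit (Kaplan-Meier) survival estimate.

    Ties are handled by simultaneous risk-set reduction; censored times
    leave the curve flat.
    """
    if not records:
        raise ValueError("need >= 1 record")
    if any(r.time_months < 0 for r in records):
        raise ValueError("negative survival time")
    df = _to_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(times, method="ffill").to_numpy()
    return KMCurve(times=times, survival=surv, at_risk=at_risk)


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> dict:
    """Two-group log-rank test (1 df) on CHN-free survival."""
    if not group_a or not group_b:
        raise ValueError("both groups need >= 1 record")
    events = sum(r.event for r in group_a) + sum(r.event for r in group_b)
    if events == 0:
        warnings.warn("no events in either group; log-rank p set to 1")
        return {"chi2": 0.0, "p_value": 1.0}
    a, b = _to_frame(group_a), _to_frame(group_b)
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return {"chi2": float(res.test_statistic), "p_value": float(res.p_value)}


def cox_hr_binary(records: Sequence[SurvivalRecord]) -> CoxResult:
    """Cox proportional-hazards fit with the biomarker group as the
    single binary covariate (Efron tie handling, Wald 95% CI).

    Complete separation of events between groups drives the partial
    likelihood monotone; the result is then flagged and the CI is
    unbounded.
    """
    df = _to_frame(records)
    if df["event"].sum() == 0:
        raise ValueError("no events in the data")
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    # high_burden (or lexicographically later group) coded 1
    positive = "high_burden" if "high_burden" in groups else groups[-1]
    df["x"] = (df["group"] == positive).astype(float)
    events_by_group = df.groupby("x")["event"].sum()
    monotone = bool((events_by_group == 0).any())
    cph = CoxPHFitter()
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        try:
            cph.fit(df[["time", "event", "x"]], duration_col="time", event_col="event")
        except Exception:
            if monotone:
                return CoxResult(math.inf, 0.0, math.inf, math.nan, True)
            # near-separation can break the unpenalized Newton-Raphson even
            # with events in both groups; a light ridge stabilizes it, and
            # the runaway-coefficient check below still flags the result
            try:
                cph = CoxPHFitter(penalizer=0.1)
                cph.fit(df[["time", "event", "x"]], duration_col="time",
                        event_col="event")
            except Exception:
                return CoxResult(math.inf, 0.0, math.inf, math.nan, True)
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    p = float(cph.summary.loc["x", "p"])
    # a near-separated data set drives the partial likelihood monotone:
    # the coefficient runs away and the Wald SE explodes
    if monotone or abs(coef) > 15 or se > 10:
        return CoxResult(math.exp(min(coef, 700.0)), 0.0, math.inf, p, True)
    z = 1.959963984540054
    return CoxResult(
        hr=math.exp(coef),
        ci_low=math.exp(coef - z * se),
        ci_high=math.exp(coef + z * se),
        p_value=p,
        monotone_likelihood=False,
    )


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def diagnostic_metrics(table: ConfusionTable, decimals: int = 1) -> dict:
    """Sensitivity/specificity/PPV/NPV as percentages (half-up rounding).

    A metric with a zero denominator is reported as None.
    """
    def pct(num: int, den: int) -> float | None:
        if den == 0:
            return None
        return _round_half_up(100.0 * num / den, decimals)

    return {
        "sensitivity": pct(table.tp, table.tp + table.fn),
        "specificity": pct(table.tn, table.tn + table.fp),
        "ppv": pct(table.tp, table.tp + table.fp),
        "npv": pct(table.tn, table.tn + table.fn),
    }


def reconstruct_confusion(
    n_total: int, sens_pct: float, spec_pct: float, decimals: int = 1
) -> list[ConfusionTable]:
    """All 2x2 tables of size ``n_total`` whose sensitivity and
    specificity round (half-up) to the given percentages.

    Exhaustive search over non-negative integer tables; an empty list
    means the printed values are jointly unattainable at that size.
    """
    if n_total > 10_000:
        raise ValueError("n_total too large for exhaustive search")
    out = []
    for n_pos in range(n_total + 1):  # event-positive cases: tp + fn
        n_neg = n_total - n_pos
        for tp in range(n_pos + 1):
            if n_pos > 0 and _round_half_up(100.0 * tp / n_pos, decimals) != sens_pct:
                continue
            if n_pos == 0:
                continue
            for tn in range(n_neg + 1):
                if n_neg == 0:
                    continue
                if _round_half_up(100.0 * tn / n_neg, decimals) != spec_pct:
                    continue
                out.append(ConfusionTable(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn))
    return out


def chn_free_analysis(
    records: Sequence[SurvivalRecord],
    calls: Mapping[str, BiomarkerCall] | Sequence[BiomarkerCall],
) -> dict:
    """Full biomarker report: per-group KM, log-rank, Cox HR, and
    diagnostic metrics of the biomarker against observed CHN.

    With a single biomarker group the survival comparisons are skipped
    with a warning; the confusion-table metrics are still computed.
    """
    if not isinstance(calls, Mapping):
        calls = {c.patient_id: c for c in calls}
    missing = [r.patient_id for r in records if r.patient_id not in calls]
    if missing:
        raise ValueError(f"no biomarker call for patients: {missing[:5]}")
    pos = [r for r in records if calls[r.patient_id].positive]
    neg = [r for r in records if not calls[r.patient_id].positive]
    table = ConfusionTable(
        tp=sum(r.event for r in pos),
        fp=sum(1 - r.event for r in pos),
        fn=sum(r.event for r in neg),
        tn=sum(1 - r.event for r in neg),
    )
    report: dict = {
        "n_positive": len(pos),
        "n_negative": len(neg),
        "confusion": table,
        "metrics": diagnostic_metrics(table),
    }
    if not pos or not neg:
        warnings.warn("single biomarker group; survival comparisons skipped")
        report.update({"km": None, "logrank": None, "cox": None})
        return report
    regroup = [
        SurvivalRecord(r.patient_id, r.time_months, r.event,
                       "high_burden" if calls[r.patient_id].positive else "low_or_absent")
        for r in records
    ]
    pos_g = [r for r in regroup if r.group == "high_burden"]
    neg_g = [r for r in regroup if r.group == "low_or_absent"]
    report["km"] = {"high_burden": km_estimate(pos_g), "low_or_absent": km_estimate(neg_g)}
    report["logrank"] = logrank_test(pos_g, neg_g)
    total_events = sum(r.event for r in regroup)
    report["cox"] = cox_hr_binary(regroup) if total_events > 0 else None
    return report
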