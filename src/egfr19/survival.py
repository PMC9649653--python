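"""Profile-stratified time-to-event comparison.

Progression-free (or overall) survival of patients whose tumours carry
profile 1 versus profile 2 exon 19 variants is compared with the
Kaplan–Meier product-limit estimator, the median survival time (smallest t
with S(t) <= 0.5), and the log-rank (Mantel–Cox) test.  Estimation is
delegated to ``lifelines``; this module adapts it to the package's record
types and conventions (events precede censorings at tied times, the
lifelines default).

Multivariable Cox regression is deliberately out of scope: `to_dataframe`
exposes cohorts in the tidy layout that standard survival packages consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .variants import classify_descriptor


@dataclass(frozen=True)
class SurvivalRecord:
    id: str
    time_months: float
    event: int  # 1 = progression/death observed, 0 = censored
    profile: Optional[int] = None
    variant_descriptor: Optional[str] = None

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError(f"record {self.id}: time must be positive")
        if self.event not in (0, 1):
            raise ValueError(f"record {self.id}: event must be 0 or 1")


def resolve_profiles(records: Sequence[SurvivalRecord]) -> Tuple[SurvivalRecord, ...]:
    """Fill missing profile labels by classifying each variant descriptor."""
    out = []
    for r in records:
        if r.profile is None:
            if r.variant_descriptor is None:
                raise ValueError(f"record {r.id}: neither profile nor descriptor")
            call = classify_descriptor(r.variant_descriptor)
            r = SurvivalRecord(
                r.id, r.time_months, r.event, call.profile, r.variant_descriptor
            )
        out.append(r)
    return tuple(out)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier step function with at-risk counts and censor marks."""

    times: np.ndarray  # ascending event/censor times
    survival: np.ndarray  # S(t) at those times (right-continuous steps)
    at_risk: np.ndarray
    censor_times: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t) of the step function (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit estimate of the survival function."""
    if not records:
        raise ValueError("no records supplied")
    t = np.array([r.time_months for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_["KM_estimate"]
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    # lifelines includes t=0 with S=1; keep observed times only
    mask = times > 0
    at_risk = kmf.event_table["at_risk"].reindex(times[mask]).to_numpy(dtype=float)
    return KMCurve(
        times=times[mask],
        survival=surv[mask],
        at_risk=at_risk,
        censor_times=np.sort(t[e == 0]),
        n=len(records),
    )


def median_survival(curve: KMCurve) -> Optional[float]:
    """Smallest time with S(t) <= 0.5, or None if S never reaches 0.5."""
    below = curve.survival <= 0.5
    if not below.any():
        return None
    return float(curve.times[np.argmax(below)])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float  # chi-square, 1 df
    p_value: float
    n_a: int
    n_b: int
    events_a: int
    events_b: int


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogRankResult:
    """Two-sided log-rank (Mantel-Cox) test on pooled event times."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ea = sum(r.event for r in group_a)
    eb = sum(r.event for r in group_b)
    if ea + eb == 0:
        raise ValueError("log-rank test undefined with zero events")
    res = _ll_logrank(
        np.array([r.time_months for r in group_a]),
        np.array([r.time_months for r in group_b]),
        event_observed_A=np.array([r.event for r in group_a]),
        event_observed_B=np.array([r.event for r in group_b]),
    )
    return LogRankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n_a=len(group_a),
        n_b=len(group_b),
        events_a=int(ea),
        events_b=int(eb),
    )


def compare_profiles(records: Sequence[SurvivalRecord]) -> Dict[str, object]:
    """KM curves, medians, and log-rank comparison of profile 1 vs profile 2."""
    records = resolve_profiles(records)
    g1 = [r for r in records if r.profile == 1]
    g2 = [r for r in records if r.profile == 2]
    out: Dict[str, object] = {"n_profile1": len(g1), "n_profile2": len(g2)}
    if g1:
        c1 = km_estimate(g1)
        out["km_profile1"] = c1
        out["median_profile1"] = median_survival(c1)
    if g2:
        c2 = km_estimate(g2)
        out["km_profile2"] = c2
        out["median_profile2"] = median_survival(c2)
    if g1 and g2:
        out["logrank"] = logrank_test(g1, g2)
    return out


def to_dataframe(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    """Tidy layout (id, time_months, event, profile, variant) for external
    survival packages (e.g. Cox proportional-hazards fits)."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "time_months": r.time_months,
                "event": r.event,
                "profile": r.profile,
                "variant_descriptor": r.variant_descriptor,
            }
            for r in records
        ]
    )
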