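"""Person-time incidence rates, intervals, and cumulative incidence.

Rates are reported as events per 1000 person-years. Interval defaults are
exact Poisson (Garwood, chi-square) bounds on the event count scaled by
person-time; a normal-approximation alternative is available. Absolute
rate differences between exposure groups use the normal approximation with
variance events/person-years² per group. Cumulative incidence is the
product-limit (Kaplan-Meier) complement, with censoring at the end of each
patient's follow-up.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .types import FollowUpRecord, IncidenceEstimate, RateDifference


def exact_poisson_ci(
    events: int, person_years: float, level: float = 0.95
) -> tuple[float, float]:
    """Garwood exact Poisson CI for the rate, per 1000 person-years.

    The chi-square bounds on the expected count are
    lower = chi2.ppf(alpha/2, 2k)/2 (0 when k = 0) and
    upper = chi2.ppf(1 - alpha/2, 2k + 2)/2, scaled by 1000/person-years.
    """
    _check(events, person_years)
    alpha = 1.0 - level
    lo = 0.0 if events == 0 else stats.chi2.ppf(alpha / 2, 2 * events) / 2.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2.0
    scale = 1000.0 / person_years
    return lo * scale, hi * scale


def normal_poisson_ci(
    events: int, person_years: float, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation CI for the rate, per 1000 person-years."""
    _check(events, person_years)
    z = stats.norm.ppf(0.5 + level / 2.0)
    rate = 1000.0 * events / person_years
    se = 1000.0 * np.sqrt(events) / person_years
    return rate - z * se, rate + z * se


def incidence_rate(
    events: int,
    person_years: float,
    level: float = 0.95,
    method: str = "exact",
) -> IncidenceEstimate:
    """Point estimate and CI for an incidence rate per 1000 person-years."""
    _check(events, person_years)
    ci_fn = {"exact": exact_poisson_ci, "normal": normal_poisson_ci}.get(method)
    if ci_fn is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = ci_fn(events, person_years, level)
    return IncidenceEstimate(
        events=events,
        person_years=person_years,
        rate_per_1000=1000.0 * events / person_years,
        ci_low=lo,
        ci_high=hi,
    )


def rate_difference(
    events_a: int,
    py_a: float,
    events_b: int,
    py_b: float,
    level: float = 0.95,
) -> RateDifference:
    """Absolute rate difference (a − b) per 1000 PY with a normal CI.

    The difference uses unrounded rates; the standard error is
    1000·sqrt(events_a/py_a² + events_b/py_b²).
    """
    _check(events_a, py_a)
    _check(events_b, py_b)
    z = stats.norm.ppf(0.5 + level / 2.0)
    diff = 1000.0 * (events_a / py_a - events_b / py_b)
    se = 1000.0 * np.sqrt(events_a / py_a**2 + events_b / py_b**2)
    return RateDifference(diff_per_1000=diff, ci_low=diff - z * se, ci_high=diff + z * se)


def _check(events: int, person_years: float) -> None:
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if events < 0:
        raise ValueError("events must be non-negative")


# ---------------------------------------------------------------------------
# cohort-level computations


def landmark_filter(
    records: list[FollowUpRecord], days: float = 30.0
) -> list[FollowUpRecord]:
    """Landmark sensitivity filter: drop events within ``days`` of index.

    Patients whose event fell inside the landmark window are excluded
    entirely; event-free patients are kept unchanged.
    """
    cutoff = days / 365.25
    return [r for r in records if not (r.event and r.time_years < cutoff)]


def group_incidence(
    records: list[FollowUpRecord],
    level: float = 0.95,
    method: str = "exact",
) -> dict[str, IncidenceEstimate]:
    """Incidence estimate per exposure category from follow-up records."""
    out: dict[str, IncidenceEstimate] = {}
    frame = pd.DataFrame(
        {
            "group": [r.exposure_category for r in records],
            "time": [r.time_years for r in records],
            "event": [r.event for r in records],
        }
    )
    for group, sub in frame.groupby("group", sort=True):
        out[str(group)] = incidence_rate(
            int(sub["event"].sum()), float(sub["time"].sum()), level, method
        )
    return out


def incidence_table(
    records: list[FollowUpRecord],
    reference: str | None = None,
    level: float = 0.95,
    method: str = "exact",
) -> pd.DataFrame:
    """Cohort risk table: events, person-years, rate [CI], and the absolute
    rate difference [CI] against a reference category."""
    estimates = group_incidence(records, level, method)
    rows = []
    ref = estimates.get(reference) if reference else None
    for group, est in estimates.items():
        row = {
            "group": group,
            "events": est.events,
            "person_years": est.person_years,
            "rate_per_1000": est.rate_per_1000,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
        }
        if ref is not None and group != reference:
            rd = rate_difference(
                est.events, est.person_years, ref.events, ref.person_years, level
            )
            row.update(
                rate_diff=rd.diff_per_1000,
                rate_diff_ci_low=rd.ci_low,
                rate_diff_ci_high=rd.ci_high,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def cumulative_incidence_curve(
    records: list[FollowUpRecord], group: str | None = None
) -> pd.DataFrame:
    """Product-limit cumulative incidence (1 − S) for one exposure group.

    Returns a step function as a frame with columns ``time`` and
    ``cumulative_incidence``; the curve is non-decreasing in time.
    """
    sel = [r for r in records if group is None or r.exposure_category == group]
    if not sel:
        raise ValueError(f"no follow-up records for group {group!r}")
    km = KaplanMeierFitter()
    km.fit(
        durations=[r.time_years for r in sel],
        event_observed=[r.event for r in sel],
    )
    sf = km.survival_function_
    return pd.DataFrame(
        {
            "time": sf.index.to_numpy(dtype=float),
            "cumulative_incidence": 1.0 - sf.iloc[:, 0].to_numpy(dtype=float),
        }
    )


def survival_frame(records: list[FollowUpRecord]) -> pd.DataFrame:
    """Analysis dataset in a survival-ready layout (for external Cox fits)."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "exposure_category": [r.exposure_category for r in records],
            "time_years": [r.time_years for r in records],
            "event": [int(r.event) for r in records],
        }
    )


def simulate_cohort(
    hazards_per_1000: dict[str, float],
    n_per_group: int,
    max_follow_up_years: float = 25.0,
    seed: int | np.random.Generator = 0,
) -> list[FollowUpRecord]:
    """Simulate a cohort with constant per-category hazards.

    Event times are exponential with the stated hazard (per 1000 PY);
    follow-up is administratively censored at ``max_follow_up_years``,
    emulating a registry with a multi-decade observation window.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[FollowUpRecord] = []
    for group, h in hazards_per_1000.items():
        rate = h / 1000.0
        event_t = rng.exponential(1.0 / rate, size=n_per_group)
        censor_t = np.full(n_per_group, max_follow_up_years)
        for i in range(n_per_group):
            t = min(event_t[i], censor_t[i])
            records.append(
                FollowUpRecord(
                    patient_id=f"{group}-{i}",
                    exposure_category=group,
                    time_years=float(t),
                    event=bool(event_t[i] <= censor_t[i]),
                )
            )
    return records


def read_followup_csv(path) -> list[FollowUpRecord]:
    """Read follow-up records from CSV with columns patient_id,
    exposure_category, time_years, event."""
    frame = pd.read_csv(path)
    return [
        FollowUpRecord(
            patient_id=str(r.patient_id),
            exposure_category=str(r.exposure_category),
            time_years=float(r.time_years),
            event=bool(int(r.event)),
        )
        for r in frame.itertuples()
    ]
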