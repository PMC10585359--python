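"""Temporal discrepancy-rate statistics with monthly resampling.

Three empirical views of a double-read cohort, all on a standardized grid
of one month (= 30.4375 days):

* cumulative discrepancy rate on the trial clock (discrepant patients
  included since trial start over patients included since trial start);
* the distribution of discrepancies along the patient-relative follow-up
  axis (percentages summing to 100);
* the per-interval probability of a first discrepancy among patients still
  evaluated and not yet discrepant (a discrete hazard);

plus a model-based expected cumulative rate combining an accrual series, an
on-study survival series and a per-interval discrepancy probability.

All interval estimates carry two-sided exact (Clopper-Pearson) confidence
bounds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kod import KOD_NAMES
from .stats import clopper_pearson

logger = logging.getLogger(__name__)

__all__ = [
    "MONTH_DAYS",
    "TrialTimeSeries",
    "build_time_series",
    "rate_over_time",
    "prop_disc_by_followup",
    "p_disc_by_followup",
    "expected_rate",
    "followup_percentile",
    "end_of_trial_rates",
    "rates_from_counts",
]

#: days per standardized month used for all resampling
MONTH_DAYS = 30.4375


def day_to_event_month(day: float) -> int:
    """Follow-up interval index of an event day: days (0, 30.4375] -> 1."""
    return max(1, int(math.ceil(day / MONTH_DAYS - 1e-9)))


def day_to_calendar_month(day: float) -> int:
    """Calendar month index of a date: days [0, 30.4375) -> 0."""
    return int(math.floor(day / MONTH_DAYS + 1e-9))


@dataclass
class TrialTimeSeries:
    """Monthly-resampled view of one cohort.

    ``inclusion_month`` is on the trial clock (0 = first patient in);
    ``followup_months`` and the event months in ``kod_fu_month`` are on the
    patient-relative follow-up clock (first interval = 1).  Event entries
    are NaN for patients without that discrepancy.
    """

    inclusion_month: np.ndarray
    followup_months: np.ndarray
    kod_fu_month: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inclusion_month = np.asarray(self.inclusion_month, dtype=int)
        self.followup_months = np.asarray(self.followup_months, dtype=int)
        n = self.inclusion_month.size
        if self.followup_months.size != n:
            raise ValueError("per-patient arrays must align")
        if np.any(self.followup_months < 1):
            raise ValueError("every patient needs >= 1 follow-up interval")
        for name, ev in self.kod_fu_month.items():
            ev = np.asarray(ev, dtype=float)
            self.kod_fu_month[name] = ev
            if ev.size != n:
                raise ValueError(f"{name}: event array must align")
            obs = ev[~np.isnan(ev)]
            if np.any(obs < 1) or np.any(obs > self.followup_months[~np.isnan(ev)]):
                raise ValueError(
                    f"{name}: events must fall inside the on-study interval"
                )

    @property
    def n_patients(self) -> int:
        return int(self.inclusion_month.size)

    def event_trial_month(self, kod_name: str) -> np.ndarray:
        return self.inclusion_month + self.kod_fu_month[kod_name]


def build_time_series(
    kod_df: pd.DataFrame,
    inclusion_day: pd.Series | dict | None = None,
    kods: tuple[str, ...] = KOD_NAMES,
) -> TrialTimeSeries:
    """Assemble a :class:`TrialTimeSeries` from a per-patient KoD table.

    ``kod_df`` needs ``patient_id``, ``included``, ``last_common_day`` and
    per-KoD flag/day columns (the output of :func:`doubleread.kod.kod_table`).
    ``inclusion_day`` maps patient id to the trial day of the patient's
    baseline; all patients are taken as included at day 0 when omitted.
    """
    df = kod_df[kod_df["included"]].reset_index(drop=True)
    if df.empty:
        raise ValueError("no included patients")
    if inclusion_day is None:
        incl_days = np.zeros(len(df))
    else:
        mapping = (
            inclusion_day
            if isinstance(inclusion_day, dict)
            else inclusion_day.to_dict()
        )
        incl_days = np.array([float(mapping[p]) for p in df["patient_id"]])
    inclusion_month = np.array([day_to_calendar_month(d) for d in incl_days])
    followup = np.array(
        [day_to_event_month(d) for d in df["last_common_day"]]
    )
    events: dict[str, np.ndarray] = {}
    for name in kods:
        ev = np.full(len(df), np.nan)
        for i, (flag, day) in enumerate(zip(df[name], df[f"{name}_day"])):
            if bool(flag) and not pd.isna(day):
                ev[i] = min(day_to_event_month(float(day)), followup[i])
        events[name] = ev
    return TrialTimeSeries(inclusion_month, followup, events)


def _cp_bounds(x: np.ndarray, n: np.ndarray, level: float):
    lo = np.empty(x.size)
    hi = np.empty(x.size)
    for i, (xi, ni) in enumerate(zip(x, n)):
        ci = clopper_pearson(int(xi), int(ni), level)
        lo[i], hi[i] = ci.low, ci.high
    return lo, hi


def rate_over_time(
    series: TrialTimeSeries, kod_name: str, level: float = 0.95
) -> pd.DataFrame:
    """Cumulative discrepancy rate per trial month.

    For each month t: discrepant patients determined by t over patients
    included by t, with exact confidence bounds.  Months before the first
    inclusion (zero denominator) are omitted.
    """
    ev = series.event_trial_month(kod_name)
    horizon = int(
        max(
            (series.inclusion_month + series.followup_months).max(),
            np.nanmax(ev) if np.any(~np.isnan(ev)) else 0,
        )
    )
    months = np.arange(0, horizon + 1)
    num = np.array([(ev[~np.isnan(ev)] <= t).sum() for t in months])
    den = np.array([(series.inclusion_month <= t).sum() for t in months])
    keep = den > 0
    if not np.all(keep):
        logger.info(
            "rate_over_time(%s): omitting %d zero-denominator months",
            kod_name,
            int((~keep).sum()),
        )
    months, num, den = months[keep], num[keep], den[keep]
    lo, hi = _cp_bounds(num, den, level)
    return pd.DataFrame(
        {
            "month": months,
            "n_discrepant": num,
            "n_included": den,
            "rate": num / den,
            "ci_low": lo,
            "ci_high": hi,
        }
    )


def prop_disc_by_followup(
    series: TrialTimeSeries, kod_name: str
) -> pd.DataFrame:
    """Percentage of all discrepancies falling in each follow-up interval."""
    ev = series.kod_fu_month[kod_name]
    obs = ev[~np.isnan(ev)].astype(int)
    if obs.size == 0:
        return pd.DataFrame(columns=["interval", "n_discrepant", "percent"])
    intervals = np.arange(1, obs.max() + 1)
    counts = np.array([(obs == f).sum() for f in intervals])
    return pd.DataFrame(
        {
            "interval": intervals,
            "n_discrepant": counts,
            "percent": 100.0 * counts / counts.sum(),
        }
    )


def p_disc_by_followup(
    series: TrialTimeSeries, kod_name: str, level: float = 0.95
) -> pd.DataFrame:
    """Discrete per-interval probability of a first discrepancy.

    The denominator at interval f counts patients evaluated during f
    (follow-up reaching f) and not yet discrepant for this KoD; intervals
    with an empty risk set are omitted.
    """
    ev = series.kod_fu_month[kod_name]
    fu = series.followup_months
    intervals = np.arange(1, fu.max() + 1)
    rows = []
    for f in intervals:
        at_risk = (fu >= f) & ~(ev < f)  # NaN comparisons are False
        n = int(at_risk.sum())
        if n == 0:
            continue
        x = int(np.nansum(ev == f))
        ci = clopper_pearson(x, n, level)
        rows.append(
            {
                "interval": int(f),
                "n_discrepant": x,
                "n_at_risk": n,
                "p_disc": x / n,
                "ci_low": ci.low,
                "ci_high": ci.high,
            }
        )
    return pd.DataFrame(rows)


def expected_rate(
    accrual: np.ndarray,
    surv: np.ndarray,
    pdisc: np.ndarray,
    mode: str = "hazard",
) -> pd.DataFrame:
    """Model-based cumulative discrepancy rate from its three components.

    ``accrual[m]`` is the number of patients first included in trial month
    m; ``surv[f-1]`` the probability of still being evaluated at follow-up
    interval f (non-increasing from 1); ``pdisc[f-1]`` the per-interval
    discrepancy probability.

    ``mode='naive'`` accumulates ``pdisc * surv`` literally, ignoring that
    already-discrepant patients cannot recur.  ``mode='hazard'`` treats
    ``pdisc`` as a discrete hazard of first discrepancy:
    ``P(first disc at f) = pdisc[f] * surv[f] * prod_{v<f}(1 - pdisc[v])``.
    Only hazard mode is self-consistent with the empirical cumulative rate.
    """
    accrual = np.asarray(accrual, dtype=float)
    surv = np.asarray(surv, dtype=float)
    pdisc = np.asarray(pdisc, dtype=float)
    if surv.size != pdisc.size:
        raise ValueError("surv and pdisc must share a follow-up grid")
    if np.any(np.diff(surv) > 1e-12) or (surv.size and surv[0] > 1 + 1e-12):
        raise ValueError("surv must be non-increasing and start <= 1")
    if mode not in ("naive", "hazard"):
        raise ValueError(f"unknown mode {mode!r}")
    fmax = surv.size
    per_interval = pdisc * surv
    if mode == "hazard":
        no_prior = np.concatenate([[1.0], np.cumprod(1.0 - pdisc)[:-1]])
        per_interval = per_interval * no_prior
    cum_p = np.concatenate([[0.0], np.cumsum(per_interval)])  # index = fu

    horizon = accrual.size - 1 + fmax
    months = np.arange(0, horizon + 1)
    rate = np.full(months.size, np.nan)
    for t in months:
        den = accrual[: t + 1].sum()
        if den == 0:
            continue
        num = 0.0
        for m in range(min(t, accrual.size - 1) + 1):
            num += accrual[m] * cum_p[min(t - m, fmax)]
        rate[t] = num / den
    keep = ~np.isnan(rate)
    return pd.DataFrame({"month": months[keep], "rate": rate[keep]})


def followup_percentile(durations, q: float) -> float:
    """Empirical q-quantile (inverted-CDF definition) of follow-up durations."""
    arr = np.asarray(durations, dtype=float)
    if arr.size == 0:
        raise ValueError("need >= 1 patient")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    return float(np.quantile(arr, q, method="inverted_cdf"))


def rates_from_counts(
    counts: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """End-of-trial rate table from per-trial discrepancy counts.

    ``counts`` has one row per trial, a column ``n`` (enrolment) and one
    column per KoD (discrepant-patient count); the index labels the trials.
    A ``Pooled`` row (summed counts over summed enrolment) is appended.
    Percentages are reported to one decimal alongside exact CI bounds.
    """
    kods = [c for c in counts.columns if c != "n"]
    pooled = counts.sum(axis=0).to_frame().T
    pooled.index = ["Pooled"]
    full = pd.concat([counts, pooled])
    rows = []
    for trial, row in full.iterrows():
        n = int(row["n"])
        for kod_name in kods:
            x = int(row[kod_name])
            ci = clopper_pearson(x, n, level)
            rows.append(
                {
                    "trial": trial,
                    "kod": kod_name,
                    "n": n,
                    "count": x,
                    "percent": round(100.0 * x / n, 1),
                    "ci_low_pct": round(100.0 * ci.low, 1),
                    "ci_high_pct": round(100.0 * ci.high, 1),
                }
            )
    return pd.DataFrame(rows)


def end_of_trial_rates(
    cohorts: dict[str, pd.DataFrame],
    kods: tuple[str, ...] = KOD_NAMES,
    level: float = 0.95,
) -> pd.DataFrame:
    """End-of-trial discrepancy rates for one or more per-patient KoD tables.

    Each cohort table is the output of :func:`doubleread.kod.kod_table`;
    only ``included`` patients enter the denominators.
    """
    rows = {}
    for trial, table in cohorts.items():
        df = table[table["included"]]
        rows[trial] = {"n": len(df), **{k: int(df[k].sum()) for k in kods}}
    counts = pd.DataFrame.from_dict(rows, orient="index")
    return rates_from_counts(counts, level=level)
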