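"""Synthetic double-read trial generator with known ground truth.

Every upstream input of the analysis pipeline can be produced here: a
long-format two-reader lesion table (consumed by :mod:`doubleread.recist`),
a ground-truth table per patient, and a direct discrepancy-process
generator used to validate the temporal estimators against a known
(accrual, survival, hazard) decomposition.

Patient model
-------------
Patients accrue uniformly over an accrual window and follow a per-trial
visit schedule.  Each patient owns a latent lesion pool (organs drawn from
a lung-primary prevalence table, sizes straddling the measurability
thresholds of 10 mm long axis / 15 mm nodal short axis).  Responders
shrink multiplicatively toward a patient-specific floor; progression is a
per-visit discrete hazard that triggers regrowth and, possibly, a new
lesion.  Follow-up ends at progression (plus a configurable number of
post-progression visits), dropout, or the schedule horizon.

Reader model
------------
Both readers share the latent pool.  Reader 2's target-lesion selection
deviates from reader 1's with probability ``1 - selection_overlap`` per
lesion (RECIST constraints of at most five targets, at most two per organ
are enforced).  Observed diameters carry multiplicative log-normal noise
with coefficient ``measurement_cv``; new-lesion detection and non-target
status calls disagree with their own probabilities.  With zero noise,
full overlap and no disagreement the two readers are identical by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .recist import Category, NtlStatus
from .temporal import MONTH_DAYS, TrialTimeSeries

__all__ = [
    "VisitRule",
    "TrueCourse",
    "ReaderModel",
    "TrialDesign",
    "preset",
    "PRESET_NAMES",
    "simulate_trial",
    "simulate_discrepancy_process",
    "recover_parameters",
]

NON_MEASURABLE_NONNODAL_MM = 10.0
NON_MEASURABLE_NODAL_MM = 15.0
DISAPPEARED_MM = 5.0  # below this a non-nodal lesion is recorded as gone

DEFAULT_ORGAN_PREVALENCE: dict[str, float] = {
    "LUNG": 0.90,
    "LYMPH_NODE_MEDIASTINAL": 0.50,
    "LYMPH_NODE_HILAR": 0.30,
    "LIVER": 0.30,
    "ADRENAL": 0.20,
    "BONE": 0.25,
    "PLEURA": 0.15,
    "BRAIN": 0.12,  # followed as NTL only
    "OTHER": 0.04,
}
NODAL_ORGANS = {"LYMPH_NODE_MEDIASTINAL", "LYMPH_NODE_HILAR"}
NTL_ONLY_ORGANS = {"BRAIN"}


@dataclass(frozen=True)
class VisitRule:
    """Scans every ``period_weeks`` until ``until_week`` (None = open-ended)."""

    period_weeks: float
    until_week: float | None = None

    def __post_init__(self) -> None:
        if self.period_weeks <= 0:
            raise ValueError("visit period must be positive")


@dataclass
class TrueCourse:
    responder_fraction: float = 0.72
    shrink_per_visit: tuple[float, float] = (0.05, 0.15)
    response_floor: tuple[float, float] = (0.05, 0.75)
    progression_hazard: float = 0.09
    #: responders progress at hazard * this multiplier (delayed progression)
    responder_hazard_ratio: float = 0.5
    dropout_hazard: float = 0.07
    regrowth_per_visit: float = 0.9
    #: probability that truth progression manifests as target-lesion regrowth
    regrowth_prob: float = 0.50
    new_lesion_prob: float = 0.75
    ntl_progression_prob: float = 0.30
    lesion_trend_sd: float = 0.06
    post_progression_visits: int = 0


@dataclass
class ReaderModel:
    selection_overlap: float = 0.70
    measurement_cv: float = 0.11
    #: sd of a persistent per-(reader, lesion) log-scale measurement bias
    #: (slice/axis choice); affects absolute thresholds, cancels in ratios
    measurement_bias_sd: float = 0.08
    new_lesion_detection_disagreement: float = 0.35
    ntl_status_disagreement: float = 0.05
    max_tls: int = 5
    max_per_organ: int = 2

    def __post_init__(self) -> None:
        for name in (
            "selection_overlap",
            "measurement_cv",
            "new_lesion_detection_disagreement",
            "ntl_status_disagreement",
        ):
            v = getattr(self, name)
            if not 0 <= v <= (np.inf if name == "measurement_cv" else 1):
                raise ValueError(f"{name}={v} out of range")


@dataclass
class TrialDesign:
    name: str = "custom"
    n_patients: int = 200
    accrual_months: float = 12.0
    visit_schedule: list[VisitRule] = field(
        default_factory=lambda: [VisitRule(6.0, 54.0), VisitRule(12.0, None)]
    )
    max_followup_weeks: float = 110.0
    true_course: TrueCourse = field(default_factory=TrueCourse)
    reader_model: ReaderModel = field(default_factory=ReaderModel)
    organ_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_PREVALENCE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.visit_schedule:
            raise ValueError("need at least one visit rule")
        if any(p <= 0 or p > 1 for p in self.organ_prevalence.values()):
            raise ValueError("organ prevalences must lie in (0, 1]")

    def visit_days(self) -> list[float]:
        """Scan days from baseline (day 0) per the period rules."""
        days = [0.0]
        week = 0.0
        rules = list(self.visit_schedule)
        while True:
            rule = next(
                (
                    r
                    for r in rules
                    if r.until_week is None or week < r.until_week
                ),
                rules[-1],
            )
            week += rule.period_weeks
            if week > self.max_followup_weeks:
                break
            days.append(week * 7.0)
        if len(days) < 2:
            raise ValueError("schedule yields no follow-up visit")
        return days

    def to_dict(self) -> dict:
        return asdict(self)


# Table-style presets: enrolment and visit periodicity per trial.
_PRESETS: dict[str, tuple[int, list[VisitRule]]] = {
    "trial1": (333, [VisitRule(6, 54), VisitRule(12)]),
    "trial2": (493, [VisitRule(6, 48), VisitRule(12)]),
    "trial3": (243, [VisitRule(8)]),
    "trial4": (276, [VisitRule(8, 152), VisitRule(12)]),
    "trial5": (379, [VisitRule(6, 48), VisitRule(9)]),
}
PRESET_NAMES = tuple(_PRESETS)


def preset(trial_name: str, seed: int = 0) -> TrialDesign:
    """Trial design with a named trial's enrolment and visit schedule."""
    try:
        n, schedule = _PRESETS[trial_name]
    except KeyError:
        raise ValueError(
            f"unknown preset {trial_name!r}; choose from {PRESET_NAMES}"
        ) from None
    return TrialDesign(
        name=trial_name, n_patients=n, visit_schedule=list(schedule), seed=seed
    )


@dataclass
class _Lesion:
    lesion_id: str
    organ: str
    is_node: bool
    measurable: bool
    size_mm: float
    trend: float  # per-visit log-scale drift relative to the patient course


def _draw_lesion_pool(rng: np.random.Generator, design: TrialDesign) -> list[_Lesion]:
    course = design.true_course
    pool: list[_Lesion] = []
    for organ, prev in design.organ_prevalence.items():
        if rng.random() >= prev:
            continue
        n_lesions = 1 + min(int(rng.poisson(0.7)), 2)
        for _ in range(n_lesions):
            is_node = organ in NODAL_ORGANS
            size = float(
                rng.lognormal(math.log(18.0 if is_node else 22.0), 0.55)
            )
            measurable = organ not in NTL_ONLY_ORGANS and (
                size >= (NON_MEASURABLE_NODAL_MM if is_node else NON_MEASURABLE_NONNODAL_MM)
            )
            pool.append(
                _Lesion(
                    lesion_id=f"L{len(pool):02d}",
                    organ=organ,
                    is_node=is_node,
                    measurable=measurable,
                    size_mm=size,
                    trend=float(rng.normal(0.0, course.lesion_trend_sd)),
                )
            )
    if not pool:
        pool.append(
            _Lesion("L00", "LUNG", False, True, float(rng.lognormal(math.log(22.0), 0.55)), 0.0)
        )
    return pool


def _select_targets(
    candidates: list[_Lesion], order: list[int], model: ReaderModel
) -> list[_Lesion]:
    chosen: list[_Lesion] = []
    per_organ: dict[str, int] = {}
    for idx in order:
        les = candidates[idx]
        if len(chosen) >= model.max_tls:
            break
        if per_organ.get(les.organ, 0) >= model.max_per_organ:
            continue
        chosen.append(les)
        per_organ[les.organ] = per_organ.get(les.organ, 0) + 1
    return chosen


def _reader_selections(
    rng: np.random.Generator, pool: list[_Lesion], model: ReaderModel
) -> tuple[list[_Lesion], list[_Lesion]]:
    """Two target-lesion selections sharing the latent pool.

    Each reader independently judges each measurable lesion a valid target
    candidate with probability ``sqrt(selection_overlap)`` (so a given true
    lesion is targeted by both readers with probability
    ``selection_overlap`` before the count constraints), then picks the
    largest candidates under the RECIST limits.  A reader rejecting every
    candidate follows the disease as non-measurable (NTL-only) - a real and
    tracked risk factor.  ``selection_overlap=1`` makes the two selections
    identical.
    """
    candidates = [l for l in pool if l.measurable]
    keep_p = math.sqrt(model.selection_overlap)
    keeps = rng.random((2, len(candidates)))
    order = sorted(range(len(candidates)), key=lambda i: -candidates[i].size_mm)
    selections = []
    for r in range(2):
        kept = [i for i in order if keeps[r, i] < keep_p]
        selections.append(_select_targets(candidates, kept, model))
    return selections[0], selections[1]


def _patient_factor(
    t: int,
    responder: bool,
    shrink: float,
    floor: float,
    drift: float,
    prog_visit: int | None,
    regrowth: float,
) -> float:
    """Multiplicative size factor of the patient's disease at visit t."""
    if responder:
        base = max(floor, (1.0 - shrink) ** t)
    else:
        base = (1.0 + drift) ** t
    if prog_visit is not None and t >= prog_visit:
        pre = (
            max(floor, (1.0 - shrink) ** (prog_visit - 1))
            if responder
            else (1.0 + drift) ** (prog_visit - 1)
        )
        base = pre * (1.0 + regrowth) ** (t - prog_visit + 1)
    return base


def simulate_trial(design: TrialDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a two-reader lesion table and its ground truth.

    Returns ``(lesion_table, truth)``.  The lesion table follows the
    long-format contract of :mod:`doubleread.recist` plus an
    ``inclusion_day`` column (trial day of the patient's baseline scan).
    Identical output for identical designs (seed included).
    """
    rng = np.random.default_rng(design.seed)
    course = design.true_course
    model = design.reader_model
    days = design.visit_days()
    n_visits = len(days) - 1

    lesion_rows: list[dict] = []
    truth_rows: list[dict] = []
    for p in range(design.n_patients):
        patient_id = f"P{p:05d}"
        inclusion_day = float(
            np.floor(rng.uniform(0.0, design.accrual_months * MONTH_DAYS))
        )
        pool = _draw_lesion_pool(rng, design)
        tl1, tl2 = _reader_selections(rng, pool, model)
        tl_ids = {1: {l.lesion_id for l in tl1}, 2: {l.lesion_id for l in tl2}}
        # persistent per-(reader, lesion) measurement bias
        bias = np.exp(model.measurement_bias_sd * rng.normal(size=(2, len(pool))))

        responder = rng.random() < course.responder_fraction
        shrink = float(rng.uniform(*course.shrink_per_visit))
        floor = float(rng.uniform(*course.response_floor))
        drift = float(rng.uniform(-0.02, 0.04))
        prog_visit = None
        hazard = course.progression_hazard * (
            course.responder_hazard_ratio if responder else 1.0
        )
        g = rng.geometric(hazard) if hazard > 0 else None
        if g is not None and g <= n_visits:
            prog_visit = int(g)
        dropout_visit = int(rng.geometric(course.dropout_hazard)) if course.dropout_hazard > 0 else n_visits
        last_visit = min(
            n_visits,
            dropout_visit,
            (prog_visit + course.post_progression_visits) if prog_visit else n_visits,
        )
        if prog_visit is not None and prog_visit > last_visit:
            prog_visit = None  # censored before true progression

        # how truth progression manifests: target regrowth, a new lesion,
        # and/or unequivocal non-target progression (at least one of them)
        regrowth_applies = rng.random() < course.regrowth_prob
        wants_new = rng.random() < course.new_lesion_prob
        new_lesion_visit = None
        new_seen_by = {1: False, 2: False}
        if prog_visit is not None and (wants_new or not regrowth_applies):
            new_lesion_visit = prog_visit
            miss_draw = rng.random()
            missing_reader = int(rng.integers(1, 3))
            new_seen_by = {1: True, 2: True}
            if miss_draw < model.new_lesion_detection_disagreement:
                new_seen_by[missing_reader] = False
        new_organ = rng.choice(list(design.organ_prevalence))
        new_size = float(rng.lognormal(math.log(12.0), 0.3))

        # non-target progression call at truth progression
        ntl_progresses = (
            prog_visit is not None and rng.random() < course.ntl_progression_prob
        )
        ntl_miss_draw = rng.random()
        ntl_missing_reader = int(rng.integers(1, 3))
        ntl_seen_by = {1: ntl_progresses, 2: ntl_progresses}
        if ntl_progresses and ntl_miss_draw < model.ntl_status_disagreement:
            ntl_seen_by[ntl_missing_reader] = False

        for t in range(0, last_visit + 1):
            factor = _patient_factor(
                t,
                responder,
                shrink,
                floor,
                drift,
                prog_visit if regrowth_applies else None,
                course.regrowth_per_visit,
            )
            # per-reader-lesion-visit measurement noise, always drawn so the
            # stream is identical across reader-model settings
            z = rng.normal(0.0, 1.0, size=(2, len(pool)))
            for reader in (1, 2):
                for j, les in enumerate(pool):
                    true_d = les.size_mm * factor * math.exp(les.trend * t)
                    if les.lesion_id in tl_ids[reader]:
                        obs = (
                            true_d
                            * bias[reader - 1, j]
                            * math.exp(model.measurement_cv * z[reader - 1, j])
                        )
                        if not les.is_node and obs < DISAPPEARED_MM:
                            obs = 0.0
                        lesion_rows.append(
                            {
                                "patient_id": patient_id,
                                "reader_id": f"R{reader}",
                                "lesion_id": les.lesion_id,
                                "organ": les.organ,
                                "category": Category.TL.value,
                                "is_lymph_node": les.is_node,
                                "visit_index": t,
                                "visit_day": days[t],
                                "diameter_mm": round(obs, 1),
                                "ntl_status": None,
                                "inclusion_day": inclusion_day,
                            }
                        )
                    else:
                        if ntl_seen_by[reader] and prog_visit is not None and t >= prog_visit:
                            status = NtlStatus.UNEQUIVOCAL_PROGRESSION
                        elif true_d < 2.0:
                            status = NtlStatus.ABSENT
                        else:
                            status = NtlStatus.PRESENT
                        lesion_rows.append(
                            {
                                "patient_id": patient_id,
                                "reader_id": f"R{reader}",
                                "lesion_id": les.lesion_id,
                                "organ": les.organ,
                                "category": Category.NTL.value,
                                "is_lymph_node": les.is_node,
                                "visit_index": t,
                                "visit_day": days[t],
                                "diameter_mm": np.nan,
                                "ntl_status": status.value,
                                "inclusion_day": inclusion_day,
                            }
                        )
                if (
                    new_lesion_visit is not None
                    and t >= new_lesion_visit
                    and new_seen_by[reader]
                ):
                    lesion_rows.append(
                        {
                            "patient_id": patient_id,
                            "reader_id": f"R{reader}",
                            "lesion_id": "LNEW",
                            "organ": str(new_organ),
                            "category": Category.NEW.value,
                            "is_lymph_node": str(new_organ) in NODAL_ORGANS,
                            "visit_index": t,
                            "visit_day": days[t],
                            "diameter_mm": round(
                                new_size * (1.2 ** (t - new_lesion_visit)), 1
                            ),
                            "ntl_status": None,
                            "inclusion_day": inclusion_day,
                        }
                    )
        truth_rows.append(
            {
                "patient_id": patient_id,
                "inclusion_day": inclusion_day,
                "responder": responder,
                "progression_visit": prog_visit,
                "dropout_visit": dropout_visit,
                "last_visit": last_visit,
                "last_day": days[last_visit],
                "new_lesion_visit": new_lesion_visit,
                "n_lesions": len(pool),
            }
        )
    lesions = pd.DataFrame(lesion_rows)
    truth = pd.DataFrame(truth_rows)
    return lesions, truth


def simulate_discrepancy_process(
    n_patients: int,
    accrual_months: int = 6,
    max_intervals: int = 18,
    dropout_hazard: float = 0.15,
    disc_hazard: float | dict[str, float] = 0.10,
    seed: int | np.random.Generator = 0,
) -> TrialTimeSeries:
    """Directly simulate the first-discrepancy process on a monthly grid.

    Patients accrue uniformly over ``accrual_months`` calendar months and
    are evaluated at follow-up intervals 1, 2, ...; at each evaluation a
    first discrepancy occurs with the per-KoD hazard, after which the
    patient continues on study with probability ``1 - dropout_hazard``
    per interval.  This generator realizes exactly the
    (accrual, survival, hazard) decomposition used by
    :func:`doubleread.temporal.expected_rate`.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    hazards = disc_hazard if isinstance(disc_hazard, dict) else {"kod": disc_hazard}
    inclusion = rng.integers(0, accrual_months, size=n_patients)
    followup = np.empty(n_patients, dtype=int)
    events = {name: np.full(n_patients, np.nan) for name in hazards}
    for i in range(n_patients):
        pending = dict(hazards)
        f = 1
        while True:
            for name, h in list(pending.items()):
                if rng.random() < h:
                    events[name][i] = f
                    del pending[name]
            if f >= max_intervals or rng.random() < dropout_hazard:
                break
            f += 1
        followup[i] = f
    return TrialTimeSeries(inclusion, followup, events)


def recover_parameters(
    series: TrialTimeSeries, kod_name: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical (accrual, survival, hazard) series from a cohort.

    ``accrual[m]`` counts inclusions in calendar month m; ``surv[f-1]`` is
    the fraction of patients still evaluated at follow-up interval f;
    ``pdisc[f-1]`` the first-discrepancy hazard among patients at risk.
    The three series plug directly into
    :func:`doubleread.temporal.expected_rate`.
    """
    incl = series.inclusion_month
    fu = series.followup_months
    ev = series.kod_fu_month[kod_name]
    accrual = np.bincount(incl, minlength=int(incl.max()) + 1).astype(float)
    fmax = int(fu.max())
    surv = np.array([(fu >= f).mean() for f in range(1, fmax + 1)])
    pdisc = np.zeros(fmax)
    for f in range(1, fmax + 1):
        at_risk = (fu >= f) & ~(ev < f)
        n = int(at_risk.sum())
        if n > 0:
            pdisc[f - 1] = float(np.nansum(ev == f)) / n
    return accrual, surv, pdisc
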