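"""Four kinds of inter-reader discrepancy from paired response timelines.

Endpoints per reader
    * BOR  - best timepoint response under the ordering CR > PR > SD > PD
             (no confirmation, no minimal-SD-duration rule);
    * DOFR - visit of the first CR or PR;
    * PDD  - whether PD was ever declared;
    * DOPD - visit of the first PD.

Discrepancy flags for a reader pair
    * pdd  - exactly one reader declared PD during follow-up;
    * dopd - one reader has no PD, or both have PD on different dates;
    * bor  - the best overall responses differ;
    * dofr - one reader has no CR/PR, or first CR/PR on different dates.

Date comparisons use calendar days since baseline (``visit_day``), so
readers assessing different scan subsets still compare correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .recist import Response

__all__ = [
    "KOD_NAMES",
    "ReaderEndpoints",
    "KoDFlags",
    "derive_endpoints",
    "endpoints_from_timelines",
    "extract_kods",
    "determination_time",
    "kod_table",
]

KOD_NAMES = ("pdd", "dopd", "bor", "dofr")

_BOR_ORDER = {
    Response.CR: 3,
    Response.PR: 2,
    Response.SD: 1,
    Response.PD: 0,
}


@dataclass(frozen=True)
class ReaderEndpoints:
    """Derived endpoints of one reader's follow-up of one patient."""

    patient_id: object
    reader_id: object
    bor: Response
    dofr_visit: int | None
    dofr_day: float | None
    pd_declared: bool
    dopd_visit: int | None
    dopd_day: float | None
    last_visit: int
    last_day: float
    n_evaluable: int  # post-baseline non-NE visits


@dataclass(frozen=True)
class KoDFlags:
    """Per-patient discrepancy indicators with determination days."""

    patient_id: object
    pdd: bool
    dopd: bool
    bor: bool
    dofr: bool
    pdd_day: float | None
    dopd_day: float | None
    bor_day: float | None
    dofr_day: float | None

    def flag(self, kod_name: str) -> bool:
        return bool(getattr(self, kod_name))

    def day(self, kod_name: str) -> float | None:
        return getattr(self, f"{kod_name}_day")


def derive_endpoints(
    responses,
    visit_days=None,
    visit_indices=None,
    patient_id=None,
    reader_id=None,
) -> ReaderEndpoints:
    """Derive BOR/DOFR/PD-declared/DOPD from one reader's ordered responses.

    ``responses`` are the post-baseline overall responses in visit order
    (baseline must not be included).  ``visit_indices`` defaults to 1..k and
    ``visit_days`` to the indices, for callers working purely on sequences.
    """
    resp = [Response(r) for r in responses]
    if not resp:
        raise ValueError("need at least one post-baseline visit")
    if visit_indices is None:
        visit_indices = list(range(1, len(resp) + 1))
    if visit_days is None:
        visit_days = [float(v) for v in visit_indices]
    if not (len(resp) == len(visit_indices) == len(visit_days)):
        raise ValueError("responses, indices and days must align")

    evaluable = [
        (v, d, r)
        for v, d, r in zip(visit_indices, visit_days, resp)
        if r is not Response.NE
    ]
    # a PD ends the evaluable course (patients are withdrawn at PD), so a
    # response recorded after a reader's first PD never enters BOR/DOFR
    for i, (_, _, r) in enumerate(evaluable):
        if r is Response.PD:
            evaluable = evaluable[: i + 1]
            break
    if not evaluable:
        bor = Response.NE
        dofr = dopd = None
    else:
        bor = max((r for _, _, r in evaluable), key=_BOR_ORDER.__getitem__)
        dofr = next(
            (
                (v, d)
                for v, d, r in evaluable
                if r in (Response.CR, Response.PR)
            ),
            None,
        )
        dopd = next(
            ((v, d) for v, d, r in evaluable if r is Response.PD), None
        )
    return ReaderEndpoints(
        patient_id=patient_id,
        reader_id=reader_id,
        bor=bor,
        dofr_visit=None if dofr is None else int(dofr[0]),
        dofr_day=None if dofr is None else float(dofr[1]),
        pd_declared=dopd is not None,
        dopd_visit=None if dopd is None else int(dopd[0]),
        dopd_day=None if dopd is None else float(dopd[1]),
        last_visit=int(visit_indices[-1]),
        last_day=float(visit_days[-1]),
        n_evaluable=len(evaluable),
    )


def endpoints_from_timelines(timelines: pd.DataFrame) -> list[ReaderEndpoints]:
    """Derive endpoints for every (patient, reader) in a response table.

    Baseline rows (``visit_index == 0``) are dropped; readers left with no
    post-baseline visit are skipped (they cannot enter any KoD denominator).
    """
    out = []
    post = timelines[timelines["visit_index"] > 0]
    for (pid, rid), grp in post.groupby(["patient_id", "reader_id"], sort=True):
        grp = grp.sort_values("visit_index")
        out.append(
            derive_endpoints(
                grp["overall"].tolist(),
                visit_days=grp["visit_day"].tolist(),
                visit_indices=grp["visit_index"].tolist(),
                patient_id=pid,
                reader_id=rid,
            )
        )
    return out


def _one_sided_day(a: ReaderEndpoints, b: ReaderEndpoints) -> float:
    # end of the pair's common follow-up
    return min(a.last_day, b.last_day)


def determination_time(
    a: ReaderEndpoints,
    b: ReaderEndpoints,
    kod_name: str,
    rule: str = "late",
) -> float | None:
    """Earliest day (since baseline) at which a flagged KoD is determinable.

    ``rule='late'`` (default): with two differing event dates, the later of
    the two; with a one-sided event, the end of the common follow-up (the
    absence of the other reader's event is only known then); BOR resolves at
    the end of the common follow-up.  ``rule='early'``: the earlier event
    day for two-sided date KoDs and the single event day for one-sided ones.
    Returns None when the named flag is false.
    """
    if rule not in ("late", "early"):
        raise ValueError(f"unknown rule {rule!r}")
    flags = extract_kods(a, b, rule=rule)
    return flags.day(kod_name)


def extract_kods(
    a: ReaderEndpoints, b: ReaderEndpoints, rule: str = "late"
) -> KoDFlags:
    """Compare two readers' endpoints and flag the four KoDs."""
    if a.patient_id != b.patient_id:
        raise ValueError(
            f"endpoints refer to different patients: "
            f"{a.patient_id!r} vs {b.patient_id!r}"
        )
    late = rule == "late"
    if rule not in ("late", "early"):
        raise ValueError(f"unknown rule {rule!r}")
    end_day = _one_sided_day(a, b)

    def date_kod(
        day_a: float | None, day_b: float | None
    ) -> tuple[bool, float | None]:
        if day_a is None and day_b is None:
            return False, None
        if day_a is None or day_b is None:
            present = day_a if day_a is not None else day_b
            return True, end_day if late else present
        if day_a == day_b:
            return False, None
        return True, max(day_a, day_b) if late else min(day_a, day_b)

    pdd = a.pd_declared != b.pd_declared
    if pdd:
        event_day = a.dopd_day if a.dopd_day is not None else b.dopd_day
        pdd_day = end_day if late else event_day
    else:
        pdd_day = None
    dopd, dopd_day = date_kod(a.dopd_day, b.dopd_day)
    dofr, dofr_day = date_kod(a.dofr_day, b.dofr_day)
    bor = a.bor != b.bor
    bor_day = end_day if bor else None
    return KoDFlags(
        patient_id=a.patient_id,
        pdd=pdd,
        dopd=dopd,
        bor=bor,
        dofr=dofr,
        pdd_day=pdd_day,
        dopd_day=dopd_day,
        bor_day=bor_day,
        dofr_day=dofr_day,
    )


def kod_table(timelines: pd.DataFrame, rule: str = "late") -> pd.DataFrame:
    """Per-patient KoD flags for a two-reader response table.

    Patients are excluded (with an ``included=False`` row) when either
    reader lacks a post-baseline visit or scored every post-baseline visit
    NE, mirroring the at-least-one-follow-up inclusion rule.
    """
    endpoints = endpoints_from_timelines(timelines)
    by_patient: dict[object, list[ReaderEndpoints]] = {}
    for ep in endpoints:
        by_patient.setdefault(ep.patient_id, []).append(ep)
    rows = []
    for pid in sorted(by_patient, key=str):
        eps = by_patient[pid]
        row: dict = {"patient_id": pid, "included": False}
        if len(eps) == 2 and all(ep.n_evaluable > 0 for ep in eps):
            flags = extract_kods(eps[0], eps[1], rule=rule)
            row["included"] = True
            row["last_common_day"] = _one_sided_day(eps[0], eps[1])
            for name in KOD_NAMES:
                row[name] = flags.flag(name)
                row[f"{name}_day"] = flags.day(name)
        rows.append(row)
    cols = ["patient_id", "included", "last_common_day"]
    for name in KOD_NAMES:
        cols += [name, f"{name}_day"]
    return pd.DataFrame(rows).reindex(columns=cols)
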