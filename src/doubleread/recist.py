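"""RECIST 1.1 response derivation from lesion-level reader records.

Turns a long-format table of per-reader, per-visit lesion observations into
per-visit overall responses (CR/PR/SD/PD/NE), tracking the sum of target
lesion diameters (SOD) and its nadir independently per reader.

Conventions (documented, not re-derived from data):

* a disappeared non-nodal target lesion contributes 0 mm to the SOD; nodal
  target lesions always contribute their measured short axis;
* PD takes precedence over CR/PR within a visit;
* a visit with no records for a reader who has records both before and
  after it is scored NE; NE never updates the nadir;
* a new lesion is sticky: once recorded, every later visit of that reader
  is PD.
"""

from __future__ import annotations

import logging
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "Response",
    "NtlResponse",
    "NtlStatus",
    "LESION_COLUMNS",
    "sum_of_diameters",
    "target_response",
    "non_target_response",
    "overall_response",
    "build_timelines",
]


class Category(str, Enum):
    TL = "TL"
    NTL = "NTL"
    NEW = "NEW"


class Response(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NE = "NE"


class NtlResponse(str, Enum):
    CR = "CR"
    NON_CR_NON_PD = "NON_CR_NON_PD"
    PD = "PD"
    NE = "NE"


class NtlStatus(str, Enum):
    PRESENT = "PRESENT"
    ABSENT = "ABSENT"
    UNEQUIVOCAL_PROGRESSION = "UNEQUIVOCAL_PROGRESSION"


#: required columns of the long-format lesion table
LESION_COLUMNS = [
    "patient_id",
    "reader_id",
    "lesion_id",
    "organ",
    "category",
    "is_lymph_node",
    "visit_index",
    "visit_day",
    "diameter_mm",
    "ntl_status",
]

# target-lesion thresholds (fractions of reference SOD / absolute mm)
PD_RELATIVE_INCREASE = 0.20
PD_ABSOLUTE_INCREASE_MM = 5.0
PR_RELATIVE_DECREASE = 0.30
NODAL_CR_SHORT_AXIS_MM = 10.0


def sum_of_diameters(diameters_mm) -> float:
    """Arithmetic sum of target-lesion diameters; empty input sums to 0."""
    arr = np.asarray(list(diameters_mm), dtype=float)
    if arr.size == 0:
        return 0.0
    if np.any(arr < 0):
        raise ValueError("diameters must be non-negative")
    return float(arr.sum())


def target_response(
    sod_t: float,
    sod_baseline: float,
    sod_nadir: float,
    all_nonnodal_absent: bool = False,
    all_nodal_below_10mm: bool = True,
) -> Response:
    """Classify the target-lesion component at one visit.

    PD: >=20% increase over the nadir AND >=5 mm absolute increase.
    CR: every non-nodal TL disappeared and every nodal TL short axis <10 mm.
    PR: >=30% decrease from baseline.  SD otherwise; PD wins conflicts.
    """
    if sod_baseline <= 0:
        raise ValueError(
            "sod_baseline must be positive; route patients without "
            "measurable disease through the non-target path"
        )
    increase = sod_t - sod_nadir
    rel = increase / sod_nadir if sod_nadir > 0 else np.inf
    if increase >= PD_ABSOLUTE_INCREASE_MM and rel >= PD_RELATIVE_INCREASE:
        return Response.PD
    if all_nonnodal_absent and all_nodal_below_10mm:
        return Response.CR
    if sod_t <= (1.0 - PR_RELATIVE_DECREASE) * sod_baseline:
        return Response.PR
    return Response.SD


def non_target_response(statuses) -> NtlResponse:
    """Classify the non-target component from qualitative lesion statuses."""
    statuses = [NtlStatus(s) for s in statuses]
    if not statuses:
        return NtlResponse.NE
    if any(s is NtlStatus.UNEQUIVOCAL_PROGRESSION for s in statuses):
        return NtlResponse.PD
    if all(s is NtlStatus.ABSENT for s in statuses):
        return NtlResponse.CR
    return NtlResponse.NON_CR_NON_PD


# (tl, ntl) -> overall, for the no-new-lesion case; None = component absent.
_INTEGRATION: dict[tuple[Response | None, NtlResponse | None], Response] = {}


def _fill_integration() -> None:
    T, N = Response, NtlResponse
    for ntl in (*N, None):
        _INTEGRATION[(T.PD, ntl)] = T.PD
    for tl in (*Response, None):
        _INTEGRATION[(tl, N.PD)] = T.PD
    _INTEGRATION[(T.CR, N.CR)] = T.CR
    _INTEGRATION[(T.CR, None)] = T.CR
    _INTEGRATION[(T.CR, N.NON_CR_NON_PD)] = T.PR
    _INTEGRATION[(T.CR, N.NE)] = T.PR
    for ntl in (N.CR, N.NON_CR_NON_PD, N.NE, None):
        _INTEGRATION[(T.PR, ntl)] = T.PR
        _INTEGRATION[(T.SD, ntl)] = T.SD
        _INTEGRATION[(T.NE, ntl)] = T.NE
    # non-target-only disease: NON_CR_NON_PD mapped to SD for timelines
    _INTEGRATION[(None, N.CR)] = T.CR
    _INTEGRATION[(None, N.NON_CR_NON_PD)] = T.SD
    _INTEGRATION[(None, N.NE)] = T.NE


_fill_integration()


def overall_response(
    tl: Response | str | None,
    ntl: NtlResponse | str | None,
    new_lesion: bool,
) -> Response:
    """Combine target, non-target and new-lesion findings into one response."""
    if tl is None and ntl is None:
        raise ValueError("no disease recorded: both components absent")
    tl = Response(tl) if tl is not None else None
    ntl = NtlResponse(ntl) if ntl is not None else None
    if new_lesion:
        return Response.PD
    return _INTEGRATION[(tl, ntl)]


class _Row:
    """Light view of one lesion record (avoids per-row pandas overhead)."""

    __slots__ = ("lesion_id", "category", "is_node", "diameter", "ntl_status")

    def __init__(self, lesion_id, category, is_node, diameter, ntl_status):
        self.lesion_id = lesion_id
        self.category = category
        self.is_node = bool(is_node)
        self.diameter = diameter
        self.ntl_status = ntl_status


def _reader_timeline(
    by_visit: dict[int, list[_Row]], visit_grid: list[tuple[int, float]]
) -> list[dict] | None:
    """Score one (patient, reader) against the patient's visit grid."""
    base_rows = by_visit.get(0)
    if not base_rows:
        return None
    tl_base = [r for r in base_rows if r.category == Category.TL.value]
    has_tl = bool(tl_base)
    has_ntl = any(r.category == Category.NTL.value for r in base_rows)
    if not has_tl and not has_ntl:
        return None
    sod_baseline = (
        sum_of_diameters(r.diameter for r in tl_base) if has_tl else 0.0
    )
    if has_tl and sod_baseline <= 0:
        return None
    tl_ids = {r.lesion_id for r in tl_base}
    nodal_ids = {r.lesion_id for r in tl_base if r.is_node}

    last_recorded = max(by_visit)
    nadir = sod_baseline
    new_seen = False
    out: list[dict] = []
    for visit_index, visit_day in visit_grid:
        if visit_index > last_recorded:
            break  # reader's follow-up ended
        rows = by_visit.get(visit_index)
        if rows is None:
            overall = Response.NE  # gap in this reader's records
        else:
            new_seen = new_seen or any(
                r.category == Category.NEW.value for r in rows
            )
            tl_resp: Response | None = None
            if has_tl:
                # missing TL row = disappeared non-nodal lesion (0 mm)
                diam = {lid: 0.0 for lid in tl_ids}
                for r in rows:
                    if r.lesion_id in tl_ids:
                        diam[r.lesion_id] = float(r.diameter)
                sod = sum_of_diameters(diam.values())
                tl_resp = target_response(
                    sod,
                    sod_baseline,
                    nadir,
                    all_nonnodal_absent=all(
                        d == 0.0
                        for lid, d in diam.items()
                        if lid not in nodal_ids
                    ),
                    all_nodal_below_10mm=all(
                        diam[lid] < NODAL_CR_SHORT_AXIS_MM
                        for lid in nodal_ids
                    ),
                )
                nadir = min(nadir, sod)
            ntl_resp: NtlResponse | None = None
            if has_ntl:
                statuses = [
                    r.ntl_status
                    for r in rows
                    if r.category == Category.NTL.value
                    and isinstance(r.ntl_status, str)
                ]
                ntl_resp = non_target_response(statuses)
            overall = overall_response(tl_resp, ntl_resp, new_seen)
        if visit_index == 0:
            overall = Response.SD if overall is not Response.NE else overall
        out.append(
            {
                "visit_index": visit_index,
                "visit_day": float(visit_day),
                "overall": overall.value,
            }
        )
    return out


def build_timelines(lesion_table: pd.DataFrame) -> pd.DataFrame:
    """Derive per-visit overall responses for every (patient, reader).

    The visit grid of a patient is the union of visit indices seen by either
    reader, so a reader missing an interior visit scores NE there.  Readers
    without a valid baseline are excluded with a logged warning.  Baseline
    rows are emitted with overall SD as a placeholder reference (endpoint
    derivation ignores visit 0).
    """
    missing = [c for c in LESION_COLUMNS if c not in lesion_table.columns]
    if missing:
        raise ValueError(f"lesion table missing columns: {missing}")
    records: list[dict] = []
    for patient_id, pat in lesion_table.groupby("patient_id", sort=True):
        grid: dict[int, float] = {}
        readers: dict[object, dict[int, list[_Row]]] = {}
        for lesion_id, category, is_node, visit_index, visit_day, diameter, status, reader in zip(
            pat["lesion_id"],
            pat["category"],
            pat["is_lymph_node"],
            pat["visit_index"],
            pat["visit_day"],
            pat["diameter_mm"],
            pat["ntl_status"],
            pat["reader_id"],
        ):
            v = int(visit_index)
            grid.setdefault(v, float(visit_day))
            readers.setdefault(reader, {}).setdefault(v, []).append(
                _Row(lesion_id, category, is_node, diameter, status)
            )
        visit_grid = sorted(grid.items())
        for reader_id in sorted(readers, key=str):
            timeline = _reader_timeline(readers[reader_id], visit_grid)
            if timeline is None:
                logger.warning(
                    "patient %s reader %s: no usable baseline; excluded",
                    patient_id,
                    reader_id,
                )
                continue
            for row in timeline:
                records.append(
                    {"patient_id": patient_id, "reader_id": reader_id, **row}
                )
    return pd.DataFrame(
        records,
        columns=["patient_id", "reader_id", "visit_index", "visit_day", "overall"],
    )
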