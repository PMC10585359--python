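"""Baseline-derived risk-factor features for a reader pair, and their
univariate screening against discrepancy flags.

All features are computed from the two readers' baseline (visit 0) lesion
records only: relative burden difference, organ-overlap indicators for
target and non-target selections, absence of measurable disease, absence of
a lung target, the share of tumour burden placed in reader-specific organs
(``sprop_sod``, a documented stand-in for an unavailable supplementary
definition), and selection of an infrequent disease location.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd

from .recist import Category
from .stats import odds_ratio, wilcoxon_rank_sum

__all__ = [
    "BINARY_FEATURES",
    "CONTINUOUS_FEATURES",
    "delta_burden",
    "organ_overlap_flags",
    "sprop_sod",
    "infrequent_location",
    "organ_frequency_table",
    "baseline_features",
    "univariate_screen",
    "optimize_threshold",
]

BINARY_FEATURES = [
    "no_disease_one_reader",
    "non_measurable_one_reader",
    "tl_not_all_same_organs",
    "all_tls_different_organs",
    "ntl_not_all_same_organs",
    "no_lung_tl_one_reader",
    "infrequent_location",
]
CONTINUOUS_FEATURES = ["delta_burden", "sprop_sod"]

#: default cohort-prevalence cutoff below which an organ is "infrequent"
INFREQUENT_CUTOFF = 0.05

#: cap reported for odds ratios from perfectly separating thresholds
OR_CAP = 1e6


def delta_burden(sod1: float, sod2: float) -> float:
    """Relative difference of the readers' baseline SODs.

    ``|sod1 - sod2| / (sod1 + sod2)``; NaN when both SODs are zero.
    """
    if sod1 < 0 or sod2 < 0:
        raise ValueError("SODs must be non-negative")
    total = sod1 + sod2
    if total == 0:
        return math.nan
    return abs(sod1 - sod2) / total


def organ_overlap_flags(
    tl_organs_1,
    tl_organs_2,
    ntl_organs_1=(),
    ntl_organs_2=(),
) -> dict[str, bool]:
    """Organ-level selection-overlap indicators between the two readers.

    * ``tl_not_all_same_organs`` - the TL organ sets differ;
    * ``all_tls_different_organs`` - the TL organ sets are disjoint and both
      non-empty;
    * ``ntl_not_all_same_organs`` - the NTL organ sets differ.
    """
    t1, t2 = set(tl_organs_1), set(tl_organs_2)
    n1, n2 = set(ntl_organs_1), set(ntl_organs_2)
    return {
        "tl_not_all_same_organs": t1 != t2,
        "all_tls_different_organs": bool(t1) and bool(t2) and t1.isdisjoint(t2),
        "ntl_not_all_same_organs": n1 != n2,
    }


def sprop_sod(
    per_organ_sod_1: dict[str, float], per_organ_sod_2: dict[str, float]
) -> float:
    """Share of the combined burden placed in reader-specific organs.

    Stand-in definition: the fraction of the two readers' summed SOD
    contributed by organs selected by only one of them.  Zero when the organ
    sets coincide; NaN when the combined SOD is zero.
    """
    total = sum(per_organ_sod_1.values()) + sum(per_organ_sod_2.values())
    if total == 0:
        return math.nan
    common = set(per_organ_sod_1) & set(per_organ_sod_2)
    specific = sum(
        v for o, v in per_organ_sod_1.items() if o not in common
    ) + sum(v for o, v in per_organ_sod_2.items() if o not in common)
    return specific / total


def infrequent_location(
    organs_any_reader,
    frequency_table: dict[str, float],
    cutoff: float = INFREQUENT_CUTOFF,
) -> bool:
    """True when any selected organ's cohort prevalence is below ``cutoff``.

    Organs missing from the table count as prevalence 0; the comparison is
    strict (prevalence exactly at the cutoff is not infrequent).
    """
    return any(
        frequency_table.get(organ, 0.0) < cutoff for organ in set(organs_any_reader)
    )


def organ_frequency_table(baseline: pd.DataFrame) -> dict[str, float]:
    """Cohort prevalence of each TL organ (fraction of patients in which any
    reader selected a target lesion there)."""
    tl = baseline[baseline["category"] == Category.TL.value]
    n_patients = baseline["patient_id"].nunique()
    if n_patients == 0:
        return {}
    counts = Counter()
    for organ, grp in tl.groupby("organ"):
        counts[organ] = grp["patient_id"].nunique()
    return {organ: c / n_patients for organ, c in counts.items()}


def _reader_baseline(grp: pd.DataFrame) -> dict:
    tl = grp[grp["category"] == Category.TL.value]
    ntl = grp[grp["category"] == Category.NTL.value]
    per_organ = tl.groupby("organ")["diameter_mm"].sum().to_dict()
    return {
        "has_disease": len(grp) > 0,
        "has_tl": len(tl) > 0,
        "sod": float(tl["diameter_mm"].sum()),
        "tl_organs": set(tl["organ"]),
        "ntl_organs": set(ntl["organ"]),
        "per_organ_sod": per_organ,
    }


def baseline_features(
    lesion_table: pd.DataFrame,
    cutoff: float = INFREQUENT_CUTOFF,
    frequency_table: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-patient baseline features from a two-reader lesion table.

    Uses visit 0 records only.  The organ frequency table defaults to the
    cohort's own TL prevalences.  Patients with fewer than two readers at
    baseline are skipped.
    """
    baseline = lesion_table[lesion_table["visit_index"] == 0]
    if frequency_table is None:
        frequency_table = organ_frequency_table(baseline)
    rows = []
    for patient_id, pat in baseline.groupby("patient_id", sort=True):
        readers = [
            _reader_baseline(grp)
            for _, grp in pat.groupby("reader_id", sort=True)
        ]
        if len(readers) != 2:
            continue
        r1, r2 = readers
        flags = organ_overlap_flags(
            r1["tl_organs"], r2["tl_organs"], r1["ntl_organs"], r2["ntl_organs"]
        )
        both_tl = r1["has_tl"] and r2["has_tl"]
        rows.append(
            {
                "patient_id": patient_id,
                "no_disease_one_reader": not (
                    r1["has_disease"] and r2["has_disease"]
                ),
                "non_measurable_one_reader": not both_tl,
                **flags,
                "delta_burden": (
                    delta_burden(r1["sod"], r2["sod"])
                    if r1["sod"] + r2["sod"] > 0
                    else math.nan
                ),
                "no_lung_tl_one_reader": both_tl
                and ("LUNG" not in r1["tl_organs"] or "LUNG" not in r2["tl_organs"]),
                "sprop_sod": sprop_sod(r1["per_organ_sod"], r2["per_organ_sod"]),
                "infrequent_location": infrequent_location(
                    r1["tl_organs"] | r2["tl_organs"], frequency_table, cutoff
                ),
            }
        )
    return pd.DataFrame(rows)


def _two_by_two(feature: pd.Series, flag: pd.Series) -> tuple[int, int, int, int]:
    f = feature.astype(bool)
    y = flag.astype(bool)
    a = int((f & y).sum())  # exposed, discrepant
    b = int((f & ~y).sum())
    c = int((~f & y).sum())
    d = int((~f & ~y).sum())
    return a, b, c, d


def univariate_screen(
    features: pd.DataFrame,
    kods: pd.DataFrame,
    kod_name: str,
    binary_features: list[str] | None = None,
    continuous_features: list[str] | None = None,
    on_degenerate: str = "raise",
) -> pd.DataFrame:
    """Screen each baseline feature against one KoD flag.

    Binary features get an odds ratio with 95% CI and p; continuous features
    a two-sample rank-sum p (discrepant vs non-discrepant groups).  Constant
    binary features raise a degenerate-feature error by default
    (``on_degenerate='skip'`` drops them instead, for cohort-level runs).
    """
    if binary_features is None:
        binary_features = BINARY_FEATURES
    if continuous_features is None:
        continuous_features = CONTINUOUS_FEATURES
    if on_degenerate not in ("raise", "skip"):
        raise ValueError("on_degenerate must be 'raise' or 'skip'")
    merged = features.merge(
        kods.loc[kods["included"], ["patient_id", kod_name]], on="patient_id"
    )
    if merged.empty:
        raise ValueError("no overlapping patients between tables")
    flag = merged[kod_name].astype(bool)
    rows = []
    for name in binary_features:
        col = merged[name].astype(bool)
        if col.nunique() < 2:
            if on_degenerate == "skip":
                continue
            raise ValueError(f"degenerate feature {name!r}: constant")
        a, b, c, d = _two_by_two(col, flag)
        res = odds_ratio(a, b, c, d)
        rows.append(
            {
                "feature": name,
                "kind": "binary",
                "prevalence": col.mean(),
                "oddsratio": res.oddsratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "corrected": res.corrected,
            }
        )
    for name in continuous_features:
        col = merged[name].astype(float)
        ok = ~col.isna()
        grp_disc = col[ok & flag]
        grp_conc = col[ok & ~flag]
        if grp_disc.empty or grp_conc.empty:
            p = math.nan
        else:
            _, p = wilcoxon_rank_sum(grp_disc, grp_conc)
        rows.append(
            {
                "feature": name,
                "kind": "continuous",
                "prevalence": math.nan,
                "oddsratio": math.nan,
                "ci_low": math.nan,
                "ci_high": math.nan,
                "p": p,
                "corrected": False,
            }
        )
    return pd.DataFrame(rows)


def optimize_threshold(
    feature, flag, grid=None
) -> tuple[float, float]:
    """Grid threshold on a continuous feature maximizing the odds ratio.

    Best-case by construction, never an unbiased estimate.  Ties resolve to
    the smallest threshold; a perfectly separating threshold reports the
    capped odds ratio ``1e6``.  Returns ``(threshold, odds_ratio)``;
    ``(nan, nan)`` when no threshold yields a valid 2x2 table.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(flag, dtype=bool)
    ok = ~np.isnan(x)
    x, y = x[ok], y[ok]
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct feature values")
    if grid is None:
        levels = np.unique(x)
        grid = (levels[:-1] + levels[1:]) / 2.0
    best_thr, best_or = math.nan, -math.inf
    for thr in np.asarray(grid, dtype=float):
        exposed = x > thr
        a = int((exposed & y).sum())
        b = int((exposed & ~y).sum())
        c = int((~exposed & y).sum())
        d = int((~exposed & ~y).sum())
        if (a + b == 0) or (c + d == 0):
            continue  # threshold off the support: no valid 2x2
        if b == 0 and c == 0 and a > 0 and d > 0:
            orr = OR_CAP  # perfect separation
        else:
            orr = odds_ratio(a, b, c, d).oddsratio
        if math.isnan(orr):
            continue
        orr = min(orr, OR_CAP)
        if orr > best_or + 1e-12:
            best_thr, best_or = float(thr), float(orr)
    if math.isnan(best_thr):
        return math.nan, math.nan
    return best_thr, best_or
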