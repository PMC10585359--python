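"""Shared fixtures: small simulated cohorts reused across test modules."""

from __future__ import annotations

import pandas as pd
import pytest

from doubleread import kod, recist
from doubleread.simulate import (
    ReaderModel,
    TrialDesign,
    simulate_trial,
)


@pytest.fixture(scope="session")
def default_trial():
    """A default-parameter simulated trial (n=500, seed=1)."""
    design = TrialDesign(n_patients=500, seed=1)
    lesions, truth = simulate_trial(design)
    return design, lesions, truth


@pytest.fixture(scope="session")
def default_timelines(default_trial) -> pd.DataFrame:
    _, lesions, _ = default_trial
    return recist.build_timelines(lesions)


@pytest.fixture(scope="session")
def default_kods(default_timelines) -> pd.DataFrame:
    return kod.kod_table(default_timelines)


@pytest.fixture(scope="session")
def identical_reader_model() -> ReaderModel:
    """Reader model with every disagreement source switched off."""
    return ReaderModel(
        selection_overlap=1.0,
        measurement_cv=0.0,
        measurement_bias_sd=0.0,
        new_lesion_detection_disagreement=0.0,
        ntl_status_disagreement=0.0,
    )


def make_lesion_row(
    patient_id="P1",
    reader_id="R1",
    lesion_id="L1",
    organ="LUNG",
    category="TL",
    is_lymph_node=False,
    visit_index=0,
    visit_day=0.0,
    diameter_mm=20.0,
    ntl_status=None,
) -> dict:
    return {
        "patient_id": patient_id,
        "reader_id": reader_id,
        "lesion_id": lesion_id,
        "organ": organ,
        "category": category,
        "is_lymph_node": is_lymph_node,
        "visit_index": visit_index,
        "visit_day": visit_day,
        "diameter_mm": diameter_mm,
        "ntl_status": ntl_status,
    }


@pytest.fixture
def lesion_row_factory():
    return make_lesion_row
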