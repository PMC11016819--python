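import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cogmark.normalization import average_visits, build_zscore_table
from cogmark.session_io import (
    Demographics,
    OISTrial,
    OMTTrial,
    Questionnaires,
    SessionRecord,
    panels_to_frame,
)
from cogmark.synthetic_data import CohortConfig, generate_cohort
from cogmark.task_scoring import PRIMARY_METRICS, score_session


@pytest.fixture
def rng():
    return np.random.default_rng(20240914)


def make_session(
    participant_id="P-001",
    group="EHC1",
    omt=None,
    ois=None,
    rocf=None,
    corsi=None,
    dsst=None,
    tmt=None,
    validation_answers=("Completely untrue", "Completely untrue"),
    age=65.0,
) -> SessionRecord:
    """Minimal hand-built session for unit and QC tests."""
    return SessionRecord(
        participant_id=participant_id,
        group=group,
        demographics=Demographics(age=age, sex="F", education_years=15),
        session_date=dt.date(2024, 1, 20),
        blood_draw_date=dt.date(2024, 1, 15) if group != "EHC2" else None,
        omt=omt or [],
        ois=ois or [],
        rocf=rocf or [],
        corsi=corsi or [],
        dsst=dsst or [],
        tmt=tmt or [],
        questionnaires=Questionnaires(validation_answers=list(validation_answers)),
    )


def perfect_omt_trial(n_items=3, target=0):
    locs = [(5.0, 5.0), (12.0, 5.0), (20.0, 10.0)][:n_items]
    return OMTTrial(
        n_items=n_items,
        item_locations=locs,
        target_index=target,
        identified=True,
        response_location=locs[target],
        identification_time=1.2,
        localization_time=2.0,
    )


def make_ois_trial(stage="immediate", chosen="guitar_1", chosen_cat="guitar",
                   target="guitar_1", target_cat="guitar",
                   target_loc=(10.0, 8.0), response_loc=(10.0, 8.0)):
    return OISTrial(
        stage=stage,
        target_object=target,
        target_category=target_cat,
        chosen_object=chosen,
        chosen_category=chosen_cat,
        target_location=target_loc,
        response_location=response_loc,
    )


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Full-size cohort generated under the default (study-calibrated) conditions."""
    return generate_cohort(CohortConfig(seed=20240914))


def build_cohort_tables(cohort):
    """Score a cohort and build the averaged metric table, z-score table, and
    biomarker frame — the core analysis inputs."""
    rows = []
    for s, _ in cohort:
        rows.append(
            {
                "participant_id": s.participant_id,
                "visit": s.visit,
                "group": s.group,
                "age": s.demographics.age,
                "sex": s.demographics.sex,
                "education_years": s.demographics.education_years,
                **score_session(s),
            }
        )
    metric_table = pd.DataFrame(rows)
    averaged = average_visits(metric_table)
    reference = averaged[averaged["group"] == "EHC2"]
    ztable = build_zscore_table(averaged, reference, PRIMARY_METRICS)
    panels = panels_to_frame(
        [p for _, p in cohort if p is not None]
    ).groupby("participant_id").mean()
    return {"metrics": averaged, "z": ztable, "panels": panels}


@pytest.fixture(scope="session")
def cohort_tables(calibrated_cohort):
    return build_cohort_tables(calibrated_cohort)
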