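"""Shared fixtures: a small split cohort and the reference templates."""

import pandas as pd
import pytest

import challenge_harness as ch
from challenge_harness.cohort import COLUMNS, _INT_COLUMNS, default_dictionary
from challenge_harness.submission import Submission


@pytest.fixture(scope="session")
def bundle():
    """A 60-subject cohort split 45/15, used across the suite."""
    return ch.split_cohort(ch.generate_cohort(60, seed=3), 45)


@pytest.fixture(scope="session")
def python_template(tmp_path_factory):
    return ch.write_python_template(tmp_path_factory.mktemp("tpl") / "python")


@pytest.fixture(scope="session")
def r_template(tmp_path_factory):
    return ch.write_r_template(tmp_path_factory.mktemp("tpl") / "r")


@pytest.fixture(scope="session")
def stochastic_template(tmp_path_factory):
    return ch.write_stochastic_template(tmp_path_factory.mktemp("tpl") / "stoch")


@pytest.fixture()
def baseline_submission(python_template):
    return Submission.from_directory(python_template, mode="final")


def make_bundle(rows: list[dict], train_ids=None, test_ids=None,
                seed: int = 0) -> ch.CohortBundle:
    """Build a bundle from explicit records (tests of forced scenarios).

    Missing fields default to a benign consistent record; partitions are
    optional.
    """
    defaults = {
        "site": "site_1", "age": 10, "sex": "Female",
        "injury_mechanism": "Fall",
        "gcs_eye_ed": 1, "gcs_verbal_ed": 2, "gcs_motor_ed": 3,
        "gcs_total_ed": 6,
        "gcs_eye_icu": 1, "gcs_verbal_icu": 2, "gcs_motor_icu": 3,
        "gcs_total_icu": 6,
        "pupil_react": "both reactive", "ct_skull_fracture": 0, "ct_ivh": 0,
        "neurosurgery": 0, "icp_start_days": None, "icp_stop_days": None,
        "hosp_los_days": 5, "mortality": "Alive", "disposition": "Home",
        "fss_total": 12,
    }
    full = []
    for i, row in enumerate(rows):
        rec = dict(defaults, subject_id=f"S{i + 1:04d}")
        rec.update(row)
        if rec["mortality"] == "Mortality":
            rec["fss_total"] = None
            rec["disposition"] = "Mortality"
        full.append(rec)
    df = pd.DataFrame(full)[COLUMNS]
    for col in _INT_COLUMNS:
        df[col] = df[col].astype("Int64")
    for col in df.columns:
        if col not in _INT_COLUMNS:
            df[col] = df[col].astype(object)
    partitions = {}
    known = set(df.loc[df["fss_total"].notna(), "subject_id"])
    if train_ids is not None:
        partitions["training"] = ch.PartitionSpec(
            "training", list(train_ids), [i for i in train_ids if i in known])
    if test_ids is not None:
        partitions["testing"] = ch.PartitionSpec(
            "testing", list(test_ids), [i for i in test_ids if i in known])
    return ch.CohortBundle(df, default_dictionary(), partitions, seed,
                           ch.GeneratorParams(), {"inconsistent_ids": []})


def compliant_predictions(bundle: ch.CohortBundle, partition: str) -> list[dict]:
    """Predictions equal to the true labels (always validation-compliant)."""
    labels = bundle.labels(partition)
    rows = []
    for rec in labels.itertuples(index=False):
        fss = "" if pd.isna(rec.fss_total) else str(int(rec.fss_total))
        rows.append({"subject_id": rec.subject_id,
                     "mortality_pred": rec.mortality, "fss_pred": fss})
    return rows
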