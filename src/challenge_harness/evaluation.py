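"""Repeated assessment of a submission and its reproducibility summary.

Because evaluation re-runs the participant's own training code, a
submission is assessed R times (100 in a real challenge) and the mean and
sample standard deviation of every statistic are recorded.  A
deterministic submission has SD exactly 0 for every statistic, which the
ranking scheme rewards with a shared reproducibility rank of 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import CohortBundle
from .errors import EvaluationError, ParameterError
from .metrics import confusion_counts, f1, mcc, mse
from .runner import TRAINING_AND_TESTING, RunRequest, run_submission
from .submission import Submission
from .validation import read_prediction_file, validate_predictions

__all__ = ["EvaluationSeries", "score_predictions", "repeat_evaluate",
           "series_to_statistic_rows"]

#: statistic -> outcome it scores
STATISTIC_OUTCOME = {"MCC": "mortality", "F1": "mortality", "MSE": "FSS"}
PARTITIONS = ("training", "testing")


@dataclass
class EvaluationSeries:
    """Per-statistic values over R repeated train-and-predict cycles."""

    participant_id: str
    repeats: int
    values: dict[tuple[str, str], list[float]] = field(default_factory=dict)
    # keys: (partition, statistic)

    def mean(self, partition: str, statistic: str) -> float:
        return float(np.mean(self.values[(partition, statistic)]))

    def sd(self, partition: str, statistic: str) -> float:
        """Sample (n-1) standard deviation; 0 iff all repeats identical."""
        vals = self.values[(partition, statistic)]
        # identical repeats must report exactly 0, not mean-subtraction noise
        if all(v == vals[0] for v in vals):
            return 0.0
        return float(np.std(vals, ddof=1))

    def to_dict(self) -> dict:
        out = {"participant_id": self.participant_id, "repeats": self.repeats,
               "series": []}
        for (part, stat), vals in sorted(self.values.items()):
            out["series"].append({
                "statistic": stat, "partition": part,
                "outcome": STATISTIC_OUTCOME[stat],
                "values": list(map(float, vals)),
                "mean": self.mean(part, stat), "sd": self.sd(part, stat),
            })
        return out

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def _aligned(rows: list[dict[str, str]]) -> dict[str, dict[str, str]]:
    return {r["subject_id"]: r for r in rows}


def score_predictions(rows: list[dict[str, str]], bundle: CohortBundle,
                      partition: str) -> dict[str, float]:
    """Score one validated prediction set: MCC, F1 (mortality) and MSE (FSS)."""
    spec = bundle.partitions[partition]
    labels = bundle.labels(partition).set_index("subject_id")
    by_id = _aligned(rows)

    observed_mort = [labels.loc[i, "mortality"] for i in spec.subject_ids]
    predicted_mort = [by_id[i]["mortality_pred"] for i in spec.subject_ids]
    c = confusion_counts(observed_mort, predicted_mort)

    observed_fss = [int(labels.loc[i, "fss_total"]) for i in spec.known_fss_ids]
    predicted_fss = [int(by_id[i]["fss_pred"]) for i in spec.known_fss_ids]
    return {"MCC": mcc(c), "F1": f1(c), "MSE": mse(observed_fss, predicted_fss)}


def repeat_evaluate(submission: Submission, bundle: CohortBundle,
                    repeats: int = 100, backend: str = "local_subprocess",
                    timeout: float | None = None) -> EvaluationSeries:
    """Run R full train-and-predict cycles and summarize every statistic.

    Each repeat re-runs the submission from scratch with testing features
    (never labels) mounted, validates both prediction files, and scores
    MCC/F1/MSE on both partitions.  Any run failure or validation failure
    aborts the evaluation with the reason recorded.
    """
    if not isinstance(repeats, (int, np.integer)) or repeats < 2:
        raise ParameterError(
            f"repeats must be an integer >= 2 (sample SD undefined), got {repeats!r}")
    series = EvaluationSeries(submission.manifest.participant_id, int(repeats))
    series.values = {(p, s): [] for p in PARTITIONS for s in STATISTIC_OUTCOME}

    kwargs = {} if timeout is None else {"timeout": timeout}
    for r in range(repeats):
        request = RunRequest(submission, data_access=TRAINING_AND_TESTING,
                             backend=backend, repeat_index=r,
                             admin_override=True, **kwargs)
        outcome = run_submission(request, bundle)
        if outcome.status != "success":
            raise EvaluationError(
                f"repeat {r}: run failed ({outcome.reason})\n{outcome.log}")
        for partition in PARTITIONS:
            rows = read_prediction_file(outcome.predictions[partition])
            report = validate_predictions(rows, bundle.partitions[partition])
            if not report.passed:
                raise EvaluationError(
                    f"repeat {r}: {partition} predictions invalid:\n"
                    + report.summary())
            scores = score_predictions(rows, bundle, partition)
            for stat, value in scores.items():
                series.values[(partition, stat)].append(value)
    return series


def series_to_statistic_rows(series: EvaluationSeries) -> list[dict]:
    """Long-form rows (participant, outcome, partition, statistic, mean, sd)
    ready for the ranking module's statistic table."""
    rows = []
    for (partition, statistic), _ in sorted(series.values.items()):
        rows.append({
            "participant": series.participant_id,
            "outcome": STATISTIC_OUTCOME[statistic],
            "partition": partition,
            "statistic": statistic,
            "mean": series.mean(partition, statistic),
            "sd": series.sd(partition, statistic),
        })
    return rows
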