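"""Prediction-file validation: completeness, type, range, and label rules.

A prediction file is a CSV with header ``subject_id,mortality_pred,fss_pred``;
an empty ``fss_pred`` cell means no FSS prediction for that subject.  The
rules, checked before any scoring:

* LENGTH           — exactly one prediction row per partition subject
                     (count must equal the partition size).
* UNKNOWN_ID       — every subject id must belong to the partition.
* LABEL_SET        — mortality predictions are exactly "Mortality"/"Alive"
                     (case-sensitive by default).
* FSS_COMPLETENESS — an FSS prediction is required for every subject whose
                     observed FSS is known (checked over ids present in
                     the file; LENGTH covers absent rows).
* FSS_INTEGER      — FSS predictions must be integers.
* FSS_RANGE        — FSS predictions must lie in [6, 30] inclusive.

FSS predictions for subjects outside the known-FSS set (e.g. deaths) are
permitted and ignored in scoring.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .cohort import PartitionSpec
from .errors import FormatError

__all__ = ["Violation", "ValidationReport", "validate_predictions",
           "read_prediction_file", "PREDICTION_HEADER"]

PREDICTION_HEADER = ["subject_id", "mortality_pred", "fss_pred"]
ALLOWED_LABELS = ("Mortality", "Alive")


@dataclass(frozen=True)
class Violation:
    rule: str                      # LENGTH | FSS_COMPLETENESS | FSS_RANGE |
    subject_ids: tuple[str, ...]   # FSS_INTEGER | LABEL_SET | UNKNOWN_ID
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def rules_fired(self) -> set[str]:
        return {v.rule for v in self.violations}

    def summary(self) -> str:
        if self.passed:
            return "PASS"
        lines = [f"FAIL ({len(self.violations)} violation(s))"]
        lines += [f"  [{v.rule}] {v.message}" for v in self.violations]
        return "\n".join(lines)


def read_prediction_file(path: str | Path) -> list[dict[str, str]]:
    """Parse a prediction CSV into raw string rows; malformed file -> FormatError."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"prediction file {path} does not exist")
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header != PREDICTION_HEADER:
                raise FormatError(
                    f"{path.name}: header must be {','.join(PREDICTION_HEADER)}, "
                    f"got {header}")
            rows = []
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != 3:
                    raise FormatError(
                        f"{path.name}: line {lineno} has {len(row)} fields, expected 3")
                rows.append(dict(zip(PREDICTION_HEADER, row)))
    except (OSError, UnicodeDecodeError, csv.Error) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return rows


def validate_predictions(predictions: list[dict[str, str]] | str | Path,
                         spec: PartitionSpec,
                         normalize_labels: bool = False) -> ValidationReport:
    """Check a prediction set against a partition; idempotent and pure.

    ``predictions`` is either a path to a prediction CSV or the parsed row
    list.  Each violation carries the offending subject ids.
    """
    if isinstance(predictions, (str, Path)):
        predictions = read_prediction_file(predictions)
    report = ValidationReport()
    expected = set(spec.subject_ids)
    known_fss = set(spec.known_fss_ids)

    if len(predictions) != spec.size:
        present = {r["subject_id"] for r in predictions}
        missing = sorted(expected - present)
        report.violations.append(Violation(
            "LENGTH", tuple(missing),
            f"expected {spec.size} predictions for partition {spec.name}, "
            f"got {len(predictions)}"
            + (f"; missing ids: {', '.join(missing)}" if missing else "")))

    unknown = sorted({r["subject_id"] for r in predictions} - expected)
    if unknown:
        report.violations.append(Violation(
            "UNKNOWN_ID", tuple(unknown),
            f"ids not in partition {spec.name}: {', '.join(unknown)}"))

    bad_labels, missing_fss, non_integer, out_of_range = [], [], [], []
    for row in predictions:
        sid = row["subject_id"]
        label = row["mortality_pred"]
        if normalize_labels:
            label = label.strip().capitalize()
        if label not in ALLOWED_LABELS:
            bad_labels.append((sid, row["mortality_pred"]))
        raw_fss = row["fss_pred"].strip()
        if raw_fss == "":
            if sid in known_fss:
                missing_fss.append(sid)
            continue
        try:
            value = int(raw_fss)
        except ValueError:
            non_integer.append((sid, raw_fss))
            continue
        if not 6 <= value <= 30:
            out_of_range.append((sid, value))

    if missing_fss:
        report.violations.append(Violation(
            "FSS_COMPLETENESS", tuple(missing_fss),
            f"FSS prediction required for known-FSS subjects: {', '.join(missing_fss)}"))
    if non_integer:
        ids = tuple(s for s, _ in non_integer)
        report.violations.append(Violation(
            "FSS_INTEGER", ids,
            "non-integer FSS predictions: "
            + ", ".join(f"{s}={v!r}" for s, v in non_integer)))
    if out_of_range:
        ids = tuple(s for s, _ in out_of_range)
        report.violations.append(Violation(
            "FSS_RANGE", ids,
            "FSS predictions outside [6, 30]: "
            + ", ".join(f"{s}={v}" for s, v in out_of_range)))
    if bad_labels:
        ids = tuple(s for s, _ in bad_labels)
        report.violations.append(Violation(
            "LABEL_SET", ids,
            'mortality predictions must be "Mortality" or "Alive": '
            + ", ".join(f"{s}={v!r}" for s, v in bad_labels)))
    return report
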