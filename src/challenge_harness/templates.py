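"""Reference participant submissions, generated programmatically.

Two deterministic baseline templates (Python and R) document the
language-agnostic submission contract and serve as end-to-end fixtures:
``train`` fits the "model" (training-mean FSS rounded half away from zero
and clamped to [6, 30]; majority mortality class, ties to "Alive") and
``predict`` writes one prediction CSV per mounted partition.  Both
languages are required to produce byte-identical prediction files on the
same bundle.

A third, intentionally unseeded stochastic template exercises the
reproducibility machinery: its repeated evaluations must show a nonzero
standard deviation.
"""

from __future__ import annotations

from pathlib import Path

from .submission import (DEFAULT_PROTECTED_PATHS, IntegrityPolicy, Submission)

__all__ = [
    "write_python_template", "write_r_template", "write_stochastic_template",
    "template_policy",
]

_IO_CONTRACT_PY = '''\
"""Data-loading and prediction-writing stubs.  DO NOT EDIT.

Edits to this file fail the sha256 integrity check at assessment time.
"""
import csv
import os


def data_dir():
    return os.environ.get("DATA_DIR", "/data")


def output_dir():
    return os.environ.get("OUTPUT_DIR", "/output")


def read_table(name):
    """Return the named mounted table as a list of dict rows, or None."""
    path = os.path.join(data_dir(), name)
    if not os.path.exists(path):
        return None
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def write_predictions(name, rows):
    """Write (subject_id, mortality_pred, fss_pred) triples as CSV."""
    path = os.path.join(output_dir(), name)
    with open(path, "w", newline="") as fh:
        fh.write("subject_id,mortality_pred,fss_pred\\n")
        for sid, mort, fss in rows:
            fh.write("%s,%s,%s\\n" % (sid, mort, fss))
'''

_TRAIN_PY = '''\
"""Baseline training: training-mean FSS and majority mortality class."""
import math
import os

from io_contract import read_table, output_dir

rows = read_table("training.csv")
if not rows:
    raise SystemExit("training.csv is empty")

fss = [float(r["fss_total"]) for r in rows if r["fss_total"] != ""]
if not fss:
    raise SystemExit("no known FSS values in training data")
mean_fss = sum(fss) / len(fss)
# round half away from zero (contract shared with the R template)
pred_fss = int(math.floor(mean_fss + 0.5))
pred_fss = min(30, max(6, pred_fss))

deaths = sum(1 for r in rows if r["mortality"] == "Mortality")
label = "Mortality" if deaths > len(rows) - deaths else "Alive"

with open(os.path.join(output_dir(), "model.txt"), "w") as fh:
    fh.write("fss_pred=%d\\nmortality_pred=%s\\n" % (pred_fss, label))
'''

_PREDICT_PY = '''\
"""Baseline prediction: constant model output for every subject."""
import os

from io_contract import read_table, write_predictions, output_dir

model = {}
with open(os.path.join(output_dir(), "model.txt")) as fh:
    for line in fh:
        key, _, value = line.strip().partition("=")
        model[key] = value

for table, out in (("training.csv", "train_predictions.csv"),
                   ("testing.csv", "test_predictions.csv")):
    rows = read_table(table)
    if rows is None:
        continue
    write_predictions(out, [(r["subject_id"], model["mortality_pred"],
                             model["fss_pred"]) for r in rows])
'''

_IO_CONTRACT_R = '''\
# Data-loading and prediction-writing stubs.  DO NOT EDIT.
#
# Edits to this file fail the sha256 integrity check at assessment time.

data_dir <- function() Sys.getenv("DATA_DIR", "/data")
output_dir <- function() Sys.getenv("OUTPUT_DIR", "/output")

read_table <- function(name) {
  path <- file.path(data_dir(), name)
  if (!file.exists(path)) return(NULL)
  read.csv(path, colClasses = "character")
}

write_predictions <- function(name, sids, mort, fss) {
  con <- file(file.path(output_dir(), name), "wb")
  writeLines(c("subject_id,mortality_pred,fss_pred",
               paste(sids, mort, fss, sep = ",")), con, sep = "\\n")
  close(con)
}
'''

_TRAIN_R = '''\
# Baseline training: training-mean FSS and majority mortality class.
source("io_contract.R")

rows <- read_table("training.csv")
stopifnot(!is.null(rows), nrow(rows) > 0)

fss <- as.numeric(rows$fss_total[rows$fss_total != ""])
stopifnot(length(fss) > 0)
mean_fss <- sum(fss) / length(fss)
# round half away from zero (contract shared with the Python template)
pred_fss <- floor(mean_fss + 0.5)
pred_fss <- min(30, max(6, pred_fss))

deaths <- sum(rows$mortality == "Mortality")
label <- if (deaths > nrow(rows) - deaths) "Mortality" else "Alive"

con <- file(file.path(output_dir(), "model.txt"), "wb")
writeLines(c(paste0("fss_pred=", pred_fss),
             paste0("mortality_pred=", label)), con, sep = "\\n")
close(con)
'''

_PREDICT_R = '''\
# Baseline prediction: constant model output for every subject.
source("io_contract.R")

model <- list()
for (line in readLines(file.path(output_dir(), "model.txt"))) {
  kv <- strsplit(line, "=", fixed = TRUE)[[1]]
  model[[kv[1]]] <- kv[2]
}

pairs <- list(c("training.csv", "train_predictions.csv"),
              c("testing.csv", "test_predictions.csv"))
for (p in pairs) {
  rows <- read_table(p[1])
  if (is.null(rows)) next
  write_predictions(p[2], rows$subject_id, model$mortality_pred, model$fss_pred)
}
'''

_PREDICT_STOCHASTIC = '''\
"""Intentionally unseeded random predictions (reproducibility fixture)."""
import random

from io_contract import read_table, write_predictions

for table, out in (("training.csv", "train_predictions.csv"),
                   ("testing.csv", "test_predictions.csv")):
    rows = read_table(table)
    if rows is None:
        continue
    write_predictions(out, [(r["subject_id"],
                             random.choice(["Mortality", "Alive"]),
                             random.randint(6, 30)) for r in rows])
'''

_DOCKERFILE_PY = '''\
FROM python:3.11-slim
# Extend this recipe with every Python module your models import, e.g.:
# RUN pip install --no-cache-dir scikit-learn pandas
'''

_DOCKERFILE_R = '''\
FROM rocker/r-ver:4.3.3
# Extend this recipe with every R package your models require, e.g.:
# RUN R -e 'install.packages(c("randomForest", "glmnet"))'
'''


def _manifest_yaml(participant_id: str, version_tag: str, language: str,
                   fss_approach: str, mortality_approach: str) -> str:
    return f"""\
participant_id: {participant_id}
contact: Reference Template <challenge-admin@example.org>
version_tag: {version_tag}
models:
  - outcome: FSS
    approach: {fss_approach}
    language: {language}
    predictors: 0
    summary: Predicts the rounded training-mean FSS for every subject.
  - outcome: mortality
    approach: {mortality_approach}
    language: {language}
    predictors: 0
    summary: Predicts the training majority mortality class for every subject.
"""


def _write(dest: Path, files: dict[str, str]) -> Path:
    dest.mkdir(parents=True, exist_ok=True)
    for name, content in files.items():
        (dest / name).write_text(content)
    return dest


def write_python_template(destination: str | Path,
                          participant_id: str = "baseline-python",
                          version_tag: str = "v1.0") -> Path:
    """Materialize the deterministic Python baseline submission."""
    return _write(Path(destination), {
        "description.yaml": _manifest_yaml(participant_id, version_tag,
                                           "python", "Mean baseline",
                                           "Majority-class baseline"),
        "io_contract.py": _IO_CONTRACT_PY,
        "train.py": _TRAIN_PY,
        "predict.py": _PREDICT_PY,
        "Dockerfile": _DOCKERFILE_PY,
    })


def write_r_template(destination: str | Path,
                     participant_id: str = "baseline-r",
                     version_tag: str = "v1.0") -> Path:
    """Materialize the deterministic R baseline submission."""
    return _write(Path(destination), {
        "description.yaml": _manifest_yaml(participant_id, version_tag,
                                           "R", "Mean baseline",
                                           "Majority-class baseline"),
        "io_contract.R": _IO_CONTRACT_R,
        "train.R": _TRAIN_R,
        "predict.R": _PREDICT_R,
        "Dockerfile": _DOCKERFILE_R,
    })


def write_stochastic_template(destination: str | Path,
                              participant_id: str = "stochastic-python",
                              version_tag: str = "v1.0") -> Path:
    """Materialize the unseeded-random submission (SD > 0 by design)."""
    return _write(Path(destination), {
        "description.yaml": _manifest_yaml(participant_id, version_tag,
                                           "python", "Unseeded random",
                                           "Unseeded random"),
        "io_contract.py": _IO_CONTRACT_PY,
        "train.py": '"""No training needed."""\n',
        "predict.py": _PREDICT_STOCHASTIC,
        "Dockerfile": _DOCKERFILE_PY,
    })


def template_policy(template_root: str | Path) -> IntegrityPolicy:
    """Integrity policy protecting the template's i/o contract stub."""
    root = Path(template_root)
    protected = ("io_contract.R",) if (root / "io_contract.R").exists() \
        else DEFAULT_PROTECTED_PATHS
    return IntegrityPolicy.from_template(root, protected)
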