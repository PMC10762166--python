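# challenge-harness

Open-source, inexpensive, reproducible infrastructure for running a
clinical-prediction **data challenge** — the kind where participants
submit *code*, not predictions, and a single administrator on an ordinary
machine re-runs every submission against a held-out partition.

Cloud platforms and industry-partnered challenge infrastructures are
financially out of reach for many investigators. This package shows that
the whole loop fits in a small library: synthetic clinical fixtures, a
submission contract with sha256 integrity checks, sandboxed execution of
train/predict entrypoints, rule-based prediction validation, repeated
scoring with reproducibility summaries, tie-aware rank aggregation with
prizes, and anonymized leaderboard/QC reporting.

The modeled challenge is a pediatric traumatic brain injury (TBI) cohort
with two prediction tasks per participant:

* **hospital mortality** — binary labels `"Mortality"`/`"Alive"`, scored
  with the Matthews correlation coefficient (MCC) and the F1 score
  (positive class `"Mortality"`);
* **Functional Status Scale (FSS) at discharge** — integers 6 (best) to
  30 (worst), defined only for survivors, scored by mean squared error
  (MSE) over subjects with a known FSS.

Because assessment re-runs participant training code, each submission is
evaluated R times; the mean **and sample SD** of every statistic enter the
ranking. Ranks use competition ("min") ranking — a three-way tie for
second among six gives (1, 2, 2, 2, 5, 6) — and a deterministic
submission's SD of 0 earns a shared reproducibility rank of 1. The
overall challenge rank is the min-rank of the sum of all average
statistic ranks across both outcomes and both partitions.

No external data is needed: the cohort generator emulates the study
structure (two sites, 388 subjects, GCS components with totals in [3, 15],
pupil reactivity, CT findings, ICP-monitor timing, LOS, mortality,
FSS for survivors, a site-balanced 300/88 train/test split) with
controlled missingness and injectable data inconsistencies. See
[docs/methods.md](docs/methods.md) for every modeling choice.

## Worked example

```python
import challenge_harness as ch
from challenge_harness.submission import Submission

bundle = ch.split_cohort(ch.generate_cohort(388, seed=1), train_size=300)
print(bundle.partitions["testing"].size)          # 88
print(len(bundle.partitions["training"].known_fss_ids))  # 246 known-FSS subjects

root = ch.write_python_template("scratch/baseline")   # deterministic baseline
sub = Submission.from_directory(root, mode="final")
series = ch.repeat_evaluate(sub, bundle, repeats=5)
print(series.mean("testing", "MSE"), series.sd("testing", "MSE"))
# 23.613333333333333 0.0
```

The baseline predicts the rounded training-mean FSS and the majority
mortality class for everyone: its test MSE of ≈ 23.6 is the variance-level
error a competitive FSS model must beat, and its SD of exactly 0.0 means
all five repeated train-and-predict cycles reproduced identical
statistics — the reproducibility property the ranking rewards.

The `examples/` directory has one short script per capability
(cohort generation/export, validation and scoring, repeated evaluation
and ranking, integrity checking, QC and challenge summary); each prints
its numbers with a line on what they mean. A thin CLI wraps the same
functions for shell use:

```sh
harness generate --n 388 --train-size 300 --seed 1 --out cohort
harness template sub --language python
harness run sub --cohort-dir cohort            # developmental: status only
harness evaluate sub --cohort-dir cohort --repeats 5 --out eval.json
harness rank eval.json --prize-map prizes.json
```

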