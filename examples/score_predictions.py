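"""Validate and score a prediction set against the challenge rules.

Builds a small cohort, fabricates a prediction file that is slightly wrong
on purpose, shows the validation report, then scores a compliant one.
"""

import pandas as pd

import challenge_harness as ch
from challenge_harness.metrics import ConfusionCounts

bundle = ch.split_cohort(ch.generate_cohort(60, seed=3), 45)
spec = bundle.partitions["testing"]

# predictions equal to the truth, except one illegal FSS value
labels = bundle.labels("testing")
rows = []
for rec in labels.itertuples(index=False):
    fss = "" if pd.isna(rec.fss_total) else str(int(rec.fss_total))
    rows.append({"subject_id": rec.subject_id,
                 "mortality_pred": rec.mortality, "fss_pred": fss})
bad = [dict(r) for r in rows]
bad[0]["fss_pred"] = "31"                      # outside the 6-30 scale
print(ch.validate_predictions(bad, spec).summary())

report = ch.validate_predictions(rows, spec)
print("compliant file:", report.summary())
scores = ch.score_predictions(rows, bundle, "testing")
print(f"truth-as-prediction scores: MCC={scores['MCC']:.3f} "
      f"F1={scores['F1']:.3f} MSE={scores['MSE']:.3f}")
# A perfect prediction gives MCC = F1 = 1 and MSE = 0; the single FSS=31
# cell above is the kind of error validation blocks before scoring.

c = ConfusionCounts(tp=6, tn=79, fp=1, fn=2)
print(f"worked confusion example: MCC={ch.mcc(c):.4f} F1={ch.f1(c):.2f}")
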