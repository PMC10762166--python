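"""Generate a synthetic pediatric-TBI cohort and export it for a challenge.

Builds a 388-subject two-site cohort, splits it 300/88 balanced between
sites, and writes both the administrator view (with the restricted
testing-label file) and the participant view (testing labels withheld).
"""

from pathlib import Path

import challenge_harness as ch

out = Path("scratch/example_cohort")
bundle = ch.split_cohort(ch.generate_cohort(388, seed=1), train_size=300)
ch.write_cohort(bundle, out / "admin")
ch.write_cohort(bundle, out / "public", participant_view=True)

train = bundle.partitions["training"]
test = bundle.partitions["testing"]
deaths = (bundle.records["mortality"] == "Mortality").sum()
print(f"cohort: {bundle.n} subjects, {deaths} deaths")
print(f"training: {train.size} subjects, {len(train.known_fss_ids)} with known FSS")
print(f"testing:  {test.size} subjects, {len(test.known_fss_ids)} with known FSS")
print(f"admin export -> {out/'admin'}   (includes testing_labels.csv)")
print(f"public export -> {out/'public'} (testing labels withheld)")
# The known-FSS counts are the completeness targets a submission's FSS
# predictions must cover; the 88-subject holdout is scored but never shown.
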