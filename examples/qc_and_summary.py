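"""Data-consistency QC and the challenge summary report.

Injects impossible ICP-monitor timing into a cohort and flags it, then
reproduces the registration/submission tallies of a completed challenge
from the bundled registry fixture.
"""

import challenge_harness as ch
from challenge_harness.fixtures import load_reference_registry

bundle = ch.generate_cohort(150, seed=31)
injected = ch.inject_inconsistencies(bundle, rate=0.1, seed=7)
findings = ch.check_consistency(injected)
print(f"{len(findings)} records with ICP monitoring past discharge "
      f"(injected: {len(injected.metadata['inconsistent_ids'])})")
f = findings[0]
print(f"  e.g. {f.subject_id}: LOS={f.hosp_los_days} d but ICP monitor "
      f"{f.icp_start_days}-{f.icp_stop_days} d after admission")
# Such rows are flagged, not corrected: participants are expected to
# explore the data and decide how to handle them.

print()
registered, manifests = load_reference_registry()
summary = ch.summarize_challenge(registered, manifests)
print(summary.to_markdown())
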