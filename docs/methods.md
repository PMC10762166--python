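# Methods

`challenge-harness` implements the full assessment loop of a lightweight
clinical-prediction data challenge: synthetic cohort → submission contract
→ sandboxed execution → validation → repeated scoring → rank aggregation →
reporting. This note records the models, conventions, and design choices
behind each stage, and what the synthetic data can and cannot demonstrate.

## The challenge being modeled

The harness targets a two-task challenge on a pediatric traumatic brain
injury (TBI) cohort: predict (1) hospital mortality (binary, labels
`"Mortality"`/`"Alive"`) and (2) the Functional Status Scale at hospital
discharge (FSS; an integer from 6, best, to 30, worst). FSS is assessed at
discharge and is therefore defined only for survivors. Participants
receive a labeled training partition and the unlabeled features of a
holdout partition; they submit code, not predictions, and the
administrator re-runs that code for every assessment.

## Synthetic cohort generator

The generator produces structurally faithful cohorts, not distributionally
calibrated ones. Asserted structure:

* age strictly under 18 years (integer years, uniform 0–17);
* Glasgow Coma Scale assessments at two time points (ED and ICU), each
  with eye (1–4), verbal (1–5), motor (1–6) components drawn from
  severity-skewed categorical distributions; the total is the component
  sum and lies in [3, 15]; an assessment is missing wholesale (all
  components and the total) rather than per component, which keeps the
  additivity invariant checkable;
* eligibility: every subject has a documented GCS total ≤ 12 at either
  assessment or the neurosurgical-procedure flag set (the flag is forced
  on when no documented total qualifies);
* hospital length of stay (LOS) from a rounded log-normal
  (exp N(2.0, 0.8²), median ≈ 7 days, minimum 1);
* ICP-monitor start/stop days within [0, LOS] for the ~40 % of subjects
  monitored — consistent by construction, so every inconsistency later
  flagged by QC is one the administrator injected;
* mortality as an independent Bernoulli draw; FSS for survivors via a
  monotone noisy map from ICU GCS total,
  `FSS ≈ clip(round(6 + 2·(15 − GCS) + N(0, 2.5²)), 6, 30)`, so worse
  neurological status predicts worse function;
* discharge disposition is `"Mortality"` for deaths and a categorical
  draw otherwise.

Default rates (all overridable via `GeneratorParams`): mortality 0.13 and
FSS missingness among survivors 0.055, chosen once so a 388-subject cohort
has an expected ≈ 319 known-FSS subjects, matching the aggregate shape of
the real two-site cohort the challenge design is modeled on (388 subjects,
319 with known FSS); GCS assessment missingness 0.08 (ED) / 0.10 (ICU); CT
findings missingness 0.05; site assignment Bernoulli(0.5).

Missingness is missing-completely-at-random and encoded as *empty fields*
in every export — never as a sentinel zero. Zero-imputation of GCS is a
documented modeling pitfall (it fabricates severities below the defined
floor of 3), and the harness refuses to normalize it into the data format.

What the generator does **not** emulate: real marginal distributions,
covariance between demographics and severity, informative missingness,
site-level case-mix differences. Tests passing on these cohorts therefore
demonstrate the harness's bookkeeping and arithmetic, not clinical model
performance.

## Train/test split

`split_cohort` allocates the training quota across the two collection
sites by largest-remainder apportionment and samples without replacement
within site, giving a per-site training fraction within one subject of the
global fraction — the operational definition adopted for "balanced between
sites". The split is seeded from the bundle's generator seed, so a bundle
regenerated from the same seed and parameters serializes byte-identically,
partitions included.

## Submission contract and integrity

A submission is a directory with a `description.yaml` manifest
(participant id, contact, version tag, one model block per outcome), the
train/predict entrypoints, and a Dockerfile. Integrity is a sha256
baseline over a configurable protected set; the default protects the i/o
contract stub (`io_contract.py`/`io_contract.R`) that reads mounted data
and writes prediction files, while model code, manifest, and recipe remain
editable. Which files to protect is a challenge-administration decision,
not a property of the method; the policy object makes it explicit.

## Sandboxed execution

The backend interface has a `container` implementation (Docker CLI; data
mounted read-only, no network) and a `local_subprocess` implementation
(entrypoints run as host subprocesses with `DATA_DIR`/`OUTPUT_DIR`
environment variables). The isolation property that matters is enforced at
the staging layer, identically for both backends: the mounted data
directory contains the labeled training table and — in final mode only —
the testing table with mortality, FSS, *and discharge disposition*
stripped. Disposition is withheld with the labels because it encodes
mortality and is collected simultaneously with FSS; leaving it in would
leak the test labels. Testing labels are never staged anywhere a run can
read. Developmental runs see no testing data at all and return only
success/failure to the participant. Default per-entrypoint timeout:
30 minutes, configurable.

## Validation rules

Before scoring, prediction files must pass: LENGTH (exactly one row per
partition subject), UNKNOWN_ID, LABEL_SET (exact strings `"Mortality"`/
`"Alive"`; case-normalization available but off by default, since the
contract quotes exact strings), FSS_COMPLETENESS (an FSS prediction for
every known-FSS subject — 251/68 in the modeled challenge's
training/testing partitions), FSS_INTEGER, and FSS_RANGE ([6, 30]). LENGTH
is deliberately count-based and FSS_COMPLETENESS is checked over rows
present in the file, so any single-field corruption of a compliant file
fires exactly one rule — a property the suite asserts field by field. FSS
predictions for subjects outside the known-FSS set (deaths) are permitted
and ignored.

## Scoring and reproducibility

Mortality is scored with the Matthews correlation coefficient and the F1
score, with `"Mortality"` as the positive class (F1 is only informative
for the rare class; configurable). Zero-denominator conventions: MCC → 0
when any marginal sum vanishes; F1 → 0 when 2TP+FP+FN = 0. FSS is scored
by mean squared error over known-FSS subjects only. The scorers are
authored in-package so these conventions are explicit; the test suite
requires agreement with scikit-learn to 1e−12 on random inputs.

Because assessment re-runs participant training code, each submission is
evaluated R times (R = 100 in a production challenge; the suite and the
acceptance script use R = 5 and small cohorts to keep a full pipeline run
in seconds) and the mean and sample (n−1) SD of each statistic are
recorded. The harness does not inject seeds into participant code:
reproducibility is measured, not enforced. An SD over bitwise-identical
repeats is reported as exactly 0 rather than mean-subtraction noise, since
"SD = 0 iff all repeats identical" is the contract the ranking rewards.

## Rank aggregation

All ranking is competition ("min") ranking: `rank_i = 1 + #{j : v_j
strictly better}`; a three-way tie for second among six values yields
(1, 2, 2, 2, 5, 6). Per (outcome, partition, statistic), participants'
means are ranked (MSE ascending, MCC/F1 descending) and their SDs ranked
ascending — deterministic submissions all share SD-rank 1. The statistic's
average rank is the mean of those two; the outcome rank for a
(participant, outcome, partition) is the sum of average ranks over that
outcome's statistics; the overall total sums every average rank across
both outcomes and both partitions, and overall challenge ranks are the
min-ranks of the totals. Prize ranking removes prize-ineligible
participants, re-ranks the remainder, and pays every participant tied at a
prize rank that rank's amount. Model parsimony (the manifest's declared
predictor count) is available as an optional ascending tie-break statistic
but is disabled by default: the core aggregation uses only means and SDs.

Participant anonymization hashes each user id with sha256, sorts the
digests lexicographically, and assigns `P01, P02, …` in that order —
deterministic, injective, and irreversible in practice.

## QC and reporting

The consistency check flags records whose ICP-monitor start or stop
(days from admission) strictly exceeds the hospital LOS — an
impossibility observed in real prospective data. `inject_inconsistencies`
plants exactly this defect (start = LOS+1, stop = LOS+4 on a
Bernoulli(rate) subset) and records the altered ids, so QC output can be
checked for exact equality. Findings are surfaced to the administrator;
the harness never corrects records — exploring and handling inconsistent
data is left to participants by design.

The challenge summary reports registrations, finalists, completion rate
(one decimal), per-finalist language tallies, and per-model approach
tallies. Leaderboards render only anonymous ids (rendering without a
complete anonymization map is an error), ordered by overall rank with ties
ordered by anonymous id for determinism.

## Numerical and degenerate-input choices

* Baseline template rounding: half away from zero (`floor(x + 0.5)`),
  stated so the Python and R templates produce byte-identical output.
* Completion rate with zero registrations: reported as undefined, not an
  exception, since an empty challenge is a valid (if sad) state.
* `repeat_evaluate` requires R ≥ 2 (sample SD undefined at R = 1).
* Empty prediction vectors, all-zero confusion counts, empty rank
  vectors, and duplicate ids to the anonymizer are parameter errors.

## Known limitations

* The container backend shells out to a Docker CLI and is exercised only
  through its failure paths where no daemon is available; the
  local-subprocess backend is the tested reference, and the staging-layer
  isolation (what data exists in the mount) is identical for both. OS-level
  isolation of the local backend is obviously weaker than a container's.
* MCAR missingness and an independent mortality draw understate the
  difficulty of real imputation and calibration work.
* The advisory check for forbidden predictors (e.g. using FSS, or
  disposition, to predict mortality) is limited to what manifests declare;
  automated code inspection is out of scope, and disqualification remains
  an administrator decision recorded as a flag.
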