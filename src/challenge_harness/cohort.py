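"""Synthetic pediatric-TBI cohort generation, splitting, and CSV round-trip.

The generator emulates the structure of a two-site prospective pediatric
traumatic-brain-injury cohort: demographics, Glasgow Coma Scale (GCS)
assessments at emergency-department (ED) and ICU time points, pupil
reactivity, CT findings, intracranial-pressure (ICP) monitor timing,
hospital length of stay, hospital mortality, discharge disposition, and the
Functional Status Scale (FSS, integers 6-30, defined only for survivors).
Only structural properties of the data are contractual (ranges, additivity
of GCS components, FSS/mortality exclusivity, site balance of the split);
marginal distributions are simple parametric stand-ins.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "GeneratorParams",
    "PartitionSpec",
    "DataDictionary",
    "VariableDef",
    "CohortBundle",
    "generate_cohort",
    "split_cohort",
    "inject_inconsistencies",
    "write_cohort",
    "read_cohort",
    "default_dictionary",
]

# Column order is part of the serialization contract.
COLUMNS = [
    "subject_id", "site", "age", "sex", "injury_mechanism",
    "gcs_eye_ed", "gcs_verbal_ed", "gcs_motor_ed", "gcs_total_ed",
    "gcs_eye_icu", "gcs_verbal_icu", "gcs_motor_icu", "gcs_total_icu",
    "pupil_react", "ct_skull_fracture", "ct_ivh", "neurosurgery",
    "icp_start_days", "icp_stop_days", "hosp_los_days",
    "mortality", "disposition", "fss_total",
]

#: Columns withheld from the participant-visible testing export.  Discharge
#: disposition is stripped alongside the outcome labels because it encodes
#: mortality and is collected simultaneously with FSS.
LABEL_COLUMNS = ["mortality", "disposition", "fss_total"]

SITES = ["site_1", "site_2"]
SEXES = ["Female", "Male"]
MECHANISMS = ["Fall", "Motor vehicle", "Pedestrian", "Assault", "Other"]
PUPIL_LEVELS = ["both reactive", "one fixed", "both fixed", "unknown"]
DISPOSITIONS = [
    "Home", "Inpatient rehabilitation", "Skilled nursing facility",
    "Other", "Mortality",
]

_INT_COLUMNS = [
    "age",
    "gcs_eye_ed", "gcs_verbal_ed", "gcs_motor_ed", "gcs_total_ed",
    "gcs_eye_icu", "gcs_verbal_icu", "gcs_motor_icu", "gcs_total_icu",
    "ct_skull_fracture", "ct_ivh", "neurosurgery",
    "icp_start_days", "icp_stop_days", "hosp_los_days", "fss_total",
]

GCS_MOTOR_LABELS = {
    1: "no response/flaccid",
    2: "abnormal extension to pain",
    3: "abnormal flexion to pain",
    4: "withdraws from painful stimuli",
    5: "localizes pain or withdraws to touch",
    6: "obeys commands",
}
GCS_EYE_LABELS = {
    1: "no response",
    2: "opens to pain",
    3: "opens to verbal stimuli",
    4: "opens spontaneously",
}
GCS_VERBAL_LABELS = {
    1: "no response",
    2: "incomprehensible sounds",
    3: "inappropriate words",
    4: "confused",
    5: "oriented",
}


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable rates for the cohort generator.

    Defaults were chosen once to match the aggregate shape of a real
    two-site pediatric severe-TBI cohort of 388 subjects in which 319
    subjects have a known FSS: a hospital-mortality rate of 0.13 and a
    5.5% FSS-missingness rate among survivors give an expected
    388 * (1 - 0.13) * (1 - 0.055) ~= 319 known-FSS subjects.
    """

    mortality_rate: float = 0.13
    fss_missing_rate: float = 0.055
    gcs_missing_rate_ed: float = 0.08
    gcs_missing_rate_icu: float = 0.10
    ct_missing_rate: float = 0.05
    icp_monitor_rate: float = 0.40
    site_ratio: float = 0.5
    inconsistency_rate: float = 0.0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not 0.0 <= float(v) <= 1.0:
                raise ParameterError(f"rate {f.name}={v!r} must lie in [0, 1]")


@dataclass
class PartitionSpec:
    """An ordered subject-id list naming one data partition."""

    name: str
    subject_ids: list[str]
    known_fss_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.subject_ids)

    def __post_init__(self) -> None:
        if self.name not in ("training", "testing"):
            raise ParameterError(f"partition name must be training/testing, got {self.name!r}")
        unknown = set(self.known_fss_ids) - set(self.subject_ids)
        if unknown:
            raise ParameterError(f"known_fss_ids not in partition: {sorted(unknown)}")


@dataclass(frozen=True)
class VariableDef:
    """One data-dictionary row: type, range/levels, and value labels."""

    name: str
    vtype: str                      # "integer" | "categorical" | "identifier"
    allowed_range: tuple[int, int] | None = None
    levels: tuple[str, ...] | None = None
    label_map: dict[int, str] | None = None
    missingness: str = "empty field"

    def check_labels_total(self) -> bool:
        """Label map, when present, must cover the whole declared range."""
        if self.label_map is None or self.allowed_range is None:
            return True
        lo, hi = self.allowed_range
        return set(self.label_map) == set(range(lo, hi + 1))


class DataDictionary:
    """Per-variable metadata: semantic type, range, levels, labels."""

    def __init__(self, variables: list[VariableDef]):
        names = [v.name for v in variables]
        if len(names) != len(set(names)):
            raise ParameterError("duplicate variable in data dictionary")
        for v in variables:
            if not v.check_labels_total():
                raise ParameterError(
                    f"label map for {v.name} does not cover its declared range")
        self.variables = {v.name: v for v in variables}

    def __getitem__(self, name: str) -> VariableDef:
        return self.variables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.variables.values():
            rows.append({
                "name": v.name,
                "type": v.vtype,
                "range": "" if v.allowed_range is None else f"{v.allowed_range[0]}-{v.allowed_range[1]}",
                "levels": "" if v.levels is None else "|".join(v.levels),
                "label_map": "" if v.label_map is None else json.dumps(
                    {str(k): s for k, s in sorted(v.label_map.items())}),
                "missingness": v.missingness,
            })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DataDictionary":
        variables = []
        for row in frame.fillna("").itertuples(index=False):
            rng = None
            if row.range:
                lo, _, hi = row.range.partition("-")
                rng = (int(lo), int(hi))
            levels = tuple(row.levels.split("|")) if row.levels else None
            lmap = ({int(k): s for k, s in json.loads(row.label_map).items()}
                    if row.label_map else None)
            variables.append(VariableDef(row.name, row.type, rng, levels,
                                         lmap, row.missingness))
        return cls(variables)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DataDictionary) and self.variables == other.variables


def default_dictionary() -> DataDictionary:
    variables = [
        VariableDef("subject_id", "identifier"),
        VariableDef("site", "categorical", levels=tuple(SITES)),
        VariableDef("age", "integer", allowed_range=(0, 17)),
        VariableDef("sex", "categorical", levels=tuple(SEXES)),
        VariableDef("injury_mechanism", "categorical", levels=tuple(MECHANISMS)),
    ]
    for when in ("ed", "icu"):
        variables += [
            VariableDef(f"gcs_eye_{when}", "integer", (1, 4), label_map=GCS_EYE_LABELS),
            VariableDef(f"gcs_verbal_{when}", "integer", (1, 5), label_map=GCS_VERBAL_LABELS),
            VariableDef(f"gcs_motor_{when}", "integer", (1, 6), label_map=GCS_MOTOR_LABELS),
            VariableDef(f"gcs_total_{when}", "integer", (3, 15)),
        ]
    variables += [
        VariableDef("pupil_react", "categorical", levels=tuple(PUPIL_LEVELS)),
        VariableDef("ct_skull_fracture", "integer", (0, 1)),
        VariableDef("ct_ivh", "integer", (0, 1)),
        VariableDef("neurosurgery", "integer", (0, 1)),
        VariableDef("icp_start_days", "integer", (0, 10_000)),
        VariableDef("icp_stop_days", "integer", (0, 10_000)),
        VariableDef("hosp_los_days", "integer", (0, 10_000)),
        VariableDef("mortality", "categorical", levels=("Mortality", "Alive")),
        VariableDef("disposition", "categorical", levels=tuple(DISPOSITIONS)),
        VariableDef("fss_total", "integer", (6, 30)),
    ]
    return DataDictionary(variables)


@dataclass
class CohortBundle:
    """A cohort table plus its dictionary, partitions, and provenance."""

    records: pd.DataFrame
    dictionary: DataDictionary
    partitions: dict[str, PartitionSpec]
    generator_seed: int
    generator_params: GeneratorParams
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.records)

    def subject_frame(self, partition: str) -> pd.DataFrame:
        spec = self.partitions[partition]
        df = self.records.set_index("subject_id", drop=False)
        return df.loc[spec.subject_ids].reset_index(drop=True)

    def labels(self, partition: str) -> pd.DataFrame:
        return self.subject_frame(partition)[["subject_id"] + LABEL_COLUMNS]

    def equals(self, other: "CohortBundle") -> bool:
        return (
            self.records.equals(other.records)
            and self.dictionary == other.dictionary
            and {k: (v.subject_ids, v.known_fss_ids) for k, v in self.partitions.items()}
            == {k: (v.subject_ids, v.known_fss_ids) for k, v in other.partitions.items()}
            and self.generator_seed == other.generator_seed
            and self.generator_params == other.generator_params
        )


# severity-skewed GCS component distributions (probabilities for scores 1..k)
_P_EYE = [0.45, 0.20, 0.20, 0.15]
_P_VERBAL = [0.45, 0.15, 0.15, 0.15, 0.10]
_P_MOTOR = [0.35, 0.10, 0.10, 0.15, 0.15, 0.15]


def _gcs_block(rng: np.random.Generator, n: int, missing_rate: float):
    eye = rng.choice(np.arange(1, 5), size=n, p=_P_EYE)
    verbal = rng.choice(np.arange(1, 6), size=n, p=_P_VERBAL)
    motor = rng.choice(np.arange(1, 7), size=n, p=_P_MOTOR)
    total = eye + verbal + motor
    missing = rng.random(n) < missing_rate
    cols = {}
    for name, arr in (("eye", eye), ("verbal", verbal), ("motor", motor), ("total", total)):
        s = pd.Series(arr, dtype="Int64")
        s[missing] = pd.NA
        cols[name] = s
    return cols


def generate_cohort(n: int, seed: int,
                    params: GeneratorParams | None = None) -> CohortBundle:
    """Generate ``n`` synthetic subjects; deterministic for a fixed seed.

    Every record satisfies the structural invariants: age < 18, GCS totals
    are component sums in [3, 15] whenever the assessment is documented,
    FSS is absent for every death and an integer in [6, 30] otherwise
    (subject to missingness), and each subject is eligible by a documented
    GCS total <= 12 or a neurosurgical-procedure flag.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise ParameterError(f"n must be an integer, got {n!r}")
    if n < 10:
        raise ParameterError(f"n must be at least 10, got {n}")
    params = params or GeneratorParams()
    params.validate()

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n)))
    df = pd.DataFrame({"subject_id": [f"S{i + 1:0{width}d}" for i in range(n)]})
    df["site"] = np.where(rng.random(n) < params.site_ratio, SITES[0], SITES[1])
    df["age"] = pd.Series(rng.integers(0, 18, size=n), dtype="Int64")
    df["sex"] = rng.choice(SEXES, size=n, p=[0.38, 0.62])
    df["injury_mechanism"] = rng.choice(MECHANISMS, size=n,
                                        p=[0.30, 0.35, 0.10, 0.15, 0.10])

    ed = _gcs_block(rng, n, params.gcs_missing_rate_ed)
    icu = _gcs_block(rng, n, params.gcs_missing_rate_icu)
    for when, block in (("ed", ed), ("icu", icu)):
        for comp in ("eye", "verbal", "motor", "total"):
            df[f"gcs_{comp}_{when}"] = block[comp]

    df["pupil_react"] = rng.choice(PUPIL_LEVELS, size=n, p=[0.70, 0.08, 0.12, 0.10])
    for col in ("ct_skull_fracture", "ct_ivh"):
        s = pd.Series(rng.integers(0, 2, size=n), dtype="Int64")
        s[rng.random(n) < params.ct_missing_rate] = pd.NA
        df[col] = s

    # Eligibility: a documented GCS total <= 12 at either assessment, or a
    # neurosurgical procedure in the first 24 h (flag forced on otherwise).
    neuro = pd.Series((rng.random(n) < 0.30).astype(int), dtype="Int64")
    documented_low = (
        df["gcs_total_ed"].le(12).fillna(False)
        | df["gcs_total_icu"].le(12).fillna(False)
    )
    neuro[~documented_low] = 1
    df["neurosurgery"] = neuro

    los = np.maximum(1, np.rint(np.exp(rng.normal(2.0, 0.8, size=n)))).astype(int)
    df["hosp_los_days"] = pd.Series(los, dtype="Int64")

    monitored = rng.random(n) < params.icp_monitor_rate
    start = rng.integers(0, 3, size=n)
    start = np.minimum(start, los)
    stop = np.minimum(start + 1 + rng.integers(0, 7, size=n), los)
    stop = np.maximum(stop, start)
    icp_start = pd.Series(start, dtype="Int64")
    icp_stop = pd.Series(stop, dtype="Int64")
    icp_start[~monitored] = pd.NA
    icp_stop[~monitored] = pd.NA
    df["icp_start_days"] = icp_start
    df["icp_stop_days"] = icp_stop

    died = rng.random(n) < params.mortality_rate
    df["mortality"] = np.where(died, "Mortality", "Alive")
    disposition = rng.choice(DISPOSITIONS[:4], size=n, p=[0.60, 0.25, 0.05, 0.10])
    df["disposition"] = np.where(died, "Mortality", disposition)

    # FSS from ICU GCS via a monotone noisy map: GCS 3 -> ~30, GCS 15 -> ~6.
    gcs_icu = df["gcs_total_icu"].astype("float").to_numpy()
    gcs_icu = np.where(np.isnan(gcs_icu), 9.0, gcs_icu)
    fss_raw = 6.0 + 2.0 * (15.0 - gcs_icu) + rng.normal(0.0, 2.5, size=n)
    fss = np.clip(np.rint(fss_raw), 6, 30).astype(int)
    fss_series = pd.Series(fss, dtype="Int64")
    fss_series[died] = pd.NA
    fss_series[(~died) & (rng.random(n) < params.fss_missing_rate)] = pd.NA
    df["fss_total"] = fss_series

    df = df[COLUMNS]
    return CohortBundle(
        records=df,
        dictionary=default_dictionary(),
        partitions={},
        generator_seed=int(seed),
        generator_params=params,
        metadata={"inconsistent_ids": []},
    )


def _known_fss_ids(records: pd.DataFrame, ids: list[str]) -> list[str]:
    known = set(records.loc[records["fss_total"].notna(), "subject_id"])
    return [i for i in ids if i in known]


def split_cohort(bundle: CohortBundle, train_size: int) -> CohortBundle:
    """Fill the training/testing partitions, balanced between sites.

    Balance means the per-site training fraction is within one subject of
    the overall training fraction; achieved by a largest-remainder
    allocation of the training quota across sites followed by simple random
    sampling within each site (seeded from the bundle's generator seed).
    """
    n = bundle.n
    if not isinstance(train_size, (int, np.integer)) or isinstance(train_size, bool):
        raise ParameterError(f"train_size must be an integer, got {train_size!r}")
    if not 0 < train_size < n:
        raise ParameterError(f"train_size must be in (0, {n}), got {train_size}")

    rng = np.random.default_rng([bundle.generator_seed, 0x5EED])
    records = bundle.records
    site_ids = {s: records.loc[records["site"] == s, "subject_id"].tolist()
                for s in sorted(records["site"].unique())}

    # largest-remainder apportionment of the training quota across sites
    quotas = {s: train_size * len(ids) / n for s, ids in site_ids.items()}
    alloc = {s: int(np.floor(q)) for s, q in quotas.items()}
    shortfall = train_size - sum(alloc.values())
    for s in sorted(quotas, key=lambda s: quotas[s] - alloc[s], reverse=True)[:shortfall]:
        alloc[s] += 1

    train_ids: list[str] = []
    for s, ids in site_ids.items():
        chosen = rng.choice(ids, size=alloc[s], replace=False)
        train_ids.extend(chosen.tolist())
    train_set = set(train_ids)
    ordered = records["subject_id"].tolist()
    train_ids = [i for i in ordered if i in train_set]
    test_ids = [i for i in ordered if i not in train_set]

    partitions = {
        "training": PartitionSpec("training", train_ids,
                                  _known_fss_ids(records, train_ids)),
        "testing": PartitionSpec("testing", test_ids,
                                 _known_fss_ids(records, test_ids)),
    }
    return CohortBundle(records, bundle.dictionary, partitions,
                        bundle.generator_seed, bundle.generator_params,
                        dict(bundle.metadata))


def inject_inconsistencies(bundle: CohortBundle, rate: float,
                           seed: int) -> CohortBundle:
    """Alter ~rate*n records so ICP-monitor timing exceeds the hospital LOS.

    Each record is altered independently with probability ``rate``; an
    altered record gets icp_start_days = LOS + 1 and icp_stop_days =
    LOS + 4, an impossibility a QC pass must flag.  Altered subject ids are
    recorded in bundle metadata so QC findings can be checked exactly.
    """
    if not 0.0 <= rate <= 1.0:
        raise ParameterError(f"rate must lie in [0, 1], got {rate}")
    records = bundle.records.copy()
    rng = np.random.default_rng(seed)
    altered_mask = rng.random(len(records)) < rate
    altered_ids = records.loc[altered_mask, "subject_id"].tolist()
    los = records.loc[altered_mask, "hosp_los_days"]
    records.loc[altered_mask, "icp_start_days"] = (los + 1).astype("Int64")
    records.loc[altered_mask, "icp_stop_days"] = (los + 4).astype("Int64")

    metadata = dict(bundle.metadata)
    metadata["inconsistent_ids"] = sorted(
        set(metadata.get("inconsistent_ids", [])) | set(altered_ids))
    params = dataclasses.replace(bundle.generator_params, inconsistency_rate=rate)
    return CohortBundle(records, bundle.dictionary, dict(bundle.partitions),
                        bundle.generator_seed, params, metadata)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def write_cohort(bundle: CohortBundle, destination: str | Path,
                 participant_view: bool = False) -> Path:
    """Serialize a bundle to a directory of CSV + JSON files.

    Administrator view (default) writes everything, with testing-partition
    labels in a separate restricted file (``testing_labels.csv``) so the
    participant-visible export can exclude them.  With
    ``participant_view=True`` the testing table is stripped of mortality,
    disposition, and FSS and no restricted file is written.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    _write_csv(bundle.dictionary.to_frame(), dest / "data_dictionary.csv")

    if bundle.partitions:
        train = bundle.subject_frame("training")
        test = bundle.subject_frame("testing")
        _write_csv(train, dest / "training.csv")
        _write_csv(test.drop(columns=LABEL_COLUMNS), dest / "testing.csv")
        if not participant_view:
            _write_csv(test[["subject_id"] + LABEL_COLUMNS],
                       dest / "testing_labels.csv")
    else:
        _write_csv(bundle.records, dest / "cohort.csv")

    meta = {
        "generator_seed": bundle.generator_seed,
        "generator_params": dataclasses.asdict(bundle.generator_params),
        "partitions": {
            name: {"subject_ids": spec.subject_ids,
                   "known_fss_ids": spec.known_fss_ids}
            for name, spec in bundle.partitions.items()
        },
        "metadata": bundle.metadata,
    }
    if participant_view:
        meta["partitions"] = {
            name: {"subject_ids": spec.subject_ids,
                   "known_fss_ids": spec.known_fss_ids if name == "training" else []}
            for name, spec in bundle.partitions.items()
        }
    (dest / "bundle.json").write_text(json.dumps(meta, indent=1) + "\n")
    return dest


def _read_table(path: Path, dictionary: DataDictionary) -> pd.DataFrame:
    df = pd.read_csv(path, dtype="string")
    for col in df.columns:
        if col in dictionary and dictionary[col].vtype == "integer":
            try:
                df[col] = df[col].astype("Int64")
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path.name}: column {col} is not integer-valued: {exc}") from exc
    return df


def _validate_against_dictionary(df: pd.DataFrame, dictionary: DataDictionary,
                                 source: str) -> None:
    for col in df.columns:
        if col not in dictionary:
            raise FormatError(f"{source}: unexpected variable {col}")
        var = dictionary[col]
        values = df[col].dropna()
        if var.vtype == "integer" and var.allowed_range is not None:
            lo, hi = var.allowed_range
            bad = values[(values < lo) | (values > hi)]
            if len(bad):
                raise FormatError(
                    f"{source}: {col} value {bad.iloc[0]} outside allowed "
                    f"range [{lo}, {hi}]")
        elif var.levels is not None:
            bad = values[~values.isin(var.levels)]
            if len(bad):
                raise FormatError(
                    f"{source}: {col} value {bad.iloc[0]!r} not an allowed level")


def read_cohort(source: str | Path) -> CohortBundle:
    """Read a bundle written by :func:`write_cohort` (administrator view).

    Tables are validated against the data dictionary; any out-of-range
    value raises :class:`FormatError` naming the offending variable.
    """
    src = Path(source)
    if not src.exists():
        raise FormatError(f"cohort directory {src} does not exist")
    dictionary = DataDictionary.from_frame(pd.read_csv(src / "data_dictionary.csv",
                                                       dtype="string").fillna(""))
    meta = json.loads((src / "bundle.json").read_text())

    if (src / "cohort.csv").exists():
        records = _read_table(src / "cohort.csv", dictionary)
    else:
        train = _read_table(src / "training.csv", dictionary)
        test_feats = _read_table(src / "testing.csv", dictionary)
        labels_path = src / "testing_labels.csv"
        if not labels_path.exists():
            raise FormatError(
                "testing_labels.csv missing: participant-view exports cannot "
                "be read back into a full bundle")
        labels = _read_table(labels_path, dictionary)
        test = test_feats.merge(labels, on="subject_id", how="left")
        records = pd.concat([train, test], ignore_index=True)
        records = records.sort_values("subject_id", ignore_index=True)
    records = records[COLUMNS]
    for col in _INT_COLUMNS:
        records[col] = records[col].astype("Int64")
    for col in records.columns:
        if col not in _INT_COLUMNS:
            records[col] = records[col].astype(object)
    _validate_against_dictionary(records, dictionary, src.name)

    partitions = {
        name: PartitionSpec(name, p["subject_ids"], p["known_fss_ids"])
        for name, p in meta["partitions"].items()
    }
    return CohortBundle(records, dictionary, partitions,
                        int(meta["generator_seed"]),
                        GeneratorParams(**meta["generator_params"]),
                        meta.get("metadata", {}))
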