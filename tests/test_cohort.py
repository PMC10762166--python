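"""Generator, splitter, inconsistency injection, and CSV round-trip."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import challenge_harness as ch
from challenge_harness.errors import FormatError, ParameterError

from conftest import make_bundle


def assert_record_invariants(df: pd.DataFrame) -> None:
    assert (df["age"] < 18).all()
    for when in ("ed", "icu"):
        comps = [f"gcs_{c}_{when}" for c in ("eye", "verbal", "motor")]
        all_present = df[comps].notna().all(axis=1)
        total = df.loc[all_present, f"gcs_total_{when}"]
        assert (total == df.loc[all_present, comps].sum(axis=1)).all()
        assert total.between(3, 15).all()
    died = df["mortality"] == "Mortality"
    assert df.loc[died, "fss_total"].isna().all()
    fss = df["fss_total"].dropna()
    assert fss.between(6, 30).all()
    # eligibility: documented GCS total <= 12 at either assessment, or the
    # neurosurgical-procedure flag
    documented_low = (df["gcs_total_ed"].le(12).fillna(False)
                      | df["gcs_total_icu"].le(12).fillna(False))
    assert (documented_low | (df["neurosurgery"] == 1)).all()


class TestGenerate:
    def test_full_cohort_invariants(self):
        bundle = ch.generate_cohort(388, seed=1)
        assert bundle.n == 388
        assert_record_invariants(bundle.records)
        assert set(bundle.records["site"]) == {"site_1", "site_2"}

    def test_zero_mortality_rate(self):
        params = ch.GeneratorParams(mortality_rate=0.0, fss_missing_rate=0.0)
        bundle = ch.generate_cohort(10, seed=5, params=params)
        assert (bundle.records["mortality"] == "Alive").all()
        assert bundle.records["fss_total"].notna().all()

    def test_mortality_fraction_within_binomial_bound(self):
        # observed fraction within 3 binomial SDs of the requested rate
        rate, n = 0.15, 200
        params = ch.GeneratorParams(mortality_rate=rate)
        bundle = ch.generate_cohort(n, seed=7, params=params)
        observed = (bundle.records["mortality"] == "Mortality").mean()
        bound = 3 * np.sqrt(rate * (1 - rate) / n)
        assert abs(observed - rate) < bound

    def test_seed_determinism_bytewise(self, tmp_path):
        dirs = []
        for name in ("a", "b"):
            bundle = ch.split_cohort(ch.generate_cohort(50, seed=11), 40)
            dirs.append(ch.write_cohort(bundle, tmp_path / name))
        diff = subprocess.run(["diff", "-r", str(dirs[0]), str(dirs[1])],
                              capture_output=True)
        assert diff.returncode == 0, diff.stdout

    @pytest.mark.parametrize("bad_n", [9, 3.5, "388", True])
    def test_bad_n_rejected(self, bad_n):
        with pytest.raises(ParameterError):
            ch.generate_cohort(bad_n, seed=1)

    def test_bad_rate_rejected(self):
        with pytest.raises(ParameterError, match="mortality_rate"):
            ch.generate_cohort(20, 1, ch.GeneratorParams(mortality_rate=1.5))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_structural_invariants_any_seed(self, seed):
        """FSS/mortality exclusivity and GCS additivity hold for any seed."""
        bundle = ch.generate_cohort(25, seed=seed)
        assert_record_invariants(bundle.records)


class TestSplit:
    def test_388_split_leaves_88(self):
        bundle = ch.split_cohort(ch.generate_cohort(388, seed=1), 300)
        assert bundle.partitions["training"].size == 300
        assert bundle.partitions["testing"].size == 88

    def test_conservation_and_disjointness(self, bundle):
        train = bundle.partitions["training"].subject_ids
        test = bundle.partitions["testing"].subject_ids
        assert len(train) + len(test) == bundle.n
        assert not set(train) & set(test)
        assert sorted(train + test) == sorted(bundle.records["subject_id"])

    def test_site_balance_within_one_subject(self):
        bundle = ch.split_cohort(ch.generate_cohort(388, seed=1), 300)
        df = bundle.records
        train = set(bundle.partitions["training"].subject_ids)
        overall = 300 / 388
        for site, group in df.groupby("site"):
            in_train = group["subject_id"].isin(train).sum()
            # within one subject of the proportional allocation
            assert abs(in_train - overall * len(group)) <= 1.0

    def test_forced_balance_one_subject_per_site(self):
        b = make_bundle([{"site": "site_1"}, {"site": "site_2"}])
        split = ch.split_cohort(b, 1)
        sites = {p: set(split.subject_frame(p)["site"])
                 for p in ("training", "testing")}
        assert sites["training"] != sites["testing"]
        assert len(sites["training"]) == len(sites["testing"]) == 1

    def test_known_fss_ids_match_records(self, bundle):
        known = set(bundle.records.loc[bundle.records["fss_total"].notna(),
                                       "subject_id"])
        for spec in bundle.partitions.values():
            assert set(spec.known_fss_ids) == known & set(spec.subject_ids)

    def test_train_size_too_large_rejected(self, bundle):
        with pytest.raises(ParameterError):
            ch.split_cohort(bundle, bundle.n)


class TestInjectInconsistencies:
    def test_rate_zero_is_identity(self, bundle):
        out = ch.inject_inconsistencies(bundle, 0.0, seed=4)
        assert out.records.equals(bundle.records)
        assert out.metadata["inconsistent_ids"] == []

    def test_single_record_alteration(self):
        b = make_bundle([{"hosp_los_days": 8, "icp_start_days": 1,
                          "icp_stop_days": 3} for _ in range(1)])
        out = ch.inject_inconsistencies(b, 1.0, seed=0)
        rec = out.records.iloc[0]
        assert rec["icp_start_days"] == 9
        assert rec["icp_stop_days"] == 12
        assert out.metadata["inconsistent_ids"] == ["S0001"]

    def test_rate_reproducible_and_binomially_plausible(self):
        bundle = ch.generate_cohort(100, seed=21)
        a = ch.inject_inconsistencies(bundle, 0.1, seed=9)
        b = ch.inject_inconsistencies(bundle, 0.1, seed=9)
        assert a.metadata["inconsistent_ids"] == b.metadata["inconsistent_ids"]
        count = len(a.metadata["inconsistent_ids"])
        assert abs(count - 10) <= 3 * np.sqrt(100 * 0.1 * 0.9)

    def test_bad_rate_rejected(self, bundle):
        with pytest.raises(ParameterError):
            ch.inject_inconsistencies(bundle, 1.2, seed=0)


class TestRoundTrip:
    def test_write_read_identity(self, bundle, tmp_path):
        ch.write_cohort(bundle, tmp_path / "c")
        again = ch.read_cohort(tmp_path / "c")
        assert bundle.equals(again)

    def test_participant_view_withholds_test_labels(self, bundle, tmp_path):
        dest = ch.write_cohort(bundle, tmp_path / "p", participant_view=True)
        assert not (dest / "testing_labels.csv").exists()
        testing = pd.read_csv(dest / "testing.csv")
        for col in ("mortality", "fss_total", "disposition"):
            assert col not in testing.columns
        training = pd.read_csv(dest / "training.csv")
        assert {"mortality", "fss_total"} <= set(training.columns)

    def test_out_of_range_fss_rejected_by_name(self, bundle, tmp_path):
        dest = ch.write_cohort(bundle, tmp_path / "bad")
        path = dest / "training.csv"
        df = pd.read_csv(path, dtype="string")
        df.loc[df["fss_total"].notna().idxmax(), "fss_total"] = "31"
        df.to_csv(path, index=False)
        with pytest.raises(FormatError, match="fss_total"):
            ch.read_cohort(dest)

    def test_dictionary_label_maps_total_over_range(self, bundle):
        motor = bundle.dictionary["gcs_motor_ed"]
        assert motor.label_map[1] == "no response/flaccid"
        assert motor.label_map[2] == "abnormal extension to pain"
        assert set(motor.label_map) == set(range(1, 7))
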