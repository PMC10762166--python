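"""Competition ranking, rank aggregation, prizes, and anonymization."""

import hashlib

import numpy as np
import pandas as pd
import pytest

import challenge_harness as ch
from challenge_harness.errors import ParameterError, RankingError
from challenge_harness.fixtures import (PRIZE_MAP, reference_prize_table)
from challenge_harness.ranking import STATISTICS


def brute_force_ranks(values, higher_is_better=False):
    """Independent definition: rank_i = 1 + #{j : v_j strictly better}."""
    out = []
    for v in values:
        better = sum(1 for w in values
                     if (w > v if higher_is_better else w < v))
        out.append(1 + better)
    return out


class TestRankWithTies:
    def test_three_way_tie_for_second(self):
        # six values, three-way tie for second place -> (1,2,2,2,5,6)
        ranks = ch.rank_with_ties([1.0, 2.0, 2.0, 2.0, 3.0, 4.0])
        assert list(ranks) == [1, 2, 2, 2, 5, 6]

    def test_all_equal_all_rank_one(self):
        assert list(ch.rank_with_ties([5, 5, 5, 5])) == [1, 1, 1, 1]

    def test_direction(self):
        assert list(ch.rank_with_ties([0.9, 0.1], higher_is_better=True)) == [1, 2]
        assert list(ch.rank_with_ties([0.9, 0.1])) == [2, 1]

    def test_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(1, 25))
            # coarse grid so ties are common
            values = rng.integers(0, 6, size=n).astype(float)
            for hib in (False, True):
                assert list(ch.rank_with_ties(values, hib)) == \
                    brute_force_ranks(values, hib)

    def test_empty_and_missing_rejected(self):
        with pytest.raises(ParameterError):
            ch.rank_with_ties([])
        with pytest.raises(ParameterError):
            ch.rank_with_ties([1.0, float("nan")])


def stats_rows(participant, values):
    """values: dict (outcome, partition, statistic) -> (mean, sd)."""
    rows = []
    for (outcome, partition, statistic), (mean, sd) in values.items():
        rows.append({"participant": participant, "outcome": outcome,
                     "partition": partition, "statistic": statistic,
                     "mean": mean, "sd": sd})
    return rows


def full_table(per_participant):
    """per_participant: {name: {(stat): (mean, sd)}} over all 6 cells."""
    rows = []
    for name, cells in per_participant.items():
        rows += stats_rows(name, cells)
    return ch.statistic_table(rows)


def uniform_cells(mse=4.0, mcc=0.5, f1=0.5, sd=0.0):
    cells = {}
    for stat, (outcome, _) in STATISTICS.items():
        mean = {"MSE": mse, "MCC": mcc, "F1": f1}[stat]
        for part in ("training", "testing"):
            cells[(outcome, part, stat)] = (mean, sd)
    return cells


class TestOutcomeRank:
    def test_single_participant_rank_equals_statistic_count(self):
        table = full_table({"solo": uniform_cells()})
        # mortality has two statistics, FSS one; all ranks are 1
        assert ch.outcome_rank(table, "solo", "mortality", "testing") == 2.0
        assert ch.outcome_rank(table, "solo", "FSS", "testing") == 1.0

    def test_hand_worked_three_participants(self):
        # FSS/testing MSE: means 4, 2, 4 -> mean-ranks 2, 1, 2
        # SDs 0, 0, 1 -> SD-ranks 1, 1, 3; average ranks 1.5, 1.0, 2.5
        noisy_c = uniform_cells(mse=4.0)
        noisy_c[("FSS", "testing", "MSE")] = (4.0, 1.0)
        table = full_table({
            "A": uniform_cells(mse=4.0),
            "B": uniform_cells(mse=2.0),
            "C": noisy_c,
        })
        assert ch.outcome_rank(table, "A", "FSS", "testing") == 1.5
        assert ch.outcome_rank(table, "B", "FSS", "testing") == 1.0
        assert ch.outcome_rank(table, "C", "FSS", "testing") == 2.5

    def test_identical_participants_share_outcome_ranks(self):
        table = full_table({"A": uniform_cells(), "B": uniform_cells()})
        for outcome in ("FSS", "mortality"):
            assert ch.outcome_rank(table, "A", outcome, "training") == \
                ch.outcome_rank(table, "B", outcome, "training")

    def test_missing_rows_rejected(self):
        rows = stats_rows("A", {("FSS", "testing", "MSE"): (1.0, 0.0)})
        with pytest.raises(RankingError, match="gaps"):
            ch.outcome_rank(ch.statistic_table(rows), "A", "FSS", "testing")


def brute_force_overall(table: pd.DataFrame) -> dict[str, float]:
    """Rebuild every rank from the raw statistics with plain loops."""
    participants = sorted(table["participant"].unique())
    totals = dict.fromkeys(participants, 0.0)
    for stat, (outcome, hib) in STATISTICS.items():
        for part in ("training", "testing"):
            sub = table[(table["outcome"] == outcome)
                        & (table["partition"] == part)
                        & (table["statistic"] == stat)]
            sub = sub.set_index("participant").loc[participants]
            mr = brute_force_ranks(sub["mean"].tolist(), hib)
            sr = brute_force_ranks(sub["sd"].tolist(), False)
            for p, a, b in zip(participants, mr, sr):
                totals[p] += (a + b) / 2
    ranks = brute_force_ranks([totals[p] for p in participants])
    return dict(zip(participants, ranks))


class TestOverallRank:
    def test_dominant_participant_ranks_first(self):
        table = full_table({
            "champ": uniform_cells(mse=1.0, mcc=0.9, f1=0.9),
            "other": uniform_cells(mse=9.0, mcc=0.1, f1=0.1),
        })
        out = ch.overall_rank(table)
        assert out.set_index("participant").loc["champ", "overall_rank"] == 1

    def test_permutation_invariance(self):
        table = full_table({
            "a": uniform_cells(mse=1.0), "b": uniform_cells(mse=2.0),
            "c": uniform_cells(mse=3.0),
        })
        shuffled = table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        left = ch.overall_rank(table).set_index("participant")
        right = ch.overall_rank(shuffled).set_index("participant")
        pd.testing.assert_frame_equal(left.sort_index(), right.sort_index())

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(41)
        for _ in range(25):
            participants = [f"p{i}" for i in range(int(rng.integers(2, 8)))]
            spec = {}
            for p in participants:
                cells = {}
                for stat, (outcome, _) in STATISTICS.items():
                    for part in ("training", "testing"):
                        cells[(outcome, part, stat)] = (
                            float(rng.integers(0, 5)),  # coarse -> ties
                            float(rng.integers(0, 3)))
                spec[p] = cells
            table = full_table(spec)
            got = ch.overall_rank(table).set_index("participant")["overall_rank"]
            expected = brute_force_overall(table)
            assert got.to_dict() == expected

    def test_deterministic_sd_shares_rank_one(self):
        table = full_table({
            "det1": uniform_cells(sd=0.0), "det2": uniform_cells(sd=0.0),
            "noisy": uniform_cells(sd=0.5),
        })
        from challenge_harness.ranking import _average_ranks
        avg = _average_ranks(table)
        det = avg[avg["participant"].isin(["det1", "det2"])]
        assert (det["sd_rank"] == 1).all()
        assert (avg.loc[avg["participant"] == "noisy", "sd_rank"] == 3).all()

    def test_adding_strictly_worst_preserves_order(self):
        base = {
            "a": uniform_cells(mse=1.0, mcc=0.8, f1=0.8),
            "b": uniform_cells(mse=2.0, mcc=0.6, f1=0.6),
        }
        before = ch.overall_rank(full_table(base)).set_index("participant")
        worst = dict(base, zz=uniform_cells(mse=99.0, mcc=-0.9, f1=0.0, sd=9.0))
        after = ch.overall_rank(full_table(worst)).set_index("participant")
        ordered_before = before["overall_rank"].loc[["a", "b"]].tolist()
        ordered_after = after["overall_rank"].loc[["a", "b"]].tolist()
        assert ordered_before == ordered_after
        assert after.loc["zz", "overall_rank"] == 3


class TestPrizeRanks:
    def test_ineligible_third_place_scenario(self):
        # challenge ranks (1,2,3,4,4,4); the rank-3 participant ineligible
        table = reference_prize_table().head(6)
        assert table["overall_rank"].tolist() == [1, 2, 3, 4, 4, 4]
        out = ch.prize_ranks(table, PRIZE_MAP)
        assert out["prize_amount"].tolist() == [500.0, 250.0, 0.0, 125.0, 125.0, 125.0]
        assert pd.isna(out.loc[2, "prize_rank"])       # ineligible: no prize rank
        assert out.loc[3:, "prize_rank"].tolist() == [3, 3, 3]

    def test_full_reference_standing(self):
        out = ch.prize_ranks(reference_prize_table(), PRIZE_MAP)
        assert out["overall_rank"].tolist() == [1, 2, 3, 4, 4, 4, 7, 8, 9, 10]
        # ranks beyond the paid range win nothing
        assert (out.loc[6:, "prize_amount"] == 0).all()

    def test_no_ties_all_eligible_equals_challenge_ranks(self):
        table = pd.DataFrame({
            "participant": ["a", "b", "c"],
            "overall_total": [3.0, 1.0, 2.0],
            "eligible": [True, True, True],
        })
        table["overall_rank"] = ch.rank_with_ties(table["overall_total"])
        out = ch.prize_ranks(table, {1: 10, 2: 5, 3: 1})
        assert out["prize_rank"].tolist() == out["overall_rank"].tolist()

    def test_two_way_tie_for_first_both_paid(self):
        table = pd.DataFrame({
            "participant": ["a", "b", "c"],
            "overall_total": [1.0, 1.0, 2.0],
            "eligible": [True, True, True],
        })
        table["overall_rank"] = ch.rank_with_ties(table["overall_total"])
        out = ch.prize_ranks(table, {1: 100, 2: 50, 3: 25})
        assert out["prize_amount"].tolist() == [100.0, 100.0, 25.0]

    def test_prize_map_gap_is_error(self):
        table = pd.DataFrame({
            "participant": ["a", "b"], "overall_total": [1.0, 2.0],
            "eligible": [True, True],
        })
        table["overall_rank"] = ch.rank_with_ties(table["overall_total"])
        with pytest.raises(RankingError, match="rank 2"):
            ch.prize_ranks(table, {1: 100, 3: 25})

    def test_stable_under_removing_trailing_ineligible(self):
        table = reference_prize_table()
        trimmed = table[table["participant"] != "P12"].copy()
        full = ch.prize_ranks(table, PRIZE_MAP).set_index("participant")
        part = ch.prize_ranks(trimmed, PRIZE_MAP).set_index("participant")
        shared = part.index
        assert full.loc[shared, "prize_rank"].tolist() == \
            part["prize_rank"].tolist()


class TestAnonymize:
    def test_single_id(self):
        assert ch.anonymize(["someone"]) == {"someone": "P01"}

    def test_deterministic(self):
        ids = ["x", "y", "z"]
        assert ch.anonymize(ids) == ch.anonymize(ids)

    def test_order_matches_sorted_sha256_digests(self):
        # digests recomputed independently and frozen:
        # alice -> 2bd806..., carol -> 4c26d9..., bob -> 81b637...
        mapping = ch.anonymize(["alice", "bob", "carol"])
        assert mapping == {"alice": "P01", "carol": "P02", "bob": "P03"}
        digests = sorted(["alice", "bob", "carol"],
                         key=lambda u: hashlib.sha256(u.encode()).hexdigest())
        assert [mapping[u] for u in digests] == ["P01", "P02", "P03"]

    def test_injective_and_padded(self):
        mapping = ch.anonymize([f"user{i}" for i in range(12)])
        assert len(set(mapping.values())) == 12
        assert all(len(v) == 3 for v in mapping.values())   # P01..P12

    def test_duplicates_rejected(self):
        with pytest.raises(ParameterError):
            ch.anonymize(["a", "a"])
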