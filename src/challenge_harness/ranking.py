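"""Rank aggregation for the data challenge.

Submissions are ranked on accuracy (MSE for FSS; MCC and F1 for mortality)
and reproducibility (the standard deviation of each statistic over repeated
assessments).  All ranking uses competition ("min") ranking: tied values
share the smallest rank of their tie group and subsequent ranks skip, so a
three-way tie for second among six values yields ranks (1, 2, 2, 2, 5, 6).

The aggregation arithmetic:

1. For each (outcome, partition, statistic), rank the participants' mean
   values (MSE ascending; MCC/F1 descending) and, separately, their SDs
   (always ascending — deterministic submissions share SD-rank 1).
2. The statistic's average rank is (mean-rank + SD-rank) / 2.
3. The outcome rank for a (participant, outcome, partition) is the sum of
   the average ranks over that outcome's statistics.
4. The overall total is the sum of average ranks over every
   (outcome, partition, statistic); overall challenge ranks are the
   min-method ranks of these totals.
5. Prize ranks re-rank only prize-eligible participants; every participant
   tied at a prize rank receives the amount mapped to that rank.

Model parsimony (the manifest's declared predictor count) is available as
an optional ascending tie-break statistic, disabled by default.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ParameterError, RankingError

__all__ = [
    "STATISTICS", "rank_with_ties", "statistic_table", "outcome_rank",
    "overall_rank", "prize_ranks", "anonymize",
]

#: statistic -> (outcome, higher_is_better)
STATISTICS = {
    "MSE": ("FSS", False),
    "MCC": ("mortality", True),
    "F1": ("mortality", True),
}
PARTITIONS = ("training", "testing")


def rank_with_ties(values: Sequence[float], higher_is_better: bool = False) -> np.ndarray:
    """Competition (min-method) ranks: rank_i = 1 + #{j : v_j strictly better}."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ParameterError("cannot rank an empty vector")
    if np.isnan(arr).any():
        raise ParameterError("cannot rank missing values")
    oriented = -arr if higher_is_better else arr
    return rankdata(oriented, method="min").astype(int)


def statistic_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Assemble and check a long-form statistic table.

    Each row: participant, outcome, partition, statistic, mean, sd.
    Exactly one row per (participant, outcome, partition, statistic).
    """
    df = pd.DataFrame(list(rows))
    required = {"participant", "outcome", "partition", "statistic", "mean", "sd"}
    missing = required - set(df.columns)
    if missing:
        raise RankingError(f"statistic table missing columns: {sorted(missing)}")
    key = ["participant", "outcome", "partition", "statistic"]
    if df.duplicated(key).any():
        dupes = df.loc[df.duplicated(key), key].to_dict("records")
        raise RankingError(f"duplicate statistic rows: {dupes}")
    return df


def _check_complete(stats: pd.DataFrame) -> list[str]:
    """Every participant needs every (outcome, partition, statistic) row."""
    participants = sorted(stats["participant"].unique())
    gaps = []
    for p in participants:
        sub = stats[stats["participant"] == p]
        have = set(zip(sub["outcome"], sub["partition"], sub["statistic"]))
        for stat, (outcome, _) in STATISTICS.items():
            for part in PARTITIONS:
                if (outcome, part, stat) not in have:
                    gaps.append(f"{p}: {outcome}/{part}/{stat}")
    if gaps:
        raise RankingError(f"statistic table has gaps: {gaps}")
    return participants


def _average_ranks(stats: pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, outcome, partition, statistic) average rank."""
    participants = _check_complete(stats)
    indexed = stats.set_index(
        ["outcome", "partition", "statistic", "participant"]).sort_index()
    out = []
    for stat, (outcome, higher_better) in STATISTICS.items():
        for part in PARTITIONS:
            block = indexed.loc[(outcome, part, stat)].loc[participants]
            mean_ranks = rank_with_ties(block["mean"].to_numpy(), higher_better)
            sd_ranks = rank_with_ties(block["sd"].to_numpy(), higher_is_better=False)
            for p, mr, sr in zip(participants, mean_ranks, sd_ranks):
                out.append({
                    "participant": p, "outcome": outcome, "partition": part,
                    "statistic": stat, "mean_rank": int(mr), "sd_rank": int(sr),
                    "average_rank": (mr + sr) / 2,
                })
    return pd.DataFrame(out)


def outcome_rank(stats: pd.DataFrame, participant: str, outcome: str,
                 partition: str) -> float:
    """Sum of average ranks over the statistics of one outcome/partition."""
    avg = _average_ranks(stats)
    sub = avg[(avg["participant"] == participant) & (avg["outcome"] == outcome)
              & (avg["partition"] == partition)]
    if sub.empty:
        raise RankingError(
            f"no rows for {participant}/{outcome}/{partition}")
    return float(sub["average_rank"].sum())


def overall_rank(stats: pd.DataFrame,
                 disqualified: Sequence[str] = (),
                 anonymous_ids: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Full rank table: outcome ranks, overall totals, overall ranks.

    ``disqualified`` participants keep their rows and overall ranks but are
    flagged ineligible for prize ranking.  Participants missing one model
    are rejected by the completeness check.
    """
    avg = _average_ranks(stats)
    participants = sorted(avg["participant"].unique())

    per_outcome = (avg.groupby(["participant", "outcome", "partition"])["average_rank"]
                   .sum().rename("outcome_rank").reset_index())
    wide = per_outcome.pivot_table(index="participant",
                                   columns=["outcome", "partition"],
                                   values="outcome_rank")
    wide.columns = [f"outcome_rank_{o}_{p}" for o, p in wide.columns]
    wide = wide.loc[participants]
    wide["overall_total"] = wide.sum(axis=1)
    wide["overall_rank"] = rank_with_ties(wide["overall_total"].to_numpy(),
                                          higher_is_better=False)
    wide["eligible"] = [p not in set(disqualified) for p in wide.index]
    if anonymous_ids is not None:
        missing = [p for p in participants if p not in anonymous_ids]
        if missing:
            raise RankingError(f"anonymous ids missing for: {missing}")
        wide["anonymous_id"] = [anonymous_ids[p] for p in wide.index]
    table = wide.reset_index().sort_values(
        ["overall_rank", "participant"], ignore_index=True)
    return table


def prize_ranks(rank_table: pd.DataFrame,
                prize_map: Mapping[int, float]) -> pd.DataFrame:
    """Re-rank prize-eligible participants and assign amounts.

    Ineligible participants are removed from the prize competition (their
    rows remain, with no prize rank); ranks are recomputed min-method over
    the eligible totals; every participant tied at a prize rank receives
    the amount for that rank.  Ranks beyond the largest mapped rank win
    nothing; a mapped-range gap that a participant lands in is an error.
    """
    table = rank_table.copy()
    prize_map = {int(k): v for k, v in prize_map.items()}
    eligible = table[table["eligible"]]
    table["prize_rank"] = pd.array([None] * len(table), dtype="Int64")
    table["prize_amount"] = 0.0
    if eligible.empty:
        return table
    ranks = rank_with_ties(eligible["overall_total"].to_numpy(),
                           higher_is_better=False)
    table.loc[eligible.index, "prize_rank"] = ranks
    max_paid = max(prize_map) if prize_map else 0
    amounts = []
    for r in ranks:
        if r in prize_map:
            amounts.append(float(prize_map[r]))
        elif r <= max_paid:
            raise RankingError(f"prize map has no amount for needed rank {r}")
        else:
            amounts.append(0.0)
    table.loc[eligible.index, "prize_amount"] = amounts
    return table


def anonymize(user_ids: Sequence[str]) -> dict[str, str]:
    """Assign anonymous identifiers P01, P02, ... by sorted sha256 digest.

    Each user id is hashed (sha256 of its UTF-8 bytes); digests are sorted
    lexicographically and identifiers assigned in that order, zero-padded
    to at least two digits.  Deterministic and injective.
    """
    ids = list(user_ids)
    if len(ids) != len(set(ids)):
        raise ParameterError("duplicate user ids cannot be anonymized")
    digests = {u: hashlib.sha256(u.encode("utf-8")).hexdigest() for u in ids}
    ordered = sorted(ids, key=digests.__getitem__)
    width = max(2, len(str(len(ids))))
    return {u: f"P{i + 1:0{width}d}" for i, u in enumerate(ordered)}
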