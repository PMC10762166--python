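"""Worked-example fixtures from a completed pediatric-TBI data challenge.

Small, text-only reference inputs used by the examples, the tests, and
the acceptance script:

* a participant registry (27 registrants, 11 finalists, each finalist's
  language and two modeling approaches);
* the final standing of the top 10 participants (rank totals reproducing
  the published challenge ranks 1, 2, 3, 4, 4, 4, 7, 8, 9, 10, with the
  third-place participant ineligible for prize money for administrative
  reasons) and the prize schedule $500 / $250 / $125.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .submission import Manifest, ModelInfo

__all__ = ["load_reference_registry", "reference_prize_table", "PRIZE_MAP"]

PRIZE_MAP = {1: 500.0, 2: 250.0, 3: 125.0}

#: (participant, rank total, prize-eligible) — totals chosen to reproduce
#: the published challenge ranks, including the three-way tie for fourth.
_FINAL_STANDING = [
    ("P07", 10.0, True),
    ("P24", 12.0, True),
    ("P22", 14.0, False),   # ineligible for prize money
    ("P03", 16.0, True),
    ("P11", 16.0, True),
    ("P26", 16.0, True),
    ("P14", 18.0, True),
    ("P15", 20.0, True),
    ("P20", 22.0, True),
    ("P12", 24.0, True),
]


def load_reference_registry() -> tuple[list[str], list[Manifest]]:
    """Registered participant ids and one manifest per finalist."""
    with resources.files("challenge_harness.data").joinpath(
            "reference_registry.csv").open("r") as fh:
        df = pd.read_csv(fh, dtype="string").fillna("")
    registered = df["participant_id"].tolist()
    manifests = []
    for row in df[df["final"] == "1"].itertuples(index=False):
        models = (
            ModelInfo("FSS", row.fss_approach, row.language, 0),
            ModelInfo("mortality", row.mortality_approach, row.language, 0),
        )
        manifests.append(Manifest(row.participant_id,
                                  "see challenge records", "final", models))
    return registered, manifests


def reference_prize_table() -> pd.DataFrame:
    """Rank-table fixture for the final standing (top 10 participants)."""
    from .ranking import rank_with_ties

    df = pd.DataFrame(_FINAL_STANDING,
                      columns=["participant", "overall_total", "eligible"])
    df["overall_rank"] = rank_with_ties(df["overall_total"].to_numpy())
    return df
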