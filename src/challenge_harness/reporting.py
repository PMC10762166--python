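"""Challenge summaries, data-consistency QC, and leaderboard rendering."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cohort import CohortBundle
from .errors import RankingError
from .submission import Manifest

__all__ = [
    "ChallengeSummary", "summarize_challenge", "ConsistencyFinding",
    "check_consistency", "render_leaderboard", "leaderboard_tsv",
    "advisory_flags", "FORBIDDEN_PREDICTORS",
]

#: outcome -> predictor terms that must not appear in that model.  FSS is
#: defined only for survivors, so its presence (or that of discharge
#: disposition, collected simultaneously) leaks the mortality outcome.
FORBIDDEN_PREDICTORS = {"mortality": ("fss",), "FSS": ("disposition",)}


def advisory_flags(manifests: Sequence[Manifest]) -> list[str]:
    """Scan manifests for declared use of forbidden predictors.

    Advisory only: it inspects what participants *declared* (approach and
    summary text), not their code.  Disqualification remains an
    administrator decision; these flags point at submissions worth a
    manual code review.
    """
    flags = []
    for m in manifests:
        for model in m.models:
            text = f"{model.approach} {model.summary}".lower()
            for term in FORBIDDEN_PREDICTORS.get(model.outcome, ()):
                if term in text:
                    flags.append(
                        f"{m.participant_id}: {model.outcome} model text "
                        f"mentions forbidden predictor {term!r}")
    return flags


@dataclass
class ChallengeSummary:
    """Registration/submission tallies for one challenge."""

    registered: int
    final_submissions: int
    completion_rate: float | None      # percent, one decimal; None if 0 registered
    language_tally: dict[str, int]     # per finalist participant
    approach_tally: dict[str, int]     # over all submitted models (2 per finalist)

    @property
    def total_models(self) -> int:
        return sum(self.approach_tally.values())

    def to_markdown(self) -> str:
        rate = "undefined" if self.completion_rate is None else f"{self.completion_rate}%"
        lines = [
            "# Challenge summary", "",
            f"- Registered participants: {self.registered}",
            f"- Final submissions: {self.final_submissions}",
            f"- Completion rate: {rate}",
            f"- Submitted models: {self.total_models}", "",
            "## Languages (finalists)", "",
        ]
        for lang, k in sorted(self.language_tally.items(), key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"- {lang}: {k}")
        lines += ["", "## Modeling approaches (all models)", ""]
        for app, k in sorted(self.approach_tally.items(), key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"- {app}: {k}")
        return "\n".join(lines) + "\n"


def summarize_challenge(registered_ids: Sequence[str],
                        manifests: Sequence[Manifest]) -> ChallengeSummary:
    """Tally registrations, finalists, languages, and modeling approaches.

    The completion rate is 100 * finalists / registered, rounded to one
    decimal; with zero registrations the rate is reported as undefined
    rather than raising.
    """
    registered = len(registered_ids)
    final = len(manifests)
    rate = None if registered == 0 else round(100.0 * final / registered, 1)

    language_tally: dict[str, int] = {}
    approach_tally: dict[str, int] = {}
    for m in manifests:
        langs = {model.language for model in m.models}
        # a participant mixing languages counts once per language used
        for lang in sorted(langs):
            language_tally[lang] = language_tally.get(lang, 0) + 1
        for model in m.models:
            approach_tally[model.approach] = approach_tally.get(model.approach, 0) + 1
    return ChallengeSummary(registered, final, rate, language_tally, approach_tally)


@dataclass(frozen=True)
class ConsistencyFinding:
    """An ICP-monitor interval extending past hospital discharge."""

    subject_id: str
    rule: str            # currently always ICP_AFTER_DISCHARGE
    hosp_los_days: int
    icp_start_days: int | None
    icp_stop_days: int | None


def check_consistency(bundle: CohortBundle) -> list[ConsistencyFinding]:
    """Flag records whose ICP monitoring starts or stops after discharge.

    A finding is emitted iff a present icp_start_days or icp_stop_days
    strictly exceeds hosp_los_days; records with absent ICP fields are
    never flagged.
    """
    records = bundle.records
    findings = []
    for row in records.itertuples(index=False):
        los = row.hosp_los_days
        start, stop = row.icp_start_days, row.icp_stop_days
        start_bad = pd.notna(start) and start > los
        stop_bad = pd.notna(stop) and stop > los
        if start_bad or stop_bad:
            findings.append(ConsistencyFinding(
                row.subject_id, "ICP_AFTER_DISCHARGE", int(los),
                None if pd.isna(start) else int(start),
                None if pd.isna(stop) else int(stop)))
    return findings


_LEADERBOARD_COLUMNS = [
    ("anonymous_id", "Participant"),
    ("outcome_rank_FSS_training", "FSS rank (train)"),
    ("outcome_rank_FSS_testing", "FSS rank (test)"),
    ("outcome_rank_mortality_training", "Mortality rank (train)"),
    ("outcome_rank_mortality_testing", "Mortality rank (test)"),
    ("overall_total", "Rank total"),
    ("overall_rank", "Challenge rank"),
    ("prize_rank", "Prize rank"),
    ("prize_amount", "Prize"),
]


def _leaderboard_frame(rank_table: pd.DataFrame,
                       anonymization: Mapping[str, str]) -> pd.DataFrame:
    if anonymization is None:
        raise RankingError("anonymization map required: real ids must never render")
    missing = [p for p in rank_table["participant"] if p not in anonymization]
    if missing:
        raise RankingError(f"anonymization map missing participants: {missing}")
    table = rank_table.copy()
    table["anonymous_id"] = [anonymization[p] for p in table["participant"]]
    table = table.sort_values(["overall_rank", "anonymous_id"], ignore_index=True)
    cols = [c for c, _ in _LEADERBOARD_COLUMNS if c in table.columns]
    return table[cols]


def _format_cell(col: str, value) -> str:
    if pd.isna(value):
        return "—" if col == "prize_rank" else ""
    if col == "prize_amount":
        return f"${value:,.0f}" if value else ""
    if col in ("overall_rank", "prize_rank"):
        return str(int(value))
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def render_leaderboard(rank_table: pd.DataFrame,
                       anonymization: Mapping[str, str]) -> str:
    """Render the leaderboard as Markdown, anonymous ids only.

    Rows are ordered by overall challenge rank, ties broken by anonymous
    id for determinism.  An empty rank table renders an empty (but valid)
    document.
    """
    frame = _leaderboard_frame(rank_table, anonymization)
    headers = [h for c, h in _LEADERBOARD_COLUMNS if c in frame.columns]
    lines = ["# Leaderboard", "",
             "| " + " | ".join(headers) + " |",
             "|" + "|".join(["---"] * len(headers)) + "|"]
    for row in frame.itertuples(index=False):
        cells = [_format_cell(c, v) for (c, _), v
                 in zip([(c, h) for c, h in _LEADERBOARD_COLUMNS if c in frame.columns],
                        row)]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def leaderboard_tsv(rank_table: pd.DataFrame,
                    anonymization: Mapping[str, str],
                    path: str | Path | None = None) -> str:
    """Leaderboard as TSV (same ordering/columns as the Markdown view)."""
    frame = _leaderboard_frame(rank_table, anonymization)
    text = frame.to_csv(sep="\t", index=False, lineterminator="\n")
    if path is not None:
        Path(path).write_text(text)
    return text
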