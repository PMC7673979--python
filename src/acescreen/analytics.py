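"""Population-level conversation analytics.

Aggregates session logs (JSONL, one record per turn) into the metrics a
public-health team monitors: per-intent popularity (sessions matched and
total uses), exit rates, mismatch percentage, mean response time,
interactions per session, and the frequency table of conversational paths.
`suggest_route` turns cohort behavior into guidance: the modal route of
users matching on coarse age and ethnicity group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

REQUIRED_KEYS = {"session_id", "ts", "utterance", "intent", "latency", "mismatch"}


@dataclass
class TurnRecord:
    timestamp: float
    utterance: str
    intent: Optional[str]
    latency: float
    mismatch: bool


@dataclass
class SessionLog:
    session_id: str
    profile: dict
    turns: list[TurnRecord] = field(default_factory=list)

    @property
    def matched_sequence(self) -> tuple[str, ...]:
        return tuple(t.intent for t in self.turns if t.intent)

    @property
    def exit_intent(self) -> Optional[str]:
        """Last matched intent of the session — the artifact's definition
        of where the user exited the conversation."""
        seq = self.matched_sequence
        return seq[-1] if seq else None


def parse_records(records: Sequence[dict]) -> tuple[list[SessionLog], int]:
    """Group flat turn records into per-session logs.

    Malformed records (missing keys, negative latency, unparsable types)
    are skipped and tallied rather than aborting the aggregation.
    """
    sessions: dict[str, SessionLog] = {}
    skipped = 0
    for rec in records:
        if not isinstance(rec, dict) or not REQUIRED_KEYS <= set(rec):
            skipped += 1
            continue
        try:
            turn = TurnRecord(
                timestamp=float(rec["ts"]),
                utterance=str(rec["utterance"]),
                intent=rec["intent"] if rec["intent"] else None,
                latency=float(rec["latency"]),
                mismatch=bool(rec["mismatch"]),
            )
        except (TypeError, ValueError):
            skipped += 1
            continue
        if turn.latency < 0:
            skipped += 1
            continue
        sid = str(rec["session_id"])
        log = sessions.get(sid)
        if log is None:
            log = SessionLog(
                session_id=sid,
                profile={
                    "age_group": rec.get("age_group", "unknown"),
                    "ethnicity_group": rec.get("ethnicity_group", "unknown"),
                    "zip": rec.get("zip", ""),
                },
            )
            sessions[sid] = log
        log.turns.append(turn)
    logs = list(sessions.values())
    for log in logs:
        log.turns.sort(key=lambda t: t.timestamp)
    logs.sort(key=lambda l: l.session_id)
    return logs, skipped


def load_session_logs(path: str | Path) -> tuple[list[SessionLog], int]:
    records = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError:
                skipped += 1
    logs, bad = parse_records(records)
    return logs, skipped + bad


# ---------------------------------------------------------------------- #
# metrics

def intent_popularity(logs: Sequence[SessionLog]) -> dict[str, dict[str, int]]:
    """Per intent: number of sessions matching it and total uses."""
    out: dict[str, dict[str, int]] = {}
    for log in logs:
        seen_in_session = set()
        for intent in log.matched_sequence:
            entry = out.setdefault(intent, {"sessions": 0, "uses": 0})
            entry["uses"] += 1
            if intent not in seen_in_session:
                entry["sessions"] += 1
                seen_in_session.add(intent)
    return dict(sorted(out.items()))


def exit_rate(logs: Sequence[SessionLog], intent: str) -> Optional[float]:
    """Percentage of sessions matching ``intent`` that ended in it.

    ``None`` when the intent was never matched (the rate is undefined).
    """
    matched = [log for log in logs if intent in log.matched_sequence]
    if not matched:
        return None
    final = sum(1 for log in matched if log.exit_intent == intent)
    return 100.0 * final / len(matched)


def conversation_paths(logs: Sequence[SessionLog]) -> list[tuple[tuple[str, ...], int]]:
    """Distinct matched-intent sequences with session counts.

    Ordered by count descending, then lexicographic, so reports are
    stable. Path counts always sum to the number of sessions.
    """
    counts: dict[tuple[str, ...], int] = {}
    for log in logs:
        seq = log.matched_sequence
        counts[seq] = counts.get(seq, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class AggregateReport:
    total_sessions: int
    total_turns: int
    mismatch_pct: float
    mean_latency: float
    interactions_per_session: dict[str, int]
    intents: dict[str, dict]
    paths: list[tuple[tuple[str, ...], int]]
    skipped_records: int = 0

    def to_dict(self) -> dict:
        return {
            "total_sessions": self.total_sessions,
            "total_turns": self.total_turns,
            "mismatch_pct": round(self.mismatch_pct, 1),
            "mismatch_pct_raw": self.mismatch_pct,
            "mean_latency": self.mean_latency,
            "interactions_per_session": self.interactions_per_session,
            "intents": self.intents,
            "paths": [
                {"path": list(path), "sessions": count} for path, count in self.paths
            ],
            "skipped_records": self.skipped_records,
        }

    def to_markdown(self) -> str:
        lines = [
            "# Conversation analytics",
            "",
            f"- sessions: {self.total_sessions}",
            f"- turns: {self.total_turns}",
            f"- mismatch rate: {self.mismatch_pct:.1f} %",
            f"- mean response time: {self.mean_latency:.3f} s",
            "",
            "## Intent popularity",
            "",
            "| intent | sessions matched | total uses | exit rate |",
            "| --- | --- | --- | --- |",
        ]
        for name, row in self.intents.items():
            exit_txt = (
                f"{row['exit_pct']:.1f} %" if row["exit_pct"] is not None else "n/a"
            )
            lines.append(
                f"| {name} | {row['sessions']} | {row['uses']} | {exit_txt} |"
            )
        lines += ["", "## Conversational paths", ""]
        for path, count in self.paths:
            label = " -> ".join(path) if path else "(no matched intent)"
            lines.append(f"- {label}: {count}")
        return "\n".join(lines) + "\n"


def summarize(logs: Sequence[SessionLog], skipped: int = 0) -> AggregateReport:
    """Compose every population metric into one report."""
    total_sessions = len(logs)
    turns = [t for log in logs for t in log.turns]
    total_turns = len(turns)
    mismatch_pct = (
        100.0 * sum(1 for t in turns if t.mismatch) / total_turns if total_turns else 0.0
    )
    mean_latency = (
        sum(t.latency for t in turns) / total_turns if total_turns else 0.0
    )
    interactions: dict[str, int] = {}
    for log in logs:
        key = str(len(log.turns))
        interactions[key] = interactions.get(key, 0) + 1
    intents = {}
    for name, row in intent_popularity(logs).items():
        intents[name] = dict(row, exit_pct=exit_rate(logs, name))
    return AggregateReport(
        total_sessions=total_sessions,
        total_turns=total_turns,
        mismatch_pct=mismatch_pct,
        mean_latency=mean_latency,
        interactions_per_session=dict(sorted(interactions.items())),
        intents=intents,
        paths=conversation_paths(logs),
        skipped_records=skipped,
    )


def suggest_route(
    logs: Sequence[SessionLog], profile: dict
) -> Optional[tuple[str, ...]]:
    """Modal conversational route of the cohort matching ``profile``.

    Similarity is exact match on coarse age group and ethnicity group.
    Ties break toward the shortest path, then lexicographic; ``None``
    when no session matches.
    """
    cohort = [
        log
        for log in logs
        if log.profile.get("age_group") == profile.get("age_group")
        and log.profile.get("ethnicity_group") == profile.get("ethnicity_group")
    ]
    if not cohort:
        return None
    counts: dict[tuple[str, ...], int] = {}
    for log in cohort:
        seq = log.matched_sequence
        counts[seq] = counts.get(seq, 0) + 1
    return min(counts.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0]))[0]
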