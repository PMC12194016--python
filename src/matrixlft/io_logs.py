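"""Data model and I/O for construction-based matrix test event logs.

A construction-based figural matrix test (e.g., DESIGMA) presents a 3x3
matrix whose cells follow logical rules (addition, subtraction, ...).  The
participant composes the solution by clicking symbols in a construction
kit; every symbol belongs to a symbol group, and each symbol group is
associated with exactly one rule.  The raw material for all downstream
analysis is the timestamped click stream per participant and item.

This module defines the validated in-memory containers (:class:`ItemSpec`,
:class:`ItemLog`, :class:`SessionLog`), the on-disk formats (event logs as
CSV or JSON-lines, item banks as JSON) and the replay semantics that turn
a raw click stream into a final symbol selection: a click on an unselected
symbol selects it, a second click deselects it (toggle semantics).
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RuleSpec",
    "ItemSpec",
    "ClickEvent",
    "ItemLog",
    "SessionLog",
    "LogFormatError",
    "LogValidationError",
    "read_event_log",
    "write_event_log",
    "read_item_bank",
    "write_item_bank",
    "default_item_bank",
    "replay_selection",
]

EVENT_COLUMNS = ("participant_id", "item_id", "t", "kind", "symbol_id")
TERMINAL_KINDS = frozenset({"submit", "timeout"})
EVENT_KINDS = frozenset({"click"}) | TERMINAL_KINDS


class LogFormatError(ValueError):
    """Malformed on-disk input (unknown ids, bad columns, broken JSON)."""


class LogValidationError(ValueError):
    """Structurally valid input that violates a log invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RuleSpec:
    """One logical rule of an item, tied to a symbol group.

    ``n_required_clicks`` is the number of symbols of this rule's group
    that appear in the correct solution.
    """

    rule_id: str
    symbol_group: str
    n_required_clicks: int

    def __post_init__(self) -> None:
        if self.n_required_clicks < 1:
            raise LogValidationError(
                f"rule {self.rule_id!r}: n_required_clicks must be >= 1"
            )


@dataclass(frozen=True)
class ItemSpec:
    """Static description of one matrix item.

    ``position`` is the 1-based administration order in the test.  Items
    with a single rule carry no information about processing structure
    (no between-rule transition exists), so they are loaded but flagged
    as excluded from analysis via :attr:`analyzed`.
    """

    item_id: str
    position: int
    rules: tuple[RuleSpec, ...]
    solution: frozenset[str]
    time_limit: float = 90.0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise LogValidationError(f"item {self.item_id!r}: position must be >= 1")
        if len(self.rules) < 1:
            raise LogValidationError(f"item {self.item_id!r}: needs at least one rule")
        if self.time_limit <= 0:
            raise LogValidationError(f"item {self.item_id!r}: time_limit must be > 0")
        groups = [r.symbol_group for r in self.rules]
        if len(set(groups)) != len(groups):
            raise LogValidationError(
                f"item {self.item_id!r}: symbol groups must be distinct across rules"
            )
        by_rule: dict[str, int] = {r.rule_id: 0 for r in self.rules}
        for sym in self.solution:
            rule = self._rule_for_symbol(sym)
            if rule is None:
                raise LogFormatError(
                    f"item {self.item_id!r}: solution symbol {sym!r} not in any "
                    "rule's symbol group"
                )
            by_rule[rule.rule_id] += 1
        for r in self.rules:
            if by_rule[r.rule_id] != r.n_required_clicks:
                raise LogValidationError(
                    f"item {self.item_id!r}: rule {r.rule_id!r} declares "
                    f"{r.n_required_clicks} solution symbols but the solution "
                    f"contains {by_rule[r.rule_id]}"
                )

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def analyzed(self) -> bool:
        """Whether the item enters the analysis set (two or more rules)."""
        return self.n_rules >= 2

    def _rule_for_symbol(self, symbol_id: str) -> RuleSpec | None:
        group = symbol_group_of(symbol_id)
        for r in self.rules:
            if r.symbol_group == group:
                return r
        return None

    def rule_of(self, symbol_id: str) -> str:
        """Map a symbol id to its rule id, or raise ``LogFormatError``."""
        rule = self._rule_for_symbol(symbol_id)
        if rule is None:
            raise LogFormatError(
                f"item {self.item_id!r}: symbol {symbol_id!r} belongs to no rule"
            )
        return rule.rule_id


def symbol_group_of(symbol_id: str) -> str:
    """Symbol ids are ``"<group>:<index>"``; return the group part."""
    group, sep, _ = symbol_id.partition(":")
    if not sep or not group:
        raise LogFormatError(f"symbol id {symbol_id!r} is not of the form 'group:k'")
    return group


@dataclass(frozen=True)
class ClickEvent:
    """A single timestamped event within an item.

    ``t`` is seconds since item onset.  ``symbol_id`` and ``rule_id`` are
    present iff ``kind == "click"``.
    """

    t: float
    kind: str
    symbol_id: str | None = None
    rule_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise LogFormatError(f"unknown event kind {self.kind!r}")
        if self.t < 0:
            raise LogValidationError(f"event time {self.t} is negative")
        if (self.kind == "click") != (self.symbol_id is not None):
            raise LogValidationError(
                "symbol_id must be present exactly for click events"
            )

    @property
    def is_terminal(self) -> bool:
        return self.kind in TERMINAL_KINDS


@dataclass(frozen=True)
class ItemLog:
    """One participant's event stream on one item, fully validated."""

    item_id: str
    participant_id: str
    events: tuple[ClickEvent, ...]
    final_selection: frozenset[str]
    correct: bool

    @property
    def clicks(self) -> tuple[ClickEvent, ...]:
        return tuple(e for e in self.events if e.kind == "click")

    @property
    def terminal(self) -> ClickEvent:
        return self.events[-1]


@dataclass(frozen=True)
class SessionLog:
    """All item logs of one participant, ordered by item position."""

    participant_id: str
    item_logs: tuple[ItemLog, ...]


# ---------------------------------------------------------------------------
# Replay and validation
# ---------------------------------------------------------------------------


def replay_selection(clicks: Iterable[ClickEvent]) -> frozenset[str]:
    """Replay toggle semantics: odd click count selects, even deselects."""
    selected: set[str] = set()
    for ev in clicks:
        if ev.kind != "click":
            continue
        assert ev.symbol_id is not None
        if ev.symbol_id in selected:
            selected.discard(ev.symbol_id)
        else:
            selected.add(ev.symbol_id)
    return frozenset(selected)


def build_item_log(
    participant_id: str,
    spec: ItemSpec,
    events: Sequence[ClickEvent],
    *,
    where: str = "",
) -> ItemLog:
    """Validate an event sequence against its item spec and assemble the log.

    Enforces: nondecreasing times, times within the item time limit,
    exactly one terminal event and it is last.  Derives ``rule_id`` for
    every click and the final selection by toggle replay.
    """
    ctx = f"{where}: " if where else ""
    if not events:
        raise LogValidationError(f"{ctx}item log has no events (missing terminal)")
    resolved: list[ClickEvent] = []
    prev_t = 0.0
    for i, ev in enumerate(events):
        if ev.t < prev_t:
            raise LogValidationError(
                f"{ctx}non-monotone event times ({ev.t} after {prev_t})"
            )
        if ev.t > spec.time_limit:
            raise LogValidationError(
                f"{ctx}event at t={ev.t} exceeds time limit {spec.time_limit}"
            )
        if ev.is_terminal and i != len(events) - 1:
            raise LogValidationError(f"{ctx}event after terminal event at t={ev.t}")
        prev_t = ev.t
        if ev.kind == "click":
            assert ev.symbol_id is not None
            resolved.append(
                ClickEvent(ev.t, "click", ev.symbol_id, spec.rule_of(ev.symbol_id))
            )
        else:
            resolved.append(ev)
    if not resolved[-1].is_terminal:
        raise LogValidationError(f"{ctx}item log does not end in submit/timeout")
    selection = replay_selection(resolved)
    return ItemLog(
        item_id=spec.item_id,
        participant_id=participant_id,
        events=tuple(resolved),
        final_selection=selection,
        correct=selection == spec.solution,
    )


# ---------------------------------------------------------------------------
# Event log I/O
# ---------------------------------------------------------------------------


def _iter_rows(path_or_stream) -> tuple[list[dict], str]:
    """Read raw rows from CSV or JSON-lines; returns (rows, format)."""
    if hasattr(path_or_stream, "read"):
        text = path_or_stream.read()
        name = getattr(path_or_stream, "name", "")
    else:
        path = Path(path_or_stream)
        text = path.read_text(encoding="utf-8")
        name = str(path)
    stripped = text.lstrip()
    is_jsonl = name.endswith((".jsonl", ".ndjson")) or stripped.startswith("{")
    rows: list[dict] = []
    if is_jsonl:
        for ln, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise LogFormatError(f"line {ln}: invalid JSON ({exc})") from exc
            rows.append(obj)
        return rows, "jsonl"
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None or not set(EVENT_COLUMNS) <= set(reader.fieldnames):
        raise LogFormatError(
            f"event log must have columns {EVENT_COLUMNS}, got {reader.fieldnames}"
        )
    rows.extend(reader)
    return rows, "csv"


def read_event_log(
    path_or_stream,
    item_bank: Sequence[ItemSpec],
) -> list[SessionLog]:
    """Read and validate an event log (CSV or JSON-lines) into sessions.

    Rows must carry ``participant_id, item_id, t, kind, symbol_id`` (symbol
    empty for submit/timeout).  Participants and items keep their order of
    first appearance; item logs are then sorted by test position.
    """
    bank = {spec.item_id: spec for spec in item_bank}
    rows, _fmt = _iter_rows(path_or_stream)
    # participant -> item -> raw events
    grouped: dict[str, dict[str, list[ClickEvent]]] = {}
    for n, row in enumerate(rows, start=1):
        try:
            pid = str(row["participant_id"])
            iid = str(row["item_id"])
            t = float(row["t"])
            kind = str(row["kind"])
            sym = row.get("symbol_id")
        except (KeyError, TypeError, ValueError) as exc:
            raise LogFormatError(f"row {n}: malformed ({exc})") from exc
        if sym in ("", None):
            sym = None
        if iid not in bank:
            raise LogFormatError(f"row {n}: unknown item_id {iid!r}")
        if kind not in EVENT_KINDS:
            raise LogFormatError(f"row {n}: unknown event kind {kind!r}")
        try:
            ev = ClickEvent(t=t, kind=kind, symbol_id=sym)
        except (LogValidationError, LogFormatError) as exc:
            raise LogFormatError(f"row {n}: {exc}") from exc
        grouped.setdefault(pid, {}).setdefault(iid, []).append(ev)
    sessions: list[SessionLog] = []
    for pid, items in grouped.items():
        logs = []
        for iid, events in items.items():
            spec = bank[iid]
            logs.append(
                build_item_log(pid, spec, events, where=f"participant {pid}, item {iid}")
            )
        logs.sort(key=lambda lg: bank[lg.item_id].position)
        sessions.append(SessionLog(participant_id=pid, item_logs=tuple(logs)))
    return sessions


def write_event_log(sessions: Sequence[SessionLog], path) -> None:
    """Write sessions to CSV; ``read_event_log`` round-trips exactly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for session in sessions:
            for log in session.item_logs:
                for ev in log.events:
                    writer.writerow(
                        [
                            session.participant_id,
                            log.item_id,
                            repr(float(ev.t)),
                            ev.kind,
                            ev.symbol_id or "",
                        ]
                    )


# ---------------------------------------------------------------------------
# Item bank I/O
# ---------------------------------------------------------------------------


def _item_from_dict(obj: Mapping) -> ItemSpec:
    try:
        rules = tuple(
            RuleSpec(
                rule_id=str(r["rule_id"]),
                symbol_group=str(r["symbol_group"]),
                n_required_clicks=int(r["n_required_clicks"]),
            )
            for r in obj["rules"]
        )
        return ItemSpec(
            item_id=str(obj["item_id"]),
            position=int(obj["position"]),
            rules=rules,
            solution=frozenset(str(s) for s in obj["solution"]),
            time_limit=float(obj.get("time_limit", 90.0)),
        )
    except (KeyError, TypeError) as exc:
        raise LogFormatError(f"malformed item entry: {exc}") from exc


def read_item_bank(path) -> list[ItemSpec]:
    """Read an item bank from a JSON file (list of item objects)."""
    path = Path(path)
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise LogFormatError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(data, list):
        raise LogFormatError(f"{path}: item bank must be a JSON list")
    bank = [_item_from_dict(obj) for obj in data]
    positions = [it.position for it in bank]
    if len(set(positions)) != len(positions):
        raise LogValidationError("item bank has duplicate positions")
    return sorted(bank, key=lambda it: it.position)


def write_item_bank(bank: Sequence[ItemSpec], path) -> None:
    """Write an item bank to JSON (inverse of :func:`read_item_bank`)."""
    data = [
        {
            "item_id": it.item_id,
            "position": it.position,
            "time_limit": it.time_limit,
            "rules": [
                {
                    "rule_id": r.rule_id,
                    "symbol_group": r.symbol_group,
                    "n_required_clicks": r.n_required_clicks,
                }
                for r in it.rules
            ],
            "solution": sorted(it.solution),
        }
        for it in bank
    ]
    Path(path).write_text(json.dumps(data, indent=1), encoding="utf-8")


def default_item_bank() -> list[ItemSpec]:
    """The packaged 22-item fixture bank.

    Mirrors the composition of the analysed DESIGMA item set: eleven
    two-rule, seven three-rule, three four-rule and one five-rule item,
    each with a 90-s time limit.  Symbol groups g1..g6 are globally tied
    to one rule each; every rule contributes two solution symbols.
    """
    with resources.files("matrixlft.data").joinpath("item_bank.json").open(
        "r", encoding="utf-8"
    ) as fh:
        data = json.load(fh)
    return sorted((_item_from_dict(obj) for obj in data), key=lambda it: it.position)
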