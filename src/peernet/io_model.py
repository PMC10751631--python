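"""Domain types, validation, and readers/writers for community event logs.

The unit of observation is a *communication event*: one post, comment,
reaction, poll, poll vote, or view inside a closed online peer-support
community.  Events reference their parent content (a comment points at the
post it answers, a reaction at the post or comment it applauds, a vote at
its poll, a view at what was viewed), which is what later lets the network
modules turn a flat log into pairwise member interactions.

Members carry a role history (designated peer leader, regular member, or
administrator account), join/exit dates, and the demographic fields the
roster collects (name-inferred sex, age band at diagnosis, region, insulin
modality).

All readers validate fully before returning: a byte stream either becomes a
:class:`CommunityLog` satisfying every invariant, or raises a located
error — never a partially populated structure.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "EventKind",
    "EngagementError",
    "ParseError",
    "IntegrityError",
    "CommunicationEvent",
    "Role",
    "RoleInterval",
    "SexInferred",
    "AgeBand",
    "InsulinModality",
    "Member",
    "CommunityLog",
    "CodeAssignment",
    "Violation",
    "ValidationReport",
    "read_log",
    "write_log",
    "read_code_assignments",
    "write_code_assignments",
    "validate_code_assignments",
]


class EngagementError(ValueError):
    """Base class for log validation failures."""


class ParseError(EngagementError):
    """Malformed record; message carries the file and record number."""


class IntegrityError(EngagementError):
    """Referential-integrity failure (dangling parent/actor, bad kind)."""


class EventKind(str, Enum):
    POST = "post"
    COMMENT = "comment"
    REACTION = "reaction"
    POLL = "poll"
    VOTE = "vote"
    VIEW = "view"


#: Kinds that start a thread and therefore never carry a parent reference.
ROOT_KINDS = frozenset({EventKind.POST, EventKind.POLL})

#: Allowed parent kinds per child kind.  A view's parent is
#: optional-but-recommended: aggregate platform exports often do not
#: attribute views to targets, and no network statistic uses them.
ALLOWED_PARENT_KINDS: Mapping[EventKind, frozenset] = {
    EventKind.COMMENT: frozenset({EventKind.POST}),
    EventKind.REACTION: frozenset({EventKind.POST, EventKind.COMMENT}),
    EventKind.VOTE: frozenset({EventKind.POLL}),
    EventKind.VIEW: frozenset({EventKind.POST, EventKind.POLL}),
}


class Role(str, Enum):
    LEADER = "leader"
    REGULAR = "regular"
    ADMIN = "admin"


class SexInferred(str, Enum):
    FEMALE_SOUNDING = "female_sounding"
    MALE_SOUNDING = "male_sounding"
    UNCLEAR = "unclear"
    MISSING = "missing"


class AgeBand(str, Enum):
    UNDER_14 = "under_14"
    EXACTLY_14 = "exactly_14"
    OVER_14 = "over_14"
    MISSING = "missing"


class InsulinModality(str, Enum):
    PUMP = "pump"
    INJECTIONS = "injections"
    MISSING = "missing"


@dataclass(frozen=True)
class CommunicationEvent:
    event_id: str
    actor_id: str
    kind: EventKind
    timestamp: datetime
    parent_id: Optional[str] = None


@dataclass(frozen=True)
class RoleInterval:
    role: Role
    start: date
    end: Optional[date] = None  # absent = still active


@dataclass(frozen=True)
class Member:
    member_id: str
    join_date: date
    role_history: tuple = ()
    exit_date: Optional[date] = None
    sex_inferred: SexInferred = SexInferred.MISSING
    age_at_diagnosis_band: AgeBand = AgeBand.MISSING
    region: Optional[str] = None
    insulin_modality: InsulinModality = InsulinModality.MISSING

    def role_on(self, day: date) -> Optional[Role]:
        for iv in self.role_history:
            if iv.start <= day and (iv.end is None or day < iv.end):
                return iv.role
        return None

    @property
    def is_ever_leader(self) -> bool:
        return any(iv.role is Role.LEADER for iv in self.role_history)

    @property
    def is_admin(self) -> bool:
        return any(iv.role is Role.ADMIN for iv in self.role_history)

    @property
    def role_group(self) -> Role:
        """Leader if the member ever held a leader role, admin if ever an
        admin account, otherwise regular."""
        if self.is_admin:
            return Role.ADMIN
        if self.is_ever_leader:
            return Role.LEADER
        return Role.REGULAR


@dataclass
class CommunityLog:
    """A validated roster + event log over a fixed observation window."""

    members: list
    events: list
    observation_start: date
    observation_end: date

    _member_index: dict = field(default_factory=dict, repr=False, compare=False)
    _event_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._member_index = {m.member_id: m for m in self.members}
        self._event_index = {e.event_id: e for e in self.events}

    def member(self, member_id: str) -> Member:
        return self._member_index[member_id]

    def event(self, event_id: str) -> CommunicationEvent:
        return self._event_index[event_id]

    def non_admin_members(self) -> list:
        return [m for m in self.members if not m.is_admin]

    def validate(self) -> "CommunityLog":
        """Check every invariant; raise IntegrityError on the first failure."""
        if len(self._member_index) != len(self.members):
            seen: set = set()
            for m in self.members:
                if m.member_id in seen:
                    raise IntegrityError(f"duplicate member_id {m.member_id!r}")
                seen.add(m.member_id)
        if len(self._event_index) != len(self.events):
            seen = set()
            for e in self.events:
                if e.event_id in seen:
                    raise IntegrityError(f"duplicate event_id {e.event_id!r}")
                seen.add(e.event_id)
        if self.observation_start > self.observation_end:
            raise IntegrityError("observation_start after observation_end")

        for m in self.members:
            if m.exit_date is not None and m.exit_date < m.join_date:
                raise IntegrityError(
                    f"member {m.member_id!r}: exit_date before join_date"
                )
            ivs = sorted(m.role_history, key=lambda iv: iv.start)
            for iv in ivs:
                if iv.end is not None and iv.start >= iv.end:
                    raise IntegrityError(
                        f"member {m.member_id!r}: role interval start >= end"
                    )
                if iv.start < m.join_date:
                    raise IntegrityError(
                        f"member {m.member_id!r}: role interval starts before join"
                    )
            for a, b in zip(ivs, ivs[1:]):
                if a.end is None or a.end > b.start:
                    raise IntegrityError(
                        f"member {m.member_id!r}: overlapping role intervals"
                    )

        for e in self.events:
            if e.actor_id not in self._member_index:
                raise IntegrityError(
                    f"event {e.event_id!r}: unknown actor_id {e.actor_id!r}"
                )
            ts = e.timestamp.date()
            if not (self.observation_start <= ts <= self.observation_end):
                raise IntegrityError(
                    f"event {e.event_id!r}: timestamp outside observation window"
                )
            if e.kind in ROOT_KINDS:
                if e.parent_id is not None:
                    raise IntegrityError(
                        f"event {e.event_id!r}: {e.kind.value} must not have a parent"
                    )
                continue
            if e.parent_id is None:
                if e.kind is EventKind.VIEW:
                    continue  # view targets may be unattributed
                raise IntegrityError(
                    f"event {e.event_id!r}: {e.kind.value} requires a parent_id"
                )
            parent = self._event_index.get(e.parent_id)
            if parent is None:
                raise IntegrityError(
                    f"event {e.event_id!r}: dangling parent_id {e.parent_id!r}"
                )
            if parent.kind not in ALLOWED_PARENT_KINDS[e.kind]:
                raise IntegrityError(
                    f"event {e.event_id!r}: {e.kind.value} may not reference a "
                    f"{parent.kind.value} ({e.parent_id!r})"
                )
            if e.timestamp < parent.timestamp:
                raise IntegrityError(
                    f"event {e.event_id!r}: timestamp precedes its parent"
                )
        return self


@dataclass(frozen=True)
class CodeAssignment:
    """Up to three rubric codes attached to one coded communication.

    ``direction`` records whether the communication was seeking support,
    providing support, or neither; it applies to the assignment's
    support-code applications.
    """

    event_id: str
    codes: tuple
    direction: Optional[str] = None  # seeking_support | providing_support | neither


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_EVENT_FIELDS = ["event_id", "actor_id", "kind", "timestamp", "parent_id"]
_MEMBER_FIELDS = [
    "member_id",
    "join_date",
    "exit_date",
    "sex_inferred",
    "age_at_diagnosis_band",
    "region",
    "insulin_modality",
]
_ROLE_FIELDS = ["member_id", "role", "start", "end"]


def _fmt_date(d: Optional[date]) -> str:
    return "" if d is None else d.isoformat()


def _parse_date(s: str, where: str) -> Optional[date]:
    if s in ("", None):
        return None
    try:
        return date.fromisoformat(s)
    except ValueError as exc:
        raise ParseError(f"{where}: bad date {s!r}") from exc


def _parse_ts(s: str, where: str) -> datetime:
    try:
        return datetime.fromisoformat(s)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{where}: bad timestamp {s!r}") from exc


def _parse_enum(enum_cls, s, where, default=None):
    if s in ("", None):
        if default is not None:
            return default
        raise ParseError(f"{where}: missing {enum_cls.__name__}")
    try:
        return enum_cls(s)
    except ValueError as exc:
        raise ParseError(
            f"{where}: unknown {enum_cls.__name__} value {s!r}"
        ) from exc


def _iter_records(path: Path, fmt: str) -> Iterable[tuple]:
    """Yield (record_number, dict) pairs; record numbers are 1-based data rows."""
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return
            for i, row in enumerate(reader, start=1):
                yield i, row
    elif fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    yield i, json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"{path.name} line {i}: invalid JSON") from exc
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'csv' or 'jsonl')")


def _write_records(path: Path, fmt: str, fields: Sequence[str], rows: Iterable[dict]) -> None:
    try:
        if fmt == "csv":
            with path.open("w", newline="", encoding="utf-8") as fh:
                writer = csv.DictWriter(fh, fieldnames=list(fields))
                writer.writeheader()
                for row in rows:
                    writer.writerow({k: ("" if row.get(k) is None else row[k]) for k in fields})
        elif fmt == "jsonl":
            with path.open("w", encoding="utf-8") as fh:
                for row in rows:
                    fh.write(json.dumps({k: row.get(k) for k in fields}) + "\n")
        else:
            raise ValueError(f"unknown format {fmt!r} (expected 'csv' or 'jsonl')")
    except OSError as exc:
        raise EngagementError(f"cannot write {path}: {exc}") from exc


def write_log(log: CommunityLog, path: str | Path, format: str = "csv") -> None:
    """Write a log as events/members/roles files plus a window sidecar.

    ``path`` is a directory; it is created if absent.  Files written:
    ``events.<fmt>``, ``members.<fmt>``, ``roles.<fmt>``, ``window.json``.
    """
    outdir = Path(path)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise EngagementError(f"cannot create directory {outdir}: {exc}") from exc
    ext = format

    _write_records(
        outdir / f"events.{ext}",
        format,
        _EVENT_FIELDS,
        (
            {
                "event_id": e.event_id,
                "actor_id": e.actor_id,
                "kind": e.kind.value,
                "timestamp": e.timestamp.isoformat(),
                "parent_id": e.parent_id,
            }
            for e in log.events
        ),
    )
    _write_records(
        outdir / f"members.{ext}",
        format,
        _MEMBER_FIELDS,
        (
            {
                "member_id": m.member_id,
                "join_date": m.join_date.isoformat(),
                "exit_date": None if m.exit_date is None else m.exit_date.isoformat(),
                "sex_inferred": m.sex_inferred.value,
                "age_at_diagnosis_band": m.age_at_diagnosis_band.value,
                "region": m.region,
                "insulin_modality": m.insulin_modality.value,
            }
            for m in log.members
        ),
    )
    _write_records(
        outdir / f"roles.{ext}",
        format,
        _ROLE_FIELDS,
        (
            {
                "member_id": m.member_id,
                "role": iv.role.value,
                "start": iv.start.isoformat(),
                "end": None if iv.end is None else iv.end.isoformat(),
            }
            for m in log.members
            for iv in m.role_history
        ),
    )
    window = {
        "observation_start": log.observation_start.isoformat(),
        "observation_end": log.observation_end.isoformat(),
    }
    try:
        (outdir / "window.json").write_text(json.dumps(window) + "\n", encoding="utf-8")
    except OSError as exc:
        raise EngagementError(f"cannot write {outdir / 'window.json'}: {exc}") from exc


def read_log(
    path: str | Path,
    format: Optional[str] = None,
    *,
    events: Optional[str | Path] = None,
    members: Optional[str | Path] = None,
    roles: Optional[str | Path] = None,
    observation_start: Optional[date] = None,
    observation_end: Optional[date] = None,
) -> CommunityLog:
    """Read and fully validate a community log.

    ``path`` is the directory produced by :func:`write_log`; individual file
    paths may be overridden.  If no ``window.json`` (or explicit window) is
    available, the observation window defaults to the span of join dates and
    event timestamps.
    """
    base = Path(path) if path is not None else None
    if format is None:
        if base is not None and (base / "events.jsonl").exists():
            format = "jsonl"
        else:
            format = "csv"
    ext = format
    events_path = Path(events) if events else base / f"events.{ext}"
    members_path = Path(members) if members else base / f"members.{ext}"
    roles_path = Path(roles) if roles else base / f"roles.{ext}"
    if not events_path.exists():
        raise EngagementError(f"events file not found: {events_path}")
    if not members_path.exists():
        raise EngagementError(f"members file not found: {members_path}")

    member_rows: dict = {}
    order: list = []
    for i, row in _iter_records(members_path, format):
        where = f"{members_path.name} record {i}"
        mid = row.get("member_id")
        if not mid:
            raise ParseError(f"{where}: missing member_id")
        jd = _parse_date(row.get("join_date"), where)
        if jd is None:
            raise ParseError(f"{where}: missing join_date")
        member_rows[mid] = dict(
            member_id=mid,
            join_date=jd,
            exit_date=_parse_date(row.get("exit_date"), where),
            sex_inferred=_parse_enum(
                SexInferred, row.get("sex_inferred"), where, SexInferred.MISSING
            ),
            age_at_diagnosis_band=_parse_enum(
                AgeBand, row.get("age_at_diagnosis_band"), where, AgeBand.MISSING
            ),
            region=row.get("region") or None,
            insulin_modality=_parse_enum(
                InsulinModality, row.get("insulin_modality"), where, InsulinModality.MISSING
            ),
            role_history=[],
        )
        order.append(mid)

    if roles_path.exists():
        for i, row in _iter_records(roles_path, format):
            where = f"{roles_path.name} record {i}"
            mid = row.get("member_id")
            if mid not in member_rows:
                raise IntegrityError(f"{where}: unknown member_id {mid!r}")
            member_rows[mid]["role_history"].append(
                RoleInterval(
                    role=_parse_enum(Role, row.get("role"), where),
                    start=_parse_date(row.get("start"), where) or member_rows[mid]["join_date"],
                    end=_parse_date(row.get("end"), where),
                )
            )

    members_list = []
    for mid in order:
        kw = member_rows[mid]
        kw["role_history"] = tuple(sorted(kw["role_history"], key=lambda iv: iv.start))
        members_list.append(Member(**kw))

    events_list = []
    for i, row in _iter_records(events_path, format):
        where = f"{events_path.name} record {i}"
        eid = row.get("event_id")
        if not eid:
            raise ParseError(f"{where}: missing event_id")
        events_list.append(
            CommunicationEvent(
                event_id=eid,
                actor_id=row.get("actor_id") or "",
                kind=_parse_enum(EventKind, row.get("kind"), where),
                timestamp=_parse_ts(row.get("timestamp"), where),
                parent_id=row.get("parent_id") or None,
            )
        )

    if observation_start is None or observation_end is None:
        window_path = (base / "window.json") if base is not None else None
        if window_path is not None and window_path.exists():
            meta = json.loads(window_path.read_text(encoding="utf-8"))
            observation_start = observation_start or date.fromisoformat(
                meta["observation_start"]
            )
            observation_end = observation_end or date.fromisoformat(
                meta["observation_end"]
            )
        else:
            dates = [m.join_date for m in members_list] + [
                e.timestamp.date() for e in events_list
            ]
            if not dates:
                raise EngagementError("empty log and no observation window given")
            observation_start = observation_start or min(dates)
            observation_end = observation_end or max(dates)

    return CommunityLog(
        members=members_list,
        events=events_list,
        observation_start=observation_start,
        observation_end=observation_end,
    ).validate()


# ---------------------------------------------------------------------------
# Code assignments
# ---------------------------------------------------------------------------

_CODEABLE_KINDS = frozenset({EventKind.POST, EventKind.COMMENT, EventKind.POLL})
_DIRECTIONS = frozenset({"seeking_support", "providing_support", "neither"})


@dataclass(frozen=True)
class Violation:
    event_id: Optional[str]
    rule: str
    detail: str


@dataclass
class ValidationReport:
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_code_assignments(
    assignments: Iterable[CodeAssignment],
    log: Optional[CommunityLog],
    codebook: Iterable[str],
) -> ValidationReport:
    """List every violation; the report is empty iff all assignments are valid.

    Violations are data, not exceptions: unknown code, more than three codes,
    duplicate codes, bad direction, a non-codeable event kind, or a dangling
    event_id (the last two only when a log is supplied).
    """
    known = set(codebook)
    out: list = []
    for a in assignments:
        if not (1 <= len(a.codes) <= 3):
            out.append(Violation(a.event_id, "max 3 codes exceeded" if len(a.codes) > 3 else "empty code list", f"{len(a.codes)} codes"))
        if len(set(a.codes)) != len(a.codes):
            out.append(Violation(a.event_id, "duplicate codes", ",".join(a.codes)))
        for c in a.codes:
            if c not in known:
                out.append(Violation(a.event_id, "unknown code", c))
        if a.direction is not None and a.direction not in _DIRECTIONS:
            out.append(Violation(a.event_id, "unknown direction", str(a.direction)))
        if log is not None:
            ev = log._event_index.get(a.event_id)
            if ev is None:
                out.append(Violation(a.event_id, "dangling event_id", a.event_id))
            elif ev.kind not in _CODEABLE_KINDS:
                out.append(Violation(a.event_id, "kind not codeable", ev.kind.value))
    return ValidationReport(out)


_CODE_FIELDS = ["event_id", "code1", "code2", "code3", "direction"]


def write_code_assignments(
    assignments: Iterable[CodeAssignment], path: str | Path, format: str = "csv"
) -> None:
    rows = []
    for a in assignments:
        padded = list(a.codes) + [None] * (3 - len(a.codes))
        rows.append(
            {
                "event_id": a.event_id,
                "code1": padded[0],
                "code2": padded[1],
                "code3": padded[2],
                "direction": a.direction,
            }
        )
    _write_records(Path(path), format, _CODE_FIELDS, rows)


def read_code_assignments(path: str | Path, format: str = "csv") -> list:
    out = []
    for i, row in _iter_records(Path(path), format):
        where = f"{Path(path).name} record {i}"
        eid = row.get("event_id")
        if not eid:
            raise ParseError(f"{where}: missing event_id")
        codes = tuple(c for c in (row.get("code1"), row.get("code2"), row.get("code3")) if c)
        out.append(CodeAssignment(event_id=eid, codes=codes, direction=row.get("direction") or None))
    return out
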