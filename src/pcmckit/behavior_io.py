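"""Data model and I/O for behavioral event streams, sessions, pairs, and censuses.

Tables are plain CSV/TSV with a header row; an XLSX adapter bundles the same
tables into a single workbook.  All within-session times are seconds from
session start in the half-open interval [0, 300); calendar timestamps are
ISO-8601.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

SESSION_LENGTH_S = 300.0
POSTPONE_WINDOW_S = 30.0
MAX_PAIR_GAP_DAYS = 14
MIN_PAIR_GAP_DAYS = 1
MAX_TOD_DIFF_S = 2 * 3600

AFFILIATIVE_BEHAVIORS = frozenset(
    {"contact", "groom_give", "groom_receive", "approach", "vocalization"}
)
AGGRESSIVE_BEHAVIORS = frozenset({"aggression_physical", "aggression_nonphysical"})
BEHAVIORS = AFFILIATIVE_BEHAVIORS | AGGRESSIVE_BEHAVIORS

SESSION_COLUMNS = [
    "session_id",
    "kind",
    "focal",
    "opponent",
    "focal_role",
    "date_time",
    "conflict_physical",
    "conflict_counter",
]
EVENT_COLUMNS = [
    "session_id",
    "t",
    "actor",
    "recipient",
    "behavior",
    "oriented_at_recipient",
    "distance_m",
]
CENSUS_COLUMNS = ["census_id", "date", "female", "state", "partners"]
PAIR_COLUMNS = ["pair_id", "pc_session_id", "mc_session_id"]


class SchemaError(ValueError):
    """A table is missing required columns or uses an unknown layout."""


class ValidationError(ValueError):
    """A row violates a field-level invariant."""


class PairingError(ValueError):
    """PC/MC sessions cannot be matched consistently."""


@dataclass(frozen=True)
class EventRecord:
    """One timestamped behavior by an actor toward a recipient within a session."""

    session_id: str
    t: float
    actor: str
    recipient: str | None
    behavior: str
    oriented_at_recipient: bool | None = None
    distance_m: float | None = None

    def validate(self, row: int | None = None) -> None:
        where = f" (row {row})" if row is not None else ""
        if not (0.0 <= self.t < SESSION_LENGTH_S):
            raise ValidationError(
                f"event time t={self.t} outside [0, {SESSION_LENGTH_S}){where}"
            )
        if self.behavior not in BEHAVIORS:
            raise ValidationError(f"unknown behavior {self.behavior!r}{where}")
        if self.behavior == "vocalization":
            if self.oriented_at_recipient is None:
                raise ValidationError(
                    f"vocalization missing oriented_at_recipient{where}"
                )
            if self.distance_m is None:
                raise ValidationError(f"vocalization missing distance_m{where}")
            if self.distance_m < 0:
                raise ValidationError(f"negative distance_m={self.distance_m}{where}")

    @property
    def is_affiliative(self) -> bool:
        return self.behavior in AFFILIATIVE_BEHAVIORS

    @property
    def is_aggressive(self) -> bool:
        return self.behavior in AGGRESSIVE_BEHAVIORS

    def involves(self, individual: str) -> bool:
        return self.actor == individual or self.recipient == individual

    def other_party(self, individual: str) -> str | None:
        if self.actor == individual:
            return self.recipient
        if self.recipient == individual:
            return self.actor
        return None


@dataclass
class Session:
    """A 5-min PC or MC focal observation."""

    session_id: str
    kind: str  # "PC" | "MC"
    focal: str
    opponent: str
    focal_role: str  # "aggressor" | "victim"
    date_time: datetime
    conflict_physical: bool
    conflict_counter: bool
    events: list[EventRecord] = field(default_factory=list)

    def validate(self) -> None:
        if self.kind not in ("PC", "MC"):
            raise ValidationError(f"session {self.session_id}: kind={self.kind!r}")
        if self.focal_role not in ("aggressor", "victim"):
            raise ValidationError(
                f"session {self.session_id}: focal_role={self.focal_role!r}"
            )
        for ev in self.events:
            ev.validate()
        ts = [ev.t for ev in self.events]
        if ts != sorted(ts):
            raise ValidationError(f"session {self.session_id}: events not time-sorted")

    def sorted_copy(self) -> "Session":
        return replace(self, events=sorted(self.events, key=lambda e: e.t))


@dataclass
class PCMCPair:
    """A matched post-conflict / matched-control session pair for one conflict."""

    pair_id: str
    pc: Session
    mc: Session

    def validate(self) -> None:
        if self.pc.kind != "PC" or self.mc.kind != "MC":
            raise ValidationError(f"pair {self.pair_id}: kinds {self.pc.kind}/{self.mc.kind}")
        for attr in ("focal", "opponent", "focal_role", "conflict_physical", "conflict_counter"):
            if getattr(self.pc, attr) != getattr(self.mc, attr):
                raise ValidationError(
                    f"pair {self.pair_id}: PC/MC disagree on {attr}"
                )
        if not _mc_matches_pc(self.pc, self.mc):
            raise ValidationError(
                f"pair {self.pair_id}: MC timing violates the 1–14 day / ±2 h rule"
            )

    @property
    def focal(self) -> str:
        return self.pc.focal

    @property
    def focal_role(self) -> str:
        return self.pc.focal_role


@dataclass(frozen=True)
class CensusRecord:
    """One female's activity in one line-census session."""

    census_id: str
    date: date
    female: str
    state: str  # "social" | "alone"
    partners: frozenset[str] = frozenset()

    def validate(self) -> None:
        if self.state not in ("social", "alone"):
            raise ValidationError(f"census {self.census_id}: state={self.state!r}")
        if self.state == "social" and not self.partners:
            raise ValidationError(
                f"census {self.census_id}: social record for {self.female} has no partners"
            )
        if self.state == "alone" and self.partners:
            raise ValidationError(
                f"census {self.census_id}: alone record for {self.female} lists partners"
            )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, dialect: str, required: list[str]) -> pd.DataFrame:
    sep = "\t" if dialect in ("tsv", "\t") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df

def _opt_float(raw: str) -> float | None:
    return None if raw == "" else float(raw)


def _opt_bool(raw: str) -> bool | None:
    if raw == "":
        return None
    return _parse_bool(raw)


def _parse_bool(raw: str) -> bool:
    low = str(raw).strip().lower()
    if low in ("1", "true", "yes", "y"):
        return True
    if low in ("0", "false", "no", "n"):
        return False
    raise ValidationError(f"cannot parse boolean from {raw!r}")


def read_events(
    events_path: str | Path,
    sessions_path: str | Path,
    dialect: str = "csv",
) -> list[Session]:
    """Read session metadata + event tables and return validated ``Session`` objects.

    Events are returned time-sorted within each session.  Unknown behavior
    labels and out-of-range times raise :class:`ValidationError` naming the
    offending row.
    """
    sess_df = _read_table(sessions_path, dialect, SESSION_COLUMNS)
    ev_df = _read_table(events_path, dialect, EVENT_COLUMNS)

    sessions: dict[str, Session] = {}
    for i, row in sess_df.iterrows():
        s = Session(
            session_id=row["session_id"],
            kind=row["kind"],
            focal=row["focal"],
            opponent=row["opponent"],
            focal_role=row["focal_role"],
            date_time=datetime.fromisoformat(row["date_time"]),
            conflict_physical=_parse_bool(row["conflict_physical"]),
            conflict_counter=_parse_bool(row["conflict_counter"]),
        )
        if s.session_id in sessions:
            raise ValidationError(f"duplicate session_id {s.session_id} (row {i + 2})")
        sessions[s.session_id] = s

    for i, row in ev_df.iterrows():
        sid = row["session_id"]
        if sid not in sessions:
            raise ValidationError(
                f"event references unknown session {sid!r} (row {i + 2})"
            )
        ev = EventRecord(
            session_id=sid,
            t=float(row["t"]),
            actor=row["actor"],
            recipient=row["recipient"] or None,
            behavior=row["behavior"],
            oriented_at_recipient=_opt_bool(row["oriented_at_recipient"]),
            distance_m=_opt_float(row["distance_m"]),
        )
        ev.validate(row=i + 2)
        sessions[sid].events.append(ev)

    out = [s.sorted_copy() for s in sessions.values()]
    for s in out:
        s.validate()
    if not out:
        warnings.warn("session table is empty", stacklevel=2)
    return out


def write_events(
    sessions: list[Session],
    events_path: str | Path,
    sessions_path: str | Path,
    dialect: str = "csv",
) -> None:
    """Inverse of :func:`read_events` (field-level round-trip)."""
    sep = "\t" if dialect in ("tsv", "\t") else ","
    sess_rows = [
        {
            "session_id": s.session_id,
            "kind": s.kind,
            "focal": s.focal,
            "opponent": s.opponent,
            "focal_role": s.focal_role,
            "date_time": s.date_time.isoformat(),
            "conflict_physical": s.conflict_physical,
            "conflict_counter": s.conflict_counter,
        }
        for s in sessions
    ]
    ev_rows = [
        {
            "session_id": ev.session_id,
            "t": ev.t,
            "actor": ev.actor,
            "recipient": ev.recipient if ev.recipient is not None else "",
            "behavior": ev.behavior,
            "oriented_at_recipient": ""
            if ev.oriented_at_recipient is None
            else ev.oriented_at_recipient,
            "distance_m": "" if ev.distance_m is None else ev.distance_m,
        }
        for s in sessions
        for ev in s.events
    ]
    pd.DataFrame(sess_rows, columns=SESSION_COLUMNS).to_csv(sessions_path, sep=sep, index=False)
    pd.DataFrame(ev_rows, columns=EVENT_COLUMNS).to_csv(events_path, sep=sep, index=False)


def read_census(path: str | Path, dialect: str = "csv") -> list[CensusRecord]:
    df = _read_table(path, dialect, CENSUS_COLUMNS)
    records = []
    for i, row in df.iterrows():
        rec = CensusRecord(
            census_id=row["census_id"],
            date=date.fromisoformat(row["date"]),
            female=row["female"],
            state=row["state"],
            partners=frozenset(p for p in row["partners"].split(";") if p),
        )
        rec.validate()
        records.append(rec)
    return records


def write_census(records: list[CensusRecord], path: str | Path, dialect: str = "csv") -> None:
    sep = "\t" if dialect in ("tsv", "\t") else ","
    rows = [
        {
            "census_id": r.census_id,
            "date": r.date.isoformat(),
            "female": r.female,
            "state": r.state,
            "partners": ";".join(sorted(r.partners)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CENSUS_COLUMNS).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# PC-MC pairing
# ---------------------------------------------------------------------------


def _mc_matches_pc(pc: Session, mc: Session) -> bool:
    gap = mc.date_time.date() - pc.date_time.date()
    if not (timedelta(days=MIN_PAIR_GAP_DAYS) <= gap <= timedelta(days=MAX_PAIR_GAP_DAYS)):
        return False
    tod_pc = pc.date_time.hour * 3600 + pc.date_time.minute * 60 + pc.date_time.second
    tod_mc = mc.date_time.hour * 3600 + mc.date_time.minute * 60 + mc.date_time.second
    return abs(tod_mc - tod_pc) <= MAX_TOD_DIFF_S


def pair_pc_mc(
    sessions: list[Session],
) -> tuple[list[PCMCPair], list[Session]]:
    """Match each PC session to at most one MC session.

    An MC is eligible for a PC when focal, opponent, role, and conflict
    attributes agree, the MC falls 1–14 days after the PC, and its time of
    day is within ±2 h.  When several MCs are eligible the earliest is
    chosen (with a warning).  Every session ends up in exactly one pair or
    in the unmatched list.
    """
    pcs = sorted(
        (s for s in sessions if s.kind == "PC"),
        key=lambda s: (s.date_time, s.session_id),
    )
    mcs = sorted(
        (s for s in sessions if s.kind == "MC"),
        key=lambda s: (s.date_time, s.session_id),
    )
    used: set[str] = set()
    pairs: list[PCMCPair] = []
    unmatched: list[Session] = []
    for pc in pcs:
        candidates = [
            mc
            for mc in mcs
            if mc.session_id not in used
            and mc.focal == pc.focal
            and mc.opponent == pc.opponent
            and mc.focal_role == pc.focal_role
            and mc.conflict_physical == pc.conflict_physical
            and mc.conflict_counter == pc.conflict_counter
            and _mc_matches_pc(pc, mc)
        ]
        if not candidates:
            unmatched.append(pc)
            continue
        if len(candidates) > 1:
            logger.warning(
                "PC %s: %d eligible MCs, choosing earliest (%s)",
                pc.session_id,
                len(candidates),
                candidates[0].session_id,
            )
        mc = candidates[0]
        used.add(mc.session_id)
        pair = PCMCPair(pair_id=f"{pc.session_id}|{mc.session_id}", pc=pc, mc=mc)
        pair.validate()
        pairs.append(pair)
    unmatched.extend(mc for mc in mcs if mc.session_id not in used)
    return pairs, unmatched


def validate_postponement(
    conflict_end_t: float, renewed_aggression_ts: list[float]
) -> bool:
    """Return False (session must be postponed/restarted) iff aggression
    between the former opponents resumes within 30 s of conflict end."""
    if conflict_end_t < 0 or any(t < 0 for t in renewed_aggression_ts):
        raise ValidationError("times must be nonnegative")
    return not any(
        0 <= t - conflict_end_t <= POSTPONE_WINDOW_S for t in renewed_aggression_ts
    )


# ---------------------------------------------------------------------------
# XLSX workbook adapter (deposited-dataset layout)
# ---------------------------------------------------------------------------

_XLSX_SHEETS = {
    "sessions": SESSION_COLUMNS,
    "events": EVENT_COLUMNS,
    "pairs": PAIR_COLUMNS,
    "census": CENSUS_COLUMNS,
}


class AdapterError(SchemaError):
    """Workbook layout does not match the documented adapter schema."""


def write_deposited_dataset(
    pairs: list[PCMCPair],
    path: str | Path,
    census: list[CensusRecord] | None = None,
) -> None:
    """Write pairs (+ optional census) as a single XLSX workbook.

    Sheets: ``sessions``, ``events``, ``pairs``, ``census`` — the same
    columns as the CSV tables.
    """
    sessions = [p.pc for p in pairs] + [p.mc for p in pairs]
    sess_rows, ev_rows = _session_frames(sessions)
    pair_rows = pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "pc_session_id": p.pc.session_id,
                "mc_session_id": p.mc.session_id,
            }
            for p in pairs
        ],
        columns=PAIR_COLUMNS,
    )
    census_rows = pd.DataFrame(
        [
            {
                "census_id": r.census_id,
                "date": r.date.isoformat(),
                "female": r.female,
                "state": r.state,
                "partners": ";".join(sorted(r.partners)),
            }
            for r in (census or [])
        ],
        columns=CENSUS_COLUMNS,
    )
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        sess_rows.to_excel(xl, sheet_name="sessions", index=False)
        ev_rows.to_excel(xl, sheet_name="events", index=False)
        pair_rows.to_excel(xl, sheet_name="pairs", index=False)
        census_rows.to_excel(xl, sheet_name="census", index=False)


def _session_frames(sessions: list[Session]) -> tuple[pd.DataFrame, pd.DataFrame]:
    sess_rows = pd.DataFrame(
        [
            {
                "session_id": s.session_id,
                "kind": s.kind,
                "focal": s.focal,
                "opponent": s.opponent,
                "focal_role": s.focal_role,
                "date_time": s.date_time.isoformat(),
                "conflict_physical": s.conflict_physical,
                "conflict_counter": s.conflict_counter,
            }
            for s in sessions
        ],
        columns=SESSION_COLUMNS,
    )
    ev_rows = pd.DataFrame(
        [
            {
                "session_id": ev.session_id,
                "t": ev.t,
                "actor": ev.actor,
                "recipient": ev.recipient if ev.recipient is not None else "",
                "behavior": ev.behavior,
                "oriented_at_recipient": ""
                if ev.oriented_at_recipient is None
                else ev.oriented_at_recipient,
                "distance_m": "" if ev.distance_m is None else ev.distance_m,
            }
            for s in sessions
            for ev in s.events
        ],
        columns=EVENT_COLUMNS,
    )
    return sess_rows, ev_rows


def read_deposited_dataset(
    path: str | Path,
) -> tuple[list[PCMCPair], list[CensusRecord]]:
    """Read an XLSX workbook in the adapter layout back into pairs + census.

    The adapter is strict: any missing sheet or renamed column raises
    :class:`AdapterError` naming the problem — never a silent partial load.
    """
    xl = pd.read_excel(path, sheet_name=None, dtype=str, engine="openpyxl")
    for sheet, cols in _XLSX_SHEETS.items():
        if sheet not in xl:
            raise AdapterError(f"{path}: workbook missing sheet {sheet!r}")
        missing = [c for c in cols if c not in xl[sheet].columns]
        if missing:
            raise AdapterError(
                f"{path}: sheet {sheet!r} missing column(s) {missing}"
            )

    def clean(df: pd.DataFrame) -> pd.DataFrame:
        return df.fillna("")

    sess_df, ev_df = clean(xl["sessions"]), clean(xl["events"])
    sessions: dict[str, Session] = {}
    for _, row in sess_df.iterrows():
        s = Session(
            session_id=row["session_id"],
            kind=row["kind"],
            focal=row["focal"],
            opponent=row["opponent"],
            focal_role=row["focal_role"],
            date_time=datetime.fromisoformat(row["date_time"]),
            conflict_physical=_parse_bool(row["conflict_physical"]),
            conflict_counter=_parse_bool(row["conflict_counter"]),
        )
        sessions[s.session_id] = s
    for i, row in ev_df.iterrows():
        sid = row["session_id"]
        if sid not in sessions:
            raise AdapterError(f"{path}: event row {i + 2} references unknown session {sid!r}")
        ev = EventRecord(
            session_id=sid,
            t=float(row["t"]),
            actor=row["actor"],
            recipient=row["recipient"] or None,
            behavior=row["behavior"],
            oriented_at_recipient=_opt_bool(row["oriented_at_recipient"]),
            distance_m=_opt_float(row["distance_m"]),
        )
        ev.validate(row=i + 2)
        sessions[sid].events.append(ev)
    sessions = {sid: s.sorted_copy() for sid, s in sessions.items()}

    pairs = []
    for _, row in clean(xl["pairs"]).iterrows():
        try:
            pc = sessions[row["pc_session_id"]]
            mc = sessions[row["mc_session_id"]]
        except KeyError as exc:
            raise AdapterError(f"{path}: pair references unknown session {exc}") from exc
        pair = PCMCPair(pair_id=row["pair_id"], pc=pc, mc=mc)
        pair.validate()
        pairs.append(pair)

    census = []
    for _, row in clean(xl["census"]).iterrows():
        rec = CensusRecord(
            census_id=row["census_id"],
            date=date.fromisoformat(row["date"]),
            female=row["female"],
            state=row["state"],
            partners=frozenset(p for p in row["partners"].split(";") if p),
        )
        rec.validate()
        census.append(rec)
    return pairs, census
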