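"""Attracted/dispersed/neutral classification and derived summaries.

Each 5-min session is divided into five one-minute timeframes (half-open
bins: minute m covers t in [60(m-1), 60m)).  A pair is *attracted* when the
first affiliative behavior comes only in, or earlier in, the PC session than
in the MC; *dispersed* symmetrically; *neutral* when tied or absent in both.
Per-timeframe labels attribute the pair to the minute of its earlier first
affiliation, so the per-timeframe categories partition the pair-level ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .behavior_io import PCMCPair, Session, ValidationError

VOCAL_RANGE_M = 5.0
MINUTES = (1, 2, 3, 4, 5)

OPPONENT_ONLY = "opponent_only"
ANY_PARTNER = "any_partner"


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Proportion as a percentage, rounded — the report's proportion routine."""
    if denominator == 0:
        raise ZeroDivisionError("proportion with zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def _qualifying_affiliative(ev, focal: str, scope: str, opponent: str) -> bool:
    if not ev.is_affiliative or not ev.involves(focal):
        return False
    other = ev.other_party(focal)
    if scope == OPPONENT_ONLY and other != opponent:
        return False
    if ev.behavior == "vocalization":
        if ev.distance_m is None or ev.oriented_at_recipient is None:
            raise ValidationError(
                f"session {ev.session_id}: vocalization lacks orientation/distance"
            )
        return bool(ev.oriented_at_recipient) and ev.distance_m <= VOCAL_RANGE_M
    return True


def first_affiliation_time(session: Session, scope: str) -> float | None:
    """Time (s) of the first qualifying affiliative event, or None."""
    for ev in session.events:
        if _qualifying_affiliative(ev, session.focal, scope, session.opponent):
            return ev.t
    return None


def first_affiliation_minute(session: Session, scope: str) -> int | None:
    """Minute (1..5) of the first qualifying affiliative event, or None.

    Scope is ``opponent_only`` (PC convention) or ``any_partner`` (MC
    convention).  Qualifying events: contact, groom give/receive, approach,
    or a vocalization oriented at its recipient within 5 m, with the focal
    as actor or recipient.
    """
    t = first_affiliation_time(session, scope)
    return None if t is None else int(t // 60) + 1


def classify_pair_at_timeframe(
    pc_minute: int | None, mc_minute: int | None, t: int
) -> str:
    """Label one PC-MC pair at timeframe ``t`` (1..5).

    Attracted at t iff the PC first affiliation falls in minute t and the MC
    first affiliation is absent or later; dispersed symmetrically; neutral
    otherwise (ties at t included).
    """
    if t not in MINUTES:
        raise ValueError(f"timeframe {t} not in 1..5")
    for m, name in ((pc_minute, "pc_minute"), (mc_minute, "mc_minute")):
        if m is not None and m not in MINUTES:
            raise ValueError(f"{name}={m} not in 1..5")
    if pc_minute == t and (mc_minute is None or mc_minute > t):
        return "attracted"
    if mc_minute == t and (pc_minute is None or pc_minute > t):
        return "dispersed"
    return "neutral"


def classify_pair(pc_minute: int | None, mc_minute: int | None) -> str:
    """Pair-level label from first-affiliation minutes (absent = never)."""
    pc = pc_minute if pc_minute is not None else 99
    mc = mc_minute if mc_minute is not None else 99
    if pc < mc:
        return "attracted"
    if mc < pc:
        return "dispersed"
    return "neutral"


@dataclass(frozen=True)
class PairClassification:
    """Minute-of-first-affiliation and labels for one PC-MC pair."""

    pair_id: str
    subject: str
    role: str
    pc_minute: int | None
    mc_minute: int | None
    overall: str
    per_timeframe: tuple[str, str, str, str, str]


def classify_pairs(
    pairs: list[PCMCPair],
    pc_scope: str = OPPONENT_ONLY,
    mc_scope: str = ANY_PARTNER,
) -> list[PairClassification]:
    """Classify every pair at the pair level and at all five timeframes.

    The PC/MC scope asymmetry (opponent-only in PC, any partner in MC) is
    the default and is deliberate; override only via the scope arguments.
    """
    out = []
    for p in pairs:
        pc_m = first_affiliation_minute(p.pc, pc_scope)
        mc_m = first_affiliation_minute(p.mc, mc_scope)
        out.append(
            PairClassification(
                pair_id=p.pair_id,
                subject=p.focal,
                role=p.focal_role,
                pc_minute=pc_m,
                mc_minute=mc_m,
                overall=classify_pair(pc_m, mc_m),
                per_timeframe=tuple(
                    classify_pair_at_timeframe(pc_m, mc_m, t) for t in MINUTES
                ),
            )
        )
    return out


@dataclass
class SubjectProportions:
    """Per-subject summaries over that subject's classified pairs."""

    subject: str
    n_pairs: int
    attracted_by_timeframe: tuple[float, ...]
    dispersed_by_timeframe: tuple[float, ...]
    attracted_overall: float
    dispersed_overall: float
    conciliatory_tendency: float = field(init=False)

    def __post_init__(self) -> None:
        self.conciliatory_tendency = self.attracted_overall - self.dispersed_overall


def subject_proportions(
    classifications: list[PairClassification], min_pairs: int = 3
) -> list[SubjectProportions]:
    """Per-subject attracted/dispersed proportions; subjects with fewer than
    ``min_pairs`` pairs are excluded."""
    if not classifications:
        warnings.warn("no classified pairs supplied", stacklevel=2)
        return []
    by_subject: dict[str, list[PairClassification]] = {}
    for c in classifications:
        by_subject.setdefault(c.subject, []).append(c)
    out = []
    for subject in sorted(by_subject):
        cs = by_subject[subject]
        n = len(cs)
        if n < min_pairs:
            continue
        att_tf = tuple(
            sum(c.per_timeframe[t - 1] == "attracted" for c in cs) / n for t in MINUTES
        )
        dis_tf = tuple(
            sum(c.per_timeframe[t - 1] == "dispersed" for c in cs) / n for t in MINUTES
        )
        out.append(
            SubjectProportions(
                subject=subject,
                n_pairs=n,
                attracted_by_timeframe=att_tf,
                dispersed_by_timeframe=dis_tf,
                attracted_overall=sum(c.overall == "attracted" for c in cs) / n,
                dispersed_overall=sum(c.overall == "dispersed" for c in cs) / n,
            )
        )
    return out


def pooled_proportions(
    classifications: list[PairClassification],
) -> dict[str, tuple[float, ...]]:
    """Pooled-over-pairs variant of the per-timeframe proportions.

    The default analysis averages within subjects first; this variant pools
    all pairs and is exposed as an alternative reading.  Returns
    ``{"attracted": (p1..p5), "dispersed": (p1..p5)}``.
    """
    if not classifications:
        raise ValueError("no classified pairs supplied")
    n = len(classifications)
    return {
        "attracted": tuple(
            sum(c.per_timeframe[t - 1] == "attracted" for c in classifications) / n
            for t in MINUTES
        ),
        "dispersed": tuple(
            sum(c.per_timeframe[t - 1] == "dispersed" for c in classifications) / n
            for t in MINUTES
        ),
    }


def conciliatory_tendency(props: list[SubjectProportions]) -> float:
    """Group conciliatory tendency: unweighted mean over subjects of
    (attracted − dispersed) / n pairs."""
    if not props:
        raise ValueError("no subjects supplied")
    return sum(p.conciliatory_tendency for p in props) / len(props)


def vocal_given(session: Session, scope: str = OPPONENT_ONLY) -> bool:
    """True iff the focal gave a vocalization oriented at a scope-eligible
    recipient within 5 m."""
    for ev in session.events:
        if ev.behavior != "vocalization" or ev.actor != session.focal:
            continue
        if ev.distance_m is None or ev.oriented_at_recipient is None:
            raise ValidationError(
                f"session {ev.session_id}: vocalization lacks orientation/distance"
            )
        if scope == OPPONENT_ONLY and ev.recipient != session.opponent:
            continue
        if ev.oriented_at_recipient and ev.distance_m <= VOCAL_RANGE_M:
            return True
    return False


def aggression_exposure(session: Session, affiliation_t: float | None) -> bool:
    """Did the focal receive aggression from the opponent in the exposure window?

    If affiliation with the opponent occurred (``affiliation_t`` in seconds),
    aggression is counted from that moment to session end; otherwise over the
    whole session excluding the first minute.
    """
    if session.kind != "PC":
        raise ValueError("aggression exposure is defined for PC sessions")
    start = affiliation_t if affiliation_t is not None else 60.0
    return any(
        ev.is_aggressive
        and ev.actor == session.opponent
        and ev.recipient == session.focal
        and ev.t >= start
        for ev in session.events
    )


def received_aggression_any(session: Session) -> bool:
    """Did the focal receive aggression from any individual in the session?"""
    return any(
        ev.is_aggressive and ev.recipient == session.focal for ev in session.events
    )


def affiliation_behavior_type(session: Session, scope: str = OPPONENT_ONLY) -> str | None:
    """Three-level type of the session's affiliative interaction.

    Returns ``vocal_only``, ``vocal_with_contact_or_approach``,
    ``contact_or_approach_only``, or None when no affiliation occurred.
    """
    has_vocal = any(
        ev.behavior == "vocalization"
        and _qualifying_affiliative(ev, session.focal, scope, session.opponent)
        for ev in session.events
    )
    has_nonvocal = any(
        ev.is_affiliative
        and ev.behavior != "vocalization"
        and _qualifying_affiliative(ev, session.focal, scope, session.opponent)
        for ev in session.events
    )
    if has_vocal and has_nonvocal:
        return "vocal_with_contact_or_approach"
    if has_vocal:
        return "vocal_only"
    if has_nonvocal:
        return "contact_or_approach_only"
    return None
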