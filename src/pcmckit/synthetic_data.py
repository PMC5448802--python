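"""Seeded generator of complete synthetic datasets with known ground truth.

Produces populations (linear hierarchy, win matrix, dyadic familiarity),
event-level PC-MC session pairs, and line-census records, so that every
pipeline stage can be tested end to end without any external data.  All
randomness flows from one ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta

import numpy as np
from scipy.special import expit, logit

from .behavior_io import CensusRecord, EventRecord, PCMCPair, Session
from .dominance import WinMatrix

__all__ = [
    "SimulationConfig",
    "Population",
    "GroundTruth",
    "simulate_population",
    "simulate_sessions",
    "simulate_census",
    "simulate_dataset",
    "simulate_binary_table",
]


@dataclass
class SimulationConfig:
    """Knobs for the synthetic scenario; defaults give a small fast dataset.

    ``paper_scale()`` returns a scenario sized like the field study
    (~90 females, ~600 pairs, 172 census sessions); ``null()`` makes the PC
    affiliation process identical to the MC process so that attracted and
    dispersed proportions are exchangeable.
    """

    n_females: int = 12
    n_conflicts: int = 60
    # hierarchy / win matrix
    dyad_observation_prob: float = 1.0
    wins_per_dyad: float = 3.0
    # conflict attributes
    p_physical: float = 0.3
    p_counter: float = 0.15
    p_victim_subordinate: float = 0.9
    # familiarity ground truth: point mass at 0, Beta tail otherwise
    familiarity_zero_mass: float = 0.6
    familiarity_beta: tuple[float, float] = (1.5, 4.0)
    familiarity_scale: float = 0.73
    # per-minute logit of affiliation with the opponent in PC
    pc_affiliation_intercept: float = -3.2
    pc_affiliation_familiarity: float = 3.0
    pc_affiliation_rankdiff: float = 0.0
    pc_affiliation_counter: float = -1.2
    pc_minute1_boost: float = 1.2
    # per-minute probability of affiliation with any partner in MC
    mc_affiliation_hazard: float = 0.045
    # vocal use given affiliation: logit = intercept + slope * familiarity
    vocal_intercept: float = 0.4
    vocal_familiarity_slope: float = -3.0
    mc_vocal_prob: float = 0.12
    # renewed aggression from the opponent, by PC state
    p_renewed_no_affiliation: float = 0.06
    p_renewed_affiliation_vocal: float = 0.12
    p_renewed_affiliation_novocal: float = 0.18
    # background aggression from third parties (drives the PC/MC contrast)
    p_background_aggression_pc: float = 0.05
    p_background_aggression_mc: float = 0.03
    # census
    census_sessions: int = 40
    detectability: float = 0.85
    detectability_overrides: dict[str, float] = field(default_factory=dict)
    proximity_scale: float = 1.0
    start: date = date(2013, 3, 1)
    span_days: int = 720

    def validate(self) -> None:
        if self.n_females < 3:
            raise ValueError("n_females must be >= 3")
        probs = {
            "dyad_observation_prob": self.dyad_observation_prob,
            "p_physical": self.p_physical,
            "p_counter": self.p_counter,
            "p_victim_subordinate": self.p_victim_subordinate,
            "familiarity_zero_mass": self.familiarity_zero_mass,
            "mc_affiliation_hazard": self.mc_affiliation_hazard,
            "mc_vocal_prob": self.mc_vocal_prob,
            "p_renewed_no_affiliation": self.p_renewed_no_affiliation,
            "p_renewed_affiliation_vocal": self.p_renewed_affiliation_vocal,
            "p_renewed_affiliation_novocal": self.p_renewed_affiliation_novocal,
            "p_background_aggression_pc": self.p_background_aggression_pc,
            "p_background_aggression_mc": self.p_background_aggression_mc,
            "detectability": self.detectability,
        }
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def null(cls, **kwargs) -> "SimulationConfig":
        """PC affiliation process identical to the MC process (no
        reconciliation effect): conciliatory tendency converges to 0."""
        hazard = kwargs.pop("mc_affiliation_hazard", 0.045)
        return cls(
            pc_affiliation_intercept=float(logit(hazard)),
            pc_affiliation_familiarity=0.0,
            pc_affiliation_rankdiff=0.0,
            pc_affiliation_counter=0.0,
            pc_minute1_boost=0.0,
            mc_affiliation_hazard=hazard,
            **kwargs,
        )

    @classmethod
    def paper_scale(cls, **kwargs) -> "SimulationConfig":
        defaults = dict(n_females=90, n_conflicts=605, census_sessions=172)
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass
class Population:
    ids: list[str]
    ranks: dict[str, int]
    familiarity: dict[tuple[str, str], float]  # symmetric, both orders present
    win_matrix: WinMatrix


@dataclass
class GroundTruth:
    ranks: dict[str, int]
    familiarity: dict[tuple[str, str], float]
    config: SimulationConfig

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["start"] = self.config.start.isoformat()
        return {
            "ranks": self.ranks,
            "familiarity": {f"{a}|{b}": v for (a, b), v in self.familiarity.items()},
            "config": cfg,
        }


def simulate_population(config: SimulationConfig, seed: int) -> Population:
    """Linear hierarchy, win matrix consistent with it, and ground-truth
    familiarity drawn from the configured zero-inflated Beta mixture."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_females
    width = max(2, int(math.ceil(math.log10(n + 1))))
    ids = [f"F{i + 1:0{width}d}" for i in range(n)]
    ranks = {f: i + 1 for i, f in enumerate(ids)}

    wins = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < config.dyad_observation_prob:
                wins[i, j] = 1 + rng.poisson(config.wins_per_dyad)

    fam: dict[tuple[str, str], float] = {}
    a_, b_ = config.familiarity_beta
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < config.familiarity_zero_mass:
                f = 0.0
            else:
                f = float(rng.beta(a_, b_) * config.familiarity_scale)
            fam[(ids[i], ids[j])] = f
            fam[(ids[j], ids[i])] = f

    return Population(
        ids=ids, ranks=ranks, familiarity=fam,
        win_matrix=WinMatrix(individuals=ids, wins=wins),
    )


def _uniform_in_minute(rng, minute: int) -> float:
    return round(float(rng.uniform(60.0 * (minute - 1), 60.0 * minute - 1e-6)), 6)


def _affiliation_events(
    rng, session_id: str, focal: str, partner: str, t: float, vocal: bool,
    with_nonvocal: bool,
) -> list[EventRecord]:
    events = []
    if vocal:
        events.append(
            EventRecord(
                session_id=session_id, t=t, actor=focal, recipient=partner,
                behavior="vocalization",
                oriented_at_recipient=True,
                distance_m=round(float(rng.uniform(0.5, 5.0)), 6),
            )
        )
        if with_nonvocal:
            t2 = round(min(t + float(rng.uniform(1.0, 10.0)), 299.9), 6)
            events.append(
                EventRecord(
                    session_id=session_id, t=t2, actor=focal, recipient=partner,
                    behavior=str(rng.choice(["contact", "approach"])),
                )
            )
    else:
        events.append(
            EventRecord(
                session_id=session_id, t=t, actor=focal, recipient=partner,
                behavior=str(rng.choice(["contact", "approach", "groom_give"])),
            )
        )
    return events


def simulate_sessions(
    population: Population, config: SimulationConfig, seed: int
) -> list[PCMCPair]:
    """Event-level PC-MC pairs for ``n_conflicts`` simulated conflicts.

    PC affiliation with the opponent follows the configured per-minute
    logistic hazard; MC affiliation with any partner follows a constant
    hazard; vocal use given affiliation follows the vocal model; renewed
    aggression follows the per-state probabilities.  All pair invariants
    (timing windows, shared conflict attributes) hold by construction.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    ids = population.ids
    ranks = population.ranks
    pairs: list[PCMCPair] = []

    for c in range(config.n_conflicts):
        i, j = rng.choice(len(ids), size=2, replace=False)
        a, b = ids[i], ids[j]
        dominant, subordinate = (a, b) if ranks[a] < ranks[b] else (b, a)
        if rng.random() < config.p_victim_subordinate:
            aggressor, victim = dominant, subordinate
        else:
            aggressor, victim = subordinate, dominant
        focal_role = "aggressor" if c % 2 == 0 else "victim"
        focal = aggressor if focal_role == "aggressor" else victim
        opponent = victim if focal_role == "aggressor" else aggressor

        physical = bool(rng.random() < config.p_physical)
        counter = bool(rng.random() < config.p_counter)
        fam = population.familiarity[(focal, opponent)]
        rd = ranks[focal] - ranks[opponent]

        day = int(rng.integers(0, max(1, config.span_days - 15)))
        hour = int(rng.integers(9, 17))
        minute_of_day = int(rng.integers(0, 60))
        pc_dt = datetime.combine(
            config.start + timedelta(days=day), datetime.min.time()
        ) + timedelta(hours=hour, minutes=minute_of_day)

        pc_id = f"C{c + 1:04d}PC"
        mc_id = f"C{c + 1:04d}MC"

        # --- PC session -----------------------------------------------------
        pc_events: list[EventRecord] = []
        base_logit = (
            config.pc_affiliation_intercept
            + config.pc_affiliation_familiarity * fam
            + config.pc_affiliation_rankdiff * rd
            + config.pc_affiliation_counter * counter
        )
        affil_minute = None
        for m in range(1, 6):
            lp = base_logit + (config.pc_minute1_boost if m == 1 else 0.0)
            if rng.random() < expit(lp):
                affil_minute = m
                break
        affil_t = None
        vocal = False
        if affil_minute is not None:
            affil_t = _uniform_in_minute(rng, affil_minute)
            vocal = bool(
                rng.random()
                < expit(config.vocal_intercept + config.vocal_familiarity_slope * fam)
            )
            pc_events.extend(
                _affiliation_events(
                    rng, pc_id, focal, opponent, affil_t, vocal,
                    with_nonvocal=bool(rng.random() < 0.6),
                )
            )
        if affil_minute is None:
            p_renew = config.p_renewed_no_affiliation
        elif vocal:
            p_renew = config.p_renewed_affiliation_vocal
        else:
            p_renew = config.p_renewed_affiliation_novocal
        if rng.random() < p_renew:
            lo = affil_t if affil_t is not None else 60.0
            t_aggr = round(float(rng.uniform(lo, 299.9)), 6)
            pc_events.append(
                EventRecord(
                    session_id=pc_id, t=t_aggr, actor=opponent, recipient=focal,
                    behavior="aggression_physical" if rng.random() < 0.3
                    else "aggression_nonphysical",
                )
            )
        if rng.random() < config.p_background_aggression_pc:
            third = _pick_third(rng, ids, focal, opponent)
            pc_events.append(
                EventRecord(
                    session_id=pc_id, t=round(float(rng.uniform(0, 299.9)), 6),
                    actor=third, recipient=focal, behavior="aggression_nonphysical",
                )
            )

        # --- MC session -----------------------------------------------------
        mc_events: list[EventRecord] = []
        mc_minute = None
        for m in range(1, 6):
            if rng.random() < config.mc_affiliation_hazard:
                mc_minute = m
                break
        if mc_minute is not None:
            partner = _pick_third(rng, ids, focal, opponent)
            t_mc = _uniform_in_minute(rng, mc_minute)
            mc_vocal = bool(rng.random() < config.mc_vocal_prob)
            mc_events.extend(
                _affiliation_events(
                    rng, mc_id, focal, partner, t_mc, mc_vocal,
                    with_nonvocal=bool(rng.random() < 0.6),
                )
            )
        if rng.random() < config.p_background_aggression_mc:
            third = _pick_third(rng, ids, focal, opponent)
            mc_events.append(
                EventRecord(
                    session_id=mc_id, t=round(float(rng.uniform(0, 299.9)), 6),
                    actor=third, recipient=focal, behavior="aggression_nonphysical",
                )
            )

        mc_dt = pc_dt + timedelta(
            days=int(rng.integers(1, 8)), minutes=int(rng.integers(-90, 91))
        )

        pc = Session(
            session_id=pc_id, kind="PC", focal=focal, opponent=opponent,
            focal_role=focal_role, date_time=pc_dt,
            conflict_physical=physical, conflict_counter=counter,
            events=sorted(pc_events, key=lambda e: e.t),
        )
        mc = Session(
            session_id=mc_id, kind="MC", focal=focal, opponent=opponent,
            focal_role=focal_role, date_time=mc_dt,
            conflict_physical=physical, conflict_counter=counter,
            events=sorted(mc_events, key=lambda e: e.t),
        )
        pair = PCMCPair(pair_id=f"P{c + 1:04d}", pc=pc, mc=mc)
        pair.validate()
        pairs.append(pair)
    return pairs


def _pick_third(rng, ids: list[str], focal: str, opponent: str) -> str:
    others = [x for x in ids if x not in (focal, opponent)]
    return str(others[int(rng.integers(0, len(others)))])


def simulate_census(
    population: Population, config: SimulationConfig, seed: int
) -> list[CensusRecord]:
    """Line-census records whose familiarity estimator converges to the
    ground truth (scaled by ``proximity_scale``) as sessions grow."""
    config.validate()
    rng = np.random.default_rng(seed)
    ids = population.ids
    records: list[CensusRecord] = []
    n_days = max(config.census_sessions, 1)
    for s in range(config.census_sessions):
        day = int(round(s * (config.span_days - 1) / n_days))
        census_id = f"S{s + 1:05d}"
        d = config.start + timedelta(days=day)
        recorded = [
            f
            for f in ids
            if rng.random()
            < config.detectability_overrides.get(f, config.detectability)
        ]
        proximate: set[frozenset[str]] = set()
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                p = min(1.0, population.familiarity[(a, b)] * config.proximity_scale)
                if p > 0 and rng.random() < p:
                    proximate.add(frozenset((a, b)))
        for f in recorded:
            partners = frozenset(
                g for g in ids if g != f and frozenset((f, g)) in proximate
            )
            records.append(
                CensusRecord(
                    census_id=census_id, date=d, female=f,
                    state="social" if partners else "alone",
                    partners=partners,
                )
            )
    return records


def simulate_dataset(
    config: SimulationConfig, seed: int
) -> tuple[Population, list[PCMCPair], list[CensusRecord], GroundTruth]:
    """Convenience wrapper: population + sessions + census from one seed."""
    ss = np.random.SeedSequence(seed).spawn(3)
    pop_seed, sess_seed, census_seed = (int(s.generate_state(1)[0]) for s in ss)
    population = simulate_population(config, pop_seed)
    pairs = simulate_sessions(population, config, sess_seed)
    census = simulate_census(population, config, census_seed)
    truth = GroundTruth(
        ranks=population.ranks, familiarity=population.familiarity, config=config
    )
    return population, pairs, census, truth


def simulate_binary_table(
    n_rows: int,
    n_subjects: int,
    n_opponents: int,
    beta: tuple[float, float],
    subject_sd: float,
    opponent_sd: float,
    seed: int,
):
    """Logistic table with crossed random intercepts for GLMM calibration.

    ``beta`` is (intercept, slope on a standard-normal covariate ``x``).
    Returns a DataFrame with columns subject, opponent, role, x, y.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    subj = rng.integers(0, n_subjects, size=n_rows)
    opp = rng.integers(0, n_opponents, size=n_rows)
    u = rng.normal(0.0, subject_sd, size=n_subjects)
    v = rng.normal(0.0, opponent_sd, size=n_opponents)
    x = rng.normal(size=n_rows)
    eta = beta[0] + beta[1] * x + u[subj] + v[opp]
    y = (rng.random(n_rows) < expit(eta)).astype(float)
    return pd.DataFrame(
        {
            "subject": [f"S{i:03d}" for i in subj],
            "opponent": [f"O{i:03d}" for i in opp],
            "role": "victim",
            "x": x,
            "y": y,
        }
    )
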