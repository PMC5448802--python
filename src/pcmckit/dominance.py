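"""Dominance rank inference, Landau linearity, and de Vries' improved h'.

Dyad direction is decided by majority of wins; equal nonzero counts give a
tied dyad and zero interactions an unknown dyad.  Rank ordering minimizes
the number, then the strength, of inconsistencies (entries where a
lower-ranked individual beats a higher-ranked one): exhaustive search for
N <= 8, simulated annealing above (the exhaustive path doubles as the test
oracle).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WinMatrix",
    "rank_order",
    "landau_h",
    "devries_h_prime",
    "rank_difference",
    "read_win_matrix",
    "write_win_matrix",
]

_EXHAUSTIVE_N = 8


@dataclass
class WinMatrix:
    """Square matrix of dyadic outcomes: wins[i][j] = times i beat j."""

    individuals: list[str]
    wins: np.ndarray

    def __post_init__(self) -> None:
        self.wins = np.asarray(self.wins)
        n = len(self.individuals)
        if self.wins.shape != (n, n):
            raise ValueError(f"wins shape {self.wins.shape} != ({n}, {n})")
        if np.any(np.diag(self.wins) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.wins < 0) or not np.issubdtype(self.wins.dtype, np.integer):
            raise ValueError("win counts must be nonnegative integers")

    @property
    def n(self) -> int:
        return len(self.individuals)

    def dominance_signs(self) -> np.ndarray:
        """+1 where row dominates column, -1 where dominated, 0 tied/unknown."""
        return np.sign(self.wins - self.wins.T)


@dataclass
class DominanceModel:
    ranks: dict[str, int]  # 1 = most dominant
    h: float
    h_prime: float
    p_linearity: float
    unobserved: list[str]


def _inconsistencies(signs: np.ndarray, order: np.ndarray) -> tuple[int, int]:
    """(count, strength) of dominance entries pointing up the order."""
    s = signs[np.ix_(order, order)]
    lower = np.tril(s, k=-1)  # rows below columns in the candidate order
    bad = lower > 0  # a lower-ranked animal dominating a higher-ranked one
    count = int(bad.sum())
    i_idx, j_idx = np.nonzero(bad)
    strength = int((i_idx - j_idx).sum())
    return count, strength


def rank_order(w: WinMatrix, seed: int = 0) -> tuple[dict[str, int], list[str]]:
    """Inconsistency-minimizing rank assignment (1 = most dominant).

    Individuals with no interactions at all are placed last and returned in
    the flagged list.  Exhaustive for N <= 8; simulated annealing (seeded,
    deterministic) above.  Ties broken by id.
    """
    if w.n < 2:
        raise ValueError("need at least two individuals")
    signs = w.dominance_signs()
    interacting = [
        i for i in range(w.n) if (w.wins[i].sum() + w.wins[:, i].sum()) > 0
    ]
    isolated = [i for i in range(w.n) if i not in interacting]

    sub = np.ix_(interacting, interacting)
    sub_signs = signs[sub]
    k = len(interacting)
    if k <= 1:
        best = np.arange(k)
    elif k <= _EXHAUSTIVE_N:
        best, best_cost = None, None
        for perm in itertools.permutations(range(k)):
            order = np.array(perm)
            cost = _inconsistencies(sub_signs, order)
            key = cost + (tuple(w.individuals[interacting[i]] for i in order),)
            if best is None or key < best_cost:
                best, best_cost = order, key
        assert best is not None
    else:
        best = _anneal_order(sub_signs, seed)

    ordered = [interacting[i] for i in best] + sorted(
        isolated, key=lambda i: w.individuals[i]
    )
    ranks = {w.individuals[i]: r + 1 for r, i in enumerate(ordered)}
    return ranks, [w.individuals[i] for i in isolated]


def _anneal_order(signs: np.ndarray, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n = signs.shape[0]
    # start from win-fraction ordering
    wins_above = (signs > 0).sum(axis=1)
    order = np.argsort(-wins_above, kind="stable")
    cost = _inconsistencies(signs, order)
    best_order, best_cost = order.copy(), cost
    temp = 2.0
    for sweep in range(400):
        for _ in range(n):
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            cand = order.copy()
            cand[i], cand[j] = cand[j], cand[i]
            c = _inconsistencies(signs, cand)
            delta = (c[0] - cost[0]) * 1000 + (c[1] - cost[1])
            if delta <= 0 or rng.random() < np.exp(-delta / max(temp, 1e-9)):
                order, cost = cand, c
                if (cost[0], cost[1]) < (best_cost[0], best_cost[1]):
                    best_order, best_cost = order.copy(), cost
        temp *= 0.985
    return best_order


def landau_h(w: WinMatrix | np.ndarray) -> float:
    """Landau's linearity h = 12/(N^3 - N) * sum_i (V_i - (N-1)/2)^2,
    where V_i counts the individuals i strictly dominates."""
    signs = w.dominance_signs() if isinstance(w, WinMatrix) else np.sign(w)
    n = signs.shape[0]
    if n < 3:
        raise ValueError("h undefined for N < 3")
    v = (signs > 0).sum(axis=1)
    return float(12.0 / (n**3 - n) * ((v - (n - 1) / 2.0) ** 2).sum())


def devries_h_prime(
    w: WinMatrix, n_randomizations: int = 10_000, seed: int | None = None
) -> tuple[float, float]:
    """Improved linearity index h' with two-step randomization.

    Step 1: unknown and tied dyads are resolved by fair coin in each of
    ``n_randomizations`` replicates; h' is the mean h over replicates.
    Step 2: p is the fraction of fully random tournaments of the same size
    whose h meets or exceeds h'.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    rng = np.random.default_rng(seed)
    signs = w.dominance_signs()
    n = w.n
    iu = np.triu_indices(n, k=1)
    undecided = signs[iu] == 0
    n_undecided = int(undecided.sum())

    if n_undecided == 0:
        h_prime = landau_h(w)
    else:
        hs = np.empty(n_randomizations)
        for r in range(n_randomizations):
            s = signs.copy()
            coin = rng.integers(0, 2, size=n_undecided) * 2 - 1
            upper = s[iu].copy()
            upper[undecided] = coin
            s[iu] = upper
            s.T[iu] = -upper
            hs[r] = landau_h(s)
        h_prime = float(hs.mean())

    rand_hs = np.empty(n_randomizations)
    m = iu[0].size
    for r in range(n_randomizations):
        s = np.zeros((n, n))
        coin = rng.integers(0, 2, size=m) * 2 - 1
        s[iu] = coin
        s.T[iu] = -coin
        rand_hs[r] = landau_h(s)
    p_linearity = float((rand_hs >= h_prime - 1e-12).mean())
    return h_prime, p_linearity


def read_win_matrix(path) -> WinMatrix:
    """Win-matrix CSV: first column = winner id, remaining columns = losers."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column ids disagree")
    return WinMatrix(
        individuals=[str(i) for i in df.index],
        wins=df.to_numpy(dtype=np.int64),
    )


def write_win_matrix(w: WinMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(w.wins, index=w.individuals, columns=w.individuals).to_csv(path)


def rank_difference(subject_rank: int, opponent_rank: int) -> int:
    """Subject's absolute rank minus the opponent's; positive means the
    subject is subordinate."""
    for r in (subject_rank, opponent_rank):
        if r is None or r < 1:
            raise ValueError(f"invalid rank {r!r}")
    return int(subject_rank) - int(opponent_rank)
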