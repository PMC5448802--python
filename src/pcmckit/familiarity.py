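"""Directional dyadic familiarity indices from line-census records.

The index of A with B is the number of census sessions in which A was in
contact with or within 3 m of B, divided by the number of sessions in which
A was recorded at all.  It is directional (the two denominators differ) and
*undefined* — never zero — for females absent from the census.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
from scipy.stats import pearsonr

from .behavior_io import CensusRecord

DEFAULT_PERIOD_BOUNDARY = date(2014, 4, 1)


@dataclass
class FamiliarityMatrix:
    """Directional familiarity indices for one observation period."""

    period: str
    index: dict[tuple[str, str], float]
    denominator: dict[str, int]

    def get(self, a: str, b: str) -> float | None:
        """Index of A with B, or None when undefined (A never recorded)."""
        if self.denominator.get(a, 0) == 0:
            return None
        return self.index.get((a, b), 0.0)


def familiarity_index(
    census: list[CensusRecord],
    a: str,
    b: str,
    period: tuple[date, date] | None = None,
) -> float | None:
    """Fraction of A's census sessions in which B was a contact/proximity
    partner of A.  None (undefined) if A was never recorded."""
    recs = _in_period(census, period)
    sessions_with_a = {r.census_id for r in recs if r.female == a}
    if not sessions_with_a:
        return None
    with_b = {
        r.census_id for r in recs if r.female == a and b in r.partners
    }
    return len(with_b) / len(sessions_with_a)


def _in_period(
    census: list[CensusRecord], period: tuple[date, date] | None
) -> list[CensusRecord]:
    if period is None:
        return census
    lo, hi = period
    return [r for r in census if lo <= r.date <= hi]


def familiarity_matrix(
    census: list[CensusRecord],
    period_label: str = "all",
    period: tuple[date, date] | None = None,
) -> FamiliarityMatrix:
    """All directional indices for one period in a single pass."""
    recs = _in_period(census, period)
    denom: dict[str, int] = {}
    numer: dict[tuple[str, str], int] = {}
    for r in recs:
        denom[r.female] = denom.get(r.female, 0) + 1
        for p in r.partners:
            key = (r.female, p)
            numer[key] = numer.get(key, 0) + 1
    index = {key: n / denom[key[0]] for key, n in numer.items()}
    return FamiliarityMatrix(period=period_label, index=index, denominator=denom)


def split_periods(
    census: list[CensusRecord], boundary: date = DEFAULT_PERIOD_BOUNDARY
) -> tuple[list[CensusRecord], list[CensusRecord]]:
    """Partition census records into two observation periods at ``boundary``
    (records dated strictly before the boundary fall in period 1)."""
    first = [r for r in census if r.date < boundary]
    second = [r for r in census if r.date >= boundary]
    return first, second


def period_correlation(
    m1: FamiliarityMatrix,
    m2: FamiliarityMatrix,
    dyads: list[tuple[str, str]] | None = None,
) -> tuple[float, int, float]:
    """Pearson correlation of dyadic indices defined in both periods.

    ``dyads`` restricts the universe (e.g. to dyads appearing in analyzed
    PC-MC pairs); by default every directional dyad defined in both periods
    enters.  Returns ``(r, n, p)``.
    """
    if dyads is None:
        keys = sorted(set(m1.index) | set(m2.index))
    else:
        keys = sorted(set(dyads))
    x, y = [], []
    for a, b in keys:
        v1, v2 = m1.get(a, b), m2.get(a, b)
        if v1 is None or v2 is None:
            continue
        x.append(v1)
        y.append(v2)
    n = len(x)
    if n < 3:
        raise ValueError(f"only {n} dyads defined in both periods (need >= 3)")
    x_arr, y_arr = np.asarray(x), np.asarray(y)
    if x_arr.std() == 0 or y_arr.std() == 0:
        raise ValueError("zero variance in one period's indices")
    r, p = pearsonr(x_arr, y_arr)
    return float(r), n, float(p)
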