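"""Exact Wilcoxon signed-rank test by shift recursion over sign assignments.

Zero differences are dropped before ranking; tied absolute differences get
midranks.  The null distribution is the exact permutation distribution of V
(sum of positive-difference ranks) over the 2^n equiprobable sign vectors,
conditional on the observed midranks — computed by a convolution (shift)
recursion, never a normal approximation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "SignedRankResult",
    "signed_rank_statistic",
    "exact_null_distribution",
    "enumerate_null_distribution",
    "exact_wilcoxon_test",
]


@dataclass(frozen=True)
class SignedRankResult:
    V: float
    n_effective: int
    n_zero: int
    p_two_sided: float
    method: str  # "exact-shift" | "degenerate"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            vmax = self.n_effective * (self.n_effective + 1) / 2
            if not (0 <= self.V <= vmax):
                raise ValueError(f"V={self.V} outside [0, {vmax}]")
        if not (0 < self.p_two_sided <= 1):
            raise ValueError(f"p={self.p_two_sided} outside (0, 1]")


def signed_rank_statistic(diffs) -> tuple[float, np.ndarray, int]:
    """V statistic plus the midrank vector of the nonzero |differences|.

    Returns ``(V, ranks, n_zero)`` where ``ranks`` aligns with the nonzero
    differences in input order.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference vector")
    nonzero = d[d != 0]
    n_zero = int(d.size - nonzero.size)
    if nonzero.size == 0:
        return 0.0, np.empty(0), n_zero
    ranks = rankdata(np.abs(nonzero))
    V = float(ranks[nonzero > 0].sum())
    return V, ranks, n_zero


def _half_units(ranks: np.ndarray) -> np.ndarray:
    """Midranks doubled to exact integers (half-integers are the only
    non-integer midranks possible)."""
    doubled = np.round(ranks * 2).astype(np.int64)
    if not np.allclose(doubled, ranks * 2, atol=1e-9):
        raise ValueError("ranks are not half-integers")
    return doubled


def exact_null_distribution(rank_magnitudes) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of V under equiprobable sign assignments.

    Returns ``(support, pmf)``; ``support`` is the sorted achievable V
    values and ``pmf`` sums to 1.  Computed by the shift recursion: cost
    O(n * total), equivalent to full 2^n enumeration.
    """
    ranks = np.asarray(rank_magnitudes, dtype=float)
    if ranks.size == 0:
        raise ValueError("empty rank vector")
    units = _half_units(ranks)
    total = int(units.sum())
    # counts[s] = number of sign vectors with doubled-V equal to s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for u in units:
        shifted = np.zeros_like(counts)
        shifted[u:] = counts[: total + 1 - u]
        counts = counts + shifted
    pmf_all = counts / 2.0 ** len(units)
    support_2v = np.nonzero(counts)[0]
    return support_2v / 2.0, pmf_all[support_2v]


def enumerate_null_distribution(rank_magnitudes) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force 2^n enumeration of the null pmf (test oracle; n <= ~16)."""
    ranks = np.asarray(rank_magnitudes, dtype=float)
    if ranks.size == 0:
        raise ValueError("empty rank vector")
    if ranks.size > 20:
        raise ValueError("enumeration oracle limited to n <= 20")
    sums: dict[float, int] = {}
    for signs in itertools.product((0, 1), repeat=len(ranks)):
        v = float(sum(r for r, s in zip(ranks, signs) if s))
        sums[v] = sums.get(v, 0) + 1
    support = np.array(sorted(sums))
    pmf = np.array([sums[v] for v in support], dtype=float) / 2.0 ** len(ranks)
    return support, pmf


def _two_sided_p(
    support: np.ndarray, pmf: np.ndarray, v_obs: float, convention: str
) -> float:
    lower = pmf[support <= v_obs + 1e-9].sum()
    upper = pmf[support >= v_obs - 1e-9].sum()
    if convention == "doubled":
        return float(min(1.0, 2.0 * min(lower, upper)))
    if convention == "minlike":
        p_obs = pmf[np.isclose(support, v_obs)].sum()
        return float(min(1.0, pmf[pmf <= p_obs + 1e-12].sum()))
    raise ValueError(f"unknown two-sided convention {convention!r}")


def exact_wilcoxon_test(x, y, convention: str = "doubled") -> SignedRankResult:
    """Exact two-sided paired signed-rank test of x vs y.

    ``convention`` selects the two-sided rule: ``doubled`` (default) doubles
    the smaller tail and caps at 1; ``minlike`` sums all outcomes no more
    probable than the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty samples")
    V, ranks, n_zero = signed_rank_statistic(x - y)
    if ranks.size == 0:
        return SignedRankResult(
            V=0.0, n_effective=0, n_zero=n_zero, p_two_sided=1.0,
            method="degenerate", degenerate=True,
        )
    support, pmf = exact_null_distribution(ranks)
    p = _two_sided_p(support, pmf, V, convention)
    return SignedRankResult(
        V=V, n_effective=int(ranks.size), n_zero=n_zero,
        p_two_sided=p, method="exact-shift",
    )
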