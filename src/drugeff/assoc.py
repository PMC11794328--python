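"""Hypergeometric overlap scoring of bipartite network projections.

Two outer-layer nodes (e.g. a phenotype and a gene) that share neighbours in
a common middle layer (e.g. diseases) are scored with the hypergeometric
index (HyI): the -log10 of the upper-tail probability that two sets of the
observed sizes, drawn at random from the middle-layer population, share at
least the observed number of elements.  Higher index values mean the overlap
is less likely to be chance.  An index threshold of 2 corresponds to a
p-value of 0.01, and 3.5 to ~0.0003.

The tail probability is computed in log space (log-gamma binomial
coefficients combined with log-sum-exp) so that extremely significant
overlaps do not underflow to zero; the index is capped at 300.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import ContractError

log = logging.getLogger(__name__)

#: Cap on the hypergeometric index; p-values below 1e-300 are reported at
#: exactly this index with a warning (doubles underflow near 1e-308).
HYI_CAP = 300.0

_LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BipartiteEdges:
    """A deduplicated edge list for one layer pair of the tripartite network.

    Parameters
    ----------
    edges
        Set of ``(outer_id, middle_id)`` pairs.
    outer_role, middle_role
        Layer labels, e.g. ``"phenotype"``/``"disease"`` or
        ``"drug"``/``"target"``.  Projections require both operands to share
        the same ``middle_role``.
    extra_middles
        Middle-layer entities that belong to the population but have no edge
        in this list (isolated records); they enlarge the projection
        universe without creating pairs.
    """

    edges: frozenset[tuple[str, str]]
    outer_role: str
    middle_role: str
    extra_middles: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for o, m in self.edges:
            if not o or not m:
                raise ValueError(f"empty ID in edge ({o!r}, {m!r})")
        for m in self.extra_middles:
            if not m:
                raise ValueError("empty ID among extra middle entities")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        outer_role: str,
        middle_role: str,
        extra_middles: Iterable[str] = (),
    ) -> "BipartiteEdges":
        """Build from an iterable of pairs, deduplicating (and logging)."""
        raw = list(pairs)
        uniq = frozenset(raw)
        if len(raw) != len(uniq):
            log.info(
                "deduplicated %d duplicate %s-%s edges",
                len(raw) - len(uniq), outer_role, middle_role,
            )
        return cls(uniq, outer_role, middle_role, frozenset(extra_middles))

    @property
    def outers(self) -> set[str]:
        return {o for o, _ in self.edges}

    @property
    def middles(self) -> set[str]:
        return {m for _, m in self.edges} | set(self.extra_middles)

    def neighbours(self) -> dict[str, set[str]]:
        """Map outer node -> set of its middle-layer neighbours."""
        nb: dict[str, set[str]] = {}
        for o, m in self.edges:
            nb.setdefault(o, set()).add(m)
        return nb

    def flipped(self, new_outer_role: Optional[str] = None,
                new_middle_role: Optional[str] = None) -> "BipartiteEdges":
        """Swap outer and middle layers."""
        return BipartiteEdges(
            frozenset((m, o) for o, m in self.edges),
            new_outer_role or self.middle_role,
            new_middle_role or self.outer_role,
        )


@dataclass(frozen=True)
class OverlapScore:
    """Hypergeometric overlap record for one pair of outer-layer nodes.

    ``N`` is the middle-layer population size, ``size_a``/``size_b`` the two
    nodes' degrees, ``k`` the number of shared neighbours, ``p_value`` the
    upper-tail probability P(X >= k) and ``hyi`` its -log10.
    """

    a_id: str
    b_id: str
    N: int
    size_a: int
    size_b: int
    k: int
    p_value: float
    hyi: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.size_a, self.size_b)):
            raise ValueError(
                f"k={self.k} outside [0, min({self.size_a}, {self.size_b})]")
        if self.size_a > self.N or self.size_b > self.N:
            raise ValueError("set size exceeds population size")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


@dataclass(frozen=True)
class ScoredPairList:
    """An ordered list of :class:`OverlapScore` records.

    ``threshold_applied`` records the index threshold last used to filter the
    list (``None`` if unfiltered).
    """

    pairs: tuple[OverlapScore, ...]
    threshold_applied: Optional[float] = None

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def pair_set(self) -> set[tuple[str, str]]:
        return {(s.a_id, s.b_id) for s in self.pairs}

    def to_edges(self, outer_role: str, middle_role: str) -> BipartiteEdges:
        """Reinterpret the scored pairs as plain a->b edges."""
        return BipartiteEdges(
            frozenset((s.a_id, s.b_id) for s in self.pairs),
            outer_role, middle_role,
        )


# ---------------------------------------------------------------------------
# Probability machinery
# ---------------------------------------------------------------------------

def _check_hypergeom_args(k: int, size_a: int, size_b: int, N: int) -> None:
    if N < 0:
        raise ValueError(f"population size N={N} must be >= 0")
    if not (0 <= size_a <= N):
        raise ValueError(f"size_a={size_a} outside [0, N={N}]")
    if not (0 <= size_b <= N):
        raise ValueError(f"size_b={size_b} outside [0, N={N}]")
    if not (0 <= k <= min(size_a, size_b)):
        raise ValueError(
            f"k={k} outside [0, min(size_a={size_a}, size_b={size_b})]")


def _log_binom(n: np.ndarray | int, r: np.ndarray | int) -> np.ndarray:
    """Natural log of C(n, r), vectorised; assumes 0 <= r <= n."""
    n = np.asarray(n, dtype=float)
    r = np.asarray(r, dtype=float)
    return gammaln(n + 1.0) - gammaln(r + 1.0) - gammaln(n - r + 1.0)


def log_hypergeometric_upper_tail(k: int, size_a: int, size_b: int,
                                  N: int) -> float:
    """Natural log of P(X >= k) for X ~ Hypergeom(N, size_a, size_b).

    Summed in log space over the overlap range [k, min(size_a, size_b)] so
    that tails far below double-precision underflow remain usable.
    """
    _check_hypergeom_args(k, size_a, size_b, N)
    if k == 0:
        return 0.0
    i = np.arange(k, min(size_a, size_b) + 1)
    terms = (
        _log_binom(size_a, i)
        + _log_binom(N - size_a, size_b - i)
        - _log_binom(N, size_b)
    )
    return float(min(logsumexp(terms), 0.0))


def hypergeometric_upper_tail(k: int, size_a: int, size_b: int,
                              N: int) -> float:
    """P(X >= k): probability that two random subsets of sizes ``size_a``
    and ``size_b`` of an ``N``-element population share at least ``k``
    elements.

    Examples
    --------
    >>> hypergeometric_upper_tail(0, 4, 5, 10)
    1.0
    >>> round(hypergeometric_upper_tail(3, 3, 3, 6), 12)
    0.05
    """
    return math.exp(log_hypergeometric_upper_tail(k, size_a, size_b, N))


def hyi_from_p(p: float) -> float:
    """The hypergeometric index of a probability: ``-log10(p)``.

    ``hyi_from_p(0.01) == 2.0`` — an index threshold of 2 keeps pairs whose
    overlap has chance probability at most 1 in 100.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p={p} outside (0, 1]")
    return -math.log10(p) + 0.0  # +0.0 normalises -0.0 for p == 1


def p_from_hyi(hyi: float) -> float:
    """Invert the index back to a probability: ``10**-hyi``."""
    if hyi < 0:
        raise ValueError(f"index {hyi} must be >= 0")
    return 10.0 ** (-hyi)


def _score_from_log_p(a_id: str, b_id: str, N: int, size_a: int, size_b: int,
                      k: int, log_p: float) -> OverlapScore:
    hyi = -log_p / _LN10
    if hyi > HYI_CAP:
        log.warning("index for (%s, %s) capped at %g (p ~ 1e-%d)",
                    a_id, b_id, HYI_CAP, round(hyi))
        hyi = HYI_CAP
    p = math.exp(log_p)
    if p <= 0.0:  # underflow guard; consistent with the capped index
        p = 10.0 ** (-HYI_CAP)
    return OverlapScore(a_id, b_id, N, size_a, size_b, k, p, hyi)


# ---------------------------------------------------------------------------
# Projection and filtering
# ---------------------------------------------------------------------------

def project_and_score(
    left: BipartiteEdges,
    right: BipartiteEdges,
    universe: Optional[int] = None,
) -> ScoredPairList:
    """Project two edge lists sharing a middle layer into scored pairs.

    For every (left-outer, right-outer) pair with at least one shared
    middle-layer neighbour, emits an :class:`OverlapScore` with population
    ``N`` equal to the number of distinct middle entities across both lists
    (or the ``universe`` override).  Pairs with zero shared neighbours are
    never emitted.  Output is ordered by descending index, then
    lexicographically by the two IDs.
    """
    if left.middle_role != right.middle_role:
        raise ContractError(
            f"middle roles differ: {left.middle_role!r} vs "
            f"{right.middle_role!r}")
    left_nb = left.neighbours()
    right_nb = right.neighbours()
    n_union = len(left.middles | right.middles)
    N = n_union if universe is None else int(universe)
    if N < n_union:
        raise ValueError(
            f"universe override {N} smaller than the {n_union} middle "
            "entities present in the edge lists")

    # Invert the right list and count shared middles per (a, b) pair; this
    # touches only co-occurring pairs, never the full cross-product.
    mid_to_right: dict[str, list[str]] = {}
    for b, mids in right_nb.items():
        for m in mids:
            mid_to_right.setdefault(m, []).append(b)

    shared: Counter[tuple[str, str]] = Counter()
    for a, mids in left_nb.items():
        for m in mids:
            for b in mid_to_right.get(m, ()):
                shared[(a, b)] += 1

    scores = []
    for (a, b), k in shared.items():
        size_a = len(left_nb[a])
        size_b = len(right_nb[b])
        log_p = log_hypergeometric_upper_tail(k, size_a, size_b, N)
        scores.append(_score_from_log_p(a, b, N, size_a, size_b, k, log_p))
    scores.sort(key=lambda s: (-s.hyi, s.a_id, s.b_id))
    return ScoredPairList(tuple(scores))


def filter_by_threshold(pairs: ScoredPairList,
                        threshold: float) -> ScoredPairList:
    """Retain pairs whose index is at least ``threshold``.

    Counts are non-increasing in the threshold; threshold 0 is the identity.
    """
    if threshold < 0:
        raise ValueError(f"threshold {threshold} must be >= 0")
    kept = tuple(s for s in pairs.pairs if s.hyi >= threshold)
    return ScoredPairList(kept, threshold_applied=threshold)
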