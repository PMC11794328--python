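"""Validation of predicted phenotype-drug pairs.

Two independent checks: overlap with a gold-standard effect list
(SIDER-style marketed-drug side effects) and overlap with phenotype-drug
pairs that co-occur significantly in the literature.  In both, the observed
overlap ("confirmed" pairs) is compared with the mean overlap of randomized
prediction lists in which connections are shuffled while every phenotype's
and drug's pair count is preserved (links-based, degree-preserving
randomization); the confirmed/random ratio summarises the enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np

from .assoc import ScoredPairList, hypergeometric_upper_tail
from .errors import ContractError

log = logging.getLogger(__name__)

Pair = tuple[str, str]  # (hpo_id, drug_id)

#: Significance cutoff for literature co-occurrence.
COOCCURRENCE_ALPHA = 1e-3

#: Attempted double-edge swaps per edge in one randomization draw.
SWAPS_PER_EDGE = 10


@dataclass(frozen=True)
class GoldStandard:
    """Known phenotype-drug effect pairs (the gold standard)."""

    pairs: frozenset[Pair]

    @property
    def drugs(self) -> set[str]:
        return {d for _, d in self.pairs}

    @property
    def phenotypes(self) -> set[str]:
        return {h for h, _ in self.pairs}


@dataclass(frozen=True)
class CooccurrenceRecord:
    """Literature mention counts for one (drug, HPO term) pair."""

    drug_id: str
    hpo_id: str
    n_drug: int
    n_hpo: int
    n_both: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_both > min(self.n_drug, self.n_hpo):
            raise ValueError(
                f"n_both={self.n_both} exceeds min(n_drug={self.n_drug}, "
                f"n_hpo={self.n_hpo})")
        if max(self.n_drug, self.n_hpo) > self.n_total:
            raise ValueError("marginal count exceeds corpus size")
        if min(self.n_drug, self.n_hpo, self.n_both, self.n_total) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ValidationReport:
    """Confirmed overlap vs the randomized null at one threshold."""

    threshold: float
    confirmed: int
    random_mean: float
    random_sd: float
    ratio: float  # math.inf when random_mean == 0
    n_replicates: int
    seed: int


def _as_pair_set(predicted: Union[ScoredPairList, Iterable[Pair]]
                 ) -> set[Pair]:
    if isinstance(predicted, ScoredPairList):
        return predicted.pair_set()
    return set(predicted)


def restrict_to_gold_universe(predicted: ScoredPairList,
                              gold: GoldStandard) -> ScoredPairList:
    """Keep predictions whose drug AND phenotype each occur somewhere in the
    gold standard (membership per entity, not per pair)."""
    if not gold.pairs:
        raise ContractError("gold standard is empty")
    hs, ds = gold.phenotypes, gold.drugs
    kept = tuple(s for s in predicted
                 if s.a_id in hs and s.b_id in ds)
    return ScoredPairList(kept, threshold_applied=predicted.threshold_applied)


def randomize_links(pairs: Iterable[Pair], seed: int,
                    swaps_per_edge: int = SWAPS_PER_EDGE) -> set[Pair]:
    """Shuffle the connections of a pair list, preserving every phenotype's
    and every drug's pair count (degree-preserving randomization).

    Implemented as repeated double-edge swaps on the bipartite pair graph:
    two edges (h1,d1), (h2,d2) are rewired to (h1,d2), (h2,d1) unless that
    would create a duplicate pair.  Edge indices are drawn with replacement
    (a self-pick is a no-op), which makes the chain aperiodic and its
    stationary distribution uniform over the simple configurations with the
    given degree sequence.  Deterministic given ``seed``.
    """
    edges = sorted(set(pairs))
    if not edges:
        raise ValueError("empty pair set")
    hs = {h for h, _ in edges}
    ds = {d for _, d in edges}
    if len(hs) < 2 or len(ds) < 2 or len(edges) == len(hs) * len(ds):
        # complete bipartite or a single node on one side: the degree
        # sequence admits only this configuration
        log.warning("degree sequence admits a single configuration; "
                    "returning the input unchanged")
        return set(edges)

    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    m = len(edges)
    picks = rng.integers(0, m, size=(swaps_per_edge * m, 2))
    for i, j in picks:
        if i == j:
            continue
        h1, d1 = edges[i]
        h2, d2 = edges[j]
        if h1 == h2 or d1 == d2:
            continue
        e1, e2 = (h1, d2), (h2, d1)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((h1, d1))
        edge_set.discard((h2, d2))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i], edges[j] = e1, e2
    return edge_set


def overlap_ratio(
    predicted: Union[ScoredPairList, Iterable[Pair]],
    gold: GoldStandard,
    n_replicates: int = 100,
    seed: int = 0,
    threshold: float = 0.0,
) -> ValidationReport:
    """Confirmed overlap with the gold standard vs the randomized null.

    ``confirmed`` counts predicted pairs found in the gold standard;
    ``random_mean``/``random_sd`` summarise the overlap of ``n_replicates``
    degree-preserving shuffles of the predicted list (replicate ``i`` uses
    seed ``seed + i``); ``ratio`` is confirmed / random_mean, reported as
    infinity when the null never overlaps.
    """
    pred = _as_pair_set(predicted)
    if not pred:
        raise ContractError("no predicted pairs to validate")
    if not gold.pairs:
        raise ContractError("gold standard is empty")
    confirmed = len(pred & gold.pairs)
    overlaps = np.array([
        len(randomize_links(pred, seed + i) & gold.pairs)
        for i in range(n_replicates)
    ], dtype=float)
    mean = float(overlaps.mean())
    sd = float(overlaps.std(ddof=1)) if n_replicates > 1 else 0.0
    ratio = confirmed / mean if mean > 0 else math.inf
    return ValidationReport(threshold, confirmed, mean, sd, ratio,
                            n_replicates, seed)


def cooccurrence_pvalue(rec: CooccurrenceRecord) -> float:
    """Upper-tail probability of the observed number of co-mentioning
    articles, given the two marginal mention counts and the corpus size
    (hypergeometric, i.e. a one-sided Fisher test)."""
    return hypergeometric_upper_tail(
        rec.n_both, rec.n_hpo, rec.n_drug, rec.n_total)


def significant_comention_pairs(
    comentions: Iterable[CooccurrenceRecord],
    alpha: float = COOCCURRENCE_ALPHA,
) -> set[Pair]:
    """Pairs whose literature co-occurrence is significant (p < alpha)."""
    return {(r.hpo_id, r.drug_id) for r in comentions
            if cooccurrence_pvalue(r) < alpha}


def literature_overlap(
    predicted: Union[ScoredPairList, Iterable[Pair]],
    comentions: Iterable[CooccurrenceRecord],
    n_replicates: int = 100,
    seed: int = 0,
    threshold: float = 0.0,
    alpha: float = COOCCURRENCE_ALPHA,
) -> ValidationReport:
    """Overlap of predictions with significantly co-mentioned pairs, under
    the same degree-preserving randomized null as the gold-standard check."""
    sig = significant_comention_pairs(comentions, alpha)
    if not sig:
        pred = _as_pair_set(predicted)
        if not pred:
            raise ContractError("no predicted pairs to validate")
        return ValidationReport(threshold, 0, 0.0, 0.0, math.inf,
                                n_replicates, seed)
    return overlap_ratio(predicted, GoldStandard(frozenset(sig)),
                         n_replicates, seed, threshold)
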