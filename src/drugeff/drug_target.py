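"""Drug-target pair extraction and drug-FunFam binomial enrichment.

A ChEMBL-style activity table is filtered to confident therapeutic
interactions: small molecules with a therapeutic flag, direct binding
assays against single proteins (assay type B, relationship type D), and
potency pChEMBL >= 6 (at most 1 uM).  For the domain-target chain, each
drug is associated with the CATH FunFams significantly overrepresented
among its filtered targets by a one-sided binomial test against the
FunFam's background frequency in the target universe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

from scipy.stats import binom

from .assoc import BipartiteEdges
from .errors import ContractError
from .pheno_target import GeneDomainMap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActivityRecord:
    """One drug-target assay row (ChEMBL-style columns)."""

    drug_id: str
    target_id: str
    therapeutic_flag: int
    assay_type: str
    relationship_type: str
    target_type: str
    pchembl: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pchembl is not None and not (
                math.isfinite(self.pchembl) and self.pchembl >= 0):
            raise ValueError(f"pchembl {self.pchembl} must be finite and >= 0")


@dataclass(frozen=True)
class EnrichmentResult:
    """Binomial overrepresentation record for one (drug, FunFam) pair.

    ``n`` is the drug's number of distinct filtered targets, ``x`` how many
    of them carry the FunFam, and ``q`` the FunFam's background proportion
    in the target universe.
    """

    drug_id: str
    funfam_id: str
    n: int
    x: int
    q: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.x <= self.n):
            raise ValueError(f"x={self.x} outside [0, n={self.n}]")
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"q={self.q} outside [0, 1]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


#: Filter criteria for confident therapeutic activities.
PCHEMBL_MIN = 6.0
ASSAY_TYPE = "b"            # direct binding assay
RELATIONSHIP_TYPE = "d"     # direct protein-ligand relationship
TARGET_TYPE = "single protein"


def filter_activities(records: Iterable[ActivityRecord]) -> BipartiteEdges:
    """Reduce raw activities to unique confident (drug, target) edges.

    Keeps therapeutic_flag=1, binding assays (B) with a direct relationship
    (D) on single-protein targets, and pChEMBL >= 6 inclusive; string
    criteria match case-insensitively.  Per-criterion removal counts are
    logged; surviving rows are deduplicated to unique edges.
    """
    removed = {"therapeutic_flag": 0, "assay_type": 0,
               "relationship_type": 0, "target_type": 0, "pchembl": 0}
    kept: list[tuple[str, str]] = []
    for rec in records:
        if rec.therapeutic_flag != 1:
            removed["therapeutic_flag"] += 1
        elif rec.assay_type.lower() != ASSAY_TYPE:
            removed["assay_type"] += 1
        elif rec.relationship_type.lower() != RELATIONSHIP_TYPE:
            removed["relationship_type"] += 1
        elif rec.target_type.lower() != TARGET_TYPE:
            removed["target_type"] += 1
        elif rec.pchembl is None or rec.pchembl < PCHEMBL_MIN:
            removed["pchembl"] += 1
        else:
            kept.append((rec.drug_id, rec.target_id))
    for criterion, n in removed.items():
        if n:
            log.info("filter_activities: %d records removed by %s",
                     n, criterion)
    return BipartiteEdges.from_pairs(kept, outer_role="drug",
                                     middle_role="target")


def binomial_upper_tail(x: int, n: int, q: float) -> float:
    """P(Bin(n, q) >= x), the one-sided binomial overrepresentation tail.

    Examples
    --------
    >>> binomial_upper_tail(0, 5, 0.2)
    1.0
    >>> round(binomial_upper_tail(3, 5, 0.2), 5)
    0.05792
    """
    if n < 0:
        raise ValueError(f"n={n} must be >= 0")
    if not (0 <= x <= n):
        raise ValueError(f"x={x} outside [0, n={n}]")
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q={q} outside [0, 1]")
    if x == 0:
        return 1.0
    return float(binom.sf(x - 1, n, q))


def drug_funfam_enrichment(
    drug_targets: BipartiteEdges,
    domains: GeneDomainMap,
    alpha: float = 0.05,
    background: Optional[dict[str, float]] = None,
) -> tuple[list[EnrichmentResult], BipartiteEdges]:
    """Associate drugs with FunFams overrepresented among their targets.

    The background universe is the set of distinct proteins appearing as
    targets in ``drug_targets``; each FunFam's expected probability ``q`` is
    the fraction of universe proteins carrying it (a protein with several
    domains of one FunFam counts once), overridable via ``background``.
    Pairs with p < ``alpha`` (strict) are emitted; boundary p == alpha cases
    are logged.

    Returns the significant :class:`EnrichmentResult` records (sorted by
    ascending p, then IDs) and the corresponding drug->funfam edge list.
    """
    universe = drug_targets.middles
    if not universe:
        raise ContractError("empty target universe: no filtered activities")
    carriers: dict[str, set[str]] = {}
    for g, ff in domains.gene_funfam.edges:
        if g in universe:
            carriers.setdefault(ff, set()).add(g)
    if background is None:
        background = {ff: len(c) / len(universe)
                      for ff, c in carriers.items()}

    ffs_by_target: dict[str, set[str]] = {}
    for ff, genes in carriers.items():
        for g in genes:
            ffs_by_target.setdefault(g, set()).add(ff)

    results: list[EnrichmentResult] = []
    for drug, targets in sorted(drug_targets.neighbours().items()):
        n = len(targets)
        hit_ffs = sorted({ff for t in targets
                          for ff in ffs_by_target.get(t, ())})
        for ff in hit_ffs:
            x = len(carriers[ff] & targets)
            q = background.get(ff, 0.0)
            p = binomial_upper_tail(x, n, q)
            if p < alpha:
                results.append(EnrichmentResult(drug, ff, n, x, q, p))
            elif p == alpha:
                log.info("boundary p == alpha for (%s, %s); excluded",
                         drug, ff)
    results.sort(key=lambda r: (r.p_value, r.drug_id, r.funfam_id))
    edges = BipartiteEdges.from_pairs(
        ((r.drug_id, r.funfam_id) for r in results),
        outer_role="drug", middle_role="funfam",
    )
    return results, edges
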