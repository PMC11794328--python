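"""Phenotype-target-drug tripartite combination.

The phenotype-target pairs (targets as proteins or FunFams) and the
drug-target edge list are combined by projecting over the shared target
layer: phenotypes and drugs are associated when they touch the same
targets, scored with the hypergeometric index, and reported at each
requested index threshold (threshold 0 is the unfiltered "Total" list).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .assoc import (
    BipartiteEdges,
    OverlapScore,
    ScoredPairList,
    filter_by_threshold,
    log_hypergeometric_upper_tail,
    project_and_score,
    _score_from_log_p,
)
from .drug_target import ActivityRecord, drug_funfam_enrichment, \
    filter_activities
from .errors import ContractError
from .pheno_target import (
    DiseaseAnnotations,
    GeneDomainMap,
    build_phenotype_funfam_pairs,
    build_phenotype_gene_pairs,
)

log = logging.getLogger(__name__)


def associate(
    phenotype_targets: ScoredPairList,
    drug_targets: BipartiteEdges,
    thresholds: Sequence[float],
) -> dict[float, ScoredPairList]:
    """Project phenotype->target against drug->target into scored
    phenotype-drug pairs, one filtered list per requested threshold.

    Every phenotype and every drug connected to at least one target takes
    part; the target population is the union of targets on both sides.
    """
    pheno_edges = phenotype_targets.to_edges(
        outer_role="phenotype", middle_role=drug_targets.middle_role)
    if not (pheno_edges.middles & drug_targets.middles):
        raise ContractError(
            "phenotype-side and drug-side target namespaces do not overlap")
    scored = project_and_score(pheno_edges, drug_targets)
    return {t: filter_by_threshold(scored, t) for t in thresholds}


def run_protein_chain(
    ann: DiseaseAnnotations,
    activities: Iterable[ActivityRecord],
    thresholds: Sequence[float],
    pheno_gene_threshold: float = 2.0,
) -> dict[float, ScoredPairList]:
    """End-to-end protein-target chain: disease annotations + activities ->
    per-threshold phenotype-drug lists, with genes/proteins as targets."""
    activities = list(activities)
    if not activities:
        raise ContractError("activity table is empty")
    pheno_gene = build_phenotype_gene_pairs(ann, pheno_gene_threshold)
    drug_target = filter_activities(activities)
    if not drug_target.edges:
        raise ContractError("no activities survive the confidence filters")
    return associate(pheno_gene, drug_target, thresholds)


def run_domain_chain(
    ann: DiseaseAnnotations,
    activities: Iterable[ActivityRecord],
    domains: GeneDomainMap,
    thresholds: Sequence[float],
    pheno_gene_threshold: float = 2.0,
    pheno_funfam_threshold: float = 2.0,
    alpha: float = 0.05,
) -> dict[float, ScoredPairList]:
    """End-to-end domain-target chain, with CATH FunFams as targets.

    Composes phenotype-gene -> phenotype-FunFam scoring with the drug-FunFam
    binomial enrichment, then associates over the FunFam namespace.
    """
    activities = list(activities)
    if not activities:
        raise ContractError("activity table is empty")
    pheno_gene = build_phenotype_gene_pairs(ann, pheno_gene_threshold)
    pheno_funfam = build_phenotype_funfam_pairs(
        pheno_gene, domains, pheno_funfam_threshold)
    drug_target = filter_activities(activities)
    if not drug_target.edges:
        raise ContractError("no activities survive the confidence filters")
    if not (drug_target.middles & {g for g, _ in domains.gene_funfam.edges}):
        raise ContractError(
            "domain map covers none of the filtered drug targets")
    _, drug_funfam = drug_funfam_enrichment(drug_target, domains, alpha)
    if not drug_funfam.edges or not pheno_funfam.pairs:
        log.warning("no %s pair survives; phenotype-drug lists are empty",
                    "drug-FunFam" if not drug_funfam.edges
                    else "phenotype-FunFam")
        return {t: ScoredPairList((), threshold_applied=t)
                for t in thresholds}
    return associate(pheno_funfam, drug_funfam, thresholds)


def explain_pair(
    phenotype_targets: ScoredPairList,
    drug_targets: BipartiteEdges,
    phenotype: str,
    drug: str,
) -> dict:
    """Recover the witnessing shared targets and score components for one
    predicted (phenotype, drug) pair."""
    pheno_nb = {s.a_id: set() for s in phenotype_targets}
    for s in phenotype_targets:
        pheno_nb[s.a_id].add(s.b_id)
    if phenotype not in pheno_nb:
        raise ContractError(f"{phenotype} has no retained targets")
    drug_nb = drug_targets.neighbours()
    if drug not in drug_nb:
        raise ContractError(f"{drug} has no targets")
    a_set, b_set = pheno_nb[phenotype], drug_nb[drug]
    shared = sorted(a_set & b_set)
    universe = {t for ts in pheno_nb.values() for t in ts} \
        | drug_targets.middles
    N = len(universe)
    k = len(shared)
    if k == 0:
        raise ContractError(
            f"({phenotype}, {drug}) share no target; pair not predicted")
    log_p = log_hypergeometric_upper_tail(k, len(a_set), len(b_set), N)
    score: OverlapScore = _score_from_log_p(
        phenotype, drug, N, len(a_set), len(b_set), k, log_p)
    return {
        "phenotype": phenotype,
        "drug": drug,
        "shared_targets": shared,
        "phenotype_targets": sorted(a_set),
        "drug_targets": sorted(b_set),
        "N": N,
        "k": k,
        "size_a": len(a_set),
        "size_b": len(b_set),
        "p_value": score.p_value,
        "hyi": score.hyi,
    }
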