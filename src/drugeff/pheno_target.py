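"""Phenotype-target pair construction from rare-disease annotations.

Genes and phenotypes annotated to the same diseases (OMIM-like or
Orphanet-like catalogues, processed independently and never merged) are
paired and scored with the hypergeometric index.  For the domain-target
chain, each gene is expanded to the CATH FunFams (functional families of
protein domains) found in its protein product, and phenotype-FunFam pairs
are scored the same way with genes as the middle layer.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .assoc import (
    BipartiteEdges,
    ScoredPairList,
    filter_by_threshold,
    project_and_score,
)
from .errors import ContractError

log = logging.getLogger(__name__)

HPO_ID_RE = re.compile(r"^HP:\d{7}$")
FUNFAM_ID_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+-ff-\d+$")


@dataclass(frozen=True)
class DiseaseAnnotations:
    """Disease->gene and disease->phenotype annotations from one catalogue.

    Both edge lists use the disease as the middle layer; phenotype IDs are
    Human Phenotype Ontology terms (``HP:NNNNNNN``).
    """

    disease_gene: BipartiteEdges        # outer=gene, middle=disease
    disease_phenotype: BipartiteEdges   # outer=HPO term, middle=disease
    source_label: str = "omim-like"

    def __post_init__(self) -> None:
        for hpo, _ in self.disease_phenotype.edges:
            if not HPO_ID_RE.match(hpo):
                raise ValueError(f"malformed HPO ID {hpo!r}")
        if self.disease_gene.middle_role != self.disease_phenotype.middle_role:
            raise ContractError("annotation layers use different middle roles")


@dataclass(frozen=True)
class GeneDomainMap:
    """Gene -> CATH FunFam membership (``C.A.T.H-ff-N`` IDs)."""

    gene_funfam: BipartiteEdges  # outer=gene, middle=funfam

    def __post_init__(self) -> None:
        for _, ff in self.gene_funfam.edges:
            if not FUNFAM_ID_RE.match(ff):
                raise ValueError(f"malformed FunFam ID {ff!r}")

    @property
    def funfams(self) -> set[str]:
        return {ff for _, ff in self.gene_funfam.edges}

    def funfams_of(self, gene: str) -> set[str]:
        return {ff for g, ff in self.gene_funfam.edges if g == gene}


def build_phenotype_gene_pairs(ann: DiseaseAnnotations,
                               threshold: float) -> ScoredPairList:
    """Score phenotype-gene pairs via shared diseases and threshold them.

    The phenotype is ``a_id`` and the gene ``b_id``; the population is the
    distinct diseases across both annotation lists.
    """
    if not ann.disease_gene.edges or not ann.disease_phenotype.edges:
        raise ContractError(
            f"{ann.source_label}: both disease-gene and disease-phenotype "
            "annotations must be non-empty")
    scored = project_and_score(ann.disease_phenotype, ann.disease_gene)
    return filter_by_threshold(scored, threshold)


def build_phenotype_funfam_pairs(
    pheno_gene: ScoredPairList,
    domains: GeneDomainMap,
    threshold: float = 2.0,
) -> ScoredPairList:
    """Score phenotype-FunFam pairs with genes as the middle layer.

    The genes of the retained phenotype-gene pairs form the population; the
    domain map is restricted to those genes.  Genes with no FunFam
    annotation drop out of the domain chain (counted in the log).
    """
    genes_in_pairs = {s.b_id for s in pheno_gene}
    pheno_edges = BipartiteEdges(
        frozenset((s.a_id, s.b_id) for s in pheno_gene),
        outer_role="phenotype", middle_role="gene",
    )
    map_genes = {g for g, _ in domains.gene_funfam.edges}
    overlap = genes_in_pairs & map_genes
    if not overlap:
        raise ContractError(
            "gene namespaces of the phenotype-gene pairs and the domain map "
            f"do not overlap ({len(genes_in_pairs)} pair genes vs "
            f"{len(map_genes)} mapped genes)")
    dropped = len(genes_in_pairs - map_genes)
    if dropped:
        log.info("%d phenotype-linked genes carry no FunFam annotation",
                 dropped)
    funfam_edges = BipartiteEdges(
        frozenset((ff, g) for g, ff in domains.gene_funfam.edges
                  if g in genes_in_pairs),
        outer_role="funfam", middle_role="gene",
    )
    scored = project_and_score(pheno_edges, funfam_edges)
    # a_id=phenotype, b_id=funfam already, by argument order
    return filter_by_threshold(scored, threshold)
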