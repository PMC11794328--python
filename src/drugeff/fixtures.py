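"""Synthetic tripartite universes with planted phenotype-drug signal.

Generates every input table the pipeline consumes — disease-gene and
disease-phenotype annotations, gene-FunFam membership, a ChEMBL-style
activity table, a gold-standard effect list, and literature co-mention
counts — from a single seeded random stream.  A configurable number of
(phenotype, drug) chains is planted: each planted drug binds a set of genes
that are annotated (through a shared disease) to the planted phenotype and
that carry a common FunFam, so the planted pair is guaranteed to share at
least ``planted_overlap`` targets in both the protein and domain chains.
Background edges are independent Bernoulli draws per node pair, the
simplest exchangeable null consistent with the degree-preserving
randomization model.

Also hosts :func:`reference_oracle`, an exact-rational brute-force twin of
the hypergeometric tail used only as an independent check in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np

from .assoc import BipartiteEdges
from .drug_target import ActivityRecord
from .pheno_target import DiseaseAnnotations, GeneDomainMap
from .validation import CooccurrenceRecord, GoldStandard


@dataclass(frozen=True)
class FixtureConfig:
    """Shape and signal parameters of a synthetic universe.

    Defaults give a small but non-degenerate universe: sparse background
    layers, three planted chains of two shared targets each, a clean gold
    standard with a few background pairs, and a 1e6-article co-mention
    corpus in which planted pairs are strongly co-mentioned.
    """

    n_diseases: int = 40
    n_genes: int = 60
    n_phenotypes: int = 30
    n_funfams: int = 12
    n_drugs: int = 30
    density_disease_gene: float = 0.05
    density_disease_phenotype: float = 0.08
    density_gene_funfam: float = 0.06
    density_activity: float = 0.02
    activity_fail_rate: float = 0.5
    n_planted: int = 3
    planted_overlap: int = 2
    gold_noise: float = 0.0
    n_gold_background: int = 12
    comention_corpus: int = 1_000_000
    n_comention_background: int = 10
    seed: int = 7

    def __post_init__(self) -> None:
        counts = (self.n_diseases, self.n_genes, self.n_phenotypes,
                  self.n_funfams, self.n_drugs)
        if min(counts) < 1:
            raise ValueError("all entity counts must be >= 1")
        dens = (self.density_disease_gene, self.density_disease_phenotype,
                self.density_gene_funfam, self.density_activity,
                self.activity_fail_rate, self.gold_noise)
        if not all(0.0 <= d <= 1.0 for d in dens):
            raise ValueError("densities and rates must lie in [0, 1]")
        if self.planted_overlap < 1:
            raise ValueError("planted_overlap must be >= 1")
        if self.n_planted * self.planted_overlap > self.n_genes:
            raise ValueError(
                f"{self.n_planted} chains x {self.planted_overlap} genes "
                f"exceed the {self.n_genes} available genes")
        if self.n_planted > min(self.n_diseases, self.n_phenotypes,
                                self.n_funfams, self.n_drugs):
            raise ValueError("n_planted exceeds an entity count")


@dataclass(frozen=True)
class SyntheticUniverse:
    """All generated input tables plus the planted truth."""

    config: FixtureConfig
    annotations: DiseaseAnnotations
    domains: GeneDomainMap
    activities: tuple[ActivityRecord, ...]
    gold: GoldStandard
    comentions: tuple[CooccurrenceRecord, ...]
    planted_pairs: frozenset[tuple[str, str]]  # (hpo_id, drug_id)


def _ids(cfg: FixtureConfig):
    diseases = [f"MIM:{600000 + i}" for i in range(cfg.n_diseases)]
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    phenos = [f"HP:{i + 1:07d}" for i in range(cfg.n_phenotypes)]
    funfams = [f"3.40.50.{300 + i}-ff-{i + 1}" for i in range(cfg.n_funfams)]
    drugs = [f"CHEMBL{i + 1}" for i in range(cfg.n_drugs)]
    return diseases, genes, phenos, funfams, drugs


def _bernoulli_edges(rng, rows, cols, density):
    mask = rng.random((len(rows), len(cols))) < density
    return [(rows[i], cols[j]) for i, j in zip(*np.nonzero(mask))]


def _passing_activity(drug, target, pchembl):
    return ActivityRecord(drug, target, 1, "B", "D", "Single Protein",
                          float(pchembl))


def _failing_activity(rng, drug, target):
    mode = rng.integers(0, 5)
    if mode == 0:
        return ActivityRecord(drug, target, 0, "B", "D", "Single Protein",
                              7.0)
    if mode == 1:
        return ActivityRecord(drug, target, 1, "F", "D", "Single Protein",
                              7.0)
    if mode == 2:
        return ActivityRecord(drug, target, 1, "B", "H", "Single Protein",
                              7.0)
    if mode == 3:
        return ActivityRecord(drug, target, 1, "B", "D", "Protein Complex",
                              7.0)
    return ActivityRecord(drug, target, 1, "B", "D", "Single Protein",
                          float(rng.uniform(2.0, 5.9)))


def generate_universe(cfg: FixtureConfig) -> SyntheticUniverse:
    """Generate a full synthetic universe; byte-identical given one seed."""
    rng = np.random.default_rng(cfg.seed)
    diseases, genes, phenos, funfams, drugs = _ids(cfg)

    disease_gene: list[tuple[str, str]] = []      # (gene, disease)
    disease_pheno: list[tuple[str, str]] = []     # (hpo, disease)
    gene_funfam: list[tuple[str, str]] = []       # (gene, funfam)
    activities: list[ActivityRecord] = []
    planted: set[tuple[str, str]] = set()

    # Planted chains: drug -> genes -> disease -> phenotype, with the genes
    # sharing one FunFam so the domain chain recovers the same pair.
    for j in range(cfg.n_planted):
        chain_genes = genes[j * cfg.planted_overlap:
                            (j + 1) * cfg.planted_overlap]
        disease, pheno = diseases[j], phenos[j]
        drug, funfam = drugs[j], funfams[j]
        disease_pheno.append((pheno, disease))
        for g in chain_genes:
            disease_gene.append((g, disease))
            gene_funfam.append((g, funfam))
            activities.append(_passing_activity(
                drug, g, rng.uniform(6.5, 9.0)))
        planted.add((pheno, drug))

    # Background layers.
    disease_gene += _bernoulli_edges(rng, genes, diseases,
                                     cfg.density_disease_gene)
    disease_pheno += _bernoulli_edges(rng, phenos, diseases,
                                      cfg.density_disease_phenotype)
    gene_funfam += _bernoulli_edges(rng, genes, funfams,
                                    cfg.density_gene_funfam)
    for drug, gene in _bernoulli_edges(rng, drugs, genes,
                                       cfg.density_activity):
        if rng.random() < cfg.activity_fail_rate:
            activities.append(_failing_activity(rng, drug, gene))
        else:
            activities.append(_passing_activity(
                drug, gene, rng.uniform(6.0, 9.0)))

    ann = DiseaseAnnotations(
        disease_gene=BipartiteEdges.from_pairs(
            disease_gene, outer_role="gene", middle_role="disease"),
        disease_phenotype=BipartiteEdges.from_pairs(
            disease_pheno, outer_role="phenotype", middle_role="disease"),
        source_label="omim-like",
    )
    domains = GeneDomainMap(BipartiteEdges.from_pairs(
        gene_funfam, outer_role="gene", middle_role="funfam"))

    # Gold standard: planted pairs (each replaced by a random pair with
    # probability gold_noise) plus a few background pairs so the gold
    # universe is larger than the planted truth.
    gold_pairs: set[tuple[str, str]] = set()
    for pair in sorted(planted):
        if rng.random() < cfg.gold_noise:
            gold_pairs.add((phenos[rng.integers(0, cfg.n_phenotypes)],
                            drugs[rng.integers(0, cfg.n_drugs)]))
        else:
            gold_pairs.add(pair)
    while len(gold_pairs) < len(planted) + cfg.n_gold_background:
        cand = (phenos[rng.integers(0, cfg.n_phenotypes)],
                drugs[rng.integers(0, cfg.n_drugs)])
        if cand not in planted:
            gold_pairs.add(cand)
    gold = GoldStandard(frozenset(gold_pairs))

    # Co-mention counts: planted pairs co-occur far above chance; background
    # pairs are drawn at their chance rate (expected n_both ~ 0.04), so they
    # are insignificant on average.
    comentions: list[CooccurrenceRecord] = []
    for pheno, drug in sorted(planted):
        comentions.append(CooccurrenceRecord(
            drug, pheno, n_drug=200, n_hpo=200, n_both=30,
            n_total=cfg.comention_corpus))
    seen = set(planted)
    while len(comentions) < len(planted) + cfg.n_comention_background:
        pair = (phenos[rng.integers(0, cfg.n_phenotypes)],
                drugs[rng.integers(0, cfg.n_drugs)])
        if pair in seen:
            continue
        seen.add(pair)
        comentions.append(CooccurrenceRecord(
            pair[1], pair[0], n_drug=200, n_hpo=200,
            n_both=int(rng.poisson(0.04)),
            n_total=cfg.comention_corpus))

    return SyntheticUniverse(
        config=cfg,
        annotations=ann,
        domains=domains,
        activities=tuple(activities),
        gold=gold,
        comentions=tuple(comentions),
        planted_pairs=frozenset(planted),
    )


def reference_oracle(k: int, size_a: int, size_b: int, N: int) -> Fraction:
    """Exact hypergeometric upper tail by exhaustive subset enumeration.

    Marks the first ``size_a`` population elements as set A, enumerates all
    C(N, size_b) draws of size ``size_b`` and counts those sharing at least
    ``k`` elements with A.  Exact rational arithmetic; restricted to
    N <= 14.  Used only in tests, as an implementation-independent oracle.
    """
    if N > 14:
        raise ValueError(f"N={N} too large for exhaustive enumeration")
    if not (0 <= size_a <= N and 0 <= size_b <= N):
        raise ValueError("set sizes must lie in [0, N]")
    if not (0 <= k <= min(size_a, size_b)):
        raise ValueError("k outside [0, min(size_a, size_b)]")
    a_set = set(range(size_a))
    hits = sum(
        1 for draw in itertools.combinations(range(N), size_b)
        if len(a_set.intersection(draw)) >= k
    )
    return Fraction(hits, comb(N, size_b))
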