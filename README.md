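# drugeff

Tripartite **phenotype–target–drug** network analysis for predicting drug
effects — both intended and adverse — from shared targets.

Most drugs act through one or more protein targets, and variants in the
genes encoding those targets cause pathological phenotypes. `drugeff`
operationalises the tenet that *the phenotypes associated with variants in a
protein can also occur when that protein is drugged*: it links phenotypes
(Human Phenotype Ontology terms) to targets through rare-disease
annotations, links drugs to targets through curated bioactivity data, and
associates phenotypes with drugs through the targets both touch. Targets
can be whole proteins or CATH FunFams (functional families of protein
domains), the latter giving finer mechanistic resolution.

## The statistic

Every association between two entities A and B with neighbour sets of sizes
|A| and |B| in a shared middle layer of N entities is scored with the
**hypergeometric index (HyI)**:

```
P(X ≥ k) = Σ_{i=k}^{min(|A|,|B|)}  C(|A|, i) · C(N−|A|, |B|−i) / C(N, |B|)
HyI      = −log10 P(X ≥ k)
```

the upper-tail probability that the k observed shared neighbours would
arise by chance, log-transformed so that larger values mean stronger
associations. An index threshold of 2 keeps pairs with p ≤ 0.01; 3.5
corresponds to p ≈ 0.0003. The tail is summed in log space, so overlaps
far beyond double-precision underflow still score correctly (the index is
capped at 300).

The pipeline has three stages, each usable on its own:

1. **Phenotype–target** (`pheno_target`): phenotypes and genes annotated to
   the same diseases are paired and scored; for the domain chain, genes are
   expanded to their CATH FunFams and phenotype–FunFam pairs are scored
   with genes as the middle layer.
2. **Drug–target** (`drug_target`): a ChEMBL-style activity table is
   filtered to confident therapeutic interactions (therapeutic flag set,
   binding assay **B** with direct relationship **D** on a **single
   protein**, pChEMBL ≥ 6); for the domain chain, each drug is linked to
   the FunFams significantly overrepresented among its targets
   (one-sided binomial test, p < 0.05).
3. **Tripartite combination** (`tripartite`): phenotype–target and
   drug–target pairs are projected over the shared target layer into
   scored phenotype–drug associations, reported at a sweep of index
   thresholds.

Predictions are validated (`validation`) by overlap with a gold-standard
effect list and with phenotype–drug pairs that co-occur significantly in
the literature (hypergeometric test on mention counts, p < 0.001), in both
cases against a **degree-preserving randomized null**: connections are
shuffled by double-edge swaps that keep every phenotype's and drug's pair
count fixed, and the confirmed/random ratio summarises the enrichment.

## Worked example

The package ships a seeded synthetic-universe generator (`fixtures`) that
emulates every input table with planted phenotype–drug chains, so the whole
pipeline runs offline:

```bash
drugeff fixtures --seed 3 --out fx
drugeff run --mode protein \
    --disease-gene fx/disease_gene.tsv \
    --disease-phenotype fx/disease_phenotype.tsv \
    --activities fx/activities.tsv \
    --thresholds 0,2,3,3.5 --pheno-gene-threshold 0 --out run
drugeff validate --predictions run/phenotype_drug_hyi0.tsv \
    --gold fx/gold.tsv --comentions fx/comentions.tsv \
    --replicates 100 --seed 17 --out validation.tsv
```

which prints

```
threshold 0: 128 pairs -> phenotype_drug_hyi0.tsv
threshold 2: 1 pairs -> phenotype_drug_hyi2.tsv
threshold 3: 0 pairs -> phenotype_drug_hyi3.tsv
threshold 3.5: 0 pairs -> phenotype_drug_hyi3.5.tsv
confirmed=3 random=2.05±1.02 ratio=1.46
confirmed=3 random=1.13±0.79 ratio=2.65
```

128 phenotype–drug pairs share at least one target; the count shrinks as
the index threshold rises. Of the predictions inside the gold-standard
universe, 3 are confirmed known effects — the 3 planted pairs — versus
2.05 expected under the degree-preserving null (ratio 1.46); against
literature co-mentions the same 3 pairs stand against 1.13 expected
(ratio 2.65). The top of the threshold-0 list:

```
a_id        b_id     k  size_a  size_b  N   p_value   hyi
HP:0000022  CHEMBL2  2  4       2       53  0.00435   2.36
HP:0000001  CHEMBL1  2  8       2       53  0.02032   1.69
```

and any pair can be audited down to its witnessing targets:

```bash
drugeff explain --pair HP:0000001,CHEMBL1 \
    --phenotype-targets pheno_gene.tsv --drug-targets drug_target.tsv
# -> shared_targets: ["GENE0001", "GENE0002"], k=2, N=53, p=0.0203, hyi=1.69
```

Phenotype HP:0000001 and drug CHEMBL1 are linked because the drug's two
targets are both among the phenotype's eight associated genes — an overlap
with chance probability 0.02 in the 53-gene population.

The same stages are available as library functions
(`run_protein_chain`, `run_domain_chain`, `overlap_ratio`,
`literature_overlap`, …); see `docs/methods.md` for the model details and
design choices.

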