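# Methods

## Model

`drugeff` treats drug-effect prediction as a projection problem on a
tripartite network with layers **phenotype — target — drug**, where edges
exist only between adjacent layers. Two outer-layer nodes are associated
when they share middle-layer neighbours, and the strength of the
association is the hypergeometric index (HyI): the −log10 of the
probability that two sets of the observed sizes, drawn uniformly at random
from an N-element population, would share at least the observed k
elements. The index is used three times:

- phenotype–gene, with diseases as the middle layer (phenotypes and genes
  annotated to the same rare diseases);
- phenotype–FunFam, with genes as the middle layer (a gene carries a CATH
  FunFam when the family contains a domain of the gene's protein product);
- phenotype–drug, with targets (genes/proteins or FunFams) as the middle
  layer.

The drug–FunFam layer is built differently: for each drug with n distinct
filtered targets, a FunFam carried by x of them is tested against its
background frequency q in the target universe with a one-sided binomial
test P(Bin(n, q) ≥ x); pairs with p < 0.05 (strict) are kept. The
background q is the fraction of the *filtered target universe* carrying
the FunFam — a self-contained choice that requires no external proteome —
and is overridable for users who prefer, e.g., a druggable-proteome
background.

### Assumptions

- Annotation sets from different disease catalogues (OMIM-like vs
  Orphanet-like) are scored separately and never merged; they differ in
  curation philosophy and mixing them would blur the population N.
- The population N of each projection is the union of distinct
  middle-layer entities across the two edge lists being projected,
  computed per projection (an explicit `universe` override exists).
  This makes every score reproducible from the inputs alone.
- Pairs with no shared neighbour (k = 0) are never emitted.
- No propagation of phenotype annotations to ontology ancestors is
  performed; inputs are taken as given.
- No multiple-testing correction is applied to the binomial enrichment;
  a raw α = 0.05 threshold defines the drug–FunFam layer.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| index threshold sweep | 0, 2, 3, 3.5 | −log10 p cutoffs on scored pairs; 2 ↔ p = 0.01, 3.5 ↔ p ≈ 3·10⁻⁴ |
| phenotype–gene threshold | 2 | index cutoff feeding the downstream chains |
| phenotype–FunFam threshold | 2 | index cutoff on the domain-side phenotype pairs |
| pChEMBL minimum | 6 (inclusive) | ≤ 1 µM potency; weaker activities are discarded |
| enrichment α | 0.05 (strict `<`) | binomial significance for drug–FunFam pairs |
| co-occurrence α | 0.001 (strict `<`) | hypergeometric significance for literature pairs |
| randomization replicates | 100 | degree-preserving shuffles per validation |
| swaps per edge | 10 | attempted double-edge swaps per edge per shuffle |
| index cap | 300 | −log10 p ceiling; p-values below 10⁻³⁰⁰ are reported at the cap |

## Validation

Predictions are first restricted to pairs whose drug and phenotype each
appear somewhere in the gold standard (membership per entity, not per
pair), because a gold standard of marketed-drug effects cannot confirm
development-stage compounds. The *confirmed* count is the intersection
with the gold pairs; the null distribution comes from shuffling the
restricted prediction list itself with degree-preserving double-edge
swaps. Replicate i uses seed `seed + i`, making reports bit-reproducible.
The ratio confirmed/random-mean is the headline number; when the null
never overlaps, the ratio is reported as the sentinel `inf` rather than
raising.

The same machinery validates against literature co-mentions: a
(drug, HPO) pair is "known" when the hypergeometric upper tail of its
co-mention count — given the two marginal mention counts and the corpus
size — is below 0.001.

Which list to shuffle is genuinely ambiguous in the field; shuffling the
restricted *prediction* list is the statistically meaningful null (it
preserves the prediction structure while breaking its alignment with the
gold standard), and that is what `overlap_ratio` does. Shuffling the
confirmed list instead is available by passing that list explicitly.

## Numerical choices

- The hypergeometric tail is summed in log space (log-gamma binomial
  coefficients + log-sum-exp); this keeps p-values meaningful far below
  the ~10⁻³⁰⁸ double-precision underflow. The index is capped at 300
  with a warning, and the stored p-value stays consistent with the cap.
- Base-10 logarithm throughout, matching the threshold ↔ p-value
  correspondence (2 ↔ 0.01).
- The binomial survival function is delegated to scipy.
- Output pair lists are sorted by descending index, then lexicographic
  IDs — deterministic and diff-able. Floats are written at 17 significant
  digits so write → read round-trips bit-identically.
- Double-edge swap proposals draw the two edge indices *with*
  replacement. Drawing two distinct edges per attempt makes the number of
  successful swaps parity-deterministic on 2-edge inputs (the chain would
  always return to its start after an even number of attempts);
  with-replacement draws restore aperiodicity, and the rejection of
  duplicate-creating swaps makes the stationary distribution uniform over
  the simple degree-preserving configurations.
- Degenerate inputs: empty edge lists and empty gold standards raise
  contract errors; a pair list that empties under thresholding produces
  empty downstream lists rather than an error; degree sequences admitting
  a single configuration return the input with a warning.

## The synthetic-data generator

`fixtures.generate_universe` emulates every input table from one seeded
stream. Each planted chain inserts a drug that binds `planted_overlap`
genes (with passing activity rows), annotates those genes and one
phenotype to a common disease, and stamps the genes with a common FunFam —
so the planted (phenotype, drug) pair is guaranteed at least
`planted_overlap` shared targets in both chains. Background edges are
independent Bernoulli draws per node pair: the simplest exchangeable null,
chosen to be consistent with the degree-preserving randomization model
used in validation.

Default sizes (40 diseases, 60 genes, 30 phenotypes, 12 FunFams, 30 drugs,
densities 0.05–0.08, 3 planted chains of 2 targets) are deliberately
large enough that the gold-standard universe (planted pairs + 12
background gold pairs) is sparse relative to the possible pair space.
This matters: if the restricted prediction list is close to a complete
bipartite block, degree-preserving swaps have no freedom and the
confirmed/random ratio degenerates to 1 by construction — a regime real
validation data (where the gold standard dwarfs the predictions) does not
occupy. The co-mention corpus is 10⁶ articles with planted pairs
co-mentioned 30 times against an expected 0.04 (strongly significant) and
background pairs drawn at their chance rate.

What the generator does **not** emulate: realistic degree distributions
(real disease-gene networks are heavy-tailed), correlated pleiotropy,
ontology structure among phenotypes, and name-resolution noise in the
literature counts. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted signal under exchangeable
background — not performance on real annotation databases.

## Known limitations

- The union-universe convention for N makes scores dependent on the pair
  of lists projected; comparing indices across projections with very
  different universes should be done with care.
- The binomial enrichment background is the filtered target universe, a
  conservative, self-contained choice; a whole-proteome background would
  make more FunFams significant.
- The rigidity check in `randomize_links` detects only the trivially
  forced cases (complete bipartite, single node on a side); other rigid
  degree sequences are handled implicitly (no swap ever succeeds) without
  a warning.
- Problem sizes in the test and acceptance suites (universes of tens of
  nodes, 100 null replicates, 20 seeds) are the package's own desk-scale
  study conditions; the pipeline streams pairs and scales to much larger
  inputs.
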