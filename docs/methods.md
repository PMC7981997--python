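# Methods

## Scope and model of the analysis

The pipeline formalizes the screening logic of herbal network
pharmacology: a preparation's compounds are reduced to drug-like
candidates, mapped to predicted protein targets, cross-referenced against
disease genes from two independent evidence streams (curated relevance
scores and tumor-vs-normal expression), and the surviving target set is
characterized structurally (PPI topology, dense modules) and functionally
(gene-set over-representation). Every stage is a deterministic function
of its input table and its thresholds; there is no fitting.

## Drug-likeness gate

Each compound carries fourteen physicochemical descriptors (MW in Da,
three logP variants, H-bond donor/acceptor counts, TPSA in Å², rotatable
bonds, molar refractivity, heavy-atom/ring/carbon/heteroatom counts) and
an ionization class at pH 6–7. The five rule systems use the thresholds
of their common ADME-tool implementations; where a rule is sensitive to
the logP estimator, the conventional pairing is used (MLOGP for Lipinski,
WLOGP for Ghose and Egan, XLOGP for Muegge). Bounds are inclusive except
Muegge's strict carbons > 4 and heteroatoms > 1. The Abbott
bioavailability score is the Martin (2005) decision tree: anions are
scored on TPSA alone (≤ 75 → 0.85, ≤ 150 → 0.56, else 0.11); every other
class scores 0.55 if rule-of-five compliant, else 0.17. The candidate
gate — at least `min_rules_passed = 2` systems passed and score
`min_bas ≥ 0.30` — makes the gate monotone: improving any single
descriptor toward compliance can only keep or gain candidacy (a property
the suite tests).

Unknown ionization classes fall back to "neutral" with a warning rather
than failing the record, because descriptor exports routinely lack
reliable ionization calls; the fallback is configurable.

## Target and disease-gene selection

Predictions are kept at probability ≥ `p_min = 0.1` (inclusive, matching
the usual target-prediction export convention); duplicate
(compound, gene) rows collapse. A compound that appears in the prediction
table but has no passing row keeps an *empty* entry: it still shows up as
an isolated node in the compound–target network (mirroring how such
networks are usually drawn from the raw export) while being dropped from
the compound funnel as "targetless". Disease genes pass at relevance
score ≥ `score_min = 10`, inclusive.

Expression validation ranks genes by log2((mean tumor + 1)/(mean normal
+ 1)); the pseudo-count of 1 keeps the ratio defined and is negligible at
the expression magnitudes generated (baselines ≥ 2⁴). A Welch t statistic
is available as an alternative ranking (`method="welch"`) since the
upstream database's internal statistic is not public; log-fold-change is
the default because it is deterministic and matches the
"over/under-expression" semantics. The over and under sets are the first
and last ⌈fraction·G⌉ genes of one total order (effect descending, gene
symbol ascending on ties), which makes them disjoint by construction —
2⌈fraction·G⌉ > G is rejected — and makes label swapping exchange the two
sets exactly in the tie-free case. Gene symbols are uppercased and
stripped on ingest; no alias dictionary is consulted.

## Network topology

Networks are simple undirected graphs with a node-class attribute.
Betweenness is Brandes accumulation normalized by (n_c−1)(n_c−2)/2 within
each connected component; closeness is the within-component normalized
form (n_c−1)/Σd. The literal reciprocal distance sum (1/Σd) and
unnormalized betweenness sit behind flags: the normalized forms are the
defaults because they are what the standard interactive network tools
report, and only they produce closeness values in the 0.3–0.5 regime
typical of published compound–target networks. Cross-component distances
are never summed. PPI filtering is strictly greater-than the confidence
threshold (0.7), keeping the highest score of duplicate pairs and
discarding self-loops; hub ranking is by degree with deterministic
tie-breaks (betweenness, then id).

## MCODE

The three-stage Bader–Hogue algorithm. Vertex weight = k_max × density of
the k_max-core of the closed neighborhood; vertices under the degree
cutoff (2) weigh zero, so they cannot seed but may be absorbed. Complexes
grow breadth-first from the highest-weight unvisited seed, absorbing
unvisited neighbors with weight ≥ (1 − node score cutoff) × seed weight
(cutoff 0.2, depth limit 100, configurable); each vertex joins at most
one complex, so complexes are disjoint. Post-processing replaces each
complex by the 2-core of its induced subgraph (the "haircut", realized as
the full core computation, which subsumes iterated pendant removal) and
discards coreless complexes; "fluff" (absorbing neighbors whose closed
neighborhood density exceeds a threshold, potentially creating overlaps)
exists but is off by default. The cluster score is density × size,
n·2e/(n(n−1)) — equal to n exactly when the complex is a clique — and
clusters rank by score, then size, then seed id.

A consequence worth knowing: only weight-homogeneous modules (cliques)
are guaranteed to be returned whole. In a planted module wired as a
spanning cycle plus random chords, low-degree members can fall below the
80 % weight band of the seed and are trimmed; the detected complex is
then a dense subset of the planted module. The tests therefore assert
exact recovery for clique modules, containment within a single module for
everything else, and Jaccard ≥ 0.9 recovery of a 12-clique planted in a
200-node sparse background.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k) computed
by the library survival function (evaluated stably in log space); the
EASE variant P(X ≥ k−1) is selectable for compatibility with
annotation-chart tools that default to it. The universe defaults to the
union of all term memberships and is overridable; query genes outside the
universe are dropped with a warning. BH adjustment runs within each
category (BP, CC, MF, KEGG) separately, mirroring how GO domains and
pathway charts are reported separately; the significance gate is
FDR < 0.01. The rich factor is overlap/term-size (k/K). Because the
statistic is discrete, the null fraction of raw p < 0.05 is conservative;
the suite checks it stays within [0.02, 0.09] over 1000 seeded uniform
queries.

## Synthetic data: what it emulates and what it does not

The generators emulate the *column structure and filtering-relevant
statistics* of the six database exports, with planted ground truth:

- compounds: 97 rows, 56 sampled inside the intersection of all rule
  boxes (score 0.55/0.85), 41 violating every rule system (score 0.17);
- predictions: 53 active compounds sharing exactly 3747 passing pairs
  over exactly 729 genes (every compound and gene covered by
  construction), 3 gate-passing compounds with only sub-threshold rows,
  plus duplicate and sub-threshold noise rows;
- disease genes: 1893 passing scores, exactly 272 shared with the
  prediction universe, plus sub-threshold distractors;
- expression: 2000-gene panel, 30 tumor / 10 normal samples (the
  published tumor/normal designs, mirrored at reduced scale), log-normal
  baseline (log2 base uniform on [4, 10]), per-sample Gaussian log2 noise
  (SD 0.5), planted ±2 log2-fold shifts on 68 + 68 genes drawn from the
  272-gene overlap; the panel excludes the other 204 overlap genes, so
  the second intersection is exactly the planted 136;
- PPI: seven modules wired exactly to the shapes (13,58), (5,10), (5,8),
  (6,8), (3,3), (3,3), (8,10) — spanning cycle plus random chords, so a
  2-core is guaranteed — with confidences > 0.7, over an Erdős–Rényi
  background (p = 0.02) whose confidences straddle 0.7;
- annotations: per category, one term with engineered 30/40 overlap with
  the final target set plus uniform decoys.

One master seed drives per-table substreams (numpy `SeedSequence` spawn
keys), so regeneration is byte-identical and adding a generator never
perturbs existing tables. What the generators do **not** emulate: real
descriptor correlations, scale-free PPI degree structure, correlated
expression, GO term nesting, or gene-symbol aliasing. Passing tests
demonstrate that the pipeline's logic is correct under the planted
conditions, not that any biological conclusion transfers to real
database exports.

## Numerical and design choices

- Thresholds are inclusive (≥) except PPI confidence (strictly >),
  following the respective conventions of the source tools.
- All order-sensitive steps (decile boundaries, hub ranking, cluster
  ranking, seeding) break ties deterministically, ultimately by
  lexicographic id, so identical inputs give identical outputs and the
  run report is byte-reproducible.
- Compound ids and gene symbols share one node namespace in networks;
  a collision raises rather than being silently renamed.
- Problem sizes in the suite (atlas graphs ≤ 7 nodes for the centrality
  oracles, random graphs ≤ 8 nodes for the k-core oracle, 1000 null
  replicates, a 2000-gene expression panel) were chosen as the smallest
  scales at which the checked properties are non-trivial and exhaustive
  enumeration remains exact.

## Known limitations

- No SMILES-to-descriptor computation: descriptor tables are the
  canonical input (an adapter could sit in front).
- No GO ancestor propagation or term de-duplication; terms are tested as
  given.
- MCODE's directed "max depth" growth and fluff overlap semantics are
  implemented plainly (breadth-first depth limit; density-threshold
  fluff) and have not been tuned against the original plug-in beyond the
  documented defaults.
- Weighted shortest paths and directed networks are out of scope.
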