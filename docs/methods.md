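# Methods

## The task and its data model

A literature-based GO annotation is modeled as a triplet: a gene product
(numeric id, symbol, NCBI taxon), a GO term, and evidence consisting only
of the cited article's title and abstract (full text is deliberately out of
scope — many PMIDs grant no full-text access, and some old records have no
abstract at all, which the `Document` type permits). Only records with an
experimental evidence code (EXP, IDA, IPI, IMP, IGI, IEP) and a PMID are
admitted; they are assumed consistent (CO) on read. Each instance carries
exactly one label from {CO, OS, OB, IM, IG}: the inconsistency types are
treated as mutually exclusive and independent, so detection is a single
5-way classification rather than multi-label tagging.

## Ontology graph

The GO hierarchy is restricted to `is_a` and `part_of`. Every forward
(child→parent) edge is mirrored by a generated reversal (`parent_is_a`,
`parent_part_of`) so that graph learning can aggregate in both directions;
the reversal bijection is an invariant checked on load. The forward
subgraph must be acyclic (verified with networkx; a found cycle is reported
in the error). Obsolete terms remain as vertices — so old records can still
be looked up — but all their hierarchical edges are dropped and they are
excluded from traversal and from the recognizer dictionary. Ancestor
closure mixes `is_a` and `part_of` steps freely: the two relations both
express "broader than" for the purposes of specificity, and nothing in the
task requires relation-pure paths. Other relations (`regulates`,
`occurs_in`, ...) are dropped silently with a logged count.

## Synthesis of the four inconsistency types

Each rule perturbs exactly one field of a consistent source record
(single-perturbation invariant, property-tested):

* **OS** — substitute a uniformly chosen *direct child* of the term; a leaf
  term yields a skip.
* **OB** — substitute a uniformly chosen *ancestor at any depth* (uniform
  over the closure, no depth weighting: nothing justifies one); a root
  yields a skip. Allowing any depth makes OB semantically "easier" than OS,
  whose substitute is always one step away.
* **IM** — substitute a concept that the dictionary recognizer finds in the
  instance's own title+abstract but that is *not* annotated to this gene
  under this PMID; skip when no such mention exists.
* **IG** — substitute a gene product co-cited under the same PMID that is
  *not* associated with this term there; skip when the PMID cites no other
  gene.

Dataset assembly partitions PMIDs (never individual records) across
train/dev/test, so no evidence text is shared between splits; dev and train
also share no source record. Train and dev are balanced 50% CO and 12.5%
per type (largest-remainder rounding makes quotas sum exactly to the split
size); the test set is imbalanced by design — 238 CO plus 48 of each type,
430 in total, under the defaults — to mimic the consistent-majority regime
of real databases. Skipped syntheses are back-filled by drawing a fresh
source from the same split's pool until quotas are met; an exhausted pool
raises a capacity error reporting what was achievable. All randomness
derives from one seed with fixed per-split substreams, so assembly is
bit-reproducible.

**Label-noise injection** relabels exactly round(fraction·N) instances
(round-half-away-from-zero), each at most once: an inconsistency label
becomes CO, a CO label becomes one of the four types chosen uniformly (the
target type is otherwise unconstrained). Contents are untouched — noise is
purely a labeling phenomenon. **Taxon splits** partition instances by the
gene's taxon for the out-of-distribution protocol (train on one species
set, test on a disjoint one).

## Concept recognition

The recognizer is a deliberately simple, reproducible stand-in for a
full dictionary tagger: exact matching of normalized phrases (lowercase,
punctuation stripped, whitespace collapsed), greedy longest-match scanning
left-to-right on token boundaries, non-overlapping spans, synonyms behind a
flag, obsolete terms excluded. A phrase shared by several terms emits one
mention per term at the same span. No stemming or variant generation is
attempted; this matching policy is the package's own and shifts baseline
behavior relative to any richer tagger — a caveat, not a bug.

## Rule baseline

Step (a): an instance whose term is recognized in its evidence is
consistent. Step (b), applied otherwise: over-specific if the term is a
strict descendant of *every* recognized concept (evaluated first);
over-broad if it is a strict ancestor of *at least one*. An empty
recognized set routes to `inconsistent_unspecified` rather than vacuously
satisfying the universal rule — labeling something over-specific with zero
evidence concepts would be unfounded. A term satisfying both rules is
impossible on an acyclic graph and is asserted, not branched. Two blind
spots follow from the design and are preserved faithfully: IM instances are
always called consistent (their term *is* recognized), and no IG label
exists at all; evaluation records those cells as NA and excludes them from
the baseline's macro average. Note the universal quantifier in the OS rule
means OS recall 1.0 is only attainable when the recognized set of each
document is exactly the annotated source term; the single-annotation,
distractor-free world exists to exhibit that regime cleanly.

## Specificity embeddings (edge-type GNN)

Node vectors are learned from 4-way edge-type classification on the typed
graph (forward edges and reversals both carry labels and both carry
messages, so neighborhoods are effectively bidirectional). The network is
two GraphSAGE-style layers, each computing

    h_u = BatchNorm(ReLU(W_s x_u + W_n · maxpool_{v∈N(u)} ReLU(W_p x_v)))

with input and output width d = 120, batch normalization after the
activation (the pre-activation variant is not explored), followed by a
single-hidden-layer MLP (width 2d) on the ordered concatenation
[h_u ; h_v] producing 4 logits. Edges are split 74%/26% into train/test
(every typed edge in exactly one split); training is mini-batched over edge
samples with full-graph message passing per step, Adam with decoupled
weight decay 0.01 and linear warmup, cross-entropy loss, loss logged per
epoch, non-finite loss raising a training error. Batch normalization uses
batch statistics at inference too: all call sites run full-graph batches,
which keeps extraction deterministic without running-average state. The
final-layer vectors are the exported specificity embeddings.

Feature providers: (i) hashed character-3-gram bags of the term name
(CRC32 hashing — Python's builtin hash is salted and non-reproducible);
(ii) any callable mapping terms to vectors, with a fixed-seed
random-projection helper for wide encoder outputs (no pretrained encoder is
bundled); (iii) structural features [depth, fan-in, fan-out] tiled to d,
used throughout the tests because they make the learning target exact; and
an all-zero control provider that bounds what graph structure alone can do
(all nodes collapse to one embedding, so accuracy sits at chance).

All dense math, including the max-pool scatter (gradient split uniformly
across ties) and batch-norm backward, is hand-written numpy in `goaqc._nn`
and is verified against finite-difference gradients in the test suite.

## The 5-class classifier

Every instance is rendered as `[CLS] title || abstract || gene symbol
[SEP] GO term [SEP]`, padded with `[PAD]` or truncated to 350 tokens;
truncation removes abstract tokens from the right and never touches the
gene symbol or term — they are the decision-critical fields. A WordPiece
style tokenizer (greedy longest-prefix, `##` continuations, e.g.
"polycomb" → "polyc", "##omb" under a vocabulary lacking the full word) is
provided for subword encoders; the light path uses case-preserving word
tokens, keeping sentence-final periods as tokens for sentence bookkeeping.

The default encoder is a deterministic featurizer computed from the token
stream alone — an explicit, inspectable emulation of what a contextual
encoder learns for this task: exact and tail (first-token-dropped)
term-phrase occurrence in the text, longest common contiguous run, whether
the term match shares a sentence with the gene symbol, whether that
sentence carries a *different* gene-shaped token (uppercase+digit pattern),
the hashed identities of the tokens flanking the term match, term length,
and hashed bag-of-words vectors for the text and term segments (all hashing
CRC32). Any object with `dim` and `encode(seq)` can replace it, e.g. a
transformer wrapper; the architecture contract is sequence vector →
optional fusion → single-hidden-layer head → 5 logits.

In fusion mode the instance term's specificity embedding is concatenated to
the encoder vector before the head (head width is asserted to equal
encoder dim + embedding dim; a term without an embedding is an error naming
the term). Training standardizes features on the train split and optimizes
cross-entropy with Adam (decoupled weight decay 0.01, warmup 300 steps,
batch 16; 5 epochs plain / 3 fusion by default — fusion converges faster
because the specificity signal arrives precomputed; learning rate 5e-3 for
the light path, a package default not taken from elsewhere). Dev loss is
logged per epoch. Prediction applies softmax, argmax with
lowest-class-index tie-break in the fixed order CO<OS<OB<IM<IG (persisted
in the model sidecar), and τ = Shannon entropy of the probabilities in
bits, bounded by log₂5 ≈ 2.32.

## Evaluation protocol

One-vs-all per inconsistency type with CO as a permanent negative: tp =
predicted=target ∧ gold=target; fp = predicted=target ∧ gold≠target
(including gold CO); fn = predicted≠target ∧ gold=target. Adding correctly
classified consistent instances therefore changes no type metric
(CO-neutrality, property-tested), so the consistent majority cannot inflate
scores. Zero divisions yield 0 with a flag rather than NaN. The macro
average runs over exactly the four types; NA rows (baseline IM/IG) reduce
the divisor and flag the row. Uncertainty-thresholded F1 counts a
prediction positive only when its label matches the target *and* τ < t
(strict); a correct-label prediction failing the threshold is counted as a
miss — abstention is a miss, which keeps tp+fn equal to the class support
at every threshold. Default thresholds: {0.5, 0.75, 1, 1.25, 1.5, 1.75, 2,
2.3}; default noise fractions: {0, 10, 15, 25, 40, 60, 80, 100}%. The
noise and OOD harnesses accept any `train_fn(train, dev, seed) →
predict_fn` and evaluate all conditions on one shared test set.

## The synthetic world

The generator emulates the *shape* of the real inputs, not their prose.
Term names come from a closed modifier/head pseudo-vocabulary disjoint from
the sentence filler and verb vocabularies, so a term name can only occur
where one was embedded. Names are unique; a child's name extends its
primary parent's name by one leading modifier (as in real GO: "response to
calcium ion" → "cellular response to calcium ion"), which gives names a
depth signal and makes an ancestor's name a sub-phrase of its descendants'
names along primary chains. The DAG is built level-wise (6 levels by
default, sizes growing geometrically, up to 3 roots, occasional second
parents at the same level), so depth is exact. The relation kind of an
edge is a deterministic function of the child's depth — edges in the deeper
half are `part_of` — a stand-in for the namespace-correlated `part_of`
density of real GO that makes edge types predictable from structural
features; with it, edge-type classification is genuinely learnable rather
than vacuous.

Documents cite ≥2 genes of one taxon and annotate 4 terms by default; with
probability `signal` an annotation's sentence embeds the term name verbatim
next to the gene symbol, and gene-free distractor sentences embed
additional term names as irrelevant-mention material. Annotated terms are
drawn from all non-root levels with the deepest level down-weighted
(annotation bias toward mid-depth terms; it also keeps the over-specific
skip rate low). Gene symbols are uppercase letter+digit strings, visually
distinct from all vocabulary words. Taxa are assigned round-robin from
{9606, 7227, 10116, 3702, 6239}; an optional partitioned mode assigns
disjoint term sets and filler/verb dialects per taxon to create genuinely
out-of-distribution species for the OOD experiment. Defaults (400 terms,
300 genes, 6000 documents, signal 1.0) size the world so the full default
study — 20 000 train, 250 dev, 430 test — assembles without exhausting the
pool; signal 1.0 is the clean reference condition under which the source
records are assumed consistent.

What passing tests on this world do *not* show: robustness to real
biomedical prose (paraphrase, anaphora, abbreviations), to gene synonymy
and variant symbols, to real GO's term-frequency and depth distributions,
or to annotation bias across species. The world is a controlled instrument
for validating the machinery, with a signal dial connecting the trivial
regime to the impossible one.

## Numerical choices and problem sizes

All experiments run on one CPU in seconds to a couple of minutes; the
package's own test and acceptance runs use: a 120-term/1500-document world
with 2000/100/215 splits for classifier experiments; a 200-node DAG (d =
120, 50 epochs, batch 64, warmup 100) for edge-type learnability; 1000
syntheses per type for soundness; 1500-instance ID/OOD pools on a
taxon-partitioned 150-term world. These sizes were chosen as the smallest
at which the qualitative phenomena are stable. Ties in argmax resolve to
the lowest class index; max-pool gradient ties split uniformly; batch-norm
epsilon 1e-5; feature standardization guards zero variance; CRC32 is used
wherever hashing must be reproducible.

## Known limitations

The light encoder's handcrafted overlap features are tuned to the
generator's sentence templates; on real text a contextual encoder is
expected to be necessary (the interface accepts one). The IM and IG types
can be observationally identical when an irrelevant mention happens to be
another gene's annotated term — both detectors' confusion between them is
inherent to the observable signal, not a defect. The baseline's OS rule is
brittle under multi-concept evidence (see above). No statistical
significance testing is performed between detector variants, and no
attempt is made to model the two rare inconsistency kinds outside the four
types (unsupportive evidence, wrong evidence code).
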