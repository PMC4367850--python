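# Methods

## Model

A document is annotated by a set of concepts from a rooted IS_A DAG. The
working assumption is the one every neighbor-based indexer makes: similar
documents should be similarly annotated, so the concept sets of a document's
nearest annotated neighbors carry nearly all the signal needed to annotate
it. What the raw union of neighbor concepts lacks is *consistency* (it keeps
several near-synonyms where one suffices) and *precision* (it keeps
document-specific concepts supported by a single neighbor). Both problems
are addressed by scoring whole candidate sets with ontology similarity
rather than scoring concepts individually by frequency.

Specificity is intrinsic (Seco) information content,
`IC(c) = 1 − log(hypo(c)+1)/log|V|`, chosen over corpus-based IC so the
machinery applies to any vocabulary without usage statistics. It is exactly
0 at the root, exactly 1 at every leaf, and strictly decreasing from a
concept to any strict ancestor (a strict ancestor has strictly more
descendants). A useful corollary: two *distinct* concepts can never reach
Lin similarity exactly 1 under this IC, since the MICA's IC is bounded by
the smaller of the two ICs and equals it only for the concept itself.

Pairwise similarity is Lin's `2·IC(MICA)/(IC(x)+IC(y))`; groupwise
similarity is the Best Match Average; the objective is the mean BMA to the
k-NN annotations minus `μ·|A|`.

## Search

Both hill climbers are steepest-ascent: from the full pool A₀, each round
evaluates the removal of every current concept and applies the single best
strictly improving one. The first-improvement variant (remove the first
concept whose removal helps, in scan order) is kept behind
`hill_climb_naive(strategy="first")` purely as a baseline; it is order
dependent and more easily trapped.

The optimized climber maintains per-neighbor state. Because the rows of the
restricted similarity matrix (the neighbor's concepts) never change, each
neighbor's column maxima over the full pool are computed once; testing the
removal of concept c then subtracts one known value per neighbor. Row
maxima do change, but only for rows whose current best match *is* c; a
provider index (row → argmax column) identifies them, and a membership
index (concept → neighbors containing it) propagates each row's max delta
into the affected neighbors' row-max sums. Tentative removals never mutate
the state: each evaluation returns the values it would change, and the
winner's cached values are applied directly, so acceptance recomputes
nothing. In debug mode every accepted removal is followed by a from-scratch
recomputation of all sums; deviations above 1e-9 raise.

Determinism rules, fixed so the two climbers produce bit-identical traces:

* concepts are evaluated in canonical (lexicographic) order;
* a removal is accepted only if it improves f by more than 1e-12 (an
  *increase*, not a non-decrease — removals that leave f unchanged are not
  taken);
* a later candidate replaces the incumbent best only if it improves on it
  by more than 1e-12, so equal-gain ties resolve to the lexicographically
  smallest concept;
* row-max argmax ties resolve to the smallest column index.

Tie-breaking in the exhaustive oracle: among subsets within 1e-12 of the
maximal f, the smallest subset, then lexicographic concept order. The
minimum annotation size is 1, and concepts outside A₀ are never added:
enrichment buys little and complicates the bookkeeping.

Degenerate cases: a Lin denominator of zero occurs only between two roots;
similarity is 1 for the identical pair, 0 otherwise. Inputs with several
apparent roots are joined under a synthetic virtual root (IC 0) rather than
rejected. An empty BMA operand is always an error — the search cannot
produce one, so silence would hide bugs. If the ≥2-document filter empties
the pool, the unfiltered pool is used with a warning.

## Parameters

* `k` (default 20): neighbors kept. Unannotated neighbors are skipped
  without consuming a slot, so k counts *annotated* neighbors. Quality
  plateaus near k≈10–20 in this family of methods while cost keeps growing.
* `μ` (default 0.0): concision penalty per kept concept, dimensionless on
  the same scale as BMA (which lives in [0,1]). The neutral default makes
  the objective pure similarity; even at μ=0 the climber prunes concepts
  whose removal raises mean BMA. Values of a few hundredths already bite:
  each kept concept must buy that much mean similarity.
* `min_docs` (default 2): filter support threshold; 1 disables filtering.
* MDS: classical (Torgerson) scaling — deterministic eigendecomposition, no
  seed, negative eigenvalues clamped to zero; dissimilarity is
  `1 − sim_BMA`, the simplest monotone transform. The simulated expert
  click embeds a pseudo-document carrying the gold annotation *jointly*
  with the candidates (the alternative — out-of-sample projection onto a
  candidates-only map — would shift coordinates slightly; joint embedding
  keeps the click and the map in one geometry).

## Synthetic data

The generators stand in for a benchmark corpus. Ontologies are random
rooted DAGs (concepts added in order, each choosing 1..max_parents earlier
parents — `max_parents=1` yields a tree). Gold annotations are drawn
uniformly from the non-root concepts; the root carries zero IC and no
curator would annotate with it. Neighbor annotations perturb the gold
concept-wise: dropped with `p_drop`, substituted by a uniformly drawn
parent/child/sibling with `p_substitute` (sibling = shares a parent; the
substitution semantics mimic a near-miss human indexer, which is what the
Lin measure is supposed to forgive), and with `p_add` an unrelated concept
is added per slot. Neighbors are ranked by BMA similarity to the gold,
standing in for a retrieval engine's proximity score.

What this emulates — and what it does not: real neighbor annotations are
not conditionally independent perturbations of a single gold set, real
ontologies are deeper and bushier than 30–60-node random DAGs, and real
retrieval rankings are noisier than BMA-to-gold. Passing tests therefore
demonstrate the *algorithmic* contracts (equivalence, optimality bounds,
recovery, metric behavior), not absolute scores on any benchmark corpus.

Property-suite problem sizes: the equivalence suite draws 500 instances
with pool ≤ 30 and up to 12 neighbors, cycling μ through
{0, 0.005, 0.02, 0.1}; the exhaustive-bound suite 200 instances with pool
≤ 12 (2^12 subsets each, evaluated with a vectorized enumerator that is
itself cross-checked against the direct objective); recovery and noise
suites use 100 and 60 instances per condition. These sizes give stable
fractions while keeping the whole suite around half a minute.

## Known limitations

* Seco IC degenerates on a single-concept ontology (rejected) and gives
  IC 0 to every root, so concepts directly under a flat root are mutually
  dissimilar regardless of intent.
* The hill climber is greedy: on roughly 5–10% of small random instances it
  terminates at a local maximum below the exhaustive optimum (the fraction
  is measured, not asserted away).
* Only IS_A edges contribute to IC and MICA; `part_of` and other relations
  are deliberately ignored.
* Evaluation macro-averages per-document scores; no micro-averaged variant
  is provided.
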