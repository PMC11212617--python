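# Methods

## Model

The unit of evidence is a publication *k* with its duplicate-free sets of
tagged targets and disease terms; *T_k* and *D_k* are the sizes of those sets.
Both scores are fractional counts:

* **Novelty** `N_i = 1 / Σ_k 1/T_k`, summed over every publication mentioning
  target *i*, with no requirement that the publication also mention a disease.
  A target discussed only in many-target surveys retains high novelty; a
  target with dedicated single-target papers quickly loses it.
* **Importance** `I_ij = Σ_k 1/(T_k · D_k)`, summed over the publications
  supporting the (i, j) association. Each publication distributes one unit of
  attention evenly over its T_k·D_k (target, disease) pairs, so a single
  focused paper contributes at most 1.0 to any association.
* **Disease novelty** is the symmetric analogue `N_j = 1 / Σ_k 1/D_k` over the
  publications mentioning disease *j*. It exists so that target-centric
  browsing can place diseases on a novelty axis.

Because each publication's 1/T_k splits exactly across its D_k diseases, any
target whose publications all mention at least one disease satisfies the
conservation identity `Σ_j I_ij = 1/N_i` over its direct association partners.
Publications without disease mentions enter the novelty denominator but no
importance sum, breaking the identity for their targets; the test suite
asserts both directions.

## Ontology propagation

Support is propagated at the publication-set level: a publication mentioning
disease *d* supports (t, a) for each of its targets t and every
`a ∈ {d} ∪ ancestors(d)` along `is_a` edges. Unions, not score sums, are
propagated — a paper mentioning two siblings contributes once to the shared
parent, so parent importances cannot double-count. *D_k* always remains the
count of *directly* mentioned terms: propagation changes which pairs a paper
supports, never how its attention is divided. An alternative design would sum
child scores into parents; it was rejected because it double-counts multi-
descendant papers.

For an ancestor term that is never tagged directly, disease novelty is
computed over the propagated publication pool (papers mentioning the term or
any descendant), again with direct *D_k*. For directly tagged leaves this
reduces to the plain definition. This choice keeps every exported association
fully annotated with a positive disease novelty.

Only `is_a` edges are traversed. `alt_id`s resolve to their primary term;
obsolete terms carry no parents and resolve through `replaced_by` exactly
once. A cycle among non-obsolete terms or an `is_a` to an undefined term
aborts the load: a broken ontology should fail loudly, not propagate subtly
wrong supports.

## Ranking

Queries are ranked by non-dominated sorting over (novelty, importance), both
maximized; ranks are computed per query (one disease's targets, or one
target's diseases), matching how results are browsed, not globally. The
default dominance convention is weak (≥ in both coordinates, > in at least
one). With strict dominance a point that ties the front in one coordinate but
loses in the other would be promoted onto the front, which misleads exactly
where ties are common — small corpora put many associations at identical
novelty values. Strict mode remains available (`--dominance strict`); the two
differ only at exact ties, and equal points never dominate each other in
either mode, so duplicates always share a rank.

The weak-mode ranker is an O(n log n) sweep: points are processed in
lexicographically decreasing order and binary-searched into the first front
whose best point fails to dominate them (per-front maxima are monotone across
fronts, making the bisection sound). Within a front, rows are ordered by
importance descending, then novelty descending, then target and disease id —
a total order, so output is byte-stable. The top k rows (default 300) are
returned; everything is returned when fewer exist.

## Numerical choices

All score accumulation runs in double precision in publication-id-sorted
order, making outputs bit-reproducible under any input permutation. Exported
floats use `repr` (shortest round-trip decimal). Zero-publication targets or
empty supports raise instead of returning 0 or infinity: those quantities are
undefined, and silent sentinels would corrupt downstream ranking. Plot
coordinates are log10 by default (switchable to natural log); the base
affects exported coordinates only, never ranks.

## Synthetic corpora

`tinx simulate` emulates a tagged-literature corpus: per publication the
numbers of targets and diseases are Poisson draws (defaults: mean 1.5 each,
truncated at the pool size, zero allowed — single-entity papers exist in real
corpora and matter for the conservation behaviour), targets are drawn with
Zipf weights (default exponent 1.0) so that a few heavily studied targets
coexist with a dark tail, diseases uniformly, and the ontology is a random
tree of configurable depth (default 3). Defaults of 50 targets, 30 diseases
and 500 publications give corpora where propagation, ties and disease-free
papers all actually occur. A single seeded generator drives every draw;
identical configurations produce byte-identical files.

Each simulated corpus ships a ground truth computed by a naive double-loop
oracle (its own ancestor walk, its own score loops, no code shared with the
scoring or ontology modules), which the pipeline must match to 1e-12.

The generator does not model citation networks, MeSH indexing, tagging errors
or paper-mill artifacts, and real mention data is far more skewed and noisy
than a Poisson/Zipf draw. Passing tests therefore demonstrate correctness of
the computation on well-formed mention tables, not robustness of upstream
named-entity recognition.

## Artifacts and problem sizes

`tinx compute` validates and loads all inputs before writing anything, so a
failure leaves no partial artifact directory. The artifact set
(associations, per-disease ranked tables in TSV and CSV, support map,
publication metadata, checksummed manifest) is self-contained: `tinx query`
and `tinx export-json` read artifacts only, reflecting that scores are
precomputed once and queried many times. The single `ranked.tsv` is grouped
per disease (targets ranked within each disease), the primary browse
direction; per-target rankings are produced on demand by `tinx query
--target`.

The verification suite uses 100 random corpora of up to 500 publications for
the conservation and oracle checks and 1,000 random point sets of up to 2,000
points (mixing continuous coordinates with coarse integer grids to force
duplicates and ties) for the ranking oracle; these sizes exercise every code
path, including multi-front peels and propagation through 4-level DAGs, while
keeping the full suite under a minute.

## Known limitations

* Mentions are consumed as given: no named-entity recognition, no confidence
  filtering of the upstream tagger, no retrieval from PubMed or target
  databases.
* Disease novelty for ontology-internal terms is this package's definition
  (propagated publication pool); other reasonable definitions exist.
* Ranking considers exactly the two score axes; no diversity or crowding
  criteria are applied within fronts.
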