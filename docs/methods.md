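# Methods

## Data model

The store (`xenograph.store.TripleStore`) holds RDF triples of rdflib
terms in plain Python sets with subject/predicate/object indexes and a
per-triple provenance flag (`asserted` vs `inferred`). (s, p, o) identity
ignores provenance; a triple that is both asserted and derivable is stored
as asserted, and the reasoner's support bookkeeping still tracks its
derivations so retraction semantics stay correct. Blank nodes are not
used: annotation nodes get minted URIs, so graphs compare as plain sets.

The ontology (`xenograph.vocab`) declares the operational classes (Case,
Tissue, Bioentity with open-ended subtypes DNA/RNA/CellLine/Mouse/Aliquot),
the knowledge classes (Chromosome, Region, Gene, Exon, Transcript, Peptide,
Alteration with subclasses Sequence_Alteration and Copy_number_variation,
of which Feature_amplification is a subclass, Treatment, Drug_response,
Response_type) and the Annotation bridge. The axioms that drive inference:
`generates ⊑ hasDescendant` with `hasDescendant` transitive, one variant
predicate per alteration category each `⊑ has_variant`
(`has_feature_amplification ⊑ has_copy_number_variation ⊑ has_variant`),
and the subclass hierarchy above.

Validation is a report, not an exception: unknown local classes, untyped
`generates` endpoints, malformed annotation shapes (not exactly one
`has_reference`, no incoming `has_annotation`) and `generates` cycles.
Acyclicity is enforced at validation rather than insertion so that bulk
loads stay order-independent.

## Reasoner

Materialization is the fixed point of three rules — sub-property lifting,
transitivity, sub-class typing — a deliberate narrowing to the rule subset
the data model actually exercises rather than a full OWL-Horst engine.
Sub-property and sub-class relations are closed reflexively-transitively
up front, so each rule application is a single hop; transitivity applies
to the lifted super-property graph. Closure is bounded by
nodes² · predicates, so it terminates on any input, including cyclic ones
(where it computes reachability; validation separately flags the cycle).

Incremental maintenance:

* **assertion** — semi-naive propagation seeded with the new triple; each
  triple entering the graph is processed exactly once as a rule premise.
* **retraction** — delete-and-rederive (DRed): overdelete every inferred
  triple whose derivation may pass through the removed one (joins are
  evaluated against a pre-deletion snapshot), then rederive overdeleted
  triples that have an alternative derivation, to a fixed point. DRed was
  chosen over pure derivation counting because counting is unsound in the
  presence of cyclic derivations, which cyclic inputs can produce.
  Retracting an inferred triple is rejected with an explanatory error.

`support_counts` (distinct one-step derivations per inferred triple) is
computed lazily and cached, invalidated on mutation; keeping it exact
per-operation would dominate the cost of maintenance without changing any
entailment.

## Response classification

Percent tumor-volume variation Δ maps to positive (Δ ≤ −50), negative
(Δ ≥ +35) or neutral (−50 < Δ < +35). Both boundaries are inclusive toward
the outer classes — "at least −50%" and "at least +35%" read literally.
Δ < −100 or non-finite is a domain error (a tumor cannot lose more than
its own volume). The classifier is monotone non-decreasing in Δ along
positive < neutral < negative.

Annotation URIs are minted as `namespace + annotation/ + sha1(target |
reference | timestamp | session)[:16]`, with a numeric disambiguator for
identical repeats, so re-running an annotation script reproduces the same
graph. Volume variation is stored on the annotation node, not the
bioentity, so longitudinal repeats stay distinct observations.

## Cohort analytics

`roll_up` collects annotations on each case root and on every
`hasDescendant` offspring — the flattened structure makes this one
index lookup per case instead of a recursive traversal. Gene attribution
goes through the materialized `has_variant` super-property, so new
alteration categories work unchanged. Per case × treatment, replicate
observations are aggregated by arithmetic mean of volume variations and
then classified (configurable to `worst`/`best`; the mean mirrors
cohort-style assessment). Annotations on the root itself count: roots are
cases and may carry metadata annotations.

Subset semantics: *mutations only* = ≥ 1 panel sequence alteration and no
panel amplification; *amplifications only* = the converse; the two are
disjoint by construction and, together with the both/neither groups,
partition any cohort. Co-occurrence strata use **exact gene-set
identity**: a case altered in {KRAS, BRAF} is counted in the {KRAS, BRAF}
stratum and not in {KRAS}. This makes strata mutually exclusive; it is
stated prominently because marginal per-gene counting is an equally
defensible convention and yields different numbers.
`ResponseFractionMatrix.overall()` gives the count-weighted marginal over
strata, which is what the planted-effect recovery checks use. The
non-responder breakdown nests gene → alteration type → variant instance,
with the instance level only defined for sequence alterations
(amplifications collapse to one instance per gene).

## Synthetic cohorts

The generator emulates the statistical structure the analytics assume, not
biology: per case, a root, one or two tissues, and a bioentity tree drawn
from a bounded child-count distribution (default {0: 0.35, 1: 0.40,
2: 0.25}, max depth 4, at least one bioentity per tree); per-gene
alteration probabilities on the default panel BRAF/EGFR/ERBB2/KRAS chosen
so that KRAS is the most mutated gene and only EGFR and ERBB2 are
amplified, EGFR most (KRAS mut 0.30, BRAF mut 0.10, EGFR mut 0.05 amp
0.10, ERBB2 mut 0.05 amp 0.07); and one cetuximab response observation per
case with planted effects P(negative | ≥ 1 variant) = 0.70,
P(negative | no variant) = 0.30, positive and neutral splitting the
remainder evenly. Volume variations are drawn uniformly inside the class
band (negative [+35, +100], positive [−100, −50], neutral open
(−50, +35)), so classification recovers the planted class exactly and
recovery error is purely binomial: at n = 400 with roughly half the cases
variant-positive the standard error of the 0.70 estimate is about 0.033,
comfortably inside a ±0.05 check; at n = 10,000 it is about 0.0066 for a
±0.01 check. Annotation placement depth (root / random node / leaf) is a
policy knob that consumes randomness identically in all modes, so
placement is the *only* difference between cohorts generated from the same
seed — this is what the end-to-end flattening-invariance checks exploit.
One seeded `random.Random` threads through all choices and timestamps are
synthetic constants, so a fixed config + seed yields byte-identical
Turtle.

What the generator does not emulate: sequence content, genome coordinates,
longitudinal re-sequencing after treatment, inter-gene correlation of
alterations, partial/missing annotation biases beyond simple observation
probabilities. Passing tests therefore demonstrate correctness of the
graph machinery and estimators under the planted model, not robustness to
real-biobank messiness.

## Turtle I/O and querying

Parsing is rdflib's Turtle parser. Serialization is the package's own
deterministic emitter (sorted prefixes, subjects, predicates, objects;
terms formatted with rdflib's `n3`): byte-stable output across processes
is part of the generator's contract, which a hash-order-dependent
serializer cannot provide. Literals are plain strings or `xsd:decimal`;
no full XSD datatype lattice.

Queries are conjunctive triple patterns with natural join and distinct
projection — every analytic here reduces to that plus counting, so the
engine stays small and fully testable against a nested-loop oracle. The
join uses the best available index per pattern; result sets are unordered
(sets of binding tuples).

## Federation

`owl:sameAs` mappings are injective per local URI; a conflicting second
remote raises. Each analysis pattern is one request with all mapped URIs
injected VALUES-style. The remote vocabulary (encode/interact/predictor/
reference predicates) is a configuration dataclass defaulting to
Wikidata-style property URIs, including statement nodes for evidence so
per-statement literature references survive the join. The bundled fixture
(`data/synthetic_remote.ttl`) is a synthetic stand-in for the live remote
graph; the HTTP client exists behind the same contract but no test or
default path touches the network (remote content drifts over time, so
live results are never part of the package's checks). Unmapped inputs
produce warnings and are excluded; endpoint failures raise rather than
returning empty results.

## Problem sizes and numerical choices

The test and acceptance workloads use: 200 random trees/DAGs of ≤ 50 nodes
for closure-vs-reachability equivalence; 50 graphs × 500 interleaved
assert/retract operations (graphs of 3–25 nodes) with a from-scratch
comparison after every step; synthetic cohorts of n = 400 and n = 10,000
for parameter recovery; 100 random graphs for Turtle round-trips. These
sizes give the properties room to fail (cycles, diamonds, deep chains all
occur) while keeping a full run in tens of seconds. Fraction sums are
checked to 1e−9; volume variations are compared exactly where the planted
value is stored and to binomial tolerances where estimated.

## Known limitations

* No owl:sameAs smushing of local nodes, no inverse/symmetric rules, no
  RETE network — only the three-rule subset above.
* No persistence, transactions or HTTP endpoint on the local store.
* Subset/strata conventions are one defensible reading of common cohort
  practice (see above); alternative marginal counting is not implemented.
* The entity-resolution step that would *build* sameAs mappings from
  identifier tables is out of scope; mappings are inputs.
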