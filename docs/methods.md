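# Methods

## Setting and model

A *taxonomy* is a set of named concepts with atomic subsumption axioms
("a is-a b").  An *ontology network* is a set of taxonomies plus at most
one alignment per pair; a mapping is stored as one directed subsumption
axiom (`<`, `>`) or as two (`=`, one per direction, sharing a pair tag and
each independently removable).  The network's *induced ontology* is the
union of all concepts, intra-ontology axioms and mapping axioms viewed as
one taxonomy.  Part-of pairs can be attached to an ontology but never
enter any knowledge base used for derivation — they only inform
validation recommendations, because modellers commonly assert is-a where
part-of is meant.

Derivability is reflexive-transitive reachability over the directed axiom
graph.  Cycles are permitted (every equivalence mapping is a 2-cycle by
construction) and handled by plain reachability; concept identity is the
(ontology id, concept id) pair, with labels display-only.

A *knowledge base* (KB) is the scope-restricted view of the current
network's non-removed axioms: the whole network, one ontology (its intra
axioms), or an ontology pair (both ontologies plus their alignment).
Validated-but-unrepaired missing relations contribute *provisional*
axioms to the KBs of their scope and the network, reflecting that a
validated missing relation is already repaired by its least informative
action, pending a possibly more informative replacement.

## Detection

For ontology k, a candidate missing is-a relation (CMI) is an ordered
pair of *mapped* concepts of k derivable in the network KB but not in
KB_k; candidate missing mappings (CMMs) are the analogue for a pair
scope.  Ordered pairs are kept distinct — (a, b) and (b, a) can both be
candidates, jointly representing an equivalence.  Detection skips pairs
already decided in the session; candidates set aside as redundant are
*not* considered decided and are re-detected (and reopened) once the
candidate that dominated them has been repaired or refuted.  This
reopening is essential for completeness: a candidate dominated by one
that is later validated wrong would otherwise be lost.

Redundancy: candidate (a, b) is redundant if a retained candidate (c, d)
satisfies derivable(a, c) and derivable(d, b) in the scope-local KB
(including provisionals), i.e. repairing (c, d) repairs (a, b).  The
dominance preorder is condensed (mutual ties retain the lexicographically
least pair) and only maximal candidates are retained.  Scope-local
derivability is used here; this is one of the places where the formal
definition was genuinely open, and the choice is flagged in the module
documentation as a sensitivity for detection counts on real data.

For validation, retained candidates are shown in groups: connected
components of the comparability relation (a concept of one candidate
derivably comparable, either direction in the network KB, with a concept
of another), largest first.

## Validation

Verdict batches are atomic.  A batch is rejected when (1) any pair would
carry both decisions across the session, or (2) some wrong-validated pair
becomes derivable from the missing-validated pairs plus executed
additions alone.  Both rules are sound: a verdict set violating either
cannot be realized by any repaired network in which missing relations are
derivable and wrong ones are not.  Validating (a, b) missing and (b, a)
wrong is *not* contradictory (is-a is not symmetric).  The precise check
used by interactive predecessors of this workflow is unpublished; these
two rules are this package's contract.

Recommendations: a part-of relation between the concepts (asserted in the
host ontology, or known to the external-knowledge oracle) suggests
*wrong*; an oracle-confirmed is-a suggests *missing*; host part-of takes
precedence.  Oracles are pluggable and deterministic; shipped
implementations are a dictionary mock and a TSV-backed table.  Oracle
terms are normalized (lowercase, underscores to spaces).  Recommendations
never auto-decide.

## Repairing wrong relations

All justifications of the pair are computed in the current network KB:
edge sets of simple directed paths filtered to ⊆-minimality.  The
"derivation path" notion is defined here as simple paths (no repeated
concept); with atomic subsumption axioms every entailment is witnessed by
a path, so the ⊆-minimal path edge sets are exactly the minimal entailing
axiom sets (the test suite cross-checks this against exhaustive subset
enumeration).  Enumeration is exponential in the worst case, so it is
capped (default 1000 paths, path length 20) with an explicit truncation
flag; the search is restricted to descendants(a) ∩ ancestors(b), which
makes it cheap in practice.

Only original asserted axioms are removable; provisional and repair-added
axioms are validated-correct.  A justification with no removable axiom is
surfaced as unrepairable-by-removal.

Recommendation priorities: minimal hitting sets are computed over each
defect's removable sets, and each axiom x is scored by the triple
(occurrences of x across the per-defect minimal hitting sets, number of
selected defects with x in some justification, +1 if x was chosen in an
earlier executed removal this session), ranked lexicographically
descending.  Counting occurrences per defect rather than over hitting
sets of the joint system is deliberate: it makes an axiom shared by
several defects' justifications outrank an axiom private to one defect,
which is the only reading consistent with the worked grey/white-matter
example (the shared reverse equivalence component gets P1 because it is
the only way to repair more than one wrong relation at once).  A joint
hitting-set operation over arbitrary families is still provided (with
caps: size 5, count 10000) and verified against exhaustive enumeration.

Execution is transactional: after removing the chosen axioms, every
selected defect pair *and* every chosen axiom's own pair must be
underivable in the network KB, otherwise the call is rejected and the
session is bit-identical.  Wrong defects are ranked ascending by their
number of possible repairing actions.

## Repairing missing relations

For missing (a, b) with scope KB K (host ontology for is-a, pair KB for a
mapping):

    Source(a,b) = super-cone(a) − super-cone(b)   in K
    Target(a,b) = sub-cone(b) − sub-cone(a)       in K
    Repair(a,b) ⊆ Source × Target

Cones are reflexive, so (a, b) itself is ordinarily the least informative
member of Repair.  The set differences implement the
no-new-equivalence preference by construction.  Conflict filters drop
elements equal to a recorded wrong/removed pair, and elements (s, t) at
least as informative as such a pair (u, v) — derivable(u, s) and
derivable(t, v) among validated-correct axioms, i.e. the current network
KB — since adding them would re-derive the wrong relation.

Informativeness: (s, t) is at least as informative as (a, b) iff
derivable(a, s) and derivable(t, b); adding (s, t) then entails (a, b).
Provisional axioms of *other* unrepaired missing defects are visible when
computing cones, matching the way unrepaired missing relations appear in
the Source/Target displays of interactive use.

Degenerate case: when both directions of an equivalence are validated
missing, the sibling's provisional makes a and b mutually derivable and
the set differences empty — losing even the least informative action.
The pair (a, b) is therefore re-admitted to Repair whenever it passes the
conflict filters and the reverse direction b → a is *not* derivable from
original asserted axioms alone (which preserves the no-new-equivalence
preference: completing a *validated* equivalence is sanctioned, reversing
an original subsumption is not).

Recommendation returns the informativeness-maximal oracle-supported
elements, falling back to the maximal elements of Repair flagged
unsupported.  Note that maximality is judged in the scope KB including
provisionals, so an element pointing into a provisionally-placed concept
can outrank the textbook answer until repairs settle.  Execution checks
membership in Repair recomputed at call time; choosing the pair itself
promotes its provisional axiom to a repair-added one.

## Consequence propagation and termination

After every executed repair: wrong defects whose pairs became underivable
are repaired; missing defects whose pairs are derivable from their scope
KB *excluding all provisionals of still-unrepaired missing defects* are
repaired by side effect; repaired defects that regressed are reinstated
(wrong: derivable again; missing: underivable again, provisional
restored); detection re-runs on every scope and registers fresh (or
reopened) candidates; cached justifications of open wrong defects are
cleared and recomputed lazily.  The pass loops to a fixpoint.

The status report tests the four repair requirements independently:
(i) every validated missing is-a relation derivable from its repaired
host ontology (asserted non-removed + added repairs, no provisionals);
(ii) no validated wrong is-a relation derivable from the repaired
network; (iii)/(iv) the mapping analogues — plus open-candidate and
unrepaired-defect counts.  *Done* requires all four plus no open work.
The scripted driver re-runs detection immediately before judging
termination: repairs can settle everything as a side effect without an
intervening detection pass, and a dormant reopenable candidate must not
be missed.

The scripted session loops detect → validate → repair-wrong →
repair-missing (wrong before missing, mirroring how removals should not
chase targets that additions will move), with an iteration cap (50) and a
state-hash cycle detector.  All recomputation is from scratch after each
repair — no incremental closure maintenance — which is well within budget
at desk scale and removes a whole class of staleness bugs.

## Synthetic networks and ground truth

The generator draws a random true DAG over a concept universe split into
a pool shared by all ontologies and per-ontology private pools; each
ontology asserts the transitive reduction (Hasse diagram) of the true
order restricted to its concepts, so local reachability agrees exactly
with true reachability on its concepts; equivalence mappings link shared
concepts pairwise (or along a chain, which leaves unaligned pairs and
thus makes CMM detection non-vacuous).  Defaults: 3 ontologies × 60
concepts, true edge density 0.04, overlap 0.4, p_omit 0.1, p_spurious
0.03, p_wrong_mapping 0.02 — small enough for the brute-force test
oracles while exercising all code paths.

Corruption plants defects with known ground truth, and is deliberately
constructed so every planted defect is *independently detectable and
recoverable* from the network:

- perturbed mappings replace an equivalence by one to an incomparable
  shared concept (two false components, each forced into any false-only
  hitting set of the wrong candidates it creates);
- spurious intra edges connect incomparable shared concepts;
- omissions hide reduction edges between shared concepts, and are kept
  only if the omitted pair remains derivable from the uncorrupted
  remainder of the network (otherwise the edge is restored and no defect
  planted);
- corruption events consume disjoint concepts, so defects do not mask
  one another.

What this emulates — and what it does not: the generator produces
structurally clean taxonomies whose only errors are the planted ones,
with uniformly random hierarchy shape, complete correspondence knowledge
on shared concepts, and corruption rates far below real alignment error
rates.  Passing recovery tests therefore shows the *workflow logic* is
sound and complete under its assumptions (a perfectly accurate
validator, detectable defects); it does not show robustness to ambiguous
modelling, lexical variation, or expert error on real ontologies.

The ground-truth policy stands in for the domain expert: a candidate is
missing iff true-reachable; removals are a minimal hitting set drawn from
the false axioms of each justification, widened until every removed
axiom's own pair is underivable; additions are the informativeness-maximal
true element of the repair space, or the defect itself.

## Problem sizes and numerical choices

The test suite uses: random graphs up to 200 concepts (100 seeds) for the
reachability oracle; ≤ 12-axiom instances for exhaustive justification
and hitting-set enumeration; 100 seeded corruption-free chained networks
of 3 × 12 concepts for the mapped-pair completeness scan (all-pairs,
all scopes); and 100 seeded corrupted networks at the default generator
conditions for full recovery.  These sizes keep each brute-force oracle
exact while covering the combinatorics; the package itself handles
anatomy-scale input (thousands of concepts) through the same code paths.

Determinism throughout: concepts and axioms iterate in sorted order, all
randomness lives in the generator and is seed-parameterized, ties break
lexicographically, and enumeration caps carry explicit truncation flags.

## Known limitations

- Only named-concept subsumption is interpreted; role restrictions,
  disjointness and annotations beyond labels are out of scope (OWL input
  should be converted externally).
- Part-of is side information for recommendations, never debugged itself.
- The redundancy filter and the contradiction rules reconstruct
  under-specified behaviour of the interactive predecessor; detection
  counts on real corpora are sensitive to the redundancy definition.
- Live lexical resources are replaced by the pluggable oracle interface;
  recommendation quality on real data depends entirely on the table
  provided.
- Justification and hitting-set enumeration are capped; truncated results
  are flagged but not refined further.
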