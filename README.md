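# taxodebug

Detect and repair missing and wrong is-a relations and mappings in
networks of taxonomies.

## The problem

Biomedical taxonomies (anatomy, disease, phenotype vocabularies) are
routinely connected by *alignments*: sets of mappings asserting that a
concept in one ontology is equivalent to (`≡`), subsumed by (`→`) or
subsumes (`←`) a concept in another.  Both the is-a hierarchies and the
mappings contain defects — relations that are missing, and relations that
are asserted or derivable but wrong (is-a and part-of are notoriously
confused).  These defects silently corrupt ontology-based search,
annotation and data integration.

`taxodebug` implements a unified, logic-based debugging workflow for this
setting, aimed at ontology engineers and curators.  Its key idea is that
an ontology network carries knowledge *intrinsic* to itself: viewing the
whole network as one taxonomy (the **induced ontology** — all concepts,
all intra-ontology is-a axioms, all mapping axioms), relations become
derivable that individual ontologies or alignments cannot derive alone.
Every such relation is either genuinely missing locally, or evidence that
some asserted axiom is wrong — either way, an opportunity to debug.

## Method

For ontology *k* in the network, a **candidate missing is-a relation**
(CMI) is a pair `a → b` of mapped concepts of *k* (concepts occurring in
mappings) derivable from the induced ontology but not from *k* alone; a
**candidate missing mapping** (CMM) is the analogue for an ontology pair
with its alignment.  Restricting to mapped concepts loses nothing: when
all asserted axioms are correct, repairing the mapped-pair candidates
repairs all candidates (a property the test suite checks empirically).

The workflow then iterates:

1. **Detect** CMIs/CMMs; drop *redundant* candidates (those entailed by
   repairing a retained, more informative candidate) and present the rest
   in comparability groups.
2. **Validate**: a domain expert partitions candidates into *missing* and
   *wrong* (with optional recommendations from asserted part-of relations
   and an external-knowledge oracle).  Verdict batches are atomic and
   rejected on contradiction.
3. **Repair wrong** relations: compute every justification (minimal axiom
   set entailing the pair; here, edge sets of simple subsumption paths
   filtered to ⊆-minimality), and remove at least one *original asserted*
   axiom from each — validated-missing and repair-added axioms are never
   removable.  Minimal hitting sets over the per-defect justifications
   rank the possible removals (`P1`, `P2`, …); removals are transactional
   and must leave every targeted pair underivable.
4. **Repair missing** relations `(a, b)`: each starts out repaired by its
   least informative action, a provisional axiom `a → b`.  The repair
   space `Source(a,b) × Target(a,b)` with
   `Source(a,b) = super(a) − super(b)` and `Target(a,b) = sub(b) − sub(a)`
   (cones in the scope KB) offers more informative alternatives: adding
   any element entails `a → b`, the set differences avoid introducing
   non-validated equivalences, and elements that would re-derive a known
   wrong relation are filtered out.  Missing relations are ranked by
   repair-space size, and an oracle-supported informativeness-maximal
   action is recommended.
5. **Propagate consequences** after every executed repair: other defects
   may be repaired as a side effect, earlier repairs may regress, new
   candidates may appear.

The session is *done* when every validated missing relation is derivable
from its repaired scope (without provisionals), no validated wrong
relation is derivable from the repaired network, and no candidates
remain.

## Worked example

The laryngeal-cartilage fragment ships as a built-in fixture: an anatomy
ontology where `Epiglottic_`, `Cricoid_`, `Arytenoid_` and
`Thyroid_Cartilage` are asserted sub-concepts of `Laryngeal_Cartilage`,
and all four have been validated as missing the is-a relation to
`Laryngeal_Connective_Tissue`:

```python
from taxodebug import anatomy_fixture, generate_repair_space, execute_addition
from taxodebug.repair_missing import initialize_repair_state
from taxodebug.model import MISSING

network, facts = anatomy_fixture("laryngeal")
session = initialize_repair_state(network, missing_isa=facts["missing_isa"])
defect = [d for d in session.open_defects(MISSING)
          if d.pair == facts["primary_defect_pair"]][0]
space = generate_repair_space(session, defect)
print(len(space.source), len(space.target), len(space.repair))
report = execute_addition(session, defect, facts["informative_action"])
print(len(report.newly_repaired))
```

prints

```
2 4 8
3
```

meaning: the epiglottic defect has 2 Source concepts, 4 Target concepts
and 8 admissible repairing actions; executing the more informative action
`(Laryngeal_Cartilage, Laryngeal_Connective_Tissue)` repairs the other
**3** missing relations as a side effect — one added axiom settles all
four defects, and adds knowledge not derivable from the network before.

## Command line

```
taxodebug --network net.yaml --state session.json detect --scope ncia
taxodebug --state session.json validate --verdicts verdicts.tsv
taxodebug --state session.json repair-wrong \
    --defects ncia:Ascending_Colon:Colon \
    --remove ama:ascending_colon:ama:colon
taxodebug --state session.json status
taxodebug --state session.json export --out repaired/
```

Ontologies load from an OBO 1.2 subset (`[Term]`, `id`, `name`, `is_a`,
`relationship: part_of`, `is_obsolete`) or a three-column TSV dialect;
alignments from TSV rows `concept_1 <TAB> concept_2 <TAB> {=,<,>}`.  On
desk-scale hardware the detector also handles real anatomy-scale input
(thousands of concepts, hundreds of mappings): point the network config
at locally downloaded ontology and reference-alignment files and run
`detect` per ontology.

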