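"""Worked anatomy fragments and a seeded synthetic-network generator.

The four named fragments (colon, white_matter, laryngeal, bone) are small
anatomy networks exercising each repair mechanism end to end; the
white_matter fragment is a documented reconstruction whose unprinted edges
are the minimal ones consistent with its published behaviour.  The
synthetic generator plants missing and wrong axioms into networks drawn
from a known ground-truth order, and `truth_policy` answers validation and
repair questions from that ground truth, standing in for a domain expert.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
import networkx as nx

from .model import (
    Alignment, AxiomKey, CandidateDefect, ConceptRef,
    MISSING, Ontology, OntologyNetwork, Pair, WRONG, equivalence,
    make_intra,
)
from .reasoning import build_kb, NETWORK_SCOPE
from .repair_missing import informative_at_least
from .repair_wrong import minimal_hitting_sets, removal_candidates


# --- in-text fragments ----------------------------------------------------

def anatomy_fixture(name: str) -> tuple[OntologyNetwork, dict]:
    """One of the documented worked fragments, plus machine-checkable
    expected facts (counts, pairs, defect lists) used by the tests."""
    builders = {
        "colon": _colon_fixture,
        "white_matter": _white_matter_fixture,
        "laryngeal": _laryngeal_fixture,
        "bone": _bone_fixture,
    }
    try:
        return builders[name]()
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; choose from "
                         f"{sorted(builders)}") from None


def _colon_fixture() -> tuple[OntologyNetwork, dict]:
    """Two-ontology fragment: AMA asserts (ascending colon, colon) as is-a
    although the relation is actually part-of; two equivalence mappings
    make the wrong relation derivable inside NCI-A."""
    ama = Ontology("ama")
    ac = ama.add_concept(ConceptRef("ama", "ascending_colon", "ascending colon"))
    co = ama.add_concept(ConceptRef("ama", "colon", "colon"))
    ama.add_axiom(make_intra(ac, co))
    ncia = Ontology("ncia")
    nac = ncia.add_concept(ConceptRef("ncia", "Ascending_Colon", "Ascending_Colon"))
    nco = ncia.add_concept(ConceptRef("ncia", "Colon", "Colon"))
    # the true relation in NCI-A is part-of, recommendation-only knowledge
    ncia.partof.add(("Ascending_Colon", "Colon"))
    al = Alignment(("ama", "ncia"))
    for ax in equivalence(nac, ac) + equivalence(nco, co):
        al.add_mapping(ax)
    net = OntologyNetwork([ama, ncia], [al])
    facts = {
        "n_concepts": 4,
        "n_intra": 1,
        "n_equivalences": 2,
        "cmi_scope": "ncia",
        "cmi_pair": (nac, nco),
        "wrong_intra": (ac.key, co.key),
        "justification_size": 3,
    }
    return net, facts


def _white_matter_fixture() -> tuple[OntologyNetwork, dict]:
    """Reconstruction of the grey/white-matter fragment.

    Printed behaviour reproduced: three wrong candidate is-a relations in
    AMA -- (brain grey matter, white matter), (cerebellum white matter,
    brain grey matter), (cerebral white matter, brain grey matter) -- each
    with a unique justification of three axioms; the reverse component of
    the brain-grey-matter equivalence is shared by two of them, so it
    attains top removal priority, and removing both components of that
    equivalence repairs all three defects at once.
    """
    ama = Ontology("ama")
    bgm = ama.add_concept(ConceptRef("ama", "brain_grey_matter", "brain grey matter"))
    wm = ama.add_concept(ConceptRef("ama", "white_matter", "white matter"))
    cbwm = ama.add_concept(ConceptRef("ama", "cerebellum_white_matter",
                                      "cerebellum white matter"))
    crwm = ama.add_concept(ConceptRef("ama", "cerebral_white_matter",
                                      "cerebral white matter"))
    # true AMA structure: both specific white matters are white matter
    ama.add_axiom(make_intra(cbwm, wm))
    ama.add_axiom(make_intra(crwm, wm))
    ncia = Ontology("ncia")
    nbwm = ncia.add_concept(ConceptRef("ncia", "Brain_White_Matter"))
    nwm = ncia.add_concept(ConceptRef("ncia", "White_Matter"))
    ncbw = ncia.add_concept(ConceptRef("ncia", "Cerebellum_White_Matter"))
    ncrw = ncia.add_concept(ConceptRef("ncia", "Cerebral_White_Matter"))
    ncia.add_axiom(make_intra(nbwm, nwm))
    ncia.add_axiom(make_intra(ncbw, nbwm))
    ncia.add_axiom(make_intra(ncrw, nbwm))
    al = Alignment(("ama", "ncia"))
    # the defective equivalence: brain grey matter == Brain_White_Matter
    for ax in equivalence(bgm, nbwm, tag="eq:bgm=BWM"):
        al.add_mapping(ax)
    for ax in (equivalence(wm, nwm) + equivalence(cbwm, ncbw)
               + equivalence(crwm, ncrw)):
        al.add_mapping(ax)
    net = OntologyNetwork([ama, ncia], [al])
    facts = {
        "wrong_pairs": [(bgm, wm), (cbwm, bgm), (crwm, bgm)],
        "scope": "ama",
        "equivalence_components": [((bgm.key), (nbwm.key)),
                                   ((nbwm.key), (bgm.key))],
        "reverse_component": (nbwm.key, bgm.key),
        "justification_size": 3,
    }
    return net, facts


def _laryngeal_fixture() -> tuple[OntologyNetwork, dict]:
    """Single-ontology fragment: four cartilages below Laryngeal_Cartilage,
    each validated missing an is-a to Laryngeal_Connective_Tissue; the
    informative action (Laryngeal_Cartilage, Laryngeal_Connective_Tissue)
    repairs the other three as a side effect."""
    o = Ontology("ncia")
    lc = o.add_concept(ConceptRef("ncia", "Laryngeal_Cartilage"))
    lct = o.add_concept(ConceptRef("ncia", "Laryngeal_Connective_Tissue"))
    cartilages = []
    for cid in ("Epiglottic_Cartilage", "Cricoid_Cartilage",
                "Arytenoid_Cartilage", "Thyroid_Cartilage"):
        c = o.add_concept(ConceptRef("ncia", cid))
        o.add_axiom(make_intra(c, lc))
        cartilages.append(c)
    net = OntologyNetwork([o])
    facts = {
        "missing_isa": {"ncia": [(c, lct) for c in cartilages]},
        "informative_action": (lc, lct),
        "primary_defect_pair": (cartilages[0], lct),
        "side_effect_repairs": 3,
    }
    return net, facts


def _bone_fixture() -> tuple[OntologyNetwork, dict]:
    """Single-ontology viscerocranium fragment: three bones each missing
    an is-a to bone; (viscerocranium bone, bone) is the informative action
    for (nasal bone, bone) and immediately repairs the maxilla and
    lacrimal-bone defects as well."""
    o = Ontology("ama")
    bone = o.add_concept(ConceptRef("ama", "bone", "bone"))
    vb = o.add_concept(ConceptRef("ama", "viscerocranium_bone",
                                  "viscerocranium bone"))
    nb = o.add_concept(ConceptRef("ama", "nasal_bone", "nasal bone"))
    mx = o.add_concept(ConceptRef("ama", "maxilla", "maxilla"))
    lb = o.add_concept(ConceptRef("ama", "lacrimal_bone", "lacrimal bone"))
    for c in (nb, mx, lb):
        o.add_axiom(make_intra(c, vb))
    net = OntologyNetwork([o])
    facts = {
        "missing_isa": {"ama": [(nb, bone), (mx, bone), (lb, bone)]},
        "informative_action": (vb, bone),
        "primary_defect_pair": (nb, bone),
        "side_effect_repairs": 2,
        "expected_source": {nb, vb},
        "expected_target": {bone, mx, lb},
    }
    return net, facts


# --- synthetic networks ---------------------------------------------------

@dataclass
class SyntheticSpec:
    """Parameters of a planted-defect synthetic network.

    A random true DAG is drawn over a shared + private concept universe;
    each ontology asserts the transitive reduction of the true order on
    its concepts, equivalence mappings link shared concepts, and
    corruption plants defects: omitted reduction edges (missing), spurious
    false edges (wrong), perturbed mappings (wrong).  Defaults are the
    study conditions: a three-ontology network of 60 concepts each with
    modest edge density, 40% concept overlap and low corruption rates.
    """

    n_ontologies: int = 3
    concepts_per_ontology: int = 60
    true_edge_density: float = 0.04
    overlap_fraction: float = 0.4
    p_omit: float = 0.1
    p_spurious: float = 0.03
    p_wrong_mapping: float = 0.02
    seed: int = 0
    alignment_topology: str = "complete"  # or "chain"

    def validate(self) -> None:
        if self.n_ontologies < 2:
            raise ValueError("need at least two ontologies")
        for p in (self.true_edge_density, self.overlap_fraction,
                  self.p_omit, self.p_spurious, self.p_wrong_mapping):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        n_shared = round(self.overlap_fraction * self.concepts_per_ontology)
        if n_shared > self.concepts_per_ontology:
            raise ValueError("overlap larger than an ontology")
        if self.alignment_topology not in ("complete", "chain"):
            raise ValueError("alignment_topology must be complete or chain")


@dataclass
class GroundTruth:
    """What the generator knows: the true reachability over the universe,
    the planted defects, and the concept-to-universe correspondence."""

    reach: dict[int, frozenset]  # universe id -> reachable universe ids
    correspondence: dict[tuple[str, str], int]
    planted_missing: list[tuple[str, Pair]] = field(default_factory=list)
    planted_wrong: list[AxiomKey] = field(default_factory=list)

    def universe(self, c: ConceptRef) -> int:
        return self.correspondence[c.key]

    def true_reachable(self, a: ConceptRef, b: ConceptRef) -> bool:
        ua, ub = self.universe(a), self.universe(b)
        return ua == ub or ub in self.reach[ua]

    def true_axiom(self, key: AxiomKey) -> bool:
        ua = self.correspondence[key[0]]
        ub = self.correspondence[key[1]]
        return ua == ub or ub in self.reach[ua]


def synthesize_network(spec: SyntheticSpec) -> tuple[OntologyNetwork, GroundTruth]:
    """Deterministic (per seed) synthetic network with planted defects.

    Corruption events consume disjoint shared concepts, so each planted
    defect is independently detectable; a planted omission is kept only
    if the omitted pair stays derivable from the network's uncorrupted
    axioms (otherwise the edge is restored and no defect is planted).
    """
    spec.validate()
    rng = random.Random(spec.seed)
    n_shared = round(spec.overlap_fraction * spec.concepts_per_ontology)
    n_private = spec.concepts_per_ontology - n_shared
    universe = []
    shared_ids = list(range(n_shared))
    next_id = n_shared
    private_ids: list[list[int]] = []
    for _ in range(spec.n_ontologies):
        ids = list(range(next_id, next_id + n_private))
        private_ids.append(ids)
        next_id += n_private
    universe = list(range(next_id))
    # random true DAG: edges respect a random topological order
    order = universe[:]
    rng.shuffle(order)
    pos = {u: i for i, u in enumerate(order)}
    true_dag = nx.DiGraph()
    true_dag.add_nodes_from(universe)
    for u in universe:
        for v in universe:
            if pos[u] < pos[v] and rng.random() < spec.true_edge_density:
                true_dag.add_edge(u, v)
    reach = {u: frozenset(nx.descendants(true_dag, u)) for u in universe}

    ont_ids = [f"o{k+1}" for k in range(spec.n_ontologies)]
    ontologies = []
    correspondence: dict[tuple[str, str], int] = {}
    concept_of: list[dict[int, ConceptRef]] = []
    reduction_edges: list[list[tuple[int, int]]] = []
    for k, oid in enumerate(ont_ids):
        members = sorted(shared_ids + private_ids[k])
        ont = Ontology(oid)
        local: dict[int, ConceptRef] = {}
        for u in members:
            c = ont.add_concept(ConceptRef(oid, f"c{u:04d}", f"concept {u}"))
            local[u] = c
            correspondence[c.key] = u
        # Hasse diagram of the true order restricted to this ontology
        restricted = nx.DiGraph()
        restricted.add_nodes_from(members)
        mset = set(members)
        for u in members:
            for v in reach[u] & mset:
                restricted.add_edge(u, v)
        hasse = nx.transitive_reduction(restricted)
        edges = sorted(hasse.edges())
        reduction_edges.append(edges)
        for u, v in edges:
            ont.add_axiom(make_intra(local[u], local[v]))
        ontologies.append(ont)
        concept_of.append(local)

    network = OntologyNetwork(ontologies)
    if spec.alignment_topology == "complete":
        pairs = [(i, j) for i in range(spec.n_ontologies)
                 for j in range(i + 1, spec.n_ontologies)]
    else:
        pairs = [(i, i + 1) for i in range(spec.n_ontologies - 1)]
    alignments: dict[tuple[int, int], Alignment] = {}
    for i, j in pairs:
        al = Alignment((ont_ids[i], ont_ids[j]))
        for u in shared_ids:
            for ax in equivalence(concept_of[i][u], concept_of[j][u]):
                al.add_mapping(ax)
        network.add_alignment(al)
        alignments[(i, j)] = al

    truth = GroundTruth(reach=reach, correspondence=correspondence)
    consumed: set[int] = set()

    # perturbed mappings: redirect one side of an equivalence to an
    # incomparable shared concept, yielding two false mapping components
    for (i, j), al in sorted(alignments.items()):
        for u in shared_ids:
            if u in consumed or rng.random() >= spec.p_wrong_mapping:
                continue
            others = [w for w in shared_ids
                      if w not in consumed and w != u
                      and w not in reach[u] and u not in reach[w]]
            if not others:
                continue
            w = rng.choice(others)
            a_i, u_j = concept_of[i][u], concept_of[j][u]
            w_j = concept_of[j][w]
            for direction in ((a_i.key, u_j.key), (u_j.key, a_i.key)):
                del al.mappings[direction]
            for ax in equivalence(a_i, w_j, tag=f"eq:bad:{i}-{j}:{u}-{w}"):
                al.add_mapping(ax)
                truth.planted_wrong.append(ax.key)
            consumed.update({u, w})

    # spurious intra edges between incomparable shared concepts
    for k, oid in enumerate(ont_ids):
        n_events = sum(1 for _ in reduction_edges[k]
                       if rng.random() < spec.p_spurious)
        attempts = 0
        while n_events > 0 and attempts < 50 * n_events:
            attempts += 1
            candidates = [u for u in shared_ids if u not in consumed]
            if len(candidates) < 2:
                break
            u, v = rng.sample(candidates, 2)
            if v in reach[u] or u in reach[v]:
                continue
            ax = make_intra(concept_of[k][u], concept_of[k][v])
            ontologies[k].add_axiom(ax)
            truth.planted_wrong.append(ax.key)
            consumed.update({u, v})
            n_events -= 1

    # omitted reduction edges between shared concepts
    for k, oid in enumerate(ont_ids):
        for u, v in reduction_edges[k]:
            if u not in shared_ids or v in consumed or u in consumed:
                continue
            if v not in shared_ids or rng.random() >= spec.p_omit:
                continue
            key = (concept_of[k][u].key, concept_of[k][v].key)
            removed = ontologies[k].isa.pop(key)
            truth.planted_missing.append(
                (oid, (concept_of[k][u], concept_of[k][v])))
            consumed.update({u, v})

    # keep only omissions whose pair the uncorrupted remainder still derives
    true_graph = nx.DiGraph()
    for ax in _all_axioms(network):
        if truth.true_axiom(ax.key):
            true_graph.add_edge(ax.key[0], ax.key[1])
    kept = []
    for oid, (a, b) in truth.planted_missing:
        if (a.key in true_graph and b.key in true_graph
                and nx.has_path(true_graph, a.key, b.key)):
            kept.append((oid, (a, b)))
        else:
            network.ontologies[oid].add_axiom(make_intra(a, b))
    truth.planted_missing = kept
    return network, truth


def _all_axioms(network: OntologyNetwork):
    for oid in network.ontology_ids():
        yield from network.ontologies[oid].axioms()
    for pair in sorted(network.alignments):
        yield from network.alignments[pair].axioms()


# --- ground-truth decision policy ----------------------------------------

class TruthPolicy:
    """Answers the workflow's questions from the generator's ground truth:
    a candidate is missing iff its pair is true-reachable; removals are a
    minimal hitting set of false (corrupted) axioms, widened until every
    removed axiom's own pair is underivable; additions are the
    informativeness-maximal true repair element, or the defect itself."""

    def __init__(self, truth: GroundTruth):
        self.truth = truth

    def verdict(self, session, defect: CandidateDefect) -> str:
        a, b = defect.pair
        return MISSING if self.truth.true_reachable(a, b) else WRONG

    def choose_removal(self, session, defect: CandidateDefect) -> set:
        kb = build_kb(session, NETWORK_SCOPE)
        rc = removal_candidates(session, defect, network_kb=kb)
        false_sets = []
        for elig in rc.eligible:
            false = frozenset(k for k in elig if not self.truth.true_axiom(k))
            false_sets.append(false if false else elig)
        mhs, _ = minimal_hitting_sets(false_sets)
        chosen = set(mhs[0])
        # widen until no chosen axiom's own pair survives the removal
        for _ in range(100):
            removed = [kb.axioms[k] for k in sorted(chosen)]
            trial = kb.apply_changes([], removed)
            extra: set = set()
            for k in sorted(chosen):
                a = trial._concepts.get(k[0])
                b = trial._concepts.get(k[1])
                if a is None or b is None or not trial.derivable(a, b):
                    continue
                justs, _ = trial.all_justifications(a, b)
                for j in justs:
                    extra |= {ak for ak in j.axioms
                              if not self.truth.true_axiom(ak)
                              and kb.axioms[ak].removable}
            extra -= chosen
            if not extra:
                break
            chosen |= extra
        return chosen

    def choose_addition(self, session, defect: CandidateDefect, space) -> Pair:
        true_elements = [(s, t) for s, t in space.repair
                         if self.truth.true_reachable(s, t)]
        if not true_elements:
            return defect.pair
        kb = build_kb(session, scope_key_of(defect))
        maximal = [st for st in true_elements
                   if not any(other != st
                              and informative_at_least(kb, other, st)
                              and not informative_at_least(kb, st, other)
                              for other in true_elements)]
        maximal.sort(key=lambda p: (p[0].key, p[1].key))
        return maximal[0] if maximal else defect.pair


def scope_key_of(defect: CandidateDefect):
    return defect.scope if isinstance(defect.scope, str) else tuple(defect.scope)


def truth_policy(truth: GroundTruth) -> TruthPolicy:
    return TruthPolicy(truth)
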