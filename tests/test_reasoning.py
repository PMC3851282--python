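"""Knowledge-base reasoning: derivability, cones, justifications, changes.

The independent oracles here are brute-force transitive closure over the
axiom digraph and exhaustive subset enumeration for minimality.
"""

import itertools
import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from taxodebug import SessionState
from taxodebug.model import ConceptRef, Ontology, OntologyNetwork, make_intra
from taxodebug.reasoning import EnumerationCaps, KnowledgeBase, build_kb


def _ontology_from_edges(n: int, edges) -> Ontology:
    o = Ontology("o")
    cs = [o.add_concept(ConceptRef("o", f"c{i:03d}")) for i in range(n)]
    for u, v in edges:
        if u != v:
            o.add_axiom(make_intra(cs[u], cs[v]))
    return o


def _kb_from_edges(n: int, edges) -> tuple[KnowledgeBase, list[ConceptRef]]:
    o = _ontology_from_edges(n, edges)
    kb = KnowledgeBase("o", o.axioms())
    kb.add_concepts(o.concepts.values())
    return kb, [o.concept(f"c{i:03d}") for i in range(n)]


def _brute_force_closure(n: int, edges) -> set[tuple[int, int]]:
    """Reflexive-transitive closure by repeated relational composition."""
    reach = {(i, i) for i in range(n)} | {(u, v) for u, v in edges if u != v}
    changed = True
    while changed:
        changed = False
        for (a, b), (c, d) in list(itertools.product(list(reach), repeat=2)):
            if b == c and (a, d) not in reach:
                reach.add((a, d))
                changed = True
    return reach


class TestDerivable:
    def test_reflexive(self):
        kb, cs = _kb_from_edges(2, [(0, 1)])
        assert kb.derivable(cs[0], cs[0])

    def test_unknown_concept_rejected(self):
        kb, cs = _kb_from_edges(2, [(0, 1)])
        with pytest.raises(KeyError):
            kb.derivable(cs[0], ConceptRef("o", "nope"))

    def test_colon_network_path(self, colon_session):
        session, facts = colon_session
        kb = build_kb(session, "network")
        a, b = facts["cmi_pair"]
        assert kb.derivable(a, b)
        local = build_kb(session, "ncia")
        assert not local.derivable(a, b)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_closure(self, seed):
        """Reachability agrees with an independent closure computation on
        random graphs, including cyclic ones."""
        rng = random.Random(seed)
        n = rng.randint(2, 14)
        edges = [(rng.randrange(n), rng.randrange(n))
                 for _ in range(rng.randint(0, 3 * n))]
        edges = [(u, v) for u, v in edges if u != v]
        kb, cs = _kb_from_edges(n, edges)
        closure = _brute_force_closure(n, edges)
        for i in range(n):
            for j in range(n):
                assert kb.derivable(cs[i], cs[j]) == ((i, j) in closure)


class TestCone:
    def test_isolated_concept(self):
        kb, cs = _kb_from_edges(3, [(0, 1)])
        assert kb.cone(cs[2], "super") == {cs[2]}

    def test_cone_equals_derivable_set(self):
        rng = random.Random(11)
        n = 12
        edges = {(rng.randrange(n), rng.randrange(n)) for _ in range(30)}
        edges = [(u, v) for u, v in edges if u != v]
        kb, cs = _kb_from_edges(n, edges)
        for c in cs:
            assert kb.cone(c, "super") == {d for d in cs if kb.derivable(c, d)}
            assert kb.cone(c, "sub") == {d for d in cs if kb.derivable(d, c)}

    def test_bone_fixture_super_cone(self, bone):
        from taxodebug.repair_missing import initialize_repair_state

        net, facts = bone
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        kb = build_kb(session, "ama")
        nb = net.ontologies["ama"].concept("nasal_bone")
        assert {c.concept_id for c in kb.cone(nb, "super")} == \
            {"nasal_bone", "viscerocranium_bone", "bone"}

    def test_laryngeal_sub_cone_includes_provisionals(self, laryngeal):
        from taxodebug.repair_missing import initialize_repair_state

        net, facts = laryngeal
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        kb = build_kb(session, "ncia")
        lct = net.ontologies["ncia"].concept("Laryngeal_Connective_Tissue")
        assert {c.concept_id for c in kb.cone(lct, "sub")} == {
            "Laryngeal_Connective_Tissue", "Epiglottic_Cartilage",
            "Cricoid_Cartilage", "Arytenoid_Cartilage", "Thyroid_Cartilage"}


def _entails(axiom_keys, a, b) -> bool:
    g = nx.DiGraph()
    g.add_node(a.key)
    g.add_node(b.key)
    for (sk, tk) in axiom_keys:
        g.add_edge(sk, tk)
    return nx.has_path(g, a.key, b.key)


class TestAllJustifications:
    def test_direct_edge(self):
        kb, cs = _kb_from_edges(2, [(0, 1)])
        justs, truncated = kb.all_justifications(cs[0], cs[1])
        assert not truncated
        assert len(justs) == 1
        assert justs[0].axioms == {(cs[0].key, cs[1].key)}

    def test_diamond_has_two(self):
        kb, cs = _kb_from_edges(4, [(0, 1), (1, 3), (0, 2), (2, 3)])
        justs, _ = kb.all_justifications(cs[0], cs[3])
        assert len(justs) == 2
        assert all(len(j) == 2 for j in justs)

    def test_not_derivable_rejected(self):
        kb, cs = _kb_from_edges(2, [(0, 1)])
        with pytest.raises(ValueError):
            kb.all_justifications(cs[1], cs[0])

    def test_white_matter_single_justification(self, white_matter_wrong_session):
        session, facts = white_matter_wrong_session
        kb = build_kb(session, "network")
        bgm, wm = facts["wrong_pairs"][0]
        justs, _ = kb.all_justifications(bgm, wm)
        assert len(justs) == 1
        assert len(justs[0]) == 3

    @pytest.mark.parametrize("seed", range(20))
    def test_minimality_and_entailment_oracle(self, seed):
        """Every justification entails its target; no proper subset does;
        and the set matches exhaustive subset enumeration on small graphs."""
        rng = random.Random(seed)
        n = rng.randint(3, 7)
        edges = {(rng.randrange(n), rng.randrange(n)) for _ in range(10)}
        edges = sorted((u, v) for u, v in edges if u != v)
        if len(edges) > 10:
            edges = edges[:10]
        kb, cs = _kb_from_edges(n, edges)
        keys = [(cs[u].key, cs[v].key) for u, v in edges]
        for i in range(n):
            for j in range(n):
                if i == j or not kb.derivable(cs[i], cs[j]):
                    continue
                justs, truncated = kb.all_justifications(cs[i], cs[j])
                assert not truncated
                got = {frozenset(j_.axioms) for j_ in justs}
                # oracle: all minimal entailing subsets of the axiom set
                entailing = [frozenset(sub)
                             for r in range(1, len(keys) + 1)
                             for sub in itertools.combinations(keys, r)
                             if _entails(sub, cs[i], cs[j])]
                minimal = {s for s in entailing
                           if not any(t < s for t in entailing)}
                assert got == minimal

    def test_caps_must_be_positive(self):
        kb, cs = _kb_from_edges(2, [(0, 1)])
        with pytest.raises(ValueError):
            kb.all_justifications(cs[0], cs[1],
                                  caps=EnumerationCaps(max_paths=0))


class TestApplyChanges:
    def test_removing_only_path(self):
        kb, cs = _kb_from_edges(2, [(0, 1)])
        ax = next(iter(kb.axioms.values()))
        kb2 = kb.apply_changes([], [ax])
        assert not kb2.derivable(cs[0], cs[1])
        assert kb.derivable(cs[0], cs[1])  # original untouched

    def test_add_then_remove_is_identity(self):
        kb, cs = _kb_from_edges(3, [(0, 1)])
        new_ax = make_intra(cs[1], cs[2])
        kb2 = kb.apply_changes([new_ax], [])
        kb3 = kb2.apply_changes([], [new_ax])
        for a in cs:
            for b in cs:
                assert kb.derivable(a, b) == kb3.derivable(a, b)

    def test_removing_equivalence_pair_repairs_all_three(
            self, white_matter_wrong_session):
        session, facts = white_matter_wrong_session
        kb = build_kb(session, "network")
        removals = [kb.axioms[k] for k in facts["equivalence_components"]]
        kb2 = kb.apply_changes([], removals)
        for a, b in facts["wrong_pairs"]:
            assert not kb2.derivable(a, b)

    def test_remove_missing_axiom_rejected(self):
        kb, cs = _kb_from_edges(2, [(0, 1)])
        with pytest.raises(ValueError):
            kb.apply_changes([], [make_intra(cs[1], cs[0])])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_apply_changes_round_trip_property(seed):
    """apply_changes(A, R) then apply_changes(R, A) restores every
    derivability answer."""
    rng = random.Random(seed)
    n = rng.randint(3, 10)
    edges = {(rng.randrange(n), rng.randrange(n)) for _ in range(2 * n)}
    edges = [(u, v) for u, v in edges if u != v]
    kb, cs = _kb_from_edges(n, edges)
    axioms = list(kb.axioms.values())
    if not axioms:
        return
    removals = rng.sample(axioms, k=min(len(axioms), rng.randint(1, 3)))
    additions = []
    for _ in range(2):
        u, v = rng.randrange(n), rng.randrange(n)
        if u != v and (cs[u].key, cs[v].key) not in kb.axioms:
            additions.append(make_intra(cs[u], cs[v]))
    additions = [ax for i, ax in enumerate(additions)
                 if ax.key not in {a.key for a in additions[:i]}]
    kb2 = kb.apply_changes(additions, removals)
    kb3 = kb2.apply_changes(removals, additions)
    for a in cs:
        for b in cs:
            assert kb.derivable(a, b) == kb3.derivable(a, b)


class TestBuildKb:
    def test_colon_scope_contents(self, colon_session):
        session, _ = colon_session
        assert len(build_kb(session, "ncia").axioms) == 0
        assert len(build_kb(session, "network").axioms) == 5
        assert len(build_kb(session, "ama").axioms) == 1

    def test_unknown_scope(self, colon_session):
        session, _ = colon_session
        with pytest.raises(KeyError):
            build_kb(session, "nope")

    def test_laryngeal_provisionals_enter_scope_kbs(self, laryngeal):
        from taxodebug.repair_missing import initialize_repair_state

        net, facts = laryngeal
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        kb = build_kb(session, "ncia")
        # 4 asserted + 4 provisional axioms
        assert len(kb.axioms) == 8
        assert len(build_kb(session, "network").axioms) == 8

    def test_partof_never_enters_kb(self, colon_session):
        session, _ = colon_session
        assert session.network.ontologies["ncia"].partof
        assert len(build_kb(session, "ncia").axioms) == 0
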