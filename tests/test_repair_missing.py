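"""Addition-based repair: initialization, repair spaces, informativeness,
ranking, recommendation, and execution."""

import pytest

from taxodebug import SessionState, Verdict, record_verdicts
from taxodebug.io import save_state
from taxodebug.model import MISSING, WRONG
from taxodebug.reasoning import build_kb
from taxodebug.repair_missing import (execute_addition, generate_repair_space,
                                      informative_at_least,
                                      initialize_repair_state, rank_missing,
                                      recommend_additions)
from taxodebug.repair_wrong import RepairRejected
from taxodebug.session import network_status, register_new_candidates
from taxodebug.validation import DictOracle, NullOracle


class TestInitializeRepairState:
    def test_laryngeal_provisionals(self, laryngeal):
        net, facts = laryngeal
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        assert len(session.provisionals) == 4
        kb = build_kb(session, "ncia")
        for c, lct in facts["missing_isa"]["ncia"]:
            assert kb.derivable(c, lct)

    def test_empty_validated_sets(self, colon):
        net, _ = colon
        session = initialize_repair_state(net)
        assert not session.provisionals
        assert not session.ri_plus and not session.ri_minus
        assert not session.open_candidates()

    def test_contradictory_sets_rejected(self, laryngeal):
        from taxodebug.validation import ContradictionError

        net, facts = laryngeal
        pairs = facts["missing_isa"]["ncia"]
        with pytest.raises(ContradictionError):
            initialize_repair_state(net, missing_isa={"ncia": pairs[:1]},
                                    wrong_isa={"ncia": pairs[:1]})


class TestGenerateRepairSpace:
    def test_bone_source_target(self, bone):
        net, facts = bone
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        d = [x for x in session.open_defects(MISSING)
             if x.pair == facts["primary_defect_pair"]][0]
        space = generate_repair_space(session, d)
        assert set(space.source) == facts["expected_source"]
        assert set(space.target) == facts["expected_target"]
        assert facts["informative_action"] in space.repair

    def test_laryngeal_informative_action_in_repair(self, laryngeal):
        net, facts = laryngeal
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        d = [x for x in session.open_defects(MISSING)
             if x.pair == facts["primary_defect_pair"]][0]
        space = generate_repair_space(session, d)
        lc, lct = facts["informative_action"]
        assert lc in space.source
        assert (lc, lct) in space.repair

    def test_wrong_defect_rejected(self, colon_session):
        session, _ = colon_session
        (d,) = session.open_candidates()
        record_verdicts(session, [Verdict(defect=d, decision=WRONG)])
        with pytest.raises(ValueError, match="not validated missing"):
            generate_repair_space(session, d)

    def test_every_element_contributes(self, bone):
        """pref1: adding any repair element makes the defect derivable."""
        net, facts = bone
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        for d in session.open_defects(MISSING):
            space = generate_repair_space(session, d)
            kb = build_kb(session, "ama")
            prov = session.provisionals[d.key]
            base = kb.apply_changes([], [prov])
            from taxodebug.model import make_intra
            for s, t in space.repair:
                if (s, t) == d.pair:
                    continue
                trial = base.apply_changes([make_intra(s, t)], [])
                assert trial.derivable(*d.pair), (d.pair, (s, t))

    def test_no_nonvalidated_equivalence(self, bone):
        """pref3: source excludes supers of b, target excludes subs of a,
        so no repair element reverses an existing subsumption."""
        net, facts = bone
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        kb = build_kb(session, "ama")
        for d in session.open_defects(MISSING):
            a, b = d.pair
            space = generate_repair_space(session, d)
            assert not set(space.source) & (kb.cone(b, "super") - {a})
            assert not set(space.target) & (kb.cone(a, "sub") - {b})

    def test_conflict_filter_drops_rederiving_elements(self, laryngeal):
        """An element whose addition would re-derive a removed pair is
        filtered out of the repair space."""
        net, facts = laryngeal
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        lc, lct = facts["informative_action"]
        # pretend (Laryngeal_Cartilage, Laryngeal_Connective_Tissue) was
        # removed as wrong earlier in the session
        session.ri_minus.add((lc.key, lct.key))
        d = [x for x in session.open_defects(MISSING)
             if x.pair == facts["primary_defect_pair"]][0]
        space = generate_repair_space(session, d)
        assert (lc, lct) not in space.repair
        # and the defect pair itself is filtered too: adding it would
        # re-derive the removed pair? no -- adding (epiglottic, LCT) does
        # not entail (LC, LCT), so the least informative action survives
        assert d.pair in space.repair


class TestInformativeness:
    def test_preorder_on_bone(self, bone):
        net, facts = bone
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        kb = build_kb(session, "ama")
        nb, bone_c = facts["primary_defect_pair"]
        vb, _ = facts["informative_action"]
        assert informative_at_least(kb, (vb, bone_c), (nb, bone_c))
        assert not informative_at_least(kb, (nb, bone_c), (vb, bone_c))

    def test_adding_more_informative_entails(self, bone):
        from taxodebug.model import make_intra

        net, facts = bone
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        kb = build_kb(session, "ama")
        prov = list(session.provisionals.values())
        base = kb.apply_changes([], prov)
        vb, bone_c = facts["informative_action"]
        trial = base.apply_changes([make_intra(vb, bone_c)], [])
        nb = net.ontologies["ama"].concept("nasal_bone")
        assert trial.derivable(nb, bone_c)


class TestRankMissing:
    def test_fewest_actions_first(self, bone):
        net, facts = bone
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        ranked = rank_missing(session)
        sizes = [len(space.repair) for _, space in ranked]
        assert sizes == sorted(sizes)

    def test_empty_session(self, colon):
        net, _ = colon
        session = initialize_repair_state(net)
        assert rank_missing(session) == []


class TestRecommendAdditions:
    def test_bone_oracle_supported(self, bone):
        net, facts = bone
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        d = [x for x in session.open_defects(MISSING)
             if x.pair == facts["primary_defect_pair"]][0]
        space = generate_repair_space(session, d)
        kb = build_kb(session, "ama")
        oracle = DictOracle({("viscerocranium bone", "bone"): "isa"})
        actions, supported = recommend_additions(space, oracle, scope_kb=kb)
        assert supported
        assert actions == [facts["informative_action"]]

    def test_unsupported_fallback_is_maximal(self, bone):
        net, facts = bone
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        d = [x for x in session.open_defects(MISSING)
             if x.pair == facts["primary_defect_pair"]][0]
        space = generate_repair_space(session, d)
        kb = build_kb(session, "ama")
        actions, supported = recommend_additions(space, NullOracle(),
                                                 scope_kb=kb)
        assert not supported
        # returned elements are maximal: none is strictly dominated by
        # another repair element, and the (least informative) defect pair
        # is dominated, hence absent
        for st in actions:
            assert not any(other != st
                           and informative_at_least(kb, other, st)
                           and not informative_at_least(kb, st, other)
                           for other in space.repair)
        assert d.pair not in actions

    def test_oracle_supporting_only_defect_pair(self, bone):
        net, facts = bone
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        d = [x for x in session.open_defects(MISSING)
             if x.pair == facts["primary_defect_pair"]][0]
        space = generate_repair_space(session, d)
        kb = build_kb(session, "ama")
        oracle = DictOracle({("nasal bone", "bone"): "isa"})
        actions, supported = recommend_additions(space, oracle, scope_kb=kb)
        assert supported and actions == [d.pair]

    def test_empty_repair_rejected(self, bone):
        from taxodebug.model import CandidateDefect, RepairSpace

        net, facts = bone
        d = CandidateDefect(kind="CMI", pair=facts["primary_defect_pair"],
                            scope="ama", status=MISSING)
        space = RepairSpace(defect=d, source=[], target=[], repair=[])
        with pytest.raises(ValueError):
            recommend_additions(space, NullOracle())


class TestExecuteAddition:
    def test_laryngeal_side_effects(self, laryngeal):
        net, facts = laryngeal
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        d = [x for x in session.open_defects(MISSING)
             if x.pair == facts["primary_defect_pair"]][0]
        report = execute_addition(session, d, facts["informative_action"])
        assert len(report.newly_repaired) == facts["side_effect_repairs"]
        assert session.ri_plus == {(facts["informative_action"][0].key,
                                    facts["informative_action"][1].key)}
        assert network_status(session).done

    def test_self_repair_promotes_provisional(self, laryngeal):
        net, facts = laryngeal
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        d = session.open_defects(MISSING)[0]
        execute_addition(session, d, d.pair)
        key = (d.pair[0].key, d.pair[1].key)
        assert key in session.ri_plus
        host = net.ontologies["ncia"]
        assert host.isa[key].status == "repair-added"
        assert d.key not in session.provisionals

    def test_action_outside_repair_rejected(self, laryngeal, tmp_path):
        net, facts = laryngeal
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        d = [x for x in session.open_defects(MISSING)
             if x.pair == facts["primary_defect_pair"]][0]
        lct = d.pair[1]
        before = tmp_path / "b.json"
        save_state(session, before)
        with pytest.raises(RepairRejected):
            # reversed action is never in Repair
            execute_addition(session, d, (lct, d.pair[0]))
        after = tmp_path / "a.json"
        save_state(session, after)
        assert before.read_text() == after.read_text()

    def test_already_repaired_rejected(self, laryngeal):
        net, facts = laryngeal
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        d = [x for x in session.open_defects(MISSING)
             if x.pair == facts["primary_defect_pair"]][0]
        execute_addition(session, d, facts["informative_action"])
        with pytest.raises(RepairRejected):
            execute_addition(session, d, d.pair)

    def test_bone_side_effects(self, bone):
        net, facts = bone
        session = initialize_repair_state(net, missing_isa=facts["missing_isa"])
        d = [x for x in session.open_defects(MISSING)
             if x.pair == facts["primary_defect_pair"]][0]
        report = execute_addition(session, d, facts["informative_action"])
        assert len(report.newly_repaired) == 2
        assert network_status(session).done
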