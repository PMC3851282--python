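"""Phases 3.1-3.4 for missing is-a relations and missing mappings.

Each validated missing relation (a, b) starts out repaired by its *least
informative* action -- a provisional axiom a -> b.  The repair space
Source(a,b) x Target(a,b) offers more informative alternatives: Source is
the super-cone of a minus the super-cone of b, Target the sub-cone of b
minus the sub-cone of a, both in the scope KB (host ontology for a missing
is-a relation, ontology pair + alignment for a missing mapping).  Adding
any element makes (a, b) derivable, the set differences avoid introducing
non-validated equivalences, and a conflict filter drops elements that
would re-derive a known wrong relation.
"""

from __future__ import annotations

from typing import Optional

from .model import (
    Axiom, CandidateDefect, CMI, CMM, ConceptRef, INTRA, MAPPING, MISSING,
    OntologyNetwork, Pair, REPAIR, REPAIR_ADDED, RepairSpace, SessionState,
    UNVALIDATED,
)
from .reasoning import KnowledgeBase, build_kb, scope_key, NETWORK_SCOPE
from .validation import KnowledgeOracle, ISA
from .model import normalize_label


def initialize_repair_state(network: OntologyNetwork,
                            missing_isa: dict[str, list[Pair]] | None = None,
                            wrong_isa: dict[str, list[Pair]] | None = None,
                            missing_mappings: dict[tuple, list[Pair]] | None = None,
                            wrong_mappings: dict[tuple, list[Pair]] | None = None,
                            ) -> SessionState:
    """Set up a session from externally validated missing/wrong sets.

    Every validated missing relation gains a provisional axiom visible in
    its scope KBs and the network KB; the repairing-action registers and
    candidate sets start empty.  Useful for repairing a single ontology
    (or network) whose defect sets come from elsewhere.
    """
    from .validation import Verdict

    session = SessionState(network)
    entries = []
    for reg, decided, kind in ((missing_isa, MISSING, CMI),
                               (wrong_isa, "wrong", CMI),
                               (missing_mappings, MISSING, CMM),
                               (wrong_mappings, "wrong", CMM)):
        for scope in sorted(reg or {}):
            for pair in sorted(reg[scope], key=lambda p: (p[0].key, p[1].key)):
                skey = scope_key(scope)
                d = CandidateDefect(kind=kind, pair=pair, scope=skey,
                                    status=UNVALIDATED)
                session.defects[d.key] = d
                entries.append(Verdict(defect=d, decision=decided,
                                       provenance="scripted-oracle"))
    from .validation import record_verdicts
    record_verdicts(session, entries)
    session.check_invariants()
    return session


def informative_at_least(kb: KnowledgeBase, st: Pair, ab: Pair) -> bool:
    """(s, t) is at least as informative as (a, b) in ``kb``: a is-a s and
    t is-a b already hold, so adding s -> t entails a -> b."""
    (s, t), (a, b) = st, ab
    return kb.derivable(a, s) and kb.derivable(t, b)


def generate_repair_space(session, defect: CandidateDefect,
                          scope_kb: Optional[KnowledgeBase] = None,
                          network_kb: Optional[KnowledgeBase] = None,
                          ) -> RepairSpace:
    """Source/Target/Repair for one missing defect.

    Cones are reflexive, so the defect pair itself is a member of Repair
    unless filtered by conflicts.  Conflict filters: (a) elements equal to
    a recorded wrong or removed pair; (b) elements at least as informative
    as such a pair when u -> s and t -> v hold among validated-correct
    axioms (the current network KB: asserted-not-removed, provisional and
    repair-added axioms).
    """
    if defect.status != MISSING:
        raise ValueError(f"defect is not validated missing: {defect!r}")
    skey = scope_key(defect.scope)
    kb = scope_kb if scope_kb is not None else build_kb(session, skey)
    a, b = defect.pair
    source = sorted(kb.cone(a, "super") - kb.cone(b, "super"))
    target = sorted(kb.cone(b, "sub") - kb.cone(a, "sub"))
    conflicts: set[tuple] = set()
    for _, pk in session.validated_wrong:
        conflicts.add(pk)
    conflicts |= session.ri_minus | session.rm_minus
    net_kb = network_kb if network_kb is not None else build_kb(session, NETWORK_SCOPE)
    repair: list[Pair] = []
    for s in source:
        for t in target:
            if (s.key, t.key) in conflicts:
                continue
            if _conflicts_with_wrong(net_kb, (s, t), conflicts):
                continue
            repair.append((s, t))
    if (a, b) not in repair and (a.key, b.key) not in conflicts \
            and not _conflicts_with_wrong(net_kb, (a, b), conflicts) \
            and not _reverse_asserted(kb, a, b):
        # The set differences drop the defect pair itself when a validated
        # sibling (e.g. the reverse direction of an equivalence, also
        # validated missing) makes a and b mutually derivable.  The least
        # informative repairing action must stay available, so re-admit it;
        # the guard keeps the non-validated-equivalence preference intact.
        source = sorted(set(source) | {a})
        target = sorted(set(target) | {b})
        repair.append((a, b))
    return RepairSpace(defect=defect, source=source, target=target,
                       repair=repair)


def _reverse_asserted(kb: KnowledgeBase, a: ConceptRef, b: ConceptRef) -> bool:
    """True iff b -> a is derivable from original asserted axioms alone,
    in which case adding a -> b would introduce a non-validated
    equivalence."""
    original = [ax for ax in kb.axioms.values() if ax.removable]
    restricted = KnowledgeBase(kb.scope, original)
    if not (restricted.has_concept(a) and restricted.has_concept(b)):
        return False
    return restricted.derivable(b, a)


def _conflicts_with_wrong(net_kb: KnowledgeBase, st: Pair,
                          conflicts: set[tuple]) -> bool:
    s, t = st
    for (uo, uc), (vo, vc) in conflicts:
        try:
            u = net_kb._concepts[(uo, uc)]
            v = net_kb._concepts[(vo, vc)]
        except KeyError:
            continue
        if net_kb.derivable(u, s) and net_kb.derivable(t, v):
            return True
    return False


def rank_missing(session, scope=None) -> list[tuple[CandidateDefect, RepairSpace]]:
    """Missing defects with their repair spaces, ranked ascending by
    |Repair|; the first has the fewest possible repairing actions."""
    defects = session.open_defects(MISSING)
    if scope is not None:
        skey = scope_key(scope)
        defects = [d for d in defects
                   if (d.scope if isinstance(d.scope, str)
                       else tuple(d.scope)) == skey]
    net_kb = build_kb(session, NETWORK_SCOPE)
    spaces = {}
    for d in defects:
        spaces[d.key] = generate_repair_space(session, d, network_kb=net_kb)
    ranked = sorted(defects, key=lambda d: (len(spaces[d.key].repair), d.key))
    return [(d, spaces[d.key]) for d in ranked]


def recommend_additions(space: RepairSpace,
                        oracle: Optional[KnowledgeOracle] = None,
                        scope_kb: Optional[KnowledgeBase] = None,
                        ) -> tuple[list[Pair], bool]:
    """Most informative repairing actions, preferring oracle-supported ones.

    Among Repair elements whose term pair the oracle confirms as is-a,
    return the maximal elements of the informativeness preorder; when none
    is supported, fall back to the maximal elements of the whole Repair
    set, flagged unsupported.  Returns ``(pairs, supported)``.
    """
    if not space.repair:
        raise ValueError("repair space is empty")
    kb = scope_kb
    supported = []
    if oracle is not None:
        for s, t in space.repair:
            try:
                ans = oracle.query(normalize_label(s.display()),
                                   normalize_label(t.display()))
            except Exception:
                ans = "unknown"
            if ans == ISA:
                supported.append((s, t))
    pool = supported if supported else list(space.repair)
    if kb is None:
        maximal = sorted(pool, key=lambda p: (p[0].key, p[1].key))
    else:
        maximal = []
        for st in pool:
            dominated = any(
                other != st
                and informative_at_least(kb, other, st)
                and not informative_at_least(kb, st, other)
                for other in pool)
            if not dominated:
                maximal.append(st)
        maximal.sort(key=lambda p: (p[0].key, p[1].key))
    return maximal, bool(supported)


def execute_addition(session, defect: CandidateDefect, action: Pair) -> "object":
    """Execute an addition repair for a missing defect.

    The action must be in the defect's Repair set, recomputed at call
    time; otherwise the repairing is not allowed and the session is left
    unchanged.  An intra action enters RI+ and the host ontology, a
    cross-ontology action enters RM+ and the scope alignment; choosing the
    defect pair itself promotes its provisional axiom.  Consequence
    propagation runs afterwards; returns the ConsequenceReport.
    """
    from .repair_wrong import RepairRejected
    from .session import propagate_consequences

    if defect.status != MISSING:
        raise RepairRejected(f"defect is not an unrepaired missing relation: "
                             f"{defect!r}")
    space = generate_repair_space(session, defect)
    if action not in space.repair:
        raise RepairRejected(f"action {action} is not in Repair{defect.pair}")
    s, t = action
    provisional = session.provisionals.pop(defect.key)
    if action == defect.pair:
        ax = provisional
        ax.status = REPAIR_ADDED
    else:
        layer = INTRA if s.ontology_id == t.ontology_id else MAPPING
        ax = Axiom(s, t, layer=layer, status=REPAIR_ADDED, origin=REPAIR)
    if ax.layer == INTRA:
        host = session.network.ontologies[s.ontology_id]
        if ax.key not in host.isa:
            host.add_axiom(ax)
        else:  # a removed or asserted axiom with this key exists: re-add
            host.isa[ax.key].status = REPAIR_ADDED
            ax = host.isa[ax.key]
        session.ri_plus.add(ax.key)
    else:
        al = session.network.alignment(s.ontology_id, t.ontology_id, create=True)
        if ax.key not in al.mappings:
            al.add_mapping(ax)
        else:
            al.mappings[ax.key].status = REPAIR_ADDED
            ax = al.mappings[ax.key]
        session.rm_plus.add(ax.key)
    _mark_missing_repaired(session, defect)
    session.log("execute_addition", defect=defect.key,
                action=(s.key, t.key))
    return propagate_consequences(session)


def _mark_missing_repaired(session, d: CandidateDefect) -> None:
    from .model import REPAIRED
    d.status = REPAIRED
    scope = d.scope if isinstance(d.scope, str) else tuple(d.scope)
    session.missing_register(scope).discard(d.pair)
    session.provisionals.pop(d.key, None)
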