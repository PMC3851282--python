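"""Phases 3.1-3.4 for wrong is-a relations and wrong mappings.

A wrong relation is repaired by removing at least one axiom from every
justification of it in the current network.  Validated-missing provisional
axioms and repair-added axioms are never removable: only original asserted
knowledge can be withdrawn.  Minimal hitting sets over the per-defect
removable sets drive the recommendation priorities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import Axiom, AxiomKey, CandidateDefect, REMOVED, WRONG
from .reasoning import EnumerationCaps, build_kb, NETWORK_SCOPE


@dataclass
class RemovalCandidates:
    """Per-justification removable subsets for one wrong defect."""

    defect: CandidateDefect
    justification_axioms: list[frozenset[AxiomKey]]
    eligible: list[frozenset[AxiomKey]]
    truncated: bool = False

    @property
    def unrepairable(self) -> bool:
        """Some justification has no removable axiom at all."""
        return any(not e for e in self.eligible)

    def all_eligible(self) -> set[AxiomKey]:
        out: set[AxiomKey] = set()
        for e in self.eligible:
            out |= e
        return out


def removal_candidates(session, defect: CandidateDefect,
                       caps: Optional[EnumerationCaps] = None,
                       network_kb=None) -> RemovalCandidates:
    """Justifications of a wrong defect's pair in the current network KB,
    each with its subset of removal-eligible (original asserted) axioms."""
    if defect.status != WRONG:
        raise ValueError(f"defect is not validated wrong: {defect!r}")
    kb = network_kb if network_kb is not None else build_kb(session, NETWORK_SCOPE)
    a, b = defect.pair
    if not kb.derivable(a, b):
        raise ValueError(f"defect already repaired (pair underivable): {defect!r}")
    justs, truncated = kb.all_justifications(a, b, caps=caps)
    defect.justifications = justs
    eligible = []
    for j in justs:
        elig = frozenset(k for k in j.axioms
                         if (ax := kb.axioms.get(k)) is not None and ax.removable)
        eligible.append(elig)
    return RemovalCandidates(defect=defect,
                             justification_axioms=[j.axioms for j in justs],
                             eligible=eligible, truncated=truncated)


def minimal_hitting_sets(candidate_sets: list[frozenset],
                         caps: Optional[EnumerationCaps] = None,
                         ) -> tuple[list[frozenset], bool]:
    """All subset-minimal sets intersecting every candidate set, up to the
    caps; deterministic order (size, then lexicographic elements)."""
    caps = caps or EnumerationCaps()
    caps.validate()
    for s in candidate_sets:
        if not s:
            raise ValueError("no hitting set exists: a candidate set is empty")
    if not candidate_sets:
        return [], False
    sets = sorted({frozenset(s) for s in candidate_sets},
                  key=lambda s: (len(s), sorted(s)))
    # drop supersets: hitting their subset hits them too
    reduced = [s for i, s in enumerate(sets)
               if not any(t < s for t in sets)]
    truncated = False
    results: list[frozenset] = []

    def extend(partial: frozenset, remaining: list[frozenset]) -> None:
        nonlocal truncated
        if len(results) >= caps.max_hitting_sets:
            truncated = True
            return
        unhit = [s for s in remaining if not (s & partial)]
        if not unhit:
            results.append(partial)
            return
        if len(partial) >= caps.max_hitting_set_size:
            truncated = True
            return
        for el in sorted(unhit[0]):
            extend(partial | {el}, unhit[1:])

    extend(frozenset(), reduced)
    minimal = []
    uniq = sorted(set(results), key=lambda s: (len(s), sorted(s)))
    for s in uniq:
        if not any(m < s for m in minimal):
            minimal.append(s)
    return minimal, truncated


@dataclass
class RemovalRecommendation:
    axiom_key: AxiomKey
    priority: int  # 1 is highest
    score: tuple[int, int, int]


def recommend_removals(session, defects: list[CandidateDefect],
                       caps: Optional[EnumerationCaps] = None,
                       network_kb=None) -> list[RemovalRecommendation]:
    """Priority-ordered removal actions for a jointly selected set of
    wrong defects.

    score(x) = (occurrences of x over the per-defect minimal hitting
    sets, number of defects with x in some justification, 1 if x was
    chosen in an earlier executed removal of this session); priorities
    P1.. follow descending lexicographic score, ties broken by axiom key.
    An axiom hitting several defects' justifications thereby outranks one
    that repairs a single relation.
    """
    kb = network_kb if network_kb is not None else build_kb(session, NETWORK_SCOPE)
    hs_count: dict[AxiomKey, int] = {}
    defect_count: dict[AxiomKey, int] = {}
    for d in defects:
        rc = removal_candidates(session, d, caps=caps, network_kb=kb)
        if rc.unrepairable:
            raise ValueError(f"defect {d!r} has a justification with no "
                             f"removable axiom")
        mhs, _ = minimal_hitting_sets(rc.eligible, caps=caps)
        for hs in mhs:
            for k in hs:
                hs_count[k] = hs_count.get(k, 0) + 1
        for k in rc.all_eligible():
            defect_count[k] = defect_count.get(k, 0) + 1
    chosen_before = session.ri_minus | session.rm_minus
    scored = []
    for k in defect_count:
        score = (hs_count.get(k, 0), defect_count[k],
                 1 if k in chosen_before else 0)
        scored.append((score, k))
    scored.sort(key=lambda sk: (tuple(-c for c in sk[0]), sk[1]))
    return [RemovalRecommendation(axiom_key=k, priority=i + 1, score=score)
            for i, (score, k) in enumerate(scored)]


def rank_wrong(session, scope=None,
               caps: Optional[EnumerationCaps] = None) -> list[CandidateDefect]:
    """Wrong defects ranked ascending by the number of possible repairing
    actions (distinct removable axioms across justifications); the first
    has the fewest and may be the easiest starting point."""
    kb = build_kb(session, NETWORK_SCOPE)
    defects = session.open_defects(WRONG)
    if scope is not None:
        from .reasoning import scope_key
        skey = scope_key(scope)
        defects = [d for d in defects
                   if (d.scope if isinstance(d.scope, str)
                       else tuple(d.scope)) == skey]
    counted = []
    for d in defects:
        rc = removal_candidates(session, d, caps=caps, network_kb=kb)
        counted.append((len(rc.all_eligible()), d.key, d))
    counted.sort(key=lambda t: (t[0], t[1]))
    return [d for _, _, d in counted]


class RepairRejected(ValueError):
    """A repair execution violated its preconditions; session unchanged."""


def execute_removals(session, defects: list[CandidateDefect],
                     chosen: set[AxiomKey]) -> "object":
    """Execute a removal repair, transactionally.

    Every chosen axiom must be removal-eligible, and after removing them
    every defect pair and every chosen axiom's own pair must be
    underivable in the network KB; otherwise the call is rejected and the
    session is unchanged.  On success, removed intra axioms enter RI-,
    removed mappings RM-, repaired defects leave WI/WM, and consequence
    propagation runs.  Returns the ConsequenceReport.
    """
    from .session import propagate_consequences

    if not chosen:
        raise RepairRejected("no removal actions chosen")
    axioms: list[Axiom] = []
    for key in sorted(chosen):
        ax = session.network.find_axiom(key)
        if ax is None:
            raise RepairRejected(f"axiom {key} not found in the network")
        if not ax.removable:
            raise RepairRejected(f"axiom {key} is not removal-eligible")
        axioms.append(ax)
    for d in defects:
        if d.status != WRONG:
            raise RepairRejected(f"defect is not validated wrong: {d!r}")
    kb = build_kb(session, NETWORK_SCOPE)
    trial = kb.apply_changes([], axioms)
    for d in defects:
        if trial.derivable(*d.pair):
            raise RepairRejected(
                f"insufficient removal: {d.pair} still derivable")
    for ax in axioms:
        if trial.derivable(ax.sub, ax.super):
            raise RepairRejected(
                f"insufficient removal: removed pair {ax.key} still derivable")
    # commit
    for ax in axioms:
        ax.status = REMOVED
        if ax.layer == "intra-ontology":
            session.ri_minus.add(ax.key)
        else:
            session.rm_minus.add(ax.key)
    for d in defects:
        _mark_wrong_repaired(session, d)
    session.log("execute_removals",
                defects=[d.key for d in defects],
                removed=sorted(chosen))
    return propagate_consequences(session)


def _mark_wrong_repaired(session, d: CandidateDefect) -> None:
    from .model import REPAIRED
    d.status = REPAIRED
    scope = d.scope if isinstance(d.scope, str) else tuple(d.scope)
    session.wrong_register(scope).discard(d.pair)
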