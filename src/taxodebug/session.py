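"""Workflow orchestration: consequence propagation, status, scripted runs.

The debugging workflow iterates detect -> validate -> repair-wrong ->
repair-missing until no candidates and no unrepaired defects remain.
After every executed repair the consequences are computed: other defects
may be repaired as a side effect, previously repaired defects may regress,
and new candidates may appear.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Protocol

from .model import (
    CandidateDefect, MISSING, OntologyNetwork, Pair, REPAIRED,
    SessionState, UNVALIDATED, WRONG,
)
from .reasoning import EnumerationCaps, KnowledgeBase, build_kb, scope_key, \
    NETWORK_SCOPE
from . import detection
from .validation import Verdict, record_verdicts


@dataclass
class ConsequenceReport:
    """Before/after derivability diff of one propagation pass."""

    newly_repaired: list[tuple] = field(default_factory=list)
    reinstated: list[tuple] = field(default_factory=list)
    new_candidates: list[CandidateDefect] = field(default_factory=list)
    invalidated_caches: list[tuple] = field(default_factory=list)

    def empty(self) -> bool:
        return not (self.newly_repaired or self.reinstated
                    or self.new_candidates or self.invalidated_caches)


def _scope_kb_without_provisionals(session, scope) -> KnowledgeBase:
    kb = build_kb(session, scope)
    provs = [ax for ax in session.provisional_axioms() if ax.key in kb.axioms]
    return kb.apply_changes([], provs) if provs else kb


def propagate_consequences(session: SessionState,
                           detect: bool = True) -> ConsequenceReport:
    """Recompute all consequences of the latest executed repair.

    Wrong defects whose pairs became underivable move to repaired; missing
    defects whose pairs are derivable without any provisional axiom of a
    still-unrepaired missing defect are repaired by side effect; repaired
    defects that regressed are reinstated; finally detection runs on every
    scope and fresh candidates are registered.
    """
    report = ConsequenceReport()
    changed = True
    while changed:
        changed = False
        net_kb = build_kb(session, NETWORK_SCOPE)
        scope_kbs: dict[object, KnowledgeBase] = {}

        def noprov_kb(scope):
            skey = scope_key(scope)
            if skey not in scope_kbs:
                scope_kbs[skey] = _scope_kb_without_provisionals(session, skey)
            return scope_kbs[skey]

        for d in sorted(session.defects.values(), key=lambda d: d.key):
            pk = (d.pair[0].key, d.pair[1].key)
            skey = scope_key(d.scope)
            was_wrong = (skey, pk) in session.validated_wrong
            was_missing = (skey, pk) in session.validated_missing
            if d.status == WRONG and not net_kb.derivable(*d.pair):
                d.status = REPAIRED
                session.wrong_register(skey).discard(d.pair)
                report.newly_repaired.append(d.key)
                changed = True
            elif d.status == MISSING and noprov_kb(skey).derivable(*d.pair):
                d.status = REPAIRED
                session.missing_register(skey).discard(d.pair)
                session.provisionals.pop(d.key, None)
                report.newly_repaired.append(d.key)
                changed = True
            elif d.status == REPAIRED and was_wrong \
                    and net_kb.derivable(*d.pair):
                d.status = WRONG
                session.wrong_register(skey).add(d.pair)
                report.reinstated.append(d.key)
                changed = True
            elif d.status == REPAIRED and was_missing and not was_wrong \
                    and not noprov_kb(skey).derivable(*d.pair):
                d.status = MISSING
                session.missing_register(skey).add(d.pair)
                session.add_provisional(d)
                report.reinstated.append(d.key)
                changed = True
    # cached justifications are recomputed lazily on next use; clear the
    # caches of open wrong defects (their repair context changed)
    net_kb = build_kb(session, NETWORK_SCOPE)
    for d in session.open_defects(WRONG):
        if d.justifications:
            report.invalidated_caches.append(d.key)
            d.justifications = []
    if detect:
        report.new_candidates = register_new_candidates(session, net_kb)
    session.log("propagate", newly_repaired=report.newly_repaired,
                reinstated=report.reinstated,
                new_candidates=[d.key for d in report.new_candidates])
    return report


def register_new_candidates(session, network_kb=None) -> list[CandidateDefect]:
    """Run detection on every ontology and ontology pair; register and
    return candidates not seen before in this session."""
    net_kb = network_kb if network_kb is not None \
        else build_kb(session, NETWORK_SCOPE)
    new: list[CandidateDefect] = []
    scopes: list[object] = list(session.network.ontology_ids())
    if len(session.network.ontology_ids()) > 2:
        scopes += session.network.pairs()
    elif session.network.pairs():
        # with exactly two ontologies the pair KB equals the network KB,
        # so CMM detection is vacuous; skip it
        pass
    from .model import REDUNDANT
    for scope in scopes:
        for d in detection.detect_candidates(session, scope, network_kb=net_kb):
            prior = session.defects.get(d.key)
            if prior is None:
                session.defects[d.key] = d
                new.append(d)
            elif prior.status == REDUNDANT:
                # re-opened: the candidate that dominated it is gone
                prior.status = UNVALIDATED
                new.append(prior)
    return new


@dataclass
class StatusReport:
    """Requirements (i)-(iv) plus open work, each independently testable.

    (i) every validated missing is-a relation is derivable from its
    repaired host ontology (asserted non-removed + added repairs, no
    provisionals); (ii) no validated wrong is-a relation is derivable
    from the repaired network; (iii) every validated missing mapping is
    derivable from its repaired pair KB; (iv) no validated wrong mapping
    is derivable from the repaired network.
    """

    missing_isa_underivable: list[tuple] = field(default_factory=list)
    wrong_isa_derivable: list[tuple] = field(default_factory=list)
    missing_mapping_underivable: list[tuple] = field(default_factory=list)
    wrong_mapping_derivable: list[tuple] = field(default_factory=list)
    open_candidates: int = 0
    unrepaired_missing: int = 0
    unrepaired_wrong: int = 0
    done: bool = False


def network_status(session: SessionState) -> StatusReport:
    rep = StatusReport()
    net_kb = build_kb(session, NETWORK_SCOPE)
    noprov: dict[object, KnowledgeBase] = {}

    def kb_for(scope):
        skey = scope_key(scope)
        if skey not in noprov:
            noprov[skey] = _scope_kb_without_provisionals(session, skey)
        return noprov[skey]

    for scope, pair in session.all_missing_pairs():
        target = (rep.missing_isa_underivable if isinstance(scope, str)
                  else rep.missing_mapping_underivable)
        if not kb_for(scope).derivable(*pair):
            target.append((scope, (pair[0].key, pair[1].key)))
    for scope, pair in session.all_wrong_pairs():
        target = (rep.wrong_isa_derivable if isinstance(scope, str)
                  else rep.wrong_mapping_derivable)
        if net_kb.derivable(*pair):
            target.append((scope, (pair[0].key, pair[1].key)))
    rep.open_candidates = len(session.open_candidates())
    rep.unrepaired_missing = len(session.open_defects(MISSING))
    rep.unrepaired_wrong = len(session.open_defects(WRONG))
    rep.done = (not rep.missing_isa_underivable
                and not rep.wrong_isa_derivable
                and not rep.missing_mapping_underivable
                and not rep.wrong_mapping_derivable
                and rep.open_candidates == 0
                and rep.unrepaired_missing == 0
                and rep.unrepaired_wrong == 0)
    return rep


class DecisionPolicy(Protocol):
    """Scripted stand-in for the domain expert."""

    def verdict(self, session, defect: CandidateDefect) -> str: ...

    def choose_removal(self, session, defect: CandidateDefect) -> set: ...

    def choose_addition(self, session, defect: CandidateDefect,
                        space) -> Pair: ...


class IterationLimitExceeded(RuntimeError):
    def __init__(self, session, transcript):
        super().__init__("scripted session did not terminate")
        self.session = session
        self.transcript = transcript


def _state_hash(session: SessionState) -> str:
    payload = {
        "statuses": sorted((str(k), d.status)
                           for k, d in session.defects.items()),
        "ri_minus": sorted(map(str, session.ri_minus)),
        "ri_plus": sorted(map(str, session.ri_plus)),
        "rm_minus": sorted(map(str, session.rm_minus)),
        "rm_plus": sorted(map(str, session.rm_plus)),
    }
    return hashlib.sha256(json.dumps(payload).encode()).hexdigest()


def run_scripted_session(network: OntologyNetwork, policy: DecisionPolicy,
                         max_iterations: int = 50,
                         seed: Optional[int] = None,
                         caps: Optional[EnumerationCaps] = None,
                         ) -> tuple[SessionState, list[str]]:
    """Non-interactive driver: loop detect -> validate -> repair-wrong ->
    repair-missing until done or the iteration cap trips.  Deterministic
    for fixed inputs; the transcript logs every phase (and the seed, which
    only matters to policies that use one)."""
    from .repair_missing import rank_missing, execute_addition
    from .repair_wrong import rank_wrong, execute_removals

    session = SessionState(network)
    transcript = [f"session start seed={seed}"]
    seen_states: set[str] = set()
    for iteration in range(1, max_iterations + 1):
        net_kb = build_kb(session, NETWORK_SCOPE)
        new = register_new_candidates(session, net_kb)
        transcript.append(f"iter {iteration}: detected {len(new)} new candidates")
        # redundancy filtering per scope, then verdicts
        open_cands = session.open_candidates()
        by_scope: dict[object, list[CandidateDefect]] = {}
        for d in open_cands:
            by_scope.setdefault(scope_key(d.scope), []).append(d)
        verdicts = []
        for skey in sorted(by_scope, key=str):
            local_kb = build_kb(session, skey)
            retained, redundant = detection.filter_redundant(
                by_scope[skey], local_kb)
            transcript.append(
                f"iter {iteration}: scope {skey}: {len(retained)} retained, "
                f"{len(redundant)} redundant")
            for d in retained:
                verdicts.append(Verdict(defect=d,
                                        decision=policy.verdict(session, d),
                                        provenance="scripted-oracle"))
        if verdicts:
            record_verdicts(session, verdicts)
            transcript.append(f"iter {iteration}: recorded {len(verdicts)} verdicts")
            # a verdict may concern a pair a prior repair already settled;
            # propagation normalizes such defects to repaired immediately
            propagate_consequences(session, detect=False)
        # repair wrong relations, worst-ranked first
        guard = 0
        while session.open_defects(WRONG):
            d = rank_wrong(session, caps=caps)[0]
            chosen = policy.choose_removal(session, d)
            execute_removals(session, [d], chosen)
            transcript.append(f"iter {iteration}: removed {sorted(chosen)} "
                              f"for wrong {d.pair}")
            guard += 1
            if guard > 10000:
                raise IterationLimitExceeded(session, transcript)
        # repair missing relations, fewest actions first
        guard = 0
        while session.open_defects(MISSING):
            d, space = rank_missing(session)[0]
            action = policy.choose_addition(session, d, space)
            execute_addition(session, d, action)
            transcript.append(f"iter {iteration}: added {action} "
                              f"for missing {d.pair}")
            guard += 1
            if guard > 10000:
                raise IterationLimitExceeded(session, transcript)
        # repairs may have settled everything by side effect without a
        # detection pass; re-detect before judging termination so dormant
        # (formerly redundant) candidates are not missed
        register_new_candidates(session)
        status = network_status(session)
        metric = (status.open_candidates + status.unrepaired_missing
                  + status.unrepaired_wrong)
        transcript.append(f"iter {iteration}: open={status.open_candidates} "
                          f"metric={metric} done={status.done}")
        if status.done:
            transcript.append(f"done after {iteration} iterations")
            return session, transcript
        h = _state_hash(session)
        if h in seen_states:
            raise IterationLimitExceeded(session, transcript)
        seen_states.add(h)
    raise IterationLimitExceeded(session, transcript)
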