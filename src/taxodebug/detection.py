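"""Phase 1: detection of candidate missing is-a relations and mappings.

A CMI for ontology k is an ordered pair of concepts of k that is derivable
from the network's induced ontology but not from k alone; a CMM is the
analogue for a pair of ontologies plus their alignment.  Detection is
restricted to *mapped* concepts (endpoints of mappings): in the restricted
setting where all asserted axioms and mappings are correct, repairing all
mapped-pair candidates repairs every candidate, so nothing is lost, while
the search space shrinks dramatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .model import (
    CandidateDefect, CMI, CMM, ConceptRef, OntologyNetwork,
    UNVALIDATED, REDUNDANT,
)
from .reasoning import KnowledgeBase, build_kb, scope_key, NETWORK_SCOPE


def mapped_concepts(network: OntologyNetwork) -> dict[str, set[ConceptRef]]:
    """Per-ontology sets of concepts that occur as an endpoint of at least
    one non-removed mapping axiom."""
    out: dict[str, set[ConceptRef]] = {oid: set()
                                       for oid in network.ontology_ids()}
    for pair in sorted(network.alignments):
        for ax in network.alignments[pair].axioms():
            for end in (ax.sub, ax.super):
                out[end.ontology_id].add(end)
    return out


def detect_candidates(session, scope,
                      network_kb: KnowledgeBase | None = None,
                      ) -> list[CandidateDefect]:
    """All new candidates in one scope (ontology id for CMIs, ontology
    pair for CMMs): ordered pairs of mapped concepts derivable in the
    current network KB but not in the scope-local KB, excluding pairs
    already decided or already open in this session."""
    skey = scope_key(scope)
    if skey == NETWORK_SCOPE:
        raise ValueError("detection scope must be an ontology or a pair")
    net_kb = network_kb if network_kb is not None else build_kb(session, NETWORK_SCOPE)
    local_kb = build_kb(session, skey)
    mapped = mapped_concepts(session.network)
    if isinstance(skey, str):
        kind = CMI
        left = sorted(mapped[skey])
        right = left
    else:
        kind = CMM
        i, j = skey
        left = sorted(mapped[i] | mapped[j])
        right = left
    decided = session.decided_pairs(skey)
    out: list[CandidateDefect] = []
    for a in left:
        for b in right:
            if a.key == b.key:
                continue
            if kind == CMM and a.ontology_id == b.ontology_id:
                continue
            if (a, b) in decided:
                continue
            if not net_kb.derivable(a, b):
                continue
            if local_kb.derivable(a, b):
                continue
            out.append(CandidateDefect(kind=kind, pair=(a, b), scope=skey,
                                       status=UNVALIDATED))
    out.sort(key=lambda d: d.key)
    return out


def filter_redundant(candidates: list[CandidateDefect],
                     local_kb: KnowledgeBase,
                     ) -> tuple[list[CandidateDefect], list[CandidateDefect]]:
    """Split candidates of one scope into non-redundant and redundant.

    Candidate (a, b) is redundant iff some retained candidate (c, d) is at
    least as informative in the scope-local KB -- derivable(a, c) and
    derivable(d, b) -- so repairing (c, d) repairs (a, b) too.  Mutually
    informative ties retain the lexicographically least pair.
    """
    scopes = {scope_key(d.scope) for d in candidates}
    if len(scopes) > 1:
        raise ValueError(f"candidates span several scopes: {scopes}")
    cands = sorted(candidates, key=lambda d: d.key)
    n = len(cands)

    def at_least_as_informative(x: CandidateDefect, y: CandidateDefect) -> bool:
        # adding x's pair entails y's pair in the local KB
        (a, b), (c, d) = y.pair, x.pair
        return local_kb.derivable(a, c) and local_kb.derivable(d, b)

    dominance = nx.DiGraph()
    dominance.add_nodes_from(range(n))
    for ix in range(n):
        for iy in range(n):
            if ix != iy and at_least_as_informative(cands[ix], cands[iy]):
                dominance.add_edge(ix, iy)  # ix repairs iy
    # mutual ties form strongly connected components; keep lexicographic
    # least of each, then keep only components not dominated by another
    condensation = nx.condensation(dominance)
    retained_idx: set[int] = set()
    for comp_id in condensation.nodes:
        members = sorted(condensation.nodes[comp_id]["members"])
        if condensation.in_degree(comp_id) == 0:
            retained_idx.add(members[0])
    non_redundant, redundant = [], []
    for ix, d in enumerate(cands):
        if ix in retained_idx:
            non_redundant.append(d)
        else:
            d.status = REDUNDANT
            redundant.append(d)
    return non_redundant, redundant


@dataclass
class CandidateGroup:
    """A connected component of the comparability relation between
    candidates: every member shares, with some other member, a concept
    comparable (derivable either direction) in the network KB."""

    scope: object
    members: list[CandidateDefect] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def group_candidates(candidates: list[CandidateDefect],
                     network_kb: KnowledgeBase) -> list[CandidateGroup]:
    """Group candidates for validation; largest groups first, then
    lexicographic by the least member key."""
    if not candidates:
        return []
    scopes = {scope_key(d.scope) for d in candidates}
    if len(scopes) > 1:
        raise ValueError(f"candidates span several scopes: {scopes}")
    cands = sorted(candidates, key=lambda d: d.key)

    def comparable(x: ConceptRef, y: ConceptRef) -> bool:
        return (network_kb.derivable(x, y) or network_kb.derivable(y, x))

    g = nx.Graph()
    g.add_nodes_from(range(len(cands)))
    for ix in range(len(cands)):
        for iy in range(ix + 1, len(cands)):
            if any(comparable(x, y)
                   for x in cands[ix].pair for y in cands[iy].pair):
                g.add_edge(ix, iy)
    scope = scope_key(cands[0].scope)
    groups = [CandidateGroup(scope=scope, members=[cands[i] for i in sorted(comp)])
              for comp in nx.connected_components(g)]
    groups.sort(key=lambda grp: (-len(grp.members), grp.members[0].key))
    return groups
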