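"""Scoped knowledge bases over atomic subsumption axioms.

A knowledge base (KB) is a scope-restricted view of the current network's
non-removed axioms: the whole network, one ontology, or an ontology pair
with its alignment.  Derivability is reflexive-transitive reachability over
the directed subsumption graph; cycles (created by equivalence mappings by
construction) are permitted.  Justifications are edge sets of simple
directed paths filtered to subset-minimality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx

from .model import (
    Axiom, AxiomKey, ConceptRef, Justification, OntologyNetwork,
    REMOVED, induced_axioms,
)

NETWORK_SCOPE = "network"


def scope_key(scope) -> object:
    """Canonical form of a scope descriptor: 'network', an ontology id, or
    a sorted (i, j) tuple for an ontology pair."""
    if scope == NETWORK_SCOPE or scope is None:
        return NETWORK_SCOPE
    if isinstance(scope, str):
        return scope
    i, j = scope
    return (i, j) if i <= j else (j, i)


@dataclass
class EnumerationCaps:
    """Caps for justification / hitting-set enumeration (both are
    exponential in the worst case).  ``truncated`` on results flags caps
    that were hit."""

    max_paths: int = 1000
    max_path_length: int = 20
    max_hitting_sets: int = 10000
    max_hitting_set_size: int = 5

    def validate(self) -> None:
        if self.max_paths <= 0 or self.max_path_length <= 0:
            raise ValueError("enumeration caps must be positive")
        if self.max_hitting_sets <= 0 or self.max_hitting_set_size <= 0:
            raise ValueError("enumeration caps must be positive")


class KnowledgeBase:
    """A set of non-removed axioms visible in one scope, with reachability
    answered from per-node caches over the subsumption digraph."""

    def __init__(self, scope, axioms: Iterable[Axiom]):
        self.scope = scope_key(scope)
        self.axioms: dict[AxiomKey, Axiom] = {}
        self.graph = nx.DiGraph()
        self._concepts: dict[tuple[str, str], ConceptRef] = {}
        self._reach_cache: dict[tuple[str, str], frozenset] = {}
        self._rev_cache: dict[tuple[str, str], frozenset] = {}
        for ax in axioms:
            if ax.status == REMOVED:
                continue
            if ax.key in self.axioms:
                continue
            self.axioms[ax.key] = ax
            self._register(ax.sub)
            self._register(ax.super)
            self.graph.add_edge(ax.sub.key, ax.super.key)

    def _register(self, c: ConceptRef) -> None:
        self._concepts.setdefault(c.key, c)
        self.graph.add_node(c.key)

    def add_concepts(self, concepts: Iterable[ConceptRef]) -> None:
        """Declare isolated concepts so cone/derivable accept them."""
        for c in concepts:
            self._register(c)

    def has_concept(self, c: ConceptRef) -> bool:
        return c.key in self.graph

    def concepts(self) -> list[ConceptRef]:
        return [self._concepts[k] for k in sorted(self._concepts)]

    def _check(self, c: ConceptRef) -> None:
        if c.key not in self.graph:
            raise KeyError(f"concept {c!r} not visible in scope {self.scope}")

    def _reachable(self, key: tuple[str, str]) -> frozenset:
        cached = self._reach_cache.get(key)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, key)) | {key}
            self._reach_cache[key] = cached
        return cached

    def _coreachable(self, key: tuple[str, str]) -> frozenset:
        cached = self._rev_cache.get(key)
        if cached is None:
            cached = frozenset(nx.ancestors(self.graph, key)) | {key}
            self._rev_cache[key] = cached
        return cached

    def derivable(self, a: ConceptRef, b: ConceptRef) -> bool:
        """True iff a is-a b follows from this KB: a == b, or a directed
        path of axioms leads from a to b."""
        self._check(a)
        self._check(b)
        return b.key in self._reachable(a.key)

    def cone(self, c: ConceptRef, direction: str) -> set[ConceptRef]:
        """Reflexive super- or sub-concept cone of ``c``."""
        self._check(c)
        if direction == "super":
            keys = self._reachable(c.key)
        elif direction == "sub":
            keys = self._coreachable(c.key)
        else:
            raise ValueError("direction must be 'super' or 'sub'")
        return {self._concepts[k] for k in keys}

    def all_justifications(self, a: ConceptRef, b: ConceptRef,
                           caps: Optional[EnumerationCaps] = None,
                           ) -> tuple[list[Justification], bool]:
        """Every subset-minimal axiom set entailing (a, b).

        Derivation paths are simple directed paths a -> b; their edge sets
        are filtered to subset-minimal sets.  Returns ``(justifications,
        truncated)`` with justifications ordered by size then lexicographic
        axiom keys.
        """
        caps = caps or EnumerationCaps()
        caps.validate()
        self._check(a)
        self._check(b)
        if a.key == b.key:
            raise ValueError("justifications are only defined for a != b")
        if not self.derivable(a, b):
            raise ValueError(f"{a!r} -> {b!r} is not derivable in {self.scope}")
        truncated = False
        edge_sets: list[frozenset] = []
        # every a->b path stays inside descendants(a) & ancestors(b);
        # restricting the search there prunes dead-end exploration
        relevant = self._reachable(a.key) & self._coreachable(b.key)
        sub = self.graph.subgraph(relevant)
        paths = nx.all_simple_edge_paths(sub, a.key, b.key,
                                         cutoff=caps.max_path_length)
        n = 0
        for path in paths:
            edge_sets.append(frozenset(path))
            n += 1
            if n >= caps.max_paths:
                truncated = True
                break
        # A path of maximal allowed length may hide shorter alternatives
        # only if some longer path exists; flag when cutoff was reachable.
        if not truncated and any(len(es) >= caps.max_path_length
                                 for es in edge_sets):
            truncated = True
        minimal = _minimal_sets(edge_sets)
        justs = [Justification(axioms=es, target=(a.key, b.key))
                 for es in minimal]
        justs.sort(key=lambda j: (len(j.axioms), j.sorted_axioms()))
        return justs, truncated

    def apply_changes(self, additions: Iterable[Axiom],
                      removals: Iterable[Axiom]) -> "KnowledgeBase":
        """A new KB with ``removals`` dropped and ``additions`` included;
        the original KB is left untouched."""
        removals = list(removals)
        for ax in removals:
            if ax.key not in self.axioms:
                raise ValueError(f"cannot remove {ax!r}: not in KB")
        removed_keys = {ax.key for ax in removals}
        axioms = [ax for k, ax in sorted(self.axioms.items())
                  if k not in removed_keys]
        axioms.extend(additions)
        kb = KnowledgeBase(self.scope, axioms)
        kb.add_concepts(self.concepts())
        return kb

    def __repr__(self) -> str:
        return f"KnowledgeBase({self.scope}, {len(self.axioms)} axioms)"


def _minimal_sets(sets: list[frozenset]) -> list[frozenset]:
    """Subset-minimal members of a family of sets (duplicates collapsed)."""
    uniq = sorted(set(sets), key=lambda s: (len(s), sorted(s)))
    minimal: list[frozenset] = []
    for s in uniq:
        if not any(m < s for m in minimal):
            minimal.append(s)
    return minimal


def build_kb(session, scope) -> KnowledgeBase:
    """Build the knowledge base for a scope of a debugging session.

    network scope: every non-removed intra and mapping axiom plus every
    provisional axiom (validated-but-unrepaired missing relations and
    mappings).  ontology scope k: intra axioms of k plus provisional intra
    axioms of k.  pair scope (i, j): intra axioms of i and j, their
    alignment, the provisional intra axioms of both, and provisional
    mappings of the pair.
    """
    network: OntologyNetwork = session.network
    key = scope_key(scope)
    if key == NETWORK_SCOPE:
        axioms = induced_axioms(network, extra=session.provisional_axioms())
        kb = KnowledgeBase(key, axioms)
        for oid in network.ontology_ids():
            kb.add_concepts(network.ontologies[oid].concepts.values())
        return kb
    if isinstance(key, str):
        if key not in network.ontologies:
            raise KeyError(f"unknown ontology scope {key!r}")
        ont = network.ontologies[key]
        axioms = list(ont.axioms())
        axioms.extend(ax for ax in session.provisional_axioms()
                      if ax.sub.ontology_id == key
                      and ax.super.ontology_id == key)
        kb = KnowledgeBase(key, axioms)
        kb.add_concepts(ont.concepts.values())
        return kb
    i, j = key
    for oid in (i, j):
        if oid not in network.ontologies:
            raise KeyError(f"unknown ontology {oid!r} in pair scope")
    axioms = list(network.ontologies[i].axioms())
    axioms.extend(network.ontologies[j].axioms())
    al = network.alignment(i, j)
    if al is not None:
        axioms.extend(al.axioms())
    for ax in session.provisional_axioms():
        onts = {ax.sub.ontology_id, ax.super.ontology_id}
        if onts <= {i, j}:
            axioms.append(ax)
    kb = KnowledgeBase(key, axioms)
    kb.add_concepts(network.ontologies[i].concepts.values())
    kb.add_concepts(network.ontologies[j].concepts.values())
    return kb
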