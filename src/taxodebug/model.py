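"""Domain types for networked taxonomies.

A *taxonomy* is an ontology restricted to named concepts and atomic is-a
(subsumption) axioms.  Taxonomies are connected into an *ontology network*
through pairwise alignments, whose mappings (equivalence or directed
subsumption between concepts of two ontologies) are represented as directed
subsumption axioms as well.  The types here only construct and validate;
all computation lives in the sibling modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

# Axiom layers
INTRA = "intra-ontology"
MAPPING = "mapping"

# Axiom statuses
ASSERTED = "asserted"
PROVISIONAL = "provisional"
REPAIR_ADDED = "repair-added"
REMOVED = "removed"

# Axiom origins
ORIGINAL = "original"
VALIDATED_MISSING = "validated-missing"
REPAIR = "repair"
EQUIV_COMPONENT = "equivalence-component"


@dataclass(frozen=True, order=True)
class ConceptRef:
    """A concept identified by its host ontology id and concept id.

    Labels are display-only and excluded from identity; concept ids are the
    primary key within their ontology.
    """

    ontology_id: str
    concept_id: str
    label: Optional[str] = field(default=None, compare=False)

    @property
    def key(self) -> tuple[str, str]:
        return (self.ontology_id, self.concept_id)

    def display(self) -> str:
        return self.label if self.label is not None else self.concept_id

    def __repr__(self) -> str:  # compact, for transcripts
        return f"{self.ontology_id}:{self.concept_id}"


Pair = tuple[ConceptRef, ConceptRef]
AxiomKey = tuple[tuple[str, str], tuple[str, str]]


def normalize_label(text: str) -> str:
    """Normalization used when matching concept names against external
    knowledge: lowercase, underscores become spaces, whitespace collapsed."""
    return " ".join(text.replace("_", " ").lower().split())


@dataclass
class Axiom:
    """A directed subsumption axiom: ``sub`` is-a ``super``.

    An equivalence mapping is stored as two mapping axioms (one per
    direction), each independently removable, sharing a ``pair_tag``.
    """

    sub: ConceptRef
    super: ConceptRef
    layer: str
    status: str = ASSERTED
    origin: str = ORIGINAL
    pair_tag: Optional[str] = None
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sub.key == self.super.key:
            raise ValueError(f"self-axiom forbidden: {self.sub!r}")
        same = self.sub.ontology_id == self.super.ontology_id
        if self.layer == INTRA and not same:
            raise ValueError(f"intra-ontology axiom across ontologies: {self!r}")
        if self.layer == MAPPING and same:
            raise ValueError(f"mapping axiom within one ontology: {self!r}")

    @property
    def key(self) -> AxiomKey:
        return (self.sub.key, self.super.key)

    @property
    def pair(self) -> Pair:
        return (self.sub, self.super)

    @property
    def removable(self) -> bool:
        """Only original asserted knowledge may be removed during repair;
        provisional and repair-added axioms are validated-correct."""
        return self.status == ASSERTED and self.origin in (ORIGINAL, EQUIV_COMPONENT)

    def __repr__(self) -> str:
        return f"Axiom({self.sub!r} -> {self.super!r}, {self.layer}, {self.status})"


def make_intra(sub: ConceptRef, sup: ConceptRef, **kw) -> Axiom:
    return Axiom(sub, sup, layer=INTRA, **kw)


def make_mapping(sub: ConceptRef, sup: ConceptRef, **kw) -> Axiom:
    return Axiom(sub, sup, layer=MAPPING, **kw)


def equivalence(a: ConceptRef, b: ConceptRef, tag: Optional[str] = None,
                confidence: Optional[float] = None) -> list[Axiom]:
    """Expand an equivalence mapping a == b into its two directed components."""
    tag = tag or f"eq:{a.ontology_id}:{a.concept_id}={b.ontology_id}:{b.concept_id}"
    return [
        Axiom(a, b, layer=MAPPING, origin=EQUIV_COMPONENT, pair_tag=tag,
              confidence=confidence),
        Axiom(b, a, layer=MAPPING, origin=EQUIV_COMPONENT, pair_tag=tag,
              confidence=confidence),
    ]


class Ontology:
    """A taxonomy: a set of concepts, intra-ontology is-a axioms, and
    (recommendation-only) part-of pairs that never enter any knowledge base."""

    def __init__(self, id: str, concepts: Iterable[ConceptRef] = (),
                 isa: Iterable[Axiom] = (),
                 partof: Iterable[tuple[str, str]] = ()):
        self.id = id
        self.concepts: dict[str, ConceptRef] = {}
        self.isa: dict[AxiomKey, Axiom] = {}
        # part-of stored as (part concept_id, whole concept_id)
        self.partof: set[tuple[str, str]] = set(partof)
        for c in concepts:
            self.add_concept(c)
        for ax in isa:
            self.add_axiom(ax)

    def add_concept(self, c: ConceptRef) -> ConceptRef:
        if c.ontology_id != self.id:
            raise ValueError(f"concept {c!r} does not belong to ontology {self.id}")
        existing = self.concepts.get(c.concept_id)
        if existing is None:
            self.concepts[c.concept_id] = c
            return c
        return existing

    def concept(self, concept_id: str) -> ConceptRef:
        return self.concepts[concept_id]

    def add_axiom(self, ax: Axiom) -> Axiom:
        if ax.layer != INTRA or ax.sub.ontology_id != self.id:
            raise ValueError(f"axiom {ax!r} does not belong to ontology {self.id}")
        for end in (ax.sub, ax.super):
            if end.concept_id not in self.concepts:
                raise ValueError(
                    f"axiom endpoint {end!r} not declared in ontology {self.id}")
        if ax.key in self.isa:
            logger.warning("duplicate axiom %r in ontology %s dropped", ax, self.id)
            return self.isa[ax.key]
        self.isa[ax.key] = ax
        return ax

    def axioms(self, include_removed: bool = False) -> list[Axiom]:
        axs = [a for a in self.isa.values()
               if include_removed or a.status != REMOVED]
        return sorted(axs, key=lambda a: a.key)

    def __repr__(self) -> str:
        return f"Ontology({self.id}, {len(self.concepts)} concepts, {len(self.isa)} axioms)"


class Alignment:
    """The set of mappings between one ordered pair of ontologies."""

    def __init__(self, ontology_pair: tuple[str, str],
                 mappings: Iterable[Axiom] = ()):
        i, j = ontology_pair
        if i == j:
            raise ValueError("alignment requires two distinct ontologies")
        self.ontology_pair = (i, j)
        self.mappings: dict[AxiomKey, Axiom] = {}
        for m in mappings:
            self.add_mapping(m)

    def add_mapping(self, ax: Axiom) -> Axiom:
        if ax.layer != MAPPING:
            raise ValueError(f"{ax!r} is not a mapping axiom")
        onts = {ax.sub.ontology_id, ax.super.ontology_id}
        if onts != set(self.ontology_pair):
            raise ValueError(
                f"mapping {ax!r} does not connect {self.ontology_pair}")
        if ax.key in self.mappings:
            logger.warning("duplicate mapping %r dropped", ax)
            return self.mappings[ax.key]
        self.mappings[ax.key] = ax
        return ax

    def axioms(self, include_removed: bool = False) -> list[Axiom]:
        axs = [a for a in self.mappings.values()
               if include_removed or a.status != REMOVED]
        return sorted(axs, key=lambda a: a.key)

    def __repr__(self) -> str:
        return f"Alignment({self.ontology_pair}, {len(self.mappings)} mapping axioms)"


class OntologyNetwork:
    """A set of taxonomies plus at most one alignment per unordered pair.

    The *induced ontology* of the network -- all concepts, all intra axioms
    and all mapping axioms viewed as one taxonomy -- is derivable from the
    fields alone; see :func:`induced_axioms`.
    """

    def __init__(self, ontologies: Iterable[Ontology] = (),
                 alignments: Iterable[Alignment] = ()):
        self.ontologies: dict[str, Ontology] = {}
        self.alignments: dict[tuple[str, str], Alignment] = {}
        for o in ontologies:
            self.add_ontology(o)
        for a in alignments:
            self.add_alignment(a)

    def add_ontology(self, o: Ontology) -> Ontology:
        if o.id in self.ontologies:
            raise ValueError(f"duplicate ontology id {o.id}")
        self.ontologies[o.id] = o
        return o

    def add_alignment(self, a: Alignment) -> Alignment:
        key = self.pair_key(*a.ontology_pair)
        for oid in a.ontology_pair:
            if oid not in self.ontologies:
                raise ValueError(f"alignment references unknown ontology {oid}")
        if key in self.alignments:
            raise ValueError(f"duplicate alignment for pair {key}")
        for m in a.mappings.values():
            for end in (m.sub, m.super):
                if end.concept_id not in self.ontologies[end.ontology_id].concepts:
                    raise ValueError(f"mapping endpoint {end!r} unknown")
        self.alignments[key] = a
        return a

    @staticmethod
    def pair_key(i: str, j: str) -> tuple[str, str]:
        return (i, j) if i <= j else (j, i)

    def alignment(self, i: str, j: str, create: bool = False) -> Optional[Alignment]:
        key = self.pair_key(i, j)
        al = self.alignments.get(key)
        if al is None and create:
            al = Alignment(key)
            self.alignments[key] = al
        return al

    def ontology_ids(self) -> list[str]:
        return sorted(self.ontologies)

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered ontology pairs (alignment present or not)."""
        ids = self.ontology_ids()
        return [(i, j) for k, i in enumerate(ids) for j in ids[k + 1:]]

    def concept(self, key: tuple[str, str]) -> ConceptRef:
        return self.ontologies[key[0]].concept(key[1])

    def find_axiom(self, key: AxiomKey) -> Optional[Axiom]:
        (so, _), (to, _) = key
        if so == to:
            return self.ontologies[so].isa.get(key)
        al = self.alignments.get(self.pair_key(so, to))
        return al.mappings.get(key) if al is not None else None

    def __repr__(self) -> str:
        return (f"OntologyNetwork({len(self.ontologies)} ontologies, "
                f"{len(self.alignments)} alignments)")


def induced_axioms(network: OntologyNetwork,
                   extra: Iterable[Axiom] = ()) -> list[Axiom]:
    """Axioms of the network's induced ontology.

    The union of all intra-ontology axioms and all mapping axioms
    (equivalences already expanded to their two directed components),
    excluding removed axioms.  Duplicates collapse to one.
    """
    seen: dict[AxiomKey, Axiom] = {}
    for oid in network.ontology_ids():
        for ax in network.ontologies[oid].axioms():
            seen.setdefault(ax.key, ax)
    for pair in sorted(network.alignments):
        for ax in network.alignments[pair].axioms():
            seen.setdefault(ax.key, ax)
    for ax in extra:
        if ax.status != REMOVED:
            seen.setdefault(ax.key, ax)
    return [seen[k] for k in sorted(seen)]


# --- defects, justifications, repair spaces -------------------------------

CMI = "CMI"
CMM = "CMM"

UNVALIDATED = "unvalidated"
REDUNDANT = "redundant"
MISSING = "missing"
WRONG = "wrong"
REPAIRED = "repaired"


@dataclass
class CandidateDefect:
    """A candidate missing is-a relation (CMI, within one ontology) or
    candidate missing mapping (CMM, across an ontology pair): a pair
    derivable from the network but not from its own scope."""

    kind: str
    pair: Pair
    scope: object  # ontology id (CMI) or (i, j) tuple (CMM)
    status: str = UNVALIDATED
    justifications: list["Justification"] = field(default_factory=list)

    def __post_init__(self) -> None:
        a, b = self.pair
        if self.kind == CMI:
            if not (a.ontology_id == b.ontology_id == self.scope):
                raise ValueError(f"CMI concepts must both live in {self.scope}")
        elif self.kind == CMM:
            if {a.ontology_id, b.ontology_id} != set(self.scope):
                raise ValueError(f"CMM concepts must span {self.scope}")
        else:
            raise ValueError(f"unknown defect kind {self.kind}")

    @property
    def key(self) -> tuple:
        # scope normalized to a tuple so keys of CMIs and CMMs sort together
        scope = (self.scope,) if isinstance(self.scope, str) else tuple(self.scope)
        return (self.kind, scope, self.pair[0].key, self.pair[1].key)

    def __repr__(self) -> str:
        return (f"CandidateDefect({self.kind}, {self.pair[0]!r} -> "
                f"{self.pair[1]!r}, {self.status})")


@dataclass(frozen=True)
class Justification:
    """A minimal set of axioms entailing a derived pair: the edge set of a
    simple subsumption path, filtered to subset-minimality."""

    axioms: frozenset[AxiomKey]
    target: tuple[tuple[str, str], tuple[str, str]]

    def sorted_axioms(self) -> list[AxiomKey]:
        return sorted(self.axioms)

    def __len__(self) -> int:
        return len(self.axioms)


class SessionState:
    """The mutable state of one debugging session.

    Holds the current network (axiom statuses included), the registers of
    validated missing/wrong is-a relations (MI/WI, per ontology) and
    mappings (MM/WM, per ontology pair), the executed repairing actions
    (RI+/RI- for intra axioms, RM+/RM- for mappings), the open candidates
    (CMI/CMM), provisional axioms for validated-but-unrepaired missing
    relations, and an append-only decision log.
    """

    def __init__(self, network: OntologyNetwork):
        self.network = network
        # scope -> set of concept pairs
        self.mi: dict[str, set[Pair]] = {}
        self.wi: dict[str, set[Pair]] = {}
        self.mm: dict[tuple[str, str], set[Pair]] = {}
        self.wm: dict[tuple[str, str], set[Pair]] = {}
        # executed repairing actions, as axiom keys
        self.ri_plus: set[AxiomKey] = set()
        self.ri_minus: set[AxiomKey] = set()
        self.rm_plus: set[AxiomKey] = set()
        self.rm_minus: set[AxiomKey] = set()
        # every candidate ever seen, keyed by CandidateDefect.key
        self.defects: dict[tuple, CandidateDefect] = {}
        # provisional axioms of unrepaired missing defects, by defect key
        self.provisionals: dict[tuple, Axiom] = {}
        self.decision_log: list[dict] = []
        # verdict history (never shrinks): (scope key, pair) tuples
        self.validated_missing: set[tuple] = set()
        self.validated_wrong: set[tuple] = set()

    # -- register helpers --------------------------------------------------

    @staticmethod
    def _reg_get(reg: dict, scope) -> set:
        return reg.setdefault(scope, set())

    def missing_register(self, scope) -> set:
        return self._reg_get(self.mi if isinstance(scope, str) else self.mm,
                             scope if isinstance(scope, str) else tuple(scope))

    def wrong_register(self, scope) -> set:
        return self._reg_get(self.wi if isinstance(scope, str) else self.wm,
                             scope if isinstance(scope, str) else tuple(scope))

    def open_candidates(self, kind: Optional[str] = None) -> list[CandidateDefect]:
        out = [d for d in self.defects.values()
               if d.status == UNVALIDATED and (kind is None or d.kind == kind)]
        return sorted(out, key=lambda d: d.key)

    def open_defects(self, decision: str) -> list[CandidateDefect]:
        """Unrepaired validated defects: decision is 'missing' or 'wrong'."""
        out = [d for d in self.defects.values() if d.status == decision]
        return sorted(out, key=lambda d: d.key)

    def decided_pairs(self, scope) -> set[Pair]:
        """Pairs already registered (validated or still open) in a scope.

        Redundant candidates are *not* decided: they may be re-detected
        once the candidate that dominated them is repaired or rejected.
        """
        out: set[Pair] = set()
        out |= self.missing_register(scope)
        out |= self.wrong_register(scope)
        skey = scope if isinstance(scope, str) else tuple(scope)
        for d in self.defects.values():
            dscope = d.scope if isinstance(d.scope, str) else tuple(d.scope)
            if dscope == skey and d.status != REDUNDANT:
                out.add(d.pair)
        return out

    def provisional_axioms(self) -> list[Axiom]:
        return [self.provisionals[k] for k in sorted(self.provisionals)]

    def add_provisional(self, defect: CandidateDefect) -> Axiom:
        a, b = defect.pair
        layer = INTRA if a.ontology_id == b.ontology_id else MAPPING
        ax = Axiom(a, b, layer=layer, status=PROVISIONAL,
                   origin=VALIDATED_MISSING)
        self.provisionals[defect.key] = ax
        return ax

    def log(self, event: str, **info) -> None:
        self.decision_log.append({"event": event, **info})

    def all_missing_pairs(self) -> list[tuple[object, Pair]]:
        """Every (scope, pair) ever validated missing, repaired or not."""
        out = [(s, self._resolve_pair(p)) for s, p in self.validated_missing]
        return sorted(out, key=lambda sp: (str(sp[0]), sp[1]))

    def all_wrong_pairs(self) -> list[tuple[object, Pair]]:
        """Every (scope, pair) ever validated wrong, repaired or not."""
        out = [(s, self._resolve_pair(p)) for s, p in self.validated_wrong]
        return sorted(out, key=lambda sp: (str(sp[0]), sp[1]))

    def _resolve_pair(self, pair_keys: tuple) -> Pair:
        (ao, ac), (bo, bc) = pair_keys
        return (self.network.ontologies[ao].concept(ac),
                self.network.ontologies[bo].concept(bc))

    def check_invariants(self) -> None:
        for scope in set(self.mi) | set(self.wi):
            if self.mi.get(scope, set()) & self.wi.get(scope, set()):
                raise ValueError(f"MI and WI overlap in scope {scope}")
        for scope in set(self.mm) | set(self.wm):
            if self.mm.get(scope, set()) & self.wm.get(scope, set()):
                raise ValueError(f"MM and WM overlap in scope {scope}")
        if self.ri_plus & self.ri_minus or self.rm_plus & self.rm_minus:
            raise ValueError("added and removed repairing actions overlap")
        for key in self.provisionals:
            d = self.defects.get(key)
            if d is None or d.status != MISSING:
                raise ValueError(
                    f"provisional axiom without unrepaired missing defect: {key}")

    def clone(self) -> "SessionState":
        import copy
        return copy.deepcopy(self)


@dataclass
class RepairSpace:
    """Source/Target/Repair sets for one missing relation (a, b):
    Repair(a,b) is a filtered subset of Source(a,b) x Target(a,b), and
    adding any of its elements makes (a, b) derivable in the scope KB."""

    defect: CandidateDefect
    source: list[ConceptRef]
    target: list[ConceptRef]
    repair: list[Pair]

    def __post_init__(self) -> None:
        src = set(self.source)
        tgt = set(self.target)
        for s, t in self.repair:
            if s not in src or t not in tgt:
                raise ValueError("repair element outside Source x Target")
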