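"""Phase 2: expert validation of candidates.

Each open candidate is partitioned into *missing* (information absent from
its scope: repair by adding axioms) or *wrong* (derived via incorrect
axioms: repair by removals).  Verdict batches are atomic and checked for
contradictions; optional recommendations come from asserted part-of
relations and a pluggable external-knowledge oracle (is-a and part-of are
commonly confused by modellers, so a known part-of suggests a wrong is-a).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol

import networkx as nx

from .model import (
    CandidateDefect, MISSING, Ontology, UNVALIDATED, WRONG, normalize_label,
)

ISA = "isa"
PARTOF = "partof"
UNKNOWN = "unknown"


class KnowledgeOracle(Protocol):
    """External domain knowledge consulted for recommendations only.

    ``query`` takes two normalized term strings and answers 'isa',
    'partof' or 'unknown'; it must be deterministic for fixed inputs.
    """

    def query(self, term_a: str, term_b: str) -> str: ...


class DictOracle:
    """Dictionary-backed oracle; keys are (term_a, term_b) pairs,
    normalized at construction."""

    def __init__(self, entries: dict[tuple[str, str], str] | None = None):
        self._entries: dict[tuple[str, str], str] = {}
        for (a, b), rel in (entries or {}).items():
            if rel not in (ISA, PARTOF):
                raise ValueError(f"unknown oracle relation {rel!r}")
            self._entries[(normalize_label(a), normalize_label(b))] = rel

    def query(self, term_a: str, term_b: str) -> str:
        return self._entries.get(
            (normalize_label(term_a), normalize_label(term_b)), UNKNOWN)


class NullOracle:
    def query(self, term_a: str, term_b: str) -> str:
        return UNKNOWN


def load_oracle(path) -> DictOracle:
    """File-backed oracle table: TSV lines ``term_a<TAB>term_b<TAB>rel``
    with rel in {isa, partof}; '#' comments allowed."""
    entries: dict[tuple[str, str], str] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            entries[(parts[0], parts[1])] = parts[2]
    return DictOracle(entries)


@dataclass
class Verdict:
    defect: CandidateDefect
    decision: str  # missing | wrong
    provenance: str = "expert"

    def __post_init__(self) -> None:
        if self.decision not in (MISSING, WRONG):
            raise ValueError(f"decision must be missing or wrong: {self.decision}")


def recommend_verdict(defect: CandidateDefect, host: Optional[Ontology],
                      oracle: Optional[KnowledgeOracle] = None) -> str:
    """'wrong?' if a part-of relation is known between the concepts (host
    ontology first, then the oracle), 'missing?' if the oracle knows an
    is-a relation, else 'none'.  Recommendations never auto-decide."""
    if defect.status != UNVALIDATED:
        raise ValueError("recommendations apply to unvalidated candidates only")
    a, b = defect.pair
    if host is not None and (a.concept_id, b.concept_id) in host.partof:
        return "wrong?"
    if oracle is not None:
        try:
            answer = oracle.query(normalize_label(a.display()),
                                  normalize_label(b.display()))
        except Exception:  # oracle failures degrade to no recommendation
            return "none"
        if answer == PARTOF:
            return "wrong?"
        if answer == ISA:
            return "missing?"
    return "none"


class ContradictionError(ValueError):
    """A verdict batch contradicts itself or earlier decisions."""

    def __init__(self, report: list[str]):
        super().__init__("; ".join(report))
        self.report = report


def check_contradictions(session, verdicts: list[Verdict]) -> list[str]:
    """Contradiction rules over the union of past decisions and the batch:

    (1) no pair may receive both decisions;
    (2) no wrong-validated pair may be derivable from the missing-validated
        pairs plus the executed additions alone (such a verdict set cannot
        be realized by any repaired network).
    """
    report: list[str] = []
    missing_pairs = {pk for _, pk in session.validated_missing}
    wrong_pairs = {pk for _, pk in session.validated_wrong}
    for v in verdicts:
        pk = (v.defect.pair[0].key, v.defect.pair[1].key)
        (missing_pairs if v.decision == MISSING else wrong_pairs).add(pk)
    both = missing_pairs & wrong_pairs
    for pk in sorted(both):
        report.append(f"pair {pk} validated both missing and wrong")
    # rule (2): graph of missing pairs + executed additions
    g = nx.DiGraph()
    for sub, sup in missing_pairs:
        g.add_edge(sub, sup)
    for sub, sup in session.ri_plus | session.rm_plus:
        g.add_edge(sub, sup)
    for sub, sup in sorted(wrong_pairs):
        if sub in g and sup in g and nx.has_path(g, sub, sup):
            report.append(
                f"wrong pair {(sub, sup)} derivable from validated-missing "
                f"pairs and executed additions alone")
    return report


def record_verdicts(session, verdicts: list[Verdict]) -> None:
    """Apply an accepted verdict batch to the session, atomically.

    Missing pairs enter MI/MM and gain provisional axioms; wrong pairs
    enter WI/WM.  On contradiction the whole batch is rejected with a
    report and the session is left unchanged.
    """
    for v in verdicts:
        d = session.defects.get(v.defect.key)
        if d is None or d.status != UNVALIDATED:
            raise ValueError(f"not an open candidate: {v.defect!r}")
    report = check_contradictions(session, verdicts)
    if report:
        raise ContradictionError(report)
    for v in verdicts:
        d = session.defects[v.defect.key]
        scope = d.scope if isinstance(d.scope, str) else tuple(d.scope)
        pk = (d.pair[0].key, d.pair[1].key)
        d.status = v.decision
        if v.decision == MISSING:
            session.missing_register(scope).add(d.pair)
            session.validated_missing.add((scope, pk))
            session.add_provisional(d)
        else:
            session.wrong_register(scope).add(d.pair)
            session.validated_wrong.add((scope, pk))
        session.log("verdict", defect=d.key, decision=v.decision,
                    provenance=v.provenance)
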