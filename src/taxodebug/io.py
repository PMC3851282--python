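"""Readers and writers: ontologies (OBO 1.2 subset or TSV), alignments,
network configs, verdicts, oracle tables, and session state JSON.

TSV dialects are tab-separated, UTF-8, with ``#`` comments.  Ontology TSV
lines: ``C<TAB>id<TAB>label``, ``I<TAB>sub<TAB>super``, ``P<TAB>part<TAB>
whole``.  Alignment TSV columns: ``concept_1<TAB>concept_2<TAB>rel`` with
rel in ``= < >`` plus an optional confidence column (kept as metadata,
never used as a threshold).  Exports are canonically ordered (concepts
then axioms, lexicographic) so load -> export -> load is a fixpoint.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import yaml

from .model import (
    Alignment, Axiom, CandidateDefect, ConceptRef, MISSING,
    Ontology, OntologyNetwork, REMOVED, SessionState, WRONG,
    equivalence, make_intra, make_mapping,
)

logger = logging.getLogger(__name__)

STATE_SCHEMA_VERSION = 1


class ParseError(ValueError):
    pass


# --- ontologies -----------------------------------------------------------

def load_ontology(path, format: str = None, ontology_id: str = None) -> Ontology:
    """Load a taxonomy from OBO 1.2 subset or the TSV dialect.

    OBO: ``[Term]`` stanzas give concepts (id, name), ``is_a`` tags the
    is-a axioms and ``relationship: part_of`` the part-of pairs; obsolete
    terms are skipped.  A dangling axiom endpoint rejects the file.
    """
    path = Path(path)
    if format is None:
        format = "obo" if path.suffix.lower() == ".obo" else "tsv"
    oid = ontology_id or path.stem
    if format == "obo":
        ont = _load_obo(path, oid)
    elif format == "tsv":
        ont = _load_tsv_ontology(path, oid)
    else:
        raise ParseError(f"unknown ontology format {format!r}")
    logger.info("loaded ontology %s: %d concepts, %d is-a, %d part-of",
                oid, len(ont.concepts), len(ont.isa), len(ont.partof))
    return ont


def _load_obo(path: Path, oid: str) -> Ontology:
    import obonet

    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    ont = Ontology(oid)
    for node, data in sorted(graph.nodes(data=True)):
        if not data:
            raise ParseError(f"{path}: axiom endpoint {node!r} has no "
                             f"[Term] stanza")
        ont.add_concept(ConceptRef(oid, node, data.get("name")))
    for sub, sup, rel in sorted(graph.edges(keys=True)):
        if rel == "is_a":
            ont.add_axiom(make_intra(ont.concept(sub), ont.concept(sup)))
        elif rel == "part_of":
            ont.partof.add((sub, sup))
        # other relationship types are outside the taxonomic subset
    return ont


def _load_tsv_ontology(path: Path, oid: str) -> Ontology:
    ont = Ontology(oid)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            rows.append((ln, stripped.split("\t")))
    for ln, parts in rows:
        if parts[0] == "C":
            if len(parts) < 2:
                raise ParseError(f"{path}:{ln}: concept line needs an id")
            label = parts[2] if len(parts) > 2 else None
            ont.add_concept(ConceptRef(oid, parts[1], label))
    for ln, parts in rows:
        kind = parts[0]
        if kind == "C":
            continue
        if kind not in ("I", "P") or len(parts) != 3:
            raise ParseError(f"{path}:{ln}: expected I/P line with 2 ids")
        for cid in parts[1:]:
            if cid not in ont.concepts:
                raise ParseError(f"{path}:{ln}: undeclared concept {cid!r}")
        if kind == "I":
            ont.add_axiom(make_intra(ont.concept(parts[1]),
                                     ont.concept(parts[2])))
        else:
            ont.partof.add((parts[1], parts[2]))
    return ont


def save_ontology(ont: Ontology, path) -> None:
    lines = [f"# ontology {ont.id}"]
    for cid in sorted(ont.concepts):
        c = ont.concepts[cid]
        lines.append(f"C\t{cid}\t{c.label}" if c.label is not None
                     else f"C\t{cid}")
    for ax in ont.axioms():
        lines.append(f"I\t{ax.sub.concept_id}\t{ax.super.concept_id}")
    for part, whole in sorted(ont.partof):
        lines.append(f"P\t{part}\t{whole}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --- alignments -----------------------------------------------------------

def load_alignment(path, ont_i: Ontology, ont_j: Ontology) -> Alignment:
    """TSV mapping rows ``concept_1<TAB>concept_2<TAB>rel[<TAB>conf]``:
    '=' expands to two directed components with a shared pair tag, '<' is
    concept_1 -> concept_2, '>' the reverse.  Any other relation symbol
    (e.g. related-terms) is rejected: it cannot drive logical derivation.
    """
    al = Alignment((ont_i.id, ont_j.id))
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) not in (3, 4):
                raise ParseError(f"{path}:{ln}: expected 3 or 4 columns")
            c1, c2, rel = parts[0], parts[1], parts[2]
            conf = float(parts[3]) if len(parts) == 4 else None
            if c1 not in ont_i.concepts:
                raise ParseError(f"{path}:{ln}: {c1!r} not in {ont_i.id}")
            if c2 not in ont_j.concepts:
                raise ParseError(f"{path}:{ln}: {c2!r} not in {ont_j.id}")
            a, b = ont_i.concept(c1), ont_j.concept(c2)
            if rel == "=":
                for ax in equivalence(a, b, confidence=conf):
                    al.add_mapping(ax)
            elif rel == "<":
                al.add_mapping(make_mapping(a, b, confidence=conf))
            elif rel == ">":
                al.add_mapping(make_mapping(b, a, confidence=conf))
            else:
                raise ParseError(f"{path}:{ln}: unsupported relation {rel!r}")
    logger.info("loaded alignment %s: %d mapping axioms",
                al.ontology_pair, len(al.mappings))
    return al


def save_alignment(al: Alignment, path) -> None:
    i, j = al.ontology_pair
    lines = [f"# alignment {i} {j}"]
    done_tags = set()
    for ax in al.axioms():
        if ax.pair_tag is not None:
            partner_key = (ax.super.key, ax.sub.key)
            partner = al.mappings.get(partner_key)
            if (partner is not None and partner.pair_tag == ax.pair_tag
                    and partner.status != REMOVED):
                if ax.pair_tag in done_tags:
                    continue
                done_tags.add(ax.pair_tag)
                a, b = ax.pair if ax.sub.ontology_id == i else (ax.super, ax.sub)
                lines.append(_mapping_row(a, b, "=", ax.confidence))
                continue
        if ax.sub.ontology_id == i:
            lines.append(_mapping_row(ax.sub, ax.super, "<", ax.confidence))
        else:
            lines.append(_mapping_row(ax.super, ax.sub, ">", ax.confidence))
    header, rows = lines[0], sorted(lines[1:])
    Path(path).write_text("\n".join([header] + rows) + "\n", encoding="utf-8")


def _mapping_row(a: ConceptRef, b: ConceptRef, rel: str,
                 conf: Optional[float]) -> str:
    row = f"{a.concept_id}\t{b.concept_id}\t{rel}"
    return row + (f"\t{conf}" if conf is not None else "")


# --- network config -------------------------------------------------------

def load_network(config_path) -> OntologyNetwork:
    """YAML network config: ontology entries (id, path, format) and
    alignment entries (ontologies: [i, j], path); paths relative to the
    config file."""
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text(encoding="utf-8")) or {}
    base = config_path.parent
    network = OntologyNetwork()
    for entry in cfg.get("ontologies", []):
        path = base / entry["path"]
        if not path.exists():
            raise ParseError(f"ontology file not found: {path}")
        network.add_ontology(load_ontology(path, format=entry.get("format"),
                                           ontology_id=entry.get("id")))
    for entry in cfg.get("alignments", []):
        i, j = entry["ontologies"]
        path = base / entry["path"]
        if not path.exists():
            raise ParseError(f"alignment file not found: {path}")
        network.add_alignment(load_alignment(
            path, network.ontologies[i], network.ontologies[j]))
    return network


# --- verdict files --------------------------------------------------------

def load_verdict_rows(path) -> list[tuple[object, str, str, str]]:
    """Verdict TSV rows: ``scope<TAB>sub_id<TAB>super_id<TAB>decision``
    with decision in {missing, wrong}; scope is an ontology id or
    ``i,j``."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 4 or parts[3] not in (MISSING, WRONG):
                raise ParseError(f"{path}:{ln}: expected scope, sub, super, "
                                 f"missing|wrong")
            scope = tuple(parts[0].split(",")) if "," in parts[0] else parts[0]
            out.append((scope, parts[1], parts[2], parts[3]))
    return out


# --- session state --------------------------------------------------------

def _axiom_to_json(ax: Axiom) -> dict:
    return {"sub": list(ax.sub.key), "super": list(ax.super.key),
            "layer": ax.layer, "status": ax.status, "origin": ax.origin,
            "pair_tag": ax.pair_tag, "confidence": ax.confidence}


def _concept_from_json(network: OntologyNetwork, key) -> ConceptRef:
    return network.ontologies[key[0]].concept(key[1])


def save_state(session: SessionState, path) -> None:
    net = session.network
    data = {
        "schema_version": STATE_SCHEMA_VERSION,
        "ontologies": [
            {
                "id": oid,
                "concepts": [[c.concept_id, c.label]
                             for _, c in sorted(net.ontologies[oid].concepts.items())],
                "isa": [_axiom_to_json(ax)
                        for ax in net.ontologies[oid].axioms(include_removed=True)],
                "partof": sorted(map(list, net.ontologies[oid].partof)),
            }
            for oid in net.ontology_ids()
        ],
        "alignments": [
            {"pair": list(pair),
             "mappings": [_axiom_to_json(ax)
                          for ax in net.alignments[pair].axioms(include_removed=True)]}
            for pair in sorted(net.alignments)
        ],
        "registers": {
            "ri_plus": sorted(map(_key_json, session.ri_plus)),
            "ri_minus": sorted(map(_key_json, session.ri_minus)),
            "rm_plus": sorted(map(_key_json, session.rm_plus)),
            "rm_minus": sorted(map(_key_json, session.rm_minus)),
        },
        "validated_missing": sorted(
            ([_scope_json(s), _key_json(pk)]
             for s, pk in session.validated_missing), key=repr),
        "validated_wrong": sorted(
            ([_scope_json(s), _key_json(pk)]
             for s, pk in session.validated_wrong), key=repr),
        "defects": [
            {"kind": d.kind,
             "scope": _scope_json(d.scope if isinstance(d.scope, str)
                                  else tuple(d.scope)),
             "pair": _key_json((d.pair[0].key, d.pair[1].key)),
             "status": d.status}
            for _, d in sorted(session.defects.items())
        ],
        "provisionals": [
            {"defect": list(map(_nested_json, k)), "axiom": _axiom_to_json(ax)}
            for k, ax in sorted(session.provisionals.items())
        ],
        "decision_log": session.decision_log,
    }
    Path(path).write_text(json.dumps(data, indent=1, default=_jsonable),
                          encoding="utf-8")


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {obj!r}")


def _scope_json(scope):
    return scope if isinstance(scope, str) else list(scope)


def _key_json(pk):
    return [list(pk[0]), list(pk[1])]


def _nested_json(x):
    return list(x) if isinstance(x, tuple) else x


def load_state(path) -> SessionState:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"corrupt session file {path}: {exc}") from exc
    if data.get("schema_version") != STATE_SCHEMA_VERSION:
        raise ParseError(
            f"session schema version mismatch: expected "
            f"{STATE_SCHEMA_VERSION}, found {data.get('schema_version')}")
    network = OntologyNetwork()
    for entry in data["ontologies"]:
        ont = Ontology(entry["id"])
        for cid, label in entry["concepts"]:
            ont.add_concept(ConceptRef(entry["id"], cid, label))
        for axd in entry["isa"]:
            ax = make_intra(ont.concept(axd["sub"][1]), ont.concept(axd["super"][1]),
                            status=axd["status"], origin=axd["origin"],
                            pair_tag=axd["pair_tag"], confidence=axd["confidence"])
            ont.add_axiom(ax)
        ont.partof = {tuple(p) for p in entry["partof"]}
        network.add_ontology(ont)
    for entry in data["alignments"]:
        al = Alignment(tuple(entry["pair"]))
        for axd in entry["mappings"]:
            ax = make_mapping(_concept_from_json(network, axd["sub"]),
                              _concept_from_json(network, axd["super"]),
                              status=axd["status"], origin=axd["origin"],
                              pair_tag=axd["pair_tag"],
                              confidence=axd["confidence"])
            al.add_mapping(ax)
        network.add_alignment(al)
    session = SessionState(network)
    regs = data["registers"]
    session.ri_plus = {_key_from_json(k) for k in regs["ri_plus"]}
    session.ri_minus = {_key_from_json(k) for k in regs["ri_minus"]}
    session.rm_plus = {_key_from_json(k) for k in regs["rm_plus"]}
    session.rm_minus = {_key_from_json(k) for k in regs["rm_minus"]}
    session.validated_missing = {(_scope_from_json(s), _key_from_json(pk))
                                 for s, pk in data["validated_missing"]}
    session.validated_wrong = {(_scope_from_json(s), _key_from_json(pk))
                               for s, pk in data["validated_wrong"]}
    for entry in data["defects"]:
        pk = _key_from_json(entry["pair"])
        scope = _scope_from_json(entry["scope"])
        pair = (_concept_from_json(network, pk[0]),
                _concept_from_json(network, pk[1]))
        d = CandidateDefect(kind=entry["kind"], pair=pair, scope=scope,
                            status=entry["status"])
        session.defects[d.key] = d
        if d.status == MISSING:
            session.missing_register(scope).add(pair)
        elif d.status == WRONG:
            session.wrong_register(scope).add(pair)
    for entry in data["provisionals"]:
        key = tuple(tuple(x) if isinstance(x, list) else x
                    for x in entry["defect"])
        axd = entry["axiom"]
        sub = _concept_from_json(network, axd["sub"])
        sup = _concept_from_json(network, axd["super"])
        session.provisionals[key] = Axiom(
            sub, sup, layer=axd["layer"], status=axd["status"],
            origin=axd["origin"], pair_tag=axd["pair_tag"],
            confidence=axd["confidence"])
    session.decision_log = data["decision_log"]
    session.check_invariants()
    return session


def _key_from_json(k) -> tuple:
    return (tuple(k[0]), tuple(k[1]))


def _scope_from_json(s):
    return s if isinstance(s, str) else tuple(s)


# --- export ----------------------------------------------------------------

def export_repaired(session: SessionState, out_dir) -> dict:
    """Write one repaired ontology file per ontology (asserted minus
    removed plus additions and promoted provisionals), one alignment file
    per pair, and a change report listing additions and removals."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net = session.network
    report = {"added_isa": sorted(map(_key_json, session.ri_plus)),
              "removed_isa": sorted(map(_key_json, session.ri_minus)),
              "added_mappings": sorted(map(_key_json, session.rm_plus)),
              "removed_mappings": sorted(map(_key_json, session.rm_minus)),
              "unrepaired_missing": len(session.provisionals)}
    for oid in net.ontology_ids():
        save_ontology(net.ontologies[oid], out_dir / f"{oid}.tsv")
    for pair in sorted(net.alignments):
        save_alignment(net.alignments[pair],
                       out_dir / f"{pair[0]}-{pair[1]}.alignment.tsv")
    (out_dir / "changes.json").write_text(json.dumps(report, indent=1),
                                          encoding="utf-8")
    return report
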