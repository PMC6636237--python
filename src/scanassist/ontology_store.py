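"""Triple store for the early-pregnancy ultrasound knowledge base.

The knowledge base describes early-pregnancy semiology as an RDF graph:
ultrasound *signs* suggest *disorders*, disorders have signs, and each sign
requires one or more *echographic views* in which it can be demonstrated.
Entities carry SKOS preferred labels so that every reasoning step stays
reviewable by clinicians.

The store speaks a deliberately small Turtle dialect — prefix declarations,
plain subject/predicate/object statements, and string literals. Blank nodes,
collections, and datatype tags are not part of the schema and are rejected.
Parsing is delegated to :mod:`rdflib`; serialization is done in-package so
that output is byte-deterministic (prefixes and triples sorted) and
``load_turtle(save_turtle(kb))`` is the identity on the triple set.

The only inference rule applied is the inverse closure between
``epo:has_sign`` (disorder → sign, the authoritative direction) and
``epo:suggests`` (sign → disorder): asserting either materializes the other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, NamedTuple, Optional, Union

import rdflib
from rdflib.plugins.parsers.notation3 import BadSyntax

__all__ = [
    "EPO",
    "SKOS",
    "DEFAULT_PREFIXES",
    "SUGGESTS",
    "HAS_SIGN",
    "REQUIRES_VIEW",
    "LOCATED_IN",
    "PREF_LABEL",
    "KIND",
    "DEFINITION",
    "REFERENCE_IMAGE",
    "EntityKind",
    "Entity",
    "Literal",
    "Triple",
    "Issue",
    "KnowledgeBase",
    "OntologyError",
    "TurtleParseError",
    "UnknownEntityError",
    "load_turtle",
    "save_turtle",
    "entities_to_json",
]

# --------------------------------------------------------------------------
# Vocabulary
# --------------------------------------------------------------------------

EPO = "http://example.org/epo#"  # demonstration namespace; content is illustrative
SKOS = "http://www.w3.org/2004/02/skos/core#"

DEFAULT_PREFIXES: dict[str, str] = {"epo": EPO, "skos": SKOS}

SUGGESTS = "epo:suggests"
HAS_SIGN = "epo:has_sign"
REQUIRES_VIEW = "epo:requires_view"
LOCATED_IN = "epo:located_in"
PREF_LABEL = "skos:prefLabel"
KIND = "epo:kind"
DEFINITION = "epo:definition"
REFERENCE_IMAGE = "epo:reference_image"

#: predicates whose object must be an IRI
IRI_OBJECT_PREDICATES = frozenset({SUGGESTS, HAS_SIGN, REQUIRES_VIEW, LOCATED_IN})
#: predicates whose object must be a string literal
LITERAL_OBJECT_PREDICATES = frozenset({PREF_LABEL, KIND, DEFINITION, REFERENCE_IMAGE})
VOCABULARY = IRI_OBJECT_PREDICATES | LITERAL_OBJECT_PREDICATES

#: expected (subject kind, object kind) for the relational predicates;
#: None means any declared entity kind is acceptable.
_RELATION_SIGNATURES = {
    SUGGESTS: ("sign", "disorder"),
    HAS_SIGN: ("disorder", "sign"),
    REQUIRES_VIEW: ("sign", "echographic_view"),
    LOCATED_IN: (None, "anatomical_structure"),
}


class EntityKind(str, Enum):
    SIGN = "sign"
    DISORDER = "disorder"
    ECHOGRAPHIC_VIEW = "echographic_view"
    ANATOMICAL_STRUCTURE = "anatomical_structure"
    ULTRASOUND_ROUTE = "ultrasound_route"
    ULTRASOUND_MODE = "ultrasound_mode"


class Literal(str):
    """A string literal object, as opposed to an IRI reference."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Literal({str.__repr__(self)})"


class Triple(NamedTuple):
    subject: str
    predicate: str
    object: Union[str, Literal]


@dataclass(frozen=True)
class Entity:
    """A declared knowledge-base entity with its review metadata."""

    iri: str
    kind: EntityKind
    pref_label: str
    definition: Optional[str] = None
    reference_images: tuple[str, ...] = ()


@dataclass(frozen=True)
class Issue:
    """One integrity problem found by :meth:`KnowledgeBase.validate`."""

    code: str
    iri: str
    message: str


class OntologyError(ValueError):
    """Domain-level knowledge-base error."""


class TurtleParseError(OntologyError):
    """Raised when a Turtle document cannot be parsed; carries a line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class UnknownEntityError(OntologyError):
    """An IRI was used that is not declared (with the expected kind) in the KB."""

    def __init__(self, iri: str, expected_kind: Optional[str] = None):
        detail = f" (expected kind: {expected_kind})" if expected_kind else ""
        super().__init__(f"unknown entity: {iri}{detail}")
        self.iri = iri


def _check_curie(value: str) -> None:
    prefix, _, local = value.partition(":")
    if not prefix or not local:
        raise OntologyError(f"not a prefix:localname identifier: {value!r}")


# --------------------------------------------------------------------------
# The store
# --------------------------------------------------------------------------


class KnowledgeBase:
    """A small in-memory triple store with inverse-closure inference.

    Triples use compact ``prefix:localname`` identifiers throughout; the
    prefix map resolves them to full namespaces at (de)serialization time.
    """

    def __init__(self, prefixes: Optional[dict[str, str]] = None):
        self.prefixes: dict[str, str] = dict(DEFAULT_PREFIXES)
        if prefixes:
            self.prefixes.update(prefixes)
        self._triples: set[Triple] = set()
        self._by_subject: dict[str, set[Triple]] = {}
        self._by_predicate: dict[str, set[Triple]] = {}

    # -- construction ------------------------------------------------------

    def add(self, subject: str, predicate: str, obj: Union[str, Literal]) -> None:
        """Add one triple (idempotent) and materialize its inverse if any."""
        _check_curie(subject)
        _check_curie(predicate)
        if predicate in VOCABULARY:
            if predicate in IRI_OBJECT_PREDICATES and isinstance(obj, Literal):
                raise OntologyError(
                    f"literal object not allowed for {predicate}: {obj!r}"
                )
            if predicate in LITERAL_OBJECT_PREDICATES and not isinstance(obj, Literal):
                obj = Literal(obj)
        if not isinstance(obj, Literal):
            _check_curie(obj)
        self._insert(Triple(subject, predicate, obj))
        if predicate == HAS_SIGN:
            self._insert(Triple(obj, SUGGESTS, subject))
        elif predicate == SUGGESTS:
            self._insert(Triple(obj, HAS_SIGN, subject))

    def _insert(self, triple: Triple) -> None:
        if triple in self._triples:
            return
        self._triples.add(triple)
        self._by_subject.setdefault(triple.subject, set()).add(triple)
        self._by_predicate.setdefault(triple.predicate, set()).add(triple)

    def declare(
        self,
        iri: str,
        kind: EntityKind,
        label: str,
        definition: Optional[str] = None,
        reference_images: Iterable[str] = (),
    ) -> None:
        """Declare an entity: its kind, preferred label, and metadata."""
        self.add(iri, KIND, Literal(EntityKind(kind).value))
        self.add(iri, PREF_LABEL, Literal(label))
        if definition is not None:
            self.add(iri, DEFINITION, Literal(definition))
        for ref in reference_images:
            self.add(iri, REFERENCE_IMAGE, Literal(ref))

    # -- queries -----------------------------------------------------------

    def match(
        self,
        subject: Optional[str] = None,
        predicate: Optional[str] = None,
        obj: Optional[Union[str, Literal]] = None,
    ) -> list[Triple]:
        """Return all triples matching the bound positions, sorted.

        ``None`` is a wildcard. Uses the subject/predicate indexes where a
        position is bound; results are always sorted by (s, p, o) text.
        """
        if subject is not None:
            pool: Iterable[Triple] = self._by_subject.get(subject, ())
        elif predicate is not None:
            pool = self._by_predicate.get(predicate, ())
        else:
            pool = self._triples
        out = [
            t
            for t in pool
            if (predicate is None or t.predicate == predicate)
            and (obj is None or t.object == obj)
        ]
        out.sort()
        return out

    def objects(self, subject: str, predicate: str) -> list[Union[str, Literal]]:
        return [t.object for t in self.match(subject, predicate)]

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(sorted(self._triples))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return self.prefixes == other.prefixes and self._triples == other._triples

    def triples(self) -> frozenset[Triple]:
        return frozenset(self._triples)

    # -- entity access -----------------------------------------------------

    def entity(self, iri: str) -> Entity:
        kinds = self.objects(iri, KIND)
        labels = self.objects(iri, PREF_LABEL)
        if not kinds or not labels:
            raise UnknownEntityError(iri)
        definitions = self.objects(iri, DEFINITION)
        images = tuple(str(o) for o in self.objects(iri, REFERENCE_IMAGE))
        return Entity(
            iri=iri,
            kind=EntityKind(str(kinds[0])),
            pref_label=str(labels[0]),
            definition=str(definitions[0]) if definitions else None,
            reference_images=images,
        )

    def entities(self, kind: Optional[EntityKind] = None) -> list[Entity]:
        out = []
        for t in self.match(predicate=KIND):
            ent = self.entity(t.subject)
            if kind is None or ent.kind == kind:
                out.append(ent)
        out.sort(key=lambda e: e.iri)
        return out

    def has_kind(self, iri: str, kind: EntityKind) -> bool:
        return Literal(kind.value) in self.objects(iri, KIND)

    def require(self, iri: str, kind: EntityKind) -> None:
        """Raise :class:`UnknownEntityError` unless ``iri`` is declared with ``kind``."""
        if not self.has_kind(iri, kind):
            raise UnknownEntityError(iri, expected_kind=kind.value)

    def label(self, iri: str) -> str:
        labels = self.objects(iri, PREF_LABEL)
        return str(labels[0]) if labels else iri

    # -- integrity ---------------------------------------------------------

    def validate(self) -> list[Issue]:
        """Check all store invariants; issues are data, not exceptions."""
        issues: list[Issue] = []
        declared = {t.subject for t in self.match(predicate=KIND)}

        def declared_with_label(iri: str) -> bool:
            return iri in declared and bool(self.objects(iri, PREF_LABEL))

        seen_undeclared: set[str] = set()
        for predicate, (subj_kind, obj_kind) in _RELATION_SIGNATURES.items():
            for t in self.match(predicate=predicate):
                for pos_iri, expected in ((t.subject, subj_kind), (t.object, obj_kind)):
                    if not declared_with_label(pos_iri):
                        if pos_iri not in seen_undeclared:
                            seen_undeclared.add(pos_iri)
                            issues.append(
                                Issue(
                                    "undeclared_entity",
                                    pos_iri,
                                    f"{pos_iri} used with {predicate} but not "
                                    "declared with a kind and label",
                                )
                            )
                    elif expected is not None and not self.has_kind(
                        pos_iri, EntityKind(expected)
                    ):
                        issues.append(
                            Issue(
                                "kind_mismatch",
                                pos_iri,
                                f"{pos_iri} used with {predicate} but is not "
                                f"declared as {expected}",
                            )
                        )

        for t in self.match(predicate=SUGGESTS):
            if Triple(t.object, HAS_SIGN, t.subject) not in self._triples:
                issues.append(
                    Issue(
                        "inverse_closure_violation",
                        t.subject,
                        f"suggests({t.subject}, {t.object}) lacks "
                        f"has_sign({t.object}, {t.subject})",
                    )
                )
        for t in self.match(predicate=HAS_SIGN):
            if Triple(t.object, SUGGESTS, t.subject) not in self._triples:
                issues.append(
                    Issue(
                        "inverse_closure_violation",
                        t.subject,
                        f"has_sign({t.subject}, {t.object}) lacks "
                        f"suggests({t.object}, {t.subject})",
                    )
                )

        for ent in self.entities(EntityKind.SIGN):
            if not self.objects(ent.iri, REQUIRES_VIEW):
                issues.append(
                    Issue(
                        "sign_without_view",
                        ent.iri,
                        f"sign {ent.iri} has no epo:requires_view",
                    )
                )
        for ent in self.entities(EntityKind.DISORDER):
            if not self.objects(ent.iri, HAS_SIGN):
                issues.append(
                    Issue(
                        "disorder_without_sign",
                        ent.iri,
                        f"disorder {ent.iri} has no epo:has_sign",
                    )
                )
        issues.sort(key=lambda i: (i.code, i.iri, i.message))
        return issues


# --------------------------------------------------------------------------
# Turtle (de)serialization
# --------------------------------------------------------------------------


def _compact(kb_prefixes: dict[str, str], uri: str) -> str:
    best: Optional[tuple[str, str]] = None
    for prefix, ns in kb_prefixes.items():
        if uri.startswith(ns) and (best is None or len(ns) > len(kb_prefixes[best[0]])):
            best = (prefix, uri[len(ns):])
    if best is None or not best[1]:
        raise OntologyError(f"IRI {uri} is not under any declared prefix")
    return f"{best[0]}:{best[1]}"


def load_turtle(text: str) -> KnowledgeBase:
    """Parse a Turtle document into a :class:`KnowledgeBase`.

    Applies the inverse closure and collapses duplicate statements. Raises
    :class:`TurtleParseError` (with a line number when available) on bad
    syntax, and :class:`OntologyError` when a literal appears where a domain
    predicate requires an IRI, or when an IRI falls outside every declared
    prefix.
    """
    graph = rdflib.Graph(bind_namespaces="none")
    try:
        graph.parse(data=text, format="turtle")
    except BadSyntax as exc:  # rdflib's N3/Turtle error carries the line
        raise TurtleParseError(str(exc.message or exc), line=exc.lines + 1) from exc
    except Exception as exc:  # pragma: no cover - other rdflib failures
        raise TurtleParseError(str(exc)) from exc

    prefixes = dict(DEFAULT_PREFIXES)
    for prefix, ns in graph.namespaces():
        if prefix:
            prefixes[str(prefix)] = str(ns)

    kb = KnowledgeBase(prefixes)
    for s, p, o in graph:
        if isinstance(s, rdflib.BNode) or isinstance(o, rdflib.BNode):
            raise OntologyError("blank nodes are not part of the KB dialect")
        subject = _compact(kb.prefixes, str(s))
        predicate = _compact(kb.prefixes, str(p))
        if isinstance(o, rdflib.Literal):
            obj: Union[str, Literal] = Literal(str(o))
        else:
            obj = _compact(kb.prefixes, str(o))
        kb.add(subject, predicate, obj)
    return kb


def _escape(text: str) -> str:
    return (
        text.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
    )


def save_turtle(kb: KnowledgeBase) -> str:
    """Serialize deterministically: sorted prefixes, then sorted triples."""
    lines = [
        f"@prefix {prefix}: <{ns}> ."
        for prefix, ns in sorted(kb.prefixes.items())
    ]
    lines.append("")
    for t in sorted(kb.triples()):
        if isinstance(t.object, Literal):
            obj = f'"{_escape(t.object)}"'
        else:
            obj = t.object
        lines.append(f"{t.subject} {t.predicate} {obj} .")
    return "\n".join(lines) + "\n"


def entities_to_json(kb: KnowledgeBase) -> str:
    """JSON export of declared entities (iri, kind, label, definition)."""
    payload = [
        {
            "iri": e.iri,
            "kind": e.kind.value,
            "label": e.pref_label,
            "definition": e.definition,
        }
        for e in kb.entities()
    ]
    return json.dumps(payload, indent=2, sort_keys=True)
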