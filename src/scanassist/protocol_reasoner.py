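"""Personalized imaging-protocol reasoning over the knowledge base.

Given the ultrasound signs identified so far, the reasoner walks the
knowledge graph in four steps:

1. list every disorder suggested by the identified signs;
2. list every sign associated with those disorders;
3. subtract the signs already identified (and any explicitly assessed as
   absent) to obtain the *pending* signs;
4. group the pending signs by the echographic views they require, yielding
   an ordered protocol of views still worth acquiring, each with the signs
   to look for there.

Alongside the protocol the reasoner ranks the differential: each suggested
disorder scored by how many of its signs have been identified (support) and
by the identified fraction of its sign inventory (completeness). Protocol
items are ordered most-informative-first (views covering the most pending
signs), with deterministic tie-breaks on view label then IRI; the
differential is ordered by descending support, then descending completeness,
then label. Both orderings are artifact conventions, chosen for
reproducibility — the knowledge graph itself does not rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable

from .ontology_store import (
    HAS_SIGN,
    REQUIRES_VIEW,
    SUGGESTS,
    EntityKind,
    KnowledgeBase,
)

__all__ = [
    "ProtocolItem",
    "Differential",
    "disorders_for",
    "signs_of",
    "pending_signs",
    "views_for",
    "personalized_protocol",
    "differential",
]


@dataclass(frozen=True)
class ProtocolItem:
    """One step of the personalized imaging protocol.

    Attributes
    ----------
    view:
        The echographic view to acquire.
    sought_signs:
        The pending signs demonstrable in that view (nonempty).
    rank:
        1-based position in the protocol, contiguous.
    """

    view: str
    sought_signs: frozenset[str]
    rank: int


@dataclass(frozen=True)
class Differential:
    """One disorder of the differential with its evidential support."""

    disorder: str
    support: int
    total_signs: int

    @property
    def completeness(self) -> float:
        return self.support / self.total_signs


def _check_all(kb: KnowledgeBase, iris: Iterable[str], kind: EntityKind) -> None:
    for iri in iris:
        kb.require(iri, kind)


def disorders_for(kb: KnowledgeBase, identified_signs: AbstractSet[str]) -> list[str]:
    """Disorders suggested by any of the identified signs (sorted)."""
    _check_all(kb, identified_signs, EntityKind.SIGN)
    out: set[str] = set()
    for sign in identified_signs:
        out.update(kb.objects(sign, SUGGESTS))
    return sorted(out)


def signs_of(kb: KnowledgeBase, disorders: AbstractSet[str]) -> list[str]:
    """Signs associated with any of the disorders (sorted)."""
    _check_all(kb, disorders, EntityKind.DISORDER)
    out: set[str] = set()
    for disorder in disorders:
        out.update(kb.objects(disorder, HAS_SIGN))
    return sorted(out)


def pending_signs(
    kb: KnowledgeBase,
    identified_signs: AbstractSet[str],
    absent_signs: AbstractSet[str] = frozenset(),
) -> list[str]:
    """Signs of the suggested disorders still to be assessed (sorted).

    ``absent_signs`` are signs the operator explicitly searched for and did
    not find; they are retired from the pending set so the protocol loop
    terminates on real negative findings.
    """
    _check_all(kb, absent_signs, EntityKind.SIGN)
    relevant = signs_of(kb, set(disorders_for(kb, identified_signs)))
    return sorted(set(relevant) - set(identified_signs) - set(absent_signs))


def views_for(kb: KnowledgeBase, signs: AbstractSet[str]) -> list[str]:
    """Echographic views required by any of the signs (sorted)."""
    _check_all(kb, signs, EntityKind.SIGN)
    out: set[str] = set()
    for sign in signs:
        out.update(kb.objects(sign, REQUIRES_VIEW))
    return sorted(out)


def personalized_protocol(
    kb: KnowledgeBase,
    identified_signs: AbstractSet[str],
    completed_views: AbstractSet[str] = frozenset(),
    absent_signs: AbstractSet[str] = frozenset(),
) -> list[ProtocolItem]:
    """The ordered list of views still to acquire, with signs to seek.

    One item per view required by a pending sign and not yet completed;
    each item's ``sought_signs`` are the pending signs requiring that view.
    Items are ordered by descending number of sought signs, ties broken by
    ascending view label then IRI; ranks run 1..n.
    """
    _check_all(kb, completed_views, EntityKind.ECHOGRAPHIC_VIEW)
    pending = pending_signs(kb, identified_signs, absent_signs)
    per_view: dict[str, set[str]] = {}
    for sign in pending:
        for view in kb.objects(sign, REQUIRES_VIEW):
            if view not in completed_views:
                per_view.setdefault(view, set()).add(sign)
    ordered = sorted(
        per_view.items(),
        key=lambda item: (-len(item[1]), kb.label(item[0]), item[0]),
    )
    return [
        ProtocolItem(view=view, sought_signs=frozenset(signs), rank=i + 1)
        for i, (view, signs) in enumerate(ordered)
    ]


def differential(
    kb: KnowledgeBase, identified_signs: AbstractSet[str]
) -> list[Differential]:
    """Ranked differential over the disorders suggested by the signs."""
    entries = []
    for disorder in disorders_for(kb, identified_signs):
        all_signs = set(kb.objects(disorder, HAS_SIGN))
        entries.append(
            Differential(
                disorder=disorder,
                support=len(all_signs & set(identified_signs)),
                total_signs=len(all_signs),
            )
        )
    entries.sort(
        key=lambda d: (-d.support, -d.completeness, kb.label(d.disorder), d.disorder)
    )
    return entries
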