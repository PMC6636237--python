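"""Scan-session workflow: guided image analysis and structured reporting.

A :class:`Session` accumulates image annotations made with the controlled
vocabulary of its knowledge base (anatomical structures, signs present or
searched-and-absent, ultrasound route/mode/view). From the annotations it
derives the identified signs, absent signs, and completed views, and on
request delegates to the reasoner for the next protocol guidance. The
session ends with :func:`finalize`, producing an immutable structured
:class:`Report` whose conclusion is a :class:`DiagnosisStatement` — the
location class of the pregnancy, with the precise ectopic site when one is
stated.

A sign recorded present in one image and absent in another resolves to
present: a presence is an observation, an absence only a failed search.
No wall-clock reads happen here; timestamps are caller-supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

from .ontology_store import EntityKind, KnowledgeBase
from .protocol_reasoner import ProtocolItem, personalized_protocol

__all__ = [
    "DEFAULT_CLINICAL_INFO",
    "LocationClass",
    "EctopicSite",
    "DiagnosisStatement",
    "ImageAnnotation",
    "Session",
    "Report",
    "SessionError",
    "new_session",
    "add_image",
    "next_guidance",
    "finalize",
]

#: the standardized indication given for every examination
DEFAULT_CLINICAL_INFO = "moderate pelvic pain and positive pregnancy test"


class SessionError(ValueError):
    """Workflow contract violation (duplicate image, double finalize, ...)."""


class LocationClass(str, Enum):
    INTRAUTERINE = "intrauterine"
    ECTOPIC = "ectopic"
    PREGNANCY_OF_UNKNOWN_LOCATION = "pregnancy_of_unknown_location"


class EctopicSite(str, Enum):
    TUBAL = "tubal"
    INTERSTITIAL = "interstitial"
    CERVICAL = "cervical"
    CESAREAN_SCAR = "cesarean_scar"
    OVARIAN = "ovarian"
    ABDOMINAL = "abdominal"
    HETEROTOPIC = "heterotopic"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class DiagnosisStatement:
    """A structured conclusion: where the pregnancy is located.

    ``ectopic_site`` may only be set when the location class is ectopic; a
    report that merely states "ectopic pregnancy" without localizing it uses
    ``EctopicSite.UNSPECIFIED``.
    """

    location_class: LocationClass
    ectopic_site: Optional[EctopicSite] = None

    def __post_init__(self) -> None:
        if (
            self.ectopic_site is not None
            and self.location_class is not LocationClass.ECTOPIC
        ):
            raise ValueError("ectopic_site requires location_class == ectopic")

    def to_dict(self) -> dict:
        return {
            "location_class": self.location_class.value,
            "ectopic_site": self.ectopic_site.value if self.ectopic_site else None,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DiagnosisStatement":
        site = data.get("ectopic_site")
        return cls(
            location_class=LocationClass(data["location_class"]),
            ectopic_site=EctopicSite(site) if site else None,
        )


@dataclass(frozen=True)
class ImageAnnotation:
    """Keyword description of one acquired image."""

    image_id: str
    view: str
    structures: frozenset[str] = frozenset()
    signs_present: frozenset[str] = frozenset()
    signs_absent: frozenset[str] = frozenset()
    route: Optional[str] = None
    mode: Optional[str] = None

    def __post_init__(self) -> None:
        if set(self.signs_present) & set(self.signs_absent):
            raise ValueError("a sign cannot be both present and absent in one image")

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "view": self.view,
            "structures": sorted(self.structures),
            "signs_present": sorted(self.signs_present),
            "signs_absent": sorted(self.signs_absent),
            "route": self.route,
            "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ImageAnnotation":
        return cls(
            image_id=data["image_id"],
            view=data["view"],
            structures=frozenset(data.get("structures", ())),
            signs_present=frozenset(data.get("signs_present", ())),
            signs_absent=frozenset(data.get("signs_absent", ())),
            route=data.get("route"),
            mode=data.get("mode"),
        )


@dataclass
class Session:
    """One examination in progress, bound to a knowledge base."""

    kb: KnowledgeBase
    case_id: str
    clinical_info: str = DEFAULT_CLINICAL_INFO
    annotations: list[ImageAnnotation] = field(default_factory=list)
    started_at: Optional[str] = None
    finished_at: Optional[str] = None

    @property
    def identified_signs(self) -> frozenset[str]:
        out: set[str] = set()
        for ann in self.annotations:
            out.update(ann.signs_present)
        return frozenset(out)

    @property
    def absent_signs(self) -> frozenset[str]:
        # presence anywhere overrides absence elsewhere
        absent: set[str] = set()
        for ann in self.annotations:
            absent.update(ann.signs_absent)
        return frozenset(absent - self.identified_signs)

    @property
    def completed_views(self) -> frozenset[str]:
        return frozenset(ann.view for ann in self.annotations)

    @property
    def finished(self) -> bool:
        return self.finished_at is not None

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "clinical_info": self.clinical_info,
            "annotations": [a.to_dict() for a in self.annotations],
            "started_at": self.started_at,
            "finished_at": self.finished_at,
        }

    @classmethod
    def from_dict(cls, kb: KnowledgeBase, data: dict) -> "Session":
        return cls(
            kb=kb,
            case_id=data["case_id"],
            clinical_info=data.get("clinical_info", DEFAULT_CLINICAL_INFO),
            annotations=[ImageAnnotation.from_dict(a) for a in data["annotations"]],
            started_at=data.get("started_at"),
            finished_at=data.get("finished_at"),
        )


@dataclass(frozen=True)
class Report:
    """The immutable structured report produced at finalize."""

    case_id: str
    operator_id: str
    mode: str  # "assisted" | "nonassisted"
    conclusion: DiagnosisStatement
    image_ids: tuple[str, ...]
    duration_min: float
    protocol_complete: bool

    @property
    def image_count(self) -> int:
        return len(self.image_ids)

    def to_json(self) -> str:
        return json.dumps(
            {
                "case_id": self.case_id,
                "operator_id": self.operator_id,
                "mode": self.mode,
                "conclusion": self.conclusion.to_dict(),
                "image_ids": list(self.image_ids),
                "image_count": self.image_count,
                "duration_min": self.duration_min,
                "protocol_complete": self.protocol_complete,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Report":
        data = json.loads(text)
        return cls(
            case_id=data["case_id"],
            operator_id=data["operator_id"],
            mode=data["mode"],
            conclusion=DiagnosisStatement.from_dict(data["conclusion"]),
            image_ids=tuple(data["image_ids"]),
            duration_min=data["duration_min"],
            protocol_complete=data["protocol_complete"],
        )


# --------------------------------------------------------------------------
# Workflow operations
# --------------------------------------------------------------------------


def new_session(
    kb: KnowledgeBase,
    case_id: str,
    clinical_info: Optional[str] = None,
    started_at: Optional[str] = None,
) -> Session:
    """Open an empty session; clinical info defaults to the standard phrase."""
    return Session(
        kb=kb,
        case_id=case_id,
        clinical_info=clinical_info if clinical_info is not None else DEFAULT_CLINICAL_INFO,
        started_at=started_at,
    )


def add_image(session: Session, annotation: ImageAnnotation) -> Session:
    """Append a validated annotation; returns the (mutated) session.

    Every IRI in the annotation must be declared in the session's KB with
    the matching kind; image ids must be unique within the session.
    """
    if session.finished:
        raise SessionError("session is finalized")
    if any(a.image_id == annotation.image_id for a in session.annotations):
        raise SessionError(f"duplicate image_id: {annotation.image_id}")
    kb = session.kb
    kb.require(annotation.view, EntityKind.ECHOGRAPHIC_VIEW)
    for sign in sorted(annotation.signs_present | annotation.signs_absent):
        kb.require(sign, EntityKind.SIGN)
    for structure in sorted(annotation.structures):
        kb.require(structure, EntityKind.ANATOMICAL_STRUCTURE)
    if annotation.route is not None:
        kb.require(annotation.route, EntityKind.ULTRASOUND_ROUTE)
    if annotation.mode is not None:
        kb.require(annotation.mode, EntityKind.ULTRASOUND_MODE)
    session.annotations.append(annotation)
    return session


def next_guidance(session: Session) -> list[ProtocolItem]:
    """The current personalized protocol for this session."""
    return personalized_protocol(
        session.kb,
        session.identified_signs,
        completed_views=session.completed_views,
        absent_signs=session.absent_signs,
    )


def finalize(
    session: Session,
    operator_id: str,
    mode: str,
    conclusion: DiagnosisStatement,
    duration_min: float,
    finished_at: Optional[str] = None,
) -> Report:
    """Close the session and emit the structured report."""
    if session.finished:
        raise SessionError("session already finalized")
    if duration_min < 0:
        raise SessionError("duration_min must be nonnegative")
    if mode not in ("assisted", "nonassisted"):
        raise SessionError(f"mode must be 'assisted' or 'nonassisted', got {mode!r}")
    protocol_complete = not next_guidance(session)
    session.finished_at = finished_at if finished_at is not None else "finalized"
    return Report(
        case_id=session.case_id,
        operator_id=operator_id,
        mode=mode,
        conclusion=conclusion,
        image_ids=tuple(a.image_id for a in session.annotations),
        duration_min=float(duration_min),
        protocol_complete=protocol_complete,
    )
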