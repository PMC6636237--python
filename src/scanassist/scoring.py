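"""Image-set quality score, report trust scale, and kappa agreement bands.

The quality of an early-pregnancy image set is scored against a 15-item
checklist — five criteria on the sagittal view of the uterus and five per
ovary view — one point each, maximum 15. The reviewer's trust in a report
is a 5-level ordinal judgment; levels 1–3 call for a supervisor
examination, levels 4–5 do not. Both are expert judgments supplied as data:
this module scores checklists, it does not analyze images.

Kappa agreement bands follow the convention: below 0.6 poor, 0.6–0.8
moderate, above 0.8 good. The wording is inclusive-ambiguous at the
boundaries; here "moderate" is the closed interval [0.6, 0.8].
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum

__all__ = [
    "UterusSagittalChecklist",
    "OvaryChecklist",
    "QualityAssessment",
    "TrustLevel",
    "AgreementCategory",
    "MAX_QUALITY_SCORE",
    "TRUST_DESCRIPTIONS",
    "quality_score",
    "trust_description",
    "supervision_required",
    "agreement_category",
]

MAX_QUALITY_SCORE = 15


@dataclass(frozen=True)
class UterusSagittalChecklist:
    """Five quality criteria on the sagittal view of the uterus (1 point each)."""

    cervix_visible: bool = False
    fundus_visible: bool = False
    endometrial_midline_visible: bool = False
    endocervix_visible: bool = False
    uterus_over_half_image: bool = False

    def points(self) -> int:
        return sum(getattr(self, f.name) for f in fields(self))


@dataclass(frozen=True)
class OvaryChecklist:
    """Five quality criteria on one ovary view (1 point each)."""

    side: str  # "left" | "right"
    side_stated: bool = False
    follicles_visible: bool = False
    iliac_vein_visible: bool = False
    long_axis_under_30_deg: bool = False
    ovary_over_quarter_image: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    def points(self) -> int:
        return sum(
            getattr(self, f.name) for f in fields(self) if f.type == "bool"
        )


@dataclass(frozen=True)
class QualityAssessment:
    """The full 15-item checklist: uterus + both ovaries.

    A view that was never acquired simply leaves its items unticked and
    scores 0 on them; partial image sets are scored, not excluded.
    """

    uterus: UterusSagittalChecklist
    left_ovary: OvaryChecklist
    right_ovary: OvaryChecklist

    def __post_init__(self) -> None:
        if self.left_ovary.side != "left" or self.right_ovary.side != "right":
            raise ValueError("ovary checklists must carry their matching sides")

    @property
    def score(self) -> int:
        return quality_score(self)

    @classmethod
    def all_true(cls) -> "QualityAssessment":
        """The perfect image set: every criterion satisfied."""
        return cls(
            uterus=UterusSagittalChecklist(True, True, True, True, True),
            left_ovary=OvaryChecklist("left", True, True, True, True, True),
            right_ovary=OvaryChecklist("right", True, True, True, True, True),
        )


def quality_score(assessment: QualityAssessment) -> int:
    """Sum of satisfied criteria, one point each; range 0–15."""
    return (
        assessment.uterus.points()
        + assessment.left_ovary.points()
        + assessment.right_ovary.points()
    )


TRUST_DESCRIPTIONS: dict[int, str] = {
    1: (
        "No trust in the final diagnosis (incorrect): the diagnosis is most "
        "likely incorrect, and the image set suggests another diagnosis. "
        "Immediate supervisor examination is needed."
    ),
    2: (
        "No trust in the final diagnosis (low quality): the image set quality "
        "is insufficient and/or does not support the final diagnosis. "
        "Immediate supervisor examination is needed."
    ),
    3: (
        "Moderate trust in the final diagnosis: although the diagnosis might "
        "be correct, the image set quality is insufficient, and a supervisor "
        "examination is needed."
    ),
    4: (
        "The image set quality could be improved; however, it is of "
        "sufficient quality to accurately support the final diagnosis. "
        "No supervisor examination is needed."
    ),
    5: (
        "Total trust in the final diagnosis: the image set effectively "
        "supports the diagnosis, and no supervisor examination is needed."
    ),
}


@dataclass(frozen=True)
class TrustLevel:
    """A reviewer's trust in a report, on the 5-level ordinal scale."""

    level: int

    def __post_init__(self) -> None:
        if self.level not in TRUST_DESCRIPTIONS:
            raise ValueError(f"trust level must be 1..5, got {self.level}")

    @property
    def description(self) -> str:
        return TRUST_DESCRIPTIONS[self.level]

    @property
    def supervision_required(self) -> bool:
        return supervision_required(self.level)


def trust_description(level: int) -> str:
    """Canonical description of a trust level (1–5)."""
    if level not in TRUST_DESCRIPTIONS:
        raise ValueError(f"trust level must be 1..5, got {level}")
    return TRUST_DESCRIPTIONS[level]


def supervision_required(level: int) -> bool:
    """Levels 1–3 call for a supervisor examination; 4–5 do not."""
    if level not in TRUST_DESCRIPTIONS:
        raise ValueError(f"trust level must be 1..5, got {level}")
    return level <= 3


class AgreementCategory(str, Enum):
    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"


def agreement_category(kappa: float) -> AgreementCategory:
    """Band a kappa value: <0.6 poor, [0.6, 0.8] moderate, >0.8 good."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0.6:
        return AgreementCategory.POOR
    if kappa <= 0.8:
        return AgreementCategory.MODERATE
    return AgreementCategory.GOOD
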