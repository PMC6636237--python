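"""Bundled knowledge bases, printed-result transcriptions, and the
in-silico replication of the crossover evaluation study.

Three kinds of fixture live here:

* :func:`fig5_kb` — the minimal four-sign / two-disorder / three-view toy
  ontology on which the reasoning principle is usually illustrated; every
  reasoner operation has a hand-checkable answer on it.
* :func:`demo_kb` — a small demonstration knowledge base of early-pregnancy
  semiology (intrauterine pregnancy, tubal ectopic pregnancy, pregnancy of
  unknown location, ten signs, six views). Its content is illustrative:
  the production ontology behind the deployed system is not published, so
  nothing downstream depends on this KB's clinical fidelity, only on its
  graph structure.
* the study transcriptions and simulator — :func:`table1_fixture` /
  :func:`table2_fixture` transcribe the published outcome tables;
  :func:`table2_records` expands them into 128 concrete scan records whose
  summary reproduces every printed marginal; :func:`case_series` and
  :func:`run_study` stochastically replicate the 2 operators x 32 cases x
  2 modes design with a configurable operator detection model.

Simulation mechanics: a simulated operator always acquires the three
mandatory views (sagittal uterus and both adnexa) and spots each sign
demonstrable there with probability ``p_detect_spontaneous``. In assisted
mode the protocol loop then runs: the top protocol item's view is acquired,
each sought sign demonstrable in it is found with probability
``p_detect_prompted``, and sought signs not found are recorded absent.
Completed views are never re-prompted, so each sign gets at most one
detection opportunity per arm; when the mandatory views already cover every
view and the two probabilities are equal, the arms are identically
distributed (the null configuration). The report conclusion is the
top-ranked differential disorder when it has support and is not tied;
otherwise pregnancy of unknown location.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .ontology_store import EntityKind, KnowledgeBase
from .protocol_reasoner import differential
from .scan_session import (
    DiagnosisStatement,
    EctopicSite,
    ImageAnnotation,
    LocationClass,
    add_image,
    finalize,
    new_session,
    next_guidance,
)
from .study_stats import ScanRecord

__all__ = [
    "SimCase",
    "OperatorModel",
    "StudyDesign",
    "Table2Fixture",
    "STANDARD_VIEWS",
    "DISORDER_CONCLUSIONS",
    "fig5_kb",
    "demo_kb",
    "table1_fixture",
    "table2_fixture",
    "table2_records",
    "case_series",
    "run_study",
    "conclude",
    "data_path",
]


def data_path(name: str):
    """Path to a bundled fixture file (Turtle / CSV) inside the package."""
    return resources.files("scanassist") / "data" / name


# --------------------------------------------------------------------------
# Toy reasoning ontology
# --------------------------------------------------------------------------


def fig5_kb() -> KnowledgeBase:
    """The four-sign toy ontology illustrating the reasoning principle.

    sign_A suggests disorder_1 and disorder_2; together those disorders
    carry signs B, C, D, demonstrable in views j and k. Identifying sign_A
    (in view i) therefore yields the protocol over views j and k.

    How signs B/C/D split between the two disorders is not fixed by the
    reasoning pattern; this fixture assigns B, C to disorder_1 and D to
    disorder_2, one consistent choice.
    """
    kb = KnowledgeBase()
    for letter in "ABCD":
        kb.declare(f"epo:sign_{letter}", EntityKind.SIGN, f"Sign {letter}")
    for n in (1, 2):
        kb.declare(f"epo:disorder_{n}", EntityKind.DISORDER, f"Disorder {n}")
    for v in "ijk":
        kb.declare(
            f"epo:echographic_view_{v}",
            EntityKind.ECHOGRAPHIC_VIEW,
            f"Echographic view {v}",
        )
    for disorder, signs in (("epo:disorder_1", "ABC"), ("epo:disorder_2", "AD")):
        for letter in signs:
            kb.add(disorder, "epo:has_sign", f"epo:sign_{letter}")
    for letter, view in (("A", "i"), ("B", "j"), ("C", "j"), ("D", "k")):
        kb.add(f"epo:sign_{letter}", "epo:requires_view", f"epo:echographic_view_{view}")
    return kb


# --------------------------------------------------------------------------
# Demonstration early-pregnancy knowledge base
# --------------------------------------------------------------------------

#: the three mandatory views of the standard emergency protocol
STANDARD_VIEWS = frozenset(
    {"epo:uterus_sagittal_view", "epo:right_adnexal_view", "epo:left_adnexal_view"}
)

IUP = "epo:intrauterine_pregnancy"
TUBAL_EP = "epo:tubal_ectopic_pregnancy"
PUL = "epo:pregnancy_of_unknown_location"

#: how a concluded disorder maps to a structured diagnosis statement
DISORDER_CONCLUSIONS: dict[str, DiagnosisStatement] = {
    IUP: DiagnosisStatement(LocationClass.INTRAUTERINE),
    TUBAL_EP: DiagnosisStatement(LocationClass.ECTOPIC, EctopicSite.TUBAL),
    PUL: DiagnosisStatement(LocationClass.PREGNANCY_OF_UNKNOWN_LOCATION),
}

_DEMO_VIEWS = {
    "epo:uterus_sagittal_view": "Sagittal view of the uterus",
    "epo:uterus_transverse_view": "Transverse view of the uterus",
    "epo:right_adnexal_view": "Right adnexal view",
    "epo:left_adnexal_view": "Left adnexal view",
    "epo:pouch_of_douglas_view": "Pouch of Douglas view",
    "epo:endometrium_zoom_view": "Zoomed view of the endometrium",
}

# sign -> (label, definition, required views)
_DEMO_SIGNS = {
    "epo:intrauterine_gestational_sac": (
        "Intrauterine gestational sac",
        "Anechoic fluid collection with echogenic rim within the endometrial cavity.",
        ("epo:uterus_sagittal_view",),
    ),
    "epo:yolk_sac": (
        "Yolk sac",
        "Thin-walled circular structure within the gestational sac.",
        ("epo:endometrium_zoom_view",),
    ),
    "epo:embryo_with_cardiac_activity": (
        "Embryo with cardiac activity",
        "Embryonic pole with visible heartbeat.",
        ("epo:uterus_sagittal_view",),
    ),
    "epo:double_decidual_sac_sign": (
        "Double decidual sac sign",
        "Two concentric echogenic rings surrounding the gestational sac.",
        ("epo:uterus_transverse_view",),
    ),
    "epo:empty_uterus": (
        "Empty uterus",
        "No gestational sac visible within the endometrial cavity.",
        ("epo:uterus_sagittal_view",),
    ),
    "epo:adnexal_mass": (
        "Adnexal mass",
        "Inhomogeneous mass adjacent to, and moving separately from, the ovary.",
        ("epo:right_adnexal_view", "epo:left_adnexal_view"),
    ),
    "epo:tubal_ring_sign": (
        "Tubal ring sign",
        "Echogenic ring surrounding an extrauterine gestational sac.",
        ("epo:right_adnexal_view", "epo:left_adnexal_view"),
    ),
    "epo:free_pelvic_fluid": (
        "Free pelvic fluid",
        "Anechoic or echogenic fluid in the pouch of Douglas.",
        ("epo:pouch_of_douglas_view",),
    ),
    "epo:pseudogestational_sac": (
        "Pseudogestational sac",
        "Intracavitary fluid without a decidual reaction, mimicking a sac.",
        ("epo:uterus_sagittal_view",),
    ),
    "epo:thin_endometrium": (
        "Thin endometrium",
        "Endometrial thickness below expectation for early pregnancy.",
        ("epo:endometrium_zoom_view",),
    ),
}

_DEMO_DISORDERS = {
    IUP: (
        "Intrauterine pregnancy",
        "Pregnancy implanted within the endometrial cavity.",
        (
            "epo:intrauterine_gestational_sac",
            "epo:yolk_sac",
            "epo:embryo_with_cardiac_activity",
            "epo:double_decidual_sac_sign",
        ),
    ),
    TUBAL_EP: (
        "Tubal ectopic pregnancy",
        "Pregnancy implanted in the fallopian tube.",
        (
            "epo:empty_uterus",
            "epo:adnexal_mass",
            "epo:tubal_ring_sign",
            "epo:free_pelvic_fluid",
            "epo:pseudogestational_sac",
        ),
    ),
    PUL: (
        "Pregnancy of unknown location",
        "Positive pregnancy test with no pregnancy visualized on ultrasound.",
        ("epo:empty_uterus", "epo:thin_endometrium"),
    ),
}

_DEMO_STRUCTURES = {
    "epo:uterus": "Uterus",
    "epo:endometrium": "Endometrium",
    "epo:left_ovary": "Left ovary",
    "epo:right_ovary": "Right ovary",
    "epo:fallopian_tube": "Fallopian tube",
}


def demo_kb() -> KnowledgeBase:
    """A demonstration early-pregnancy knowledge base (illustrative content)."""
    kb = KnowledgeBase()
    for iri, label in _DEMO_VIEWS.items():
        kb.declare(iri, EntityKind.ECHOGRAPHIC_VIEW, label)
    for iri, (label, definition, views) in _DEMO_SIGNS.items():
        kb.declare(iri, EntityKind.SIGN, label, definition)
        for view in views:
            kb.add(iri, "epo:requires_view", view)
    for iri, (label, definition, signs) in _DEMO_DISORDERS.items():
        kb.declare(iri, EntityKind.DISORDER, label, definition)
        for sign in signs:
            kb.add(iri, "epo:has_sign", sign)
    for iri, label in _DEMO_STRUCTURES.items():
        kb.declare(iri, EntityKind.ANATOMICAL_STRUCTURE, label)
    kb.declare("epo:transvaginal_route", EntityKind.ULTRASOUND_ROUTE, "Transvaginal route")
    kb.declare("epo:b_mode", EntityKind.ULTRASOUND_MODE, "B mode")
    kb.add("epo:intrauterine_gestational_sac", "epo:located_in", "epo:uterus")
    kb.add("epo:tubal_ring_sign", "epo:located_in", "epo:fallopian_tube")
    kb.add("epo:thin_endometrium", "epo:located_in", "epo:endometrium")
    return kb


# --------------------------------------------------------------------------
# Printed-results transcriptions
# --------------------------------------------------------------------------


def table1_fixture() -> dict[str, dict[str, float]]:
    """Printed per-mode means/SDs of the continuous scan-quality outcomes."""
    return {
        "image_count": {
            "mean_assisted": 4.64,
            "sd_assisted": 0.80,
            "mean_nonassisted": 6.33,
            "sd_nonassisted": 2.07,
            "difference": -1.69,
            "pct_difference": -27,
        },
        "duration_min": {
            "mean_assisted": 14.7,
            "sd_assisted": 7.1,
            "mean_nonassisted": 6.4,
            "sd_nonassisted": 3.3,
            "difference": 8.3,
            "pct_difference": 129,
        },
        "quality_score": {
            "mean_assisted": 12.5,
            "sd_assisted": 1.86,
            "mean_nonassisted": 10.2,
            "sd_nonassisted": 1.90,
            "difference": 2.3,
            "pct_difference": 23,
        },
        "trust_level": {
            "mean_assisted": 4.12,
            "sd_assisted": 0.83,
            "mean_nonassisted": 3.42,
            "sd_nonassisted": 1.04,
            "difference": 0.70,
            "pct_difference": 20,
        },
    }


@dataclass(frozen=True)
class Table2Fixture:
    """Machine-readable transcription of the printed diagnostic outcomes.

    Counts are (assisted, nonassisted) out of ``n_per_mode`` scans each.
    The false-negative case lists carry the published per-trainee
    attribution; the two FN case sets overlap in case 44 only.
    """

    n_per_mode: int = 64
    correct_location: tuple[int, int] = (52, 39)
    exact_diagnosis: tuple[int, int] = (49, 30)
    fn_ep: tuple[int, int] = (1, 8)
    fp_ep: tuple[int, int] = (3, 3)
    fn_cases_nonassisted: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("44", ("trainee_1", "trainee_2")),
        ("23", ("trainee_1", "trainee_2")),
        ("50", ("trainee_1",)),
        ("45", ("trainee_1",)),
        ("33", ("trainee_1",)),
        ("1", ("trainee_1",)),
    )
    fn_cases_assisted: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("44", ("trainee_1",)),
    )

    def fn_scans(self, mode: str) -> list[tuple[str, str]]:
        """Expand a FN case list into (case_id, operator_id) scans."""
        source = (
            self.fn_cases_assisted if mode == "assisted" else self.fn_cases_nonassisted
        )
        return [(case, op) for case, ops in source for op in ops]


def table2_fixture() -> Table2Fixture:
    return Table2Fixture()


# the 32 case ids of the expansion; ids are arbitrary labels from the
# source series (the published FN cases 1/23/33/44/45/50 are tubal EP)
_EP_CASES = ("1", "23", "33", "44", "45", "50", "5", "9", "12", "19", "27", "38", "41", "55")
_IUP_CASES = (
    "2", "3", "4", "6", "7", "8", "10", "11", "13", "14", "15", "16", "17",
    "18", "20", "21", "22", "24",
)
_OPERATORS = ("trainee_1", "trainee_2")

# deterministic fixture values for the continuous fields (coprime cycle
# lengths so paired differences never have zero variance)
_CYCLES = {
    "assisted": {
        "image_count": (4, 5, 5, 4, 5),
        "duration_min": (14.0, 16.0, 13.0, 15.0, 15.5, 14.5),
        "quality_score": (12, 13, 12, 13, 12, 14, 11),
        "trust_level": (4, 4, 5, 4, 4, 3, 5, 4),
    },
    "nonassisted": {
        "image_count": (6, 7, 5, 8, 6, 6),
        "duration_min": (6.0, 7.0, 5.0, 8.0, 6.5),
        "quality_score": (10, 10, 11, 9, 10, 12),
        "trust_level": (3, 4, 3, 4, 3, 3, 4),
    },
}

_INTRAUTERINE = DiagnosisStatement(LocationClass.INTRAUTERINE)
_TUBAL = DiagnosisStatement(LocationClass.ECTOPIC, EctopicSite.TUBAL)
_EP_UNSPECIFIED = DiagnosisStatement(LocationClass.ECTOPIC, EctopicSite.UNSPECIFIED)
_PUL_STATEMENT = DiagnosisStatement(LocationClass.PREGNANCY_OF_UNKNOWN_LOCATION)

# per-mode trainee attribution of the three false-positive scans (three
# distinct intrauterine cases per mode, six in total; attribution invented,
# the publication does not print it)
_FP_SCANS = {
    "nonassisted": (("2", "trainee_1"), ("7", "trainee_2"), ("13", "trainee_1")),
    "assisted": (("4", "trainee_2"), ("10", "trainee_1"), ("20", "trainee_2")),
}
# exact-diagnosis counts among correct ectopic calls: 24/27 assisted,
# 11/20 nonassisted state the tubal site
_EP_SITE_STATED = {"assisted": 24, "nonassisted": 11}
# intrauterine cases concluded as definite intrauterine (the rest of the
# non-FP intrauterine scans are pregnancy-of-unknown-location calls)
_IUP_STATED = {"assisted": 25, "nonassisted": 19}


def table2_records() -> list[ScanRecord]:
    """Expand the printed outcome tables into 128 concrete scan records.

    Every printed marginal (52/39 correct location, 49/30 exact diagnosis,
    1/8 false negatives with their case attribution, 3/3 false positives)
    is reproduced exactly by ``summarize_study``; the details the tables do
    not print (which correct ectopic calls omit the site, which
    intrauterine scans got an unknown-location call) are fixed
    deterministically.
    """
    fixture = table2_fixture()
    records: list[ScanRecord] = []
    for mode in ("assisted", "nonassisted"):
        fn = set(fixture.fn_scans(mode))
        fp = set(_FP_SCANS[mode])
        ep_scans = sorted(
            (case, op) for case in _EP_CASES for op in _OPERATORS
        )
        iup_scans = sorted(
            (case, op) for case in _IUP_CASES for op in _OPERATORS
        )
        conclusions: dict[tuple[str, str], DiagnosisStatement] = {}
        # ectopic cases: printed FN scans miss the EP (the two both-trainee
        # cases read as intrauterine, the rest as unknown location); of the
        # correct calls, the first k (sorted) state the tubal site
        correct_ep = [s for s in ep_scans if s not in fn]
        for i, scan in enumerate(correct_ep):
            conclusions[scan] = (
                _TUBAL if i < _EP_SITE_STATED[mode] else _EP_UNSPECIFIED
            )
        for scan in fn:
            both_trainees = scan[0] in ("44", "23") and mode == "nonassisted"
            conclusions[scan] = _INTRAUTERINE if both_trainees else _PUL_STATEMENT
        # intrauterine cases: FP scans call an EP; of the rest, the first k
        # state intrauterine, the remainder conclude unknown location
        for scan in fp:
            conclusions[scan] = _EP_UNSPECIFIED
        other_iup = [s for s in iup_scans if s not in fp]
        for i, scan in enumerate(other_iup):
            conclusions[scan] = (
                _INTRAUTERINE if i < _IUP_STATED[mode] else _PUL_STATEMENT
            )
        cycles = _CYCLES[mode]
        for i, (case, op) in enumerate(ep_scans + iup_scans):
            gold = _TUBAL if (case, op) in set(ep_scans) else _INTRAUTERINE
            records.append(
                ScanRecord(
                    case_id=case,
                    operator_id=op,
                    mode=mode,
                    gold=gold,
                    conclusion=conclusions[(case, op)],
                    image_count=cycles["image_count"][i % len(cycles["image_count"])],
                    duration_min=cycles["duration_min"][i % len(cycles["duration_min"])],
                    quality_score=cycles["quality_score"][i % len(cycles["quality_score"])],
                    trust_level=cycles["trust_level"][i % len(cycles["trust_level"])],
                )
            )
    records.sort(key=lambda r: (r.case_id, r.operator_id, r.mode))
    return records


# --------------------------------------------------------------------------
# Stochastic study replication
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimCase:
    """One virtual case: its gold diagnosis and which signs are truly
    demonstrable in which view."""

    case_id: str
    gold: DiagnosisStatement
    sign_visibility: dict[str, frozenset[str]] = field(hash=False)

    def demonstrable(self, view: str) -> frozenset[str]:
        return self.sign_visibility.get(view, frozenset())


@dataclass(frozen=True)
class OperatorModel:
    """Detection behavior of one simulated operator.

    A demonstrable sign in an acquired view is found with probability
    ``p_detect_spontaneous`` during unguided scanning and
    ``p_detect_prompted`` when a protocol step directs attention to it.
    Scan duration is base + per-image + per-protocol-step costs (minutes).
    """

    operator_id: str
    p_detect_spontaneous: float = 0.6
    p_detect_prompted: float = 0.95
    base_views: frozenset[str] = STANDARD_VIEWS
    duration_base_min: float = 3.0
    duration_per_image_min: float = 0.5
    duration_per_step_min: float = 2.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_detect_spontaneous <= self.p_detect_prompted <= 1.0:
            raise ValueError(
                "need 0 <= p_detect_spontaneous <= p_detect_prompted <= 1"
            )


@dataclass(frozen=True)
class StudyDesign:
    """The crossover design: 2 operators x 32 cases x 2 modes = 128 scans."""

    n_intrauterine: int = 18
    n_tubal_ep: int = 14
    modes: tuple[str, ...] = ("nonassisted", "assisted")
    seed: int = 0

    @property
    def n_cases(self) -> int:
        return self.n_intrauterine + self.n_tubal_ep


# per-case probabilities that each conditional sign is demonstrable; the
# always-present anchor signs (gestational sac / empty uterus) are not
# listed. Chosen once as plausible early-pregnancy frequencies.
_IUP_SIGN_P = {
    "epo:yolk_sac": 0.8,
    "epo:embryo_with_cardiac_activity": 0.6,
    "epo:double_decidual_sac_sign": 0.5,
}
_EP_SIGN_P = {
    "epo:adnexal_mass": 0.7,
    "epo:tubal_ring_sign": 0.6,
    "epo:free_pelvic_fluid": 0.7,
    "epo:pseudogestational_sac": 0.3,
}
_ADNEXAL_SIGNS = frozenset({"epo:adnexal_mass", "epo:tubal_ring_sign"})


def case_series(seed: int, design: Optional[StudyDesign] = None) -> list[SimCase]:
    """Sample the virtual case series: 18 intrauterine + 14 tubal EP.

    Case order and per-case sign visibility are reproducible functions of
    the seed. Every visible sign is associated with the case's gold
    disorder, so the series is consistent with the demonstration KB.
    """
    design = design or StudyDesign(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    golds = ["iup"] * design.n_intrauterine + ["ep"] * design.n_tubal_ep
    golds = [golds[i] for i in rng.permutation(len(golds))]
    cases = []
    for i, kind in enumerate(golds):
        case_id = f"case_{i + 1:02d}"
        visibility: dict[str, set[str]] = {}

        def show(sign: str, view: str) -> None:
            visibility.setdefault(view, set()).add(sign)

        if kind == "iup":
            gold = _INTRAUTERINE
            show("epo:intrauterine_gestational_sac", "epo:uterus_sagittal_view")
            for sign, p in sorted(_IUP_SIGN_P.items()):
                if rng.random() < p:
                    view = _DEMO_SIGNS[sign][2][0]
                    show(sign, view)
        else:
            gold = _TUBAL
            show("epo:empty_uterus", "epo:uterus_sagittal_view")
            side_view = (
                "epo:right_adnexal_view"
                if rng.random() < 0.5
                else "epo:left_adnexal_view"
            )
            for sign, p in sorted(_EP_SIGN_P.items()):
                if rng.random() < p:
                    view = side_view if sign in _ADNEXAL_SIGNS else _DEMO_SIGNS[sign][2][0]
                    show(sign, view)
        cases.append(
            SimCase(
                case_id=case_id,
                gold=gold,
                sign_visibility={v: frozenset(s) for v, s in visibility.items()},
            )
        )
    return cases


def conclude(kb: KnowledgeBase, identified_signs: frozenset[str]) -> DiagnosisStatement:
    """Map identified signs to a report conclusion via the differential.

    The top-ranked disorder is reported when it has support and is not tied
    with the runner-up on both support and completeness; otherwise (and
    when no sign was identified) the conservative call is pregnancy of
    unknown location.
    """
    ranking = differential(kb, identified_signs)
    if not ranking or ranking[0].support < 1:
        return _PUL_STATEMENT
    if len(ranking) > 1:
        top, second = ranking[0], ranking[1]
        if top.support == second.support and top.completeness == second.completeness:
            return _PUL_STATEMENT
    return DISORDER_CONCLUSIONS.get(ranking[0].disorder, _PUL_STATEMENT)


def _simulate_scan(
    kb: KnowledgeBase,
    case: SimCase,
    operator: OperatorModel,
    mode: str,
    rng: np.random.Generator,
    quality_p: float,
    trust_p: float,
) -> ScanRecord:
    session = new_session(kb, case.case_id)
    n_images = 0
    n_steps = 0
    for view in sorted(operator.base_views):
        found = frozenset(
            sign
            for sign in sorted(case.demonstrable(view))
            if rng.random() < operator.p_detect_spontaneous
        )
        add_image(
            session,
            ImageAnnotation(
                image_id=f"{case.case_id}_{mode}_{n_images:02d}",
                view=view,
                signs_present=found,
                route="epo:transvaginal_route",
                mode="epo:b_mode",
            ),
        )
        n_images += 1
    if mode == "assisted":
        while True:
            guidance = next_guidance(session)
            if not guidance:
                break
            item = guidance[0]
            demonstrable = case.demonstrable(item.view)
            sought = sorted(item.sought_signs)
            found = frozenset(
                sign
                for sign in sought
                if sign in demonstrable and rng.random() < operator.p_detect_prompted
            )
            add_image(
                session,
                ImageAnnotation(
                    image_id=f"{case.case_id}_{mode}_{n_images:02d}",
                    view=item.view,
                    signs_present=found,
                    signs_absent=frozenset(sought) - found,
                    route="epo:transvaginal_route",
                    mode="epo:b_mode",
                ),
            )
            n_images += 1
            n_steps += 1
    conclusion = conclude(kb, session.identified_signs)
    duration = (
        operator.duration_base_min
        + operator.duration_per_image_min * n_images
        + operator.duration_per_step_min * n_steps
    )
    report = finalize(session, operator.operator_id, mode, conclusion, duration)
    return ScanRecord(
        case_id=case.case_id,
        operator_id=operator.operator_id,
        mode=mode,
        gold=case.gold,
        conclusion=report.conclusion,
        image_count=report.image_count,
        duration_min=report.duration_min,
        quality_score=int(rng.binomial(15, quality_p)),
        trust_level=1 + int(rng.binomial(4, trust_p)),
    )


#: expert review emulation: success probability per checklist item / trust step
_QUALITY_P = {"assisted": 0.83, "nonassisted": 0.68}
_TRUST_P = {"assisted": 0.78, "nonassisted": 0.60}


def run_study(
    design: StudyDesign,
    operators: Sequence[OperatorModel] = (
        OperatorModel("trainee_1"),
        OperatorModel("trainee_2"),
    ),
    kb: Optional[KnowledgeBase] = None,
    quality_p: Optional[dict[str, float]] = None,
    trust_p: Optional[dict[str, float]] = None,
) -> list[ScanRecord]:
    """Simulate the full crossover study: one record per case x operator x mode.

    Each scan draws from its own pseudo-random stream keyed by (seed, case
    index, operator index, mode index), so the arms are comparable and
    record insertion order is irrelevant. Quality and trust scores emulate
    the expert review as binomial draws with per-mode success
    probabilities; no acceptance property depends on their exact values.
    """
    kb = kb if kb is not None else demo_kb()
    quality_p = quality_p or _QUALITY_P
    trust_p = trust_p or _TRUST_P
    cases = case_series(design.seed, design)
    records = []
    for ci, case in enumerate(cases):
        for oi, operator in enumerate(operators):
            for mi, mode in enumerate(design.modes):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=design.seed, spawn_key=(1, ci, oi, mi)
                    )
                )
                records.append(
                    _simulate_scan(
                        kb, case, operator, mode, rng,
                        quality_p[mode], trust_p[mode],
                    )
                )
    return records
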