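"""Scoring and range validation for the study's clinical rating instruments.

Instruments covered: Hoehn & Yahr staging (integer 1-5), the SCOPA Motor
Scale (S-MS; examination / ADL / complications sections), the Non-Motor
Symptoms Scale (NMSS; 30 items in 9 domains, item score = severity x
frequency), the CISI-PD clinician global index (4 items, 0-6 each), the
single-item CGIS (1-7) and PGIS (1-6) global impressions, and the five-level
gold-standard clinical stage with its advanced/non-advanced binarization.

Missing items are never imputed: any instrument with a missing item scores
``None`` (flagged incomplete by callers).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

__all__ = [
    "ScaleValidationError",
    "ClinicalStage",
    "SMSScore",
    "NMSSScore",
    "CISIPDScore",
    "GlobalImpression",
    "SMS_SECTION_ITEMS",
    "SMS_SECTION_RANGES",
    "NMSS_DOMAINS",
    "validate_hy",
    "score_sms",
    "score_nmss",
    "score_cisi",
    "validate_global_impression",
    "gold_standard_binary",
]


class ScaleValidationError(ValueError):
    """An item or stage value is outside its instrument's range."""


class ClinicalStage(str, enum.Enum):
    """Five-level clinical stage assigned by the examining neurologist."""

    INITIAL = "initial"
    MILD = "mild"
    MODERATE = "moderate"
    ADVANCED = "advanced"
    LATE_STAGE = "late_stage"


#: Stages binarized as advanced PD under the gold standard.
ADVANCED_STAGES = frozenset({ClinicalStage.ADVANCED, ClinicalStage.LATE_STAGE})

# S-MS section layout.  The instrument's published score ranges (0-42
# examination, 0-21 ADL, 0-6 dyskinesias, 0-6 fluctuations, items 0-3)
# fix the per-section item counts used here; the counts live in this table
# rather than in code paths so they can be adjusted against the original
# scale literature.
SMS_SECTION_ITEMS: dict[str, int] = {
    "examination": 14,
    "adl": 7,
    "dyskinesias": 2,
    "fluctuations": 2,
}
SMS_SECTION_RANGES: dict[str, tuple[int, int]] = {
    "examination": (0, 42),
    "adl": (0, 21),
    "dyskinesias": (0, 6),
    "fluctuations": (0, 6),
}
SMS_ITEM_RANGE = (0, 3)

#: NMSS domains in instrument order with their item counts (30 items total).
NMSS_DOMAINS: tuple[tuple[str, int], ...] = (
    ("cardiovascular", 2),
    ("sleep_fatigue", 4),
    ("mood_cognition", 6),
    ("perceptual_hallucinations", 3),
    ("attention_memory", 3),
    ("gastrointestinal", 3),
    ("urinary", 3),
    ("sexual", 2),
    ("miscellaneous", 4),
)
NMSS_N_ITEMS = sum(n for _, n in NMSS_DOMAINS)


@dataclass(frozen=True)
class SMSScore:
    examination: int
    adl: int
    dyskinesias: int
    fluctuations: int

    @property
    def complications(self) -> int:
        return self.dyskinesias + self.fluctuations

    @property
    def total(self) -> int:
        return self.examination + self.adl + self.dyskinesias + self.fluctuations


@dataclass(frozen=True)
class NMSSScore:
    domains: tuple[int, ...]  # 9 domain scores in NMSS_DOMAINS order

    def __post_init__(self) -> None:
        if len(self.domains) != len(NMSS_DOMAINS):
            raise ScaleValidationError("NMSS requires 9 domain scores")

    def domain(self, name: str) -> int:
        names = [d for d, _ in NMSS_DOMAINS]
        return self.domains[names.index(name)]

    @property
    def total(self) -> int:
        return sum(self.domains)


@dataclass(frozen=True)
class CISIPDScore:
    motor_signs: int
    disability: int
    motor_complications: int
    cognitive_status: int

    @property
    def total(self) -> int:
        return (
            self.motor_signs
            + self.disability
            + self.motor_complications
            + self.cognitive_status
        )


@dataclass(frozen=True)
class GlobalImpression:
    cgis: int  # clinician, 1 "normal" .. 7 "among the most extremely ill"
    pgis: int  # patient, 1 "normal" .. 6 "severe"


def _check_int(value: object, lo: int, hi: int, what: str) -> int:
    if value is None:
        raise ScaleValidationError(f"{what}: missing value")
    if isinstance(value, bool) or int(value) != value:
        raise ScaleValidationError(f"{what}: {value!r} is not an integer")
    iv = int(value)
    if not lo <= iv <= hi:
        raise ScaleValidationError(f"{what}: {iv} outside [{lo}, {hi}]")
    return iv


def validate_hy(stage: object) -> int:
    """Hoehn & Yahr stage, integer 1-5.  Half-stages of the modified scale are rejected."""
    try:
        return _check_int(stage, 1, 5, "HY stage")
    except (TypeError, ValueError) as exc:
        raise ScaleValidationError(str(exc)) from None


def score_sms(section_items: Mapping[str, Sequence[Optional[int]]]) -> Optional[SMSScore]:
    """Score the SCOPA Motor Scale from per-item integers grouped by section.

    Returns ``None`` (incomplete) if any item is missing.  Raises
    :class:`ScaleValidationError` for out-of-range items or wrong layout.
    """
    unknown = set(section_items) - set(SMS_SECTION_ITEMS)
    if unknown:
        raise ScaleValidationError(f"unknown S-MS section(s) {sorted(unknown)}")
    sums: dict[str, int] = {}
    for section, n_items in SMS_SECTION_ITEMS.items():
        items = list(section_items.get(section, []))
        if len(items) != n_items:
            raise ScaleValidationError(
                f"S-MS {section}: expected {n_items} items, got {len(items)}"
            )
        if any(v is None for v in items):
            return None
        lo, hi = SMS_ITEM_RANGE
        sums[section] = sum(
            _check_int(v, lo, hi, f"S-MS {section} item {i + 1}")
            for i, v in enumerate(items)
        )
    return SMSScore(**sums)


def score_nmss(
    items: Sequence[tuple[Optional[int], Optional[int]]]
) -> Optional[NMSSScore]:
    """Score the NMSS from 30 (severity, frequency) pairs in instrument order.

    Item score = severity (0-3) x frequency (1-4); domain scores follow the
    fixed 2/4/6/3/3/3/3/2/4 item partition.  Returns ``None`` if any item is
    missing.
    """
    if len(items) != NMSS_N_ITEMS:
        raise ScaleValidationError(f"NMSS requires {NMSS_N_ITEMS} items, got {len(items)}")
    scores = []
    for i, (sev, freq) in enumerate(items):
        if sev is None or freq is None:
            return None
        s = _check_int(sev, 0, 3, f"NMSS item {i + 1} severity")
        f = _check_int(freq, 1, 4, f"NMSS item {i + 1} frequency")
        scores.append(s * f)
    domains = []
    pos = 0
    for _, n in NMSS_DOMAINS:
        domains.append(sum(scores[pos : pos + n]))
        pos += n
    return NMSSScore(domains=tuple(domains))


def score_cisi(items: Sequence[Optional[int]]) -> Optional[CISIPDScore]:
    """Score the CISI-PD from its four 0-6 items (motor signs, disability,
    motor complications, cognitive status)."""
    if len(items) != 4:
        raise ScaleValidationError(f"CISI-PD requires 4 items, got {len(items)}")
    if any(v is None for v in items):
        return None
    names = ("motor_signs", "disability", "motor_complications", "cognitive_status")
    values = {
        name: _check_int(v, 0, 6, f"CISI-PD {name}") for name, v in zip(names, items)
    }
    return CISIPDScore(**values)


def validate_global_impression(cgis: object, pgis: object) -> GlobalImpression:
    return GlobalImpression(
        cgis=_check_int(cgis, 1, 7, "CGIS"),
        pgis=_check_int(pgis, 1, 6, "PGIS"),
    )


def gold_standard_binary(stage: ClinicalStage | str) -> bool:
    """Binarize the five-level clinical stage: advanced/late-stage -> True."""
    try:
        stage = ClinicalStage(stage)
    except ValueError:
        raise ScaleValidationError(f"unknown clinical stage {stage!r}") from None
    return stage in ADVANCED_STAGES
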