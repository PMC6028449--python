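"""Rule engine for the CDEPA advanced-Parkinson's-disease screening questionnaire.

The CDEPA ("Cuestionario De Enfermedad de Parkinson Avanzada") is a
neurologist-administered checklist of motor, non-motor, and neuropsychiatric
symptoms, each answered yes/no and carrying a certainty tier (definitive,
probable, possible) within one of six symptom areas.  Case-level certainty is
derived deterministically:

* any *definitive* symptom present makes the case definitive (advanced PD);
* two or more *probable* symptoms from distinct areas promote the case to
  definitive;
* a *possible* disease-related (motor or non-motor) symptom together with a
  *possible* neuropsychiatric/cognitive symptom promotes the case to probable;
* otherwise the case carries the highest certainty of any present symptom.

The symptom taxonomy itself is data (a packaged YAML rule map), not code, so
users can amend symptom tiers without touching the engine.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "SymptomArea",
    "CertaintyLevel",
    "SymptomDefinition",
    "RuleSet",
    "PatientResponses",
    "RuleFiring",
    "CaseClassification",
    "RuleConfigError",
    "ResponseError",
    "load_ruleset",
    "default_ruleset",
    "validate_responses",
    "classify_case",
    "classify_cohort",
]


class SymptomArea(str, enum.Enum):
    """The six symptom areas of the questionnaire."""

    GENERAL = "general_characteristics"
    DISABILITY = "disability"
    TREATMENT_MOTOR = "treatment_motor"
    DISEASE_MOTOR = "disease_motor"
    DISEASE_NON_MOTOR = "disease_non_motor"
    NEURO_COGNITIVE = "neuropsychiatric_cognitive"


#: Areas whose *possible*-level symptoms count as "disease-related" for the
#: possible-pair promotion (partnered with a neuropsychiatric/cognitive one).
DISEASE_RELATED_AREAS = frozenset(
    {SymptomArea.DISEASE_MOTOR, SymptomArea.DISEASE_NON_MOTOR}
)


class CertaintyLevel(enum.IntEnum):
    """Ordered certainty of a symptom or a case: none < possible < probable < definitive."""

    NONE = 0
    POSSIBLE = 1
    PROBABLE = 2
    DEFINITIVE = 3

    @classmethod
    def from_label(cls, label: str) -> "CertaintyLevel":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise RuleConfigError(f"unknown certainty level {label!r}") from None

    @property
    def label(self) -> str:
        return self.name.lower()


class RuleConfigError(ValueError):
    """A rule map failed validation (duplicate id, unknown area/level, ...)."""


class ResponseError(ValueError):
    """Patient responses are malformed or violate the active rule set."""


@dataclass(frozen=True)
class SymptomDefinition:
    """One yes/no checklist item: stable id, free-text label, area, certainty tier."""

    id: str
    label: str
    area: SymptomArea
    level: CertaintyLevel

    def __post_init__(self) -> None:
        if self.level == CertaintyLevel.NONE:
            raise RuleConfigError(
                f"symptom {self.id!r}: level must be possible/probable/definitive"
            )


@dataclass(frozen=True)
class RuleSet:
    """A validated symptom taxonomy plus the combination-rule parameters.

    Parameters
    ----------
    symptoms
        The checklist items.  Ids must be unique and at least one must be
        definitive-level (otherwise no input could ever screen positive).
    promotion_b_min_areas
        Number of distinct areas probable-level "yes" symptoms must span to
        promote the case to definitive (default 2).
    diagnosis_threshold
        Minimum case-level certainty that counts as an advanced-PD screen
        positive.  The instrument's own reading is ``definitive``; lowering
        it to ``probable`` is supported for sensitivity analyses.
    """

    symptoms: tuple[SymptomDefinition, ...]
    promotion_b_min_areas: int = 2
    diagnosis_threshold: CertaintyLevel = CertaintyLevel.DEFINITIVE

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.symptoms:
            if s.id in seen:
                raise RuleConfigError(f"duplicate symptom id {s.id!r}")
            seen.add(s.id)
        if not any(s.level == CertaintyLevel.DEFINITIVE for s in self.symptoms):
            raise RuleConfigError("rule set contains no definitive-level symptom")
        if self.promotion_b_min_areas < 2:
            raise RuleConfigError("promotion_b_min_areas must be >= 2")
        if self.diagnosis_threshold == CertaintyLevel.NONE:
            raise RuleConfigError("diagnosis_threshold cannot be 'none'")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.symptoms)

    @property
    def by_id(self) -> dict[str, SymptomDefinition]:
        return {s.id: s for s in self.symptoms}

    def at_level(self, level: CertaintyLevel) -> tuple[SymptomDefinition, ...]:
        return tuple(s for s in self.symptoms if s.level == level)


@dataclass
class PatientResponses:
    """One patient's yes/no answers keyed by symptom id.

    ``None`` marks a missing answer; :func:`validate_responses` resolves
    missing answers (coercion to "no", or an error in strict mode) and stamps
    the record as validated, which :func:`classify_case` requires.
    """

    patient_id: str
    answers: dict[str, Optional[bool]]
    validated: bool = False

    @staticmethod
    def parse_answer(value: object) -> Optional[bool]:
        """Map CSV-ish cell values to True/False/None (missing)."""
        if value is None:
            return None
        if isinstance(value, bool):
            return value
        text = str(value).strip().lower()
        if text in {"", "na", "nan", "missing"}:
            return None
        if text in {"yes", "y", "1", "true"}:
            return True
        if text in {"no", "n", "0", "false"}:
            return False
        raise ResponseError(f"unrecognized answer {value!r}")


@dataclass(frozen=True)
class RuleFiring:
    """One rule clause that fired, with the symptom ids that triggered it."""

    rule: str
    symptom_ids: tuple[str, ...]


@dataclass(frozen=True)
class CaseClassification:
    """Case-level certainty, the binary screen result, and the triggering evidence."""

    patient_id: str
    case_level: CertaintyLevel
    advanced: bool
    evidence: tuple[RuleFiring, ...]

    @property
    def diagnosis(self) -> str:
        return "advanced" if self.advanced else "non_advanced"


# ---------------------------------------------------------------------------
# rule-map loading


def _coerce_mapping(source: Union[str, Path, Mapping]) -> Mapping:
    if isinstance(source, Mapping):
        return source
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_ruleset(source: Union[str, Path, Mapping]) -> RuleSet:
    """Parse and validate a rule map from YAML/JSON (path or mapping).

    Schema::

        symptoms:
          - {id: dementia, label: Dementia, area: neuropsychiatric_cognitive,
             level: definitive}
        promotion_b_min_areas: 2
        diagnosis_threshold: definitive
    """
    raw = _coerce_mapping(source)
    if not isinstance(raw, Mapping) or "symptoms" not in raw:
        raise RuleConfigError("rule map must be a mapping with a 'symptoms' list")
    symptoms = []
    for entry in raw["symptoms"]:
        missing = {"id", "label", "area", "level"} - set(entry)
        if missing:
            raise RuleConfigError(
                f"symptom entry {entry.get('id', entry)!r} missing keys {sorted(missing)}"
            )
        try:
            area = SymptomArea(entry["area"])
        except ValueError:
            raise RuleConfigError(
                f"symptom {entry['id']!r}: unknown area {entry['area']!r}"
            ) from None
        symptoms.append(
            SymptomDefinition(
                id=str(entry["id"]),
                label=str(entry["label"]),
                area=area,
                level=CertaintyLevel.from_label(str(entry["level"])),
            )
        )
    threshold = CertaintyLevel.from_label(str(raw.get("diagnosis_threshold", "definitive")))
    return RuleSet(
        symptoms=tuple(symptoms),
        promotion_b_min_areas=int(raw.get("promotion_b_min_areas", 2)),
        diagnosis_threshold=threshold,
    )


def default_ruleset() -> RuleSet:
    """The packaged CDEPA taxonomy (19 symptoms, 5 definitive)."""
    ref = resources.files("cdepa.data").joinpath("cdepa_default.yaml")
    return load_ruleset(yaml.safe_load(ref.read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# response validation and classification


def validate_responses(
    rules: RuleSet, resp: PatientResponses, strict: bool = False
) -> PatientResponses:
    """Check answers against the rule set and resolve missing answers.

    Unknown symptom ids are always an error.  A missing answer (absent key or
    ``None``) is coerced to "no" with a warning by default, or raised in
    ``strict`` mode.  Returns a new, validated :class:`PatientResponses`.
    """
    known = set(rules.ids)
    unknown = sorted(set(resp.answers) - known)
    if unknown:
        raise ResponseError(
            f"patient {resp.patient_id!r}: unknown symptom id(s) {unknown}"
        )
    answers: dict[str, Optional[bool]] = {}
    missing = []
    for sid in rules.ids:
        value = resp.answers.get(sid)
        if value is None:
            missing.append(sid)
            value = False
        answers[sid] = bool(value)
    if missing:
        if strict:
            raise ResponseError(
                f"patient {resp.patient_id!r}: missing answer(s) for {missing}"
            )
        warnings.warn(
            f"patient {resp.patient_id!r}: missing answer(s) {missing} coerced to 'no'",
            stacklevel=2,
        )
    return PatientResponses(patient_id=resp.patient_id, answers=answers, validated=True)


def classify_case(rules: RuleSet, resp: PatientResponses) -> CaseClassification:
    """Map one patient's validated answers to a case-level certainty.

    Single-pass evaluation: promotions read symptom-level certainties only —
    a case promoted to probable by the possible-pair clause does not feed the
    probable-pair clause.
    """
    if not resp.validated:
        raise ResponseError(
            f"patient {resp.patient_id!r}: responses must pass validate_responses first"
        )
    by_id = rules.by_id
    yes = [by_id[sid] for sid, ans in resp.answers.items() if ans]
    def_yes = [s for s in yes if s.level == CertaintyLevel.DEFINITIVE]
    prob_yes = [s for s in yes if s.level == CertaintyLevel.PROBABLE]
    poss_yes = [s for s in yes if s.level == CertaintyLevel.POSSIBLE]

    firings: list[tuple[CertaintyLevel, RuleFiring]] = []
    if def_yes:
        firings.append(
            (
                CertaintyLevel.DEFINITIVE,
                RuleFiring("definitive_symptom", tuple(s.id for s in def_yes)),
            )
        )
    if len({s.area for s in prob_yes}) >= rules.promotion_b_min_areas:
        firings.append(
            (
                CertaintyLevel.DEFINITIVE,
                RuleFiring("probable_cross_area_promotion", tuple(s.id for s in prob_yes)),
            )
        )
    if prob_yes:
        firings.append(
            (
                CertaintyLevel.PROBABLE,
                RuleFiring("probable_symptom", tuple(s.id for s in prob_yes)),
            )
        )
    poss_disease = [s for s in poss_yes if s.area in DISEASE_RELATED_AREAS]
    poss_neuro = [s for s in poss_yes if s.area == SymptomArea.NEURO_COGNITIVE]
    if poss_disease and poss_neuro:
        firings.append(
            (
                CertaintyLevel.PROBABLE,
                RuleFiring(
                    "possible_pair_promotion",
                    tuple(s.id for s in poss_disease + poss_neuro),
                ),
            )
        )
    if poss_yes:
        firings.append(
            (
                CertaintyLevel.POSSIBLE,
                RuleFiring("possible_symptom", tuple(s.id for s in poss_yes)),
            )
        )

    case_level = max((lvl for lvl, _ in firings), default=CertaintyLevel.NONE)
    evidence = tuple(f for lvl, f in firings if lvl == case_level)
    return CaseClassification(
        patient_id=resp.patient_id,
        case_level=case_level,
        advanced=case_level >= rules.diagnosis_threshold,
        evidence=evidence,
    )


def classify_cohort(
    rules: RuleSet, cohort: Iterable[PatientResponses]
) -> list[CaseClassification]:
    """Element-wise :func:`classify_case`, preserving order; errors carry patient ids."""
    out = []
    for resp in cohort:
        try:
            out.append(classify_case(rules, resp))
        except ResponseError:
            raise
        except Exception as exc:  # pragma: no cover - defensive context wrapper
            raise ResponseError(f"patient {resp.patient_id!r}: {exc}") from exc
    return out
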