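"""CSV readers and writers for cohort responses, scale scores, and reports.

All tabular interchange uses UTF-8, comma-separated CSV with a header row.
Two scale-score layouts are supported:

* **aggregated** — one column per section/domain total (``sms_examination``,
  ``nmss_urinary``, ``cisi_total``, ``cgis``, ``pgis``, ``hy``,
  ``clinical_stage``, ...), the layout the simulator emits and the pipeline
  consumes;
* **item-level** — namespaced per-item columns (``sms_ex_01`` ...,
  ``nmss_01_sev``/``nmss_01_freq`` ..., ``cisi_1``..``cisi_4``) scored into
  the aggregated layout by :func:`score_item_level_frame`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .rules import PatientResponses, RuleSet
from .scales import (
    NMSS_DOMAINS,
    SMS_SECTION_ITEMS,
    ClinicalStage,
    ScaleValidationError,
    score_cisi,
    score_nmss,
    score_sms,
    validate_hy,
)

__all__ = [
    "SchemaError",
    "read_responses_csv",
    "write_responses_csv",
    "read_scales_csv",
    "write_scales_csv",
    "score_item_level_frame",
    "AGGREGATED_SCALE_COLUMNS",
]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A tabular file does not match the expected column schema."""


#: Recognized aggregated scale columns (besides patient_id).
AGGREGATED_SCALE_COLUMNS: tuple[str, ...] = (
    "hy",
    "clinical_stage",
    "sms_examination",
    "sms_adl",
    "sms_dyskinesias",
    "sms_fluctuations",
    "sms_total",
    *(f"nmss_{name}" for name, _ in NMSS_DOMAINS),
    "nmss_total",
    "cisi_total",
    "cgis",
    "pgis",
)


def read_responses_csv(path: PathLike, rules: Optional[RuleSet] = None) -> list[PatientResponses]:
    """Read a patient-by-symptom yes/no table; empty cells become missing.

    When ``rules`` is given, columns outside the rule set raise
    :class:`SchemaError` naming the offending column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "patient_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'patient_id'")
    symptom_cols = [c for c in df.columns if c != "patient_id"]
    if rules is not None:
        unknown = sorted(set(symptom_cols) - set(rules.ids))
        if unknown:
            raise SchemaError(f"{path}: unknown symptom column(s) {unknown}")
    out = []
    for _, row in df.iterrows():
        answers = {c: PatientResponses.parse_answer(row[c]) for c in symptom_cols}
        out.append(PatientResponses(patient_id=str(row["patient_id"]), answers=answers))
    return out


def write_responses_csv(responses: Sequence[PatientResponses], path: PathLike) -> None:
    if not responses:
        raise ValueError("no responses to write")
    cols = list(responses[0].answers)
    rows = []
    for r in responses:
        row = {"patient_id": r.patient_id}
        for c in cols:
            v = r.answers.get(c)
            row[c] = "" if v is None else ("yes" if v else "no")
        rows.append(row)
    pd.DataFrame(rows, columns=["patient_id", *cols]).to_csv(path, index=False)


def read_scales_csv(path: PathLike) -> pd.DataFrame:
    """Read an aggregated scale-score table, validating columns and ranges."""
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'patient_id'")
    unknown = sorted(set(df.columns) - {"patient_id", *AGGREGATED_SCALE_COLUMNS})
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {unknown}")
    if "hy" in df.columns:
        for i, v in df["hy"].items():
            if not pd.isna(v):
                try:
                    validate_hy(v)
                except ScaleValidationError as exc:
                    raise SchemaError(f"{path}: row {i}: {exc}") from None
    if "clinical_stage" in df.columns:
        valid = {s.value for s in ClinicalStage}
        for i, v in df["clinical_stage"].items():
            if not pd.isna(v) and v not in valid:
                raise SchemaError(
                    f"{path}: row {i}: unknown clinical_stage {v!r}"
                )
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def write_scales_csv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# item-level scoring


def score_item_level_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Score a namespaced item-level table into the aggregated layout.

    Expected columns (any instrument may be absent as a whole):
    ``sms_ex_01``.., ``sms_adl_01``.., ``sms_dys_01``.., ``sms_flu_01``..,
    ``nmss_NN_sev``/``nmss_NN_freq`` for NN = 01..30, ``cisi_1``..``cisi_4``,
    plus pass-through ``hy``, ``clinical_stage``, ``cgis``, ``pgis``.
    Patients with a missing item score NaN (incomplete) on that instrument.
    """
    if "patient_id" not in df.columns:
        raise SchemaError("item-level table: missing required column 'patient_id'")
    prefix_of = {"examination": "sms_ex", "adl": "sms_adl", "dyskinesias": "sms_dys", "fluctuations": "sms_flu"}
    out: dict[str, list] = {"patient_id": df["patient_id"].astype(str).tolist()}

    def cell(row, col):
        v = row.get(col)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else int(v)

    has_sms = any(c.startswith("sms_ex_") for c in df.columns)
    has_nmss = any(c.startswith("nmss_") and c.endswith("_sev") for c in df.columns)
    has_cisi = any(c.startswith("cisi_") for c in df.columns)

    records = df.to_dict("records")
    if has_sms:
        for section in SMS_SECTION_ITEMS:
            out[f"sms_{section}"] = []
        out["sms_total"] = []
    if has_nmss:
        for name, _ in NMSS_DOMAINS:
            out[f"nmss_{name}"] = []
        out["nmss_total"] = []
    if has_cisi:
        out["cisi_total"] = []

    for row in records:
        if has_sms:
            sections = {
                sec: [cell(row, f"{prefix_of[sec]}_{i + 1:02d}") for i in range(n)]
                for sec, n in SMS_SECTION_ITEMS.items()
            }
            score = score_sms(sections)
            for sec in SMS_SECTION_ITEMS:
                out[f"sms_{sec}"].append(getattr(score, sec) if score else np.nan)
            out["sms_total"].append(score.total if score else np.nan)
        if has_nmss:
            items = [
                (cell(row, f"nmss_{i + 1:02d}_sev"), cell(row, f"nmss_{i + 1:02d}_freq"))
                for i in range(30)
            ]
            score = score_nmss(items)
            for j, (name, _) in enumerate(NMSS_DOMAINS):
                out[f"nmss_{name}"].append(score.domains[j] if score else np.nan)
            out["nmss_total"].append(score.total if score else np.nan)
        if has_cisi:
            score = score_cisi([cell(row, f"cisi_{i}") for i in range(1, 5)])
            out["cisi_total"].append(score.total if score else np.nan)

    result = pd.DataFrame(out)
    for passthrough in ("hy", "clinical_stage", "cgis", "pgis"):
        if passthrough in df.columns:
            result[passthrough] = df[passthrough].values
    return result
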