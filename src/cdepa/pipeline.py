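"""End-to-end validation pipeline: dataset assembly, analysis, reporting.

``run_validation`` reproduces the whole diagnostic-validation analysis for a
study dataset: the index-test-vs-gold-standard 2x2 table with all
performance statistics and Cohen's kappa, two-rater reliability sections
when a second-rater or retest block is present, nonparametric group
comparisons of every scale score between the CDEPA-defined groups, and
Youden cutoff analyses for the clinician global scores.  Every number in
the report is recomputable from the stored dataset and configuration; a
provenance block records the rule-map hash and package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .rules import (
    CaseClassification,
    PatientResponses,
    RuleSet,
    classify_cohort,
    validate_responses,
)
from .scales import ClinicalStage, gold_standard_binary
from .stats import (
    ContingencyTable,
    CutoffResult,
    DiagnosticPerformance,
    KappaResult,
    build_contingency,
    cohen_kappa,
    diagnostic_performance,
    mann_whitney_u,
    optimal_cutoff,
    percent_agreement,
    round_half_up,
)

__all__ = [
    "StudyDataset",
    "ValidationReport",
    "DatasetError",
    "run_validation",
    "read_dataset",
    "write_report",
    "dataset_from_cohort",
]


class DatasetError(ValueError):
    """Inconsistent or incomplete study dataset."""


@dataclass
class StudyDataset:
    """All per-patient study components, keyed by patient id.

    ``gold_stages`` (five-level clinical stage) is mandatory for validation;
    the second-rater and retest blocks are optional and enable the
    reliability sections.
    """

    responses: list[PatientResponses]
    gold_stages: dict[str, ClinicalStage]
    scales: Optional[pd.DataFrame] = None
    second_rater: Optional[list[PatientResponses]] = None
    retest: Optional[list[PatientResponses]] = None

    def check_consistency(self) -> None:
        ids = [r.patient_id for r in self.responses]
        if len(set(ids)) != len(ids):
            raise DatasetError("duplicate patient ids in responses")
        idset = set(ids)
        missing_gold = idset - set(self.gold_stages)
        if missing_gold:
            raise DatasetError(
                f"gold-standard stage missing for {sorted(missing_gold)[:5]}"
            )
        if self.scales is not None:
            extra = set(self.scales["patient_id"]) ^ idset
            if extra:
                raise DatasetError(f"scales/responses patient id mismatch: {sorted(extra)[:5]}")
        for name, block in (("second_rater", self.second_rater), ("retest", self.retest)):
            if block is not None:
                if {r.patient_id for r in block} - idset:
                    raise DatasetError(f"{name} block contains unknown patient ids")


def _agreement_2x2(
    a: Sequence[CaseClassification], b: Sequence[CaseClassification]
) -> np.ndarray:
    """Rows: first rater (advanced, non-advanced); columns: second rater."""
    b_by_id = {c.patient_id: c for c in b}
    table = np.zeros((2, 2), dtype=int)
    for ca in a:
        cb = b_by_id.get(ca.patient_id)
        if cb is None:
            continue
        table[0 if ca.advanced else 1, 0 if cb.advanced else 1] += 1
    return table


@dataclass
class ValidationReport:
    contingency: ContingencyTable
    performance: DiagnosticPerformance
    kappa_vs_gold: KappaResult
    inter_rater: Optional[dict] = None
    test_retest: Optional[dict] = None
    group_comparisons: dict[str, dict] = field(default_factory=dict)
    cutoffs: dict[str, dict] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        t = self.contingency
        perf_full = {
            k: getattr(self.performance, k)
            for k in (
                "sensitivity",
                "specificity",
                "ppv",
                "npv",
                "accuracy",
                "fp_rate",
                "fn_rate",
                "auc_binary",
            )
        }
        return {
            "contingency": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn, "n": t.n},
            "performance": perf_full,
            "performance_pct": self.performance.as_percentages(),
            "kappa_vs_gold": {
                "kappa": self.kappa_vs_gold.kappa,
                "kappa_2dp": round_half_up(self.kappa_vs_gold.kappa, 2),
                "observed_agreement": self.kappa_vs_gold.observed_agreement,
                "expected_agreement": self.kappa_vs_gold.expected_agreement,
                "se": self.kappa_vs_gold.se,
                "ci95": list(self.kappa_vs_gold.ci95),
                "p_value": self.kappa_vs_gold.p_value,
                "label": self.kappa_vs_gold.label,
            },
            "inter_rater": self.inter_rater if self.inter_rater else {"available": False},
            "test_retest": self.test_retest if self.test_retest else {"available": False},
            "group_comparisons": self.group_comparisons
            if self.group_comparisons
            else {"available": False},
            "cutoffs": self.cutoffs if self.cutoffs else {"available": False},
            "provenance": self.provenance,
        }

    def summary_text(self) -> str:
        """Plain-text summary in the familiar footnote style."""
        pct = self.performance.as_percentages()

        def fmt(key: str) -> str:
            v = pct[key]
            return "undefined" if v is None else f"{v:.1f}%"

        lines = [
            f"n = {self.contingency.n} "
            f"(tp {self.contingency.tp}, fp {self.contingency.fp}, "
            f"fn {self.contingency.fn}, tn {self.contingency.tn})",
            f"Sensitivity was {fmt('sensitivity')}; specificity was {fmt('specificity')}; "
            f"false positives were {fmt('fp_rate')}; false negatives were {fmt('fn_rate')}; "
            f"positive predictive value was {fmt('ppv')}; "
            f"negative predictive value was {fmt('npv')}; "
            f"total accuracy was {fmt('accuracy')}",
            f"Binary-classifier AUC: {fmt('auc_binary')}",
            f"Cohen's kappa vs gold standard: "
            f"{round_half_up(self.kappa_vs_gold.kappa, 2):.2f} "
            f"({self.kappa_vs_gold.label}, p = {self.kappa_vs_gold.p_value:.2g})",
        ]
        for name, block in (("Inter-rater", self.inter_rater), ("Test-retest", self.test_retest)):
            if block:
                lines.append(
                    f"{name}: agreement {block['percent_agreement_pct']:.1f}%, "
                    f"kappa {round_half_up(block['kappa'], 2):.2f} ({block['label']})"
                )
        return "\n".join(lines)


def run_validation(dataset: StudyDataset, rules: RuleSet, strict: bool = False) -> ValidationReport:
    """Classify the cohort and compute every statistic the dataset supports."""
    dataset.check_consistency()
    responses = [
        r if r.validated else validate_responses(rules, r, strict=strict)
        for r in dataset.responses
    ]
    classifications = classify_cohort(rules, responses)
    gold = [gold_standard_binary(dataset.gold_stages[r.patient_id]) for r in responses]
    if len(set(gold)) < 2:
        raise DatasetError("gold standard is single-class; validation statistics degenerate")
    index_dx = [c.advanced for c in classifications]

    table = build_contingency(index_dx, gold)
    report = ValidationReport(
        contingency=table,
        performance=diagnostic_performance(table),
        kappa_vs_gold=cohen_kappa(table.as_array()),
    )

    for attr, name in (("second_rater", "inter_rater"), ("retest", "test_retest")):
        block = getattr(dataset, attr)
        if block is None:
            continue
        block_validated = [
            r if r.validated else validate_responses(rules, r, strict=strict) for r in block
        ]
        other = classify_cohort(rules, block_validated)
        covered = {c.patient_id for c in other}
        firsts = [c for c in classifications if c.patient_id in covered]
        agreement = _agreement_2x2(firsts, other)
        kap = cohen_kappa(agreement)
        setattr(
            report,
            name,
            {
                "available": True,
                "n": int(agreement.sum()),
                "table": agreement.tolist(),
                "percent_agreement": percent_agreement(agreement),
                "percent_agreement_pct": round_half_up(100 * percent_agreement(agreement), 1),
                "kappa": kap.kappa,
                "ci95": list(kap.ci95),
                "label": kap.label,
            },
        )

    if dataset.scales is not None:
        adv_ids = {c.patient_id for c in classifications if c.advanced}
        scales = dataset.scales
        in_adv = scales["patient_id"].isin(adv_ids).to_numpy()
        numeric_cols = [
            c
            for c in scales.columns
            if c not in ("patient_id", "clinical_stage")
            and pd.api.types.is_numeric_dtype(scales[c])
        ]
        for col in numeric_cols:
            values = scales[col].to_numpy(dtype=float)
            ok = ~np.isnan(values)
            a = values[ok & in_adv]
            b = values[ok & ~in_adv]
            if a.size == 0 or b.size == 0:
                report.group_comparisons[col] = {"available": False, "reason": "single group"}
                continue
            cmp = mann_whitney_u(a, b)
            report.group_comparisons[col] = {
                "available": True,
                "advanced_mean": float(a.mean()),
                "advanced_sd": float(a.std(ddof=1)) if a.size > 1 else 0.0,
                "non_advanced_mean": float(b.mean()),
                "non_advanced_sd": float(b.std(ddof=1)) if b.size > 1 else 0.0,
                "u_statistic": cmp.statistic,
                "p_value": cmp.p_value,
                "group_sizes": list(cmp.group_sizes),
            }
        for col in ("cisi_total", "cgis"):
            if col not in scales.columns:
                continue
            values = scales[col].to_numpy(dtype=float)
            ok = ~np.isnan(values)
            if len(set(in_adv[ok])) < 2:
                continue
            cut = optimal_cutoff(values[ok], in_adv[ok])
            report.cutoffs[col] = {
                "available": True,
                "cutoff": cut.cutoff,
                "youden_j": cut.youden_j,
                "per_cutoff": cut.table.to_dict("records"),
            }

    report.provenance = {
        "package_version": __version__,
        "n_patients": len(responses),
        "ruleset_sha256": _ruleset_hash(rules),
        "diagnosis_threshold": rules.diagnosis_threshold.label,
    }
    return report


def _ruleset_hash(rules: RuleSet) -> str:
    canon = json.dumps(
        {
            "symptoms": [
                {"id": s.id, "area": s.area.value, "level": s.level.label}
                for s in rules.symptoms
            ],
            "promotion_b_min_areas": rules.promotion_b_min_areas,
            "diagnosis_threshold": rules.diagnosis_threshold.label,
        },
        sort_keys=True,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# dataset assembly and report serialization


def read_dataset(
    responses_path: Union[str, Path],
    scales_path: Optional[Union[str, Path]] = None,
    second_rater_path: Optional[Union[str, Path]] = None,
    retest_path: Optional[Union[str, Path]] = None,
    rules: Optional[RuleSet] = None,
) -> StudyDataset:
    """Assemble a dataset from CSV files.

    The gold-standard five-level stage is read from the ``clinical_stage``
    column of the scales table.
    """
    from .io import read_responses_csv, read_scales_csv

    responses = read_responses_csv(responses_path, rules=rules)
    if scales_path is None:
        raise DatasetError("a scales table with a clinical_stage column is required")
    scales = read_scales_csv(scales_path)
    if "clinical_stage" not in scales.columns:
        raise DatasetError(f"{scales_path}: missing gold-standard column 'clinical_stage'")
    gold = {
        str(row["patient_id"]): ClinicalStage(row["clinical_stage"])
        for _, row in scales.iterrows()
    }
    second = read_responses_csv(second_rater_path, rules=rules) if second_rater_path else None
    retest = read_responses_csv(retest_path, rules=rules) if retest_path else None
    return StudyDataset(
        responses=responses,
        gold_stages=gold,
        scales=scales,
        second_rater=second,
        retest=retest,
    )


def dataset_from_cohort(cohort, cfg=None, rater_seed=None, retest_seed=None) -> StudyDataset:
    """Build a StudyDataset from a simulated cohort, optionally with rater blocks."""
    from .simulate import cohort_scales_frame, simulate_second_rater

    dataset = StudyDataset(
        responses=[p.responses for p in cohort],
        gold_stages={p.patient_id: p.clinical_stage for p in cohort},
        scales=cohort_scales_frame(cohort),
    )
    if cfg is not None and rater_seed is not None:
        dataset.second_rater = simulate_second_rater(cohort, cfg.rater_flip_prob, rater_seed)
    if cfg is not None and retest_seed is not None:
        dataset.retest = simulate_second_rater(cohort, cfg.retest_flip_prob, retest_seed)
    return dataset


def write_report(report: ValidationReport, path: Union[str, Path]) -> None:
    """Serialize the report as JSON; a sibling ``.txt`` carries the summary."""
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=2) + "\n", encoding="utf-8")
    path.with_suffix(".txt").write_text(report.summary_text() + "\n", encoding="utf-8")
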