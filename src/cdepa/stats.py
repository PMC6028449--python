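"""Validation statistics for a screening instrument against a gold standard.

Everything the diagnostic-accuracy analysis needs: 2x2 performance
(sensitivity, specificity, predictive values, accuracy, error rates, binary
AUC), Cohen's kappa with the Landis-Koch interpretation bands, percent
agreement, Spearman rank correlation, Mann-Whitney U and Kruskal-Wallis
group comparisons, Fisher's exact test, Youden-index cutoff search on an
ordinal score, and the normal-approximation power of a one-sample
proportion test.

The binary-classifier AUC is defined as (sensitivity + specificity) / 2 —
the area under the single-operating-point ROC polygon — not a rank-based
AUC, since the index test yields a dichotomous result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "DiagnosticPerformance",
    "KappaResult",
    "PowerSpec",
    "GroupComparison",
    "CutoffResult",
    "round_half_up",
    "landis_koch_label",
    "build_contingency",
    "diagnostic_performance",
    "cohen_kappa",
    "percent_agreement",
    "spearman_rho",
    "mann_whitney_u",
    "kruskal_wallis",
    "fisher_exact",
    "optimal_cutoff",
    "power_one_sample_proportion",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for printed percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def landis_koch_label(kappa: float) -> str:
    """Landis-Koch qualitative band for a kappa value.

    Bands: 0.00-0.20 negligible, 0.21-0.40 weak, 0.41-0.60 moderate,
    0.61-0.80 substantial, 0.81-1.00 almost perfect; negative values fall
    below the scale.
    """
    if kappa < 0:
        return "below negligible"
    for hi, label in (
        (0.20, "negligible"),
        (0.40, "weak"),
        (0.60, "moderate"),
        (0.80, "substantial"),
        (1.0, "almost perfect"),
    ):
        if round_half_up(kappa, 2) <= hi:
            return label
    return "almost perfect"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of index test vs reference: tp = positive by both."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """Rows: index test (+, -); columns: reference (+, -)."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=np.int64)


def build_contingency(
    index_dx: Sequence[bool], reference_dx: Sequence[bool]
) -> ContingencyTable:
    """Cross-tabulate paired binary calls of the index test and the reference."""
    if len(index_dx) != len(reference_dx):
        raise ValueError(
            f"length mismatch: {len(index_dx)} index vs {len(reference_dx)} reference"
        )
    if len(index_dx) == 0:
        raise ValueError("empty input")
    idx = np.asarray(index_dx, dtype=bool)
    ref = np.asarray(reference_dx, dtype=bool)
    return ContingencyTable(
        tp=int(np.sum(idx & ref)),
        fp=int(np.sum(idx & ~ref)),
        fn=int(np.sum(~idx & ref)),
        tn=int(np.sum(~idx & ~ref)),
    )


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Diagnostic-accuracy proportions (all in [0, 1]; ``None`` = undefined).

    ``messages`` explains any undefined entry (zero margin)."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: float
    fp_rate: Optional[float]
    fn_rate: Optional[float]
    auc_binary: Optional[float]
    messages: tuple[str, ...] = ()

    def as_percentages(self, ndigits: int = 1) -> dict[str, Optional[float]]:
        out = {}
        for name in (
            "sensitivity",
            "specificity",
            "ppv",
            "npv",
            "accuracy",
            "fp_rate",
            "fn_rate",
            "auc_binary",
        ):
            v = getattr(self, name)
            out[name] = None if v is None else round_half_up(100.0 * v, ndigits)
        return out


def diagnostic_performance(t: ContingencyTable) -> DiagnosticPerformance:
    """All 2x2 performance statistics; zero-margin ratios come back undefined."""
    messages = []

    def ratio(num: int, den: int, what: str) -> Optional[float]:
        if den == 0:
            messages.append(f"{what} undefined: zero denominator")
            return None
        return num / den

    sens = ratio(t.tp, t.tp + t.fn, "sensitivity")
    spec = ratio(t.tn, t.tn + t.fp, "specificity")
    ppv = ratio(t.tp, t.tp + t.fp, "PPV")
    npv = ratio(t.tn, t.tn + t.fn, "NPV")
    auc = None if sens is None or spec is None else (sens + spec) / 2.0
    if auc is None:
        messages.append("binary AUC undefined: needs sensitivity and specificity")
    return DiagnosticPerformance(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=(t.tp + t.tn) / t.n,
        fp_rate=None if spec is None else 1.0 - spec,
        fn_rate=None if sens is None else 1.0 - sens,
        auc_binary=auc,
        messages=tuple(messages),
    )


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    label: str
    n: int


def cohen_kappa(table: Sequence[Sequence[float]] | np.ndarray) -> KappaResult:
    """Cohen's kappa from a square agreement table (rows: rater 1, cols: rater 2).

    kappa = (p_o - p_e) / (1 - p_e) with p_o the diagonal proportion and
    p_e the chance agreement from the margins.  The standard error uses the
    Fleiss-Cohen-Everitt large-sample variance; the CI is kappa +/- 1.96 se
    truncated to [-1, 1]; the p-value tests kappa = 0 with the null-variance
    formula.
    """
    a = np.asarray(table, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"agreement table must be square, got shape {a.shape}")
    n = a.sum()
    if n <= 0:
        raise ValueError("agreement table is empty")
    p = a / n
    po = float(np.trace(p))
    prow = p.sum(axis=1)
    pcol = p.sum(axis=0)
    pe = float(prow @ pcol)
    if pe >= 1.0 - 1e-15:
        raise ValueError("kappa undefined: expected agreement is 1 (constant raters)")
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss-Cohen-Everitt asymptotic variance of kappa-hat.
    k_ = kappa
    diag = np.diag(p)
    term1 = float(np.sum(diag * (1.0 - (prow + pcol) * (1.0 - k_)) ** 2))
    off = p.copy()
    np.fill_diagonal(off, 0.0)
    pc_plus_pr = pcol[:, None] + prow[None, :]  # p_.i + p_j. for cell (i, j)
    term2 = float((1.0 - k_) ** 2 * np.sum(off * pc_plus_pr**2))
    term3 = (k_ - pe * (1.0 - k_)) ** 2
    var = (term1 + term2 - term3) / (n * (1.0 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))

    # null-hypothesis variance (kappa = 0) for the significance test
    var0 = (pe + pe**2 - float(np.sum(prow * pcol * (prow + pcol)))) / (
        n * (1.0 - pe) ** 2
    )
    se0 = math.sqrt(max(var0, 0.0))
    if se0 > 0:
        p_value = float(2.0 * sps.norm.sf(abs(kappa) / se0))
    else:
        p_value = 1.0 if kappa == 0 else 0.0

    lo = max(-1.0, kappa - 1.96 * se)
    hi = min(1.0, kappa + 1.96 * se)
    return KappaResult(
        kappa=kappa,
        observed_agreement=po,
        expected_agreement=pe,
        se=se,
        ci95=(lo, hi),
        p_value=p_value,
        label=landis_koch_label(kappa),
        n=int(round(n)),
    )


def percent_agreement(table: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Raw agreement proportion (diagonal / total) of a square agreement table."""
    a = np.asarray(table, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"agreement table must be square, got shape {a.shape}")
    n = a.sum()
    if n <= 0:
        raise ValueError("agreement table is empty")
    return float(np.trace(a) / n)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho undefined for constant input")
    return float(sps.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class GroupComparison:
    statistic: float  # U (Mann-Whitney, for the first group) or H (Kruskal-Wallis)
    p_value: float
    group_sizes: tuple[int, ...]
    test: str


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 8
) -> GroupComparison:
    """Two-sided Mann-Whitney U test; U is reported for the first group.

    Small samples (min group size <= ``exact_max_n``, no ties) use the exact
    permutation null; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_sizes=(int(a.size), int(b.size)),
        test="mann_whitney_u",
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """Kruskal-Wallis H test with tie correction; p from chi-square, k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupComparison(
            statistic=0.0,
            p_value=1.0,
            group_sizes=tuple(int(g.size) for g in arrays),
            test="kruskal_wallis",
        )
    res = sps.kruskal(*arrays)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=tuple(int(g.size) for g in arrays),
        test="kruskal_wallis",
    )


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table."""
    return float(sps.fisher_exact(t.as_array(), alternative="two-sided").pvalue)


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    youden_j: float
    table: pd.DataFrame = field(repr=False)  # per-cutoff sens/spec/J
    degenerate: bool = False


def optimal_cutoff(scores: Sequence[float], labels: Sequence[bool]) -> CutoffResult:
    """Youden-optimal threshold for the rule "positive if score >= cutoff".

    Every observed score is tried as a candidate cutoff; ties in Youden's J
    break toward the smallest cutoff.  The full per-cutoff table is returned
    for transparency.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to choose a cutoff")
    candidates = np.unique(scores)
    rows = []
    for c in candidates:
        pred = scores >= c
        sens = np.sum(pred & labels) / n_pos
        spec = np.sum(~pred & ~labels) / n_neg
        rows.append((float(c), float(sens), float(spec), float(sens + spec - 1.0)))
    table = pd.DataFrame(rows, columns=["cutoff", "sensitivity", "specificity", "youden_j"])
    degenerate = candidates.size == 1
    if degenerate:
        warnings.warn("all scores identical: cutoff is degenerate", stacklevel=2)
    best = table.loc[table["youden_j"].idxmax()]  # idxmax takes the first (smallest c)
    return CutoffResult(
        cutoff=float(best["cutoff"]),
        youden_j=float(best["youden_j"]),
        table=table,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class PowerSpec:
    """One-sample two-sided proportion test: detect p1 against the null p0 at size n."""

    p0: float
    p1: float
    n: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < 1.0 and 0.0 < self.p1 < 1.0):
            raise ValueError("p0 and p1 must lie strictly inside (0, 1)")
        if self.n < 10:
            raise ValueError("n must be at least 10 for the normal approximation")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def power_one_sample_proportion(spec: PowerSpec) -> float:
    """Normal-approximation power of the two-sided one-sample proportion test.

    Rejection boundaries sit at p0 +/- z_{1-alpha/2} * sqrt(p0 q0 / n); power
    is the probability under p1 of landing beyond either boundary, with the
    sampling SD evaluated at p1.  No continuity correction.
    """
    z = float(sps.norm.ppf(1.0 - spec.alpha / 2.0))
    se0 = math.sqrt(spec.p0 * (1.0 - spec.p0) / spec.n)
    se1 = math.sqrt(spec.p1 * (1.0 - spec.p1) / spec.n)
    upper = spec.p0 + z * se0
    lower = spec.p0 - z * se0
    power = float(
        sps.norm.sf((upper - spec.p1) / se1) + sps.norm.cdf((lower - spec.p1) / se1)
    )
    return min(max(power, 0.0), 1.0)
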