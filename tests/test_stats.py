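"""Validation statistics against hand computations and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom, rankdata

from cdepa.stats import (
    ContingencyTable,
    PowerSpec,
    build_contingency,
    cohen_kappa,
    diagnostic_performance,
    fisher_exact,
    kruskal_wallis,
    landis_koch_label,
    mann_whitney_u,
    optimal_cutoff,
    percent_agreement,
    power_one_sample_proportion,
    round_half_up,
    spearman_rho,
)

# ---------------------------------------------------------------------------
# contingency table construction


class TestBuildContingency:
    def test_perfect_agreement(self):
        t = build_contingency([1, 0, 1, 0], [1, 0, 1, 0])
        assert (t.fp, t.fn) == (0, 0)
        assert (t.tp, t.tn) == (2, 2)

    def test_margins_partition_n(self, rng):
        idx = rng.random(173) < 0.6
        ref = rng.random(173) < 0.4
        t = build_contingency(idx, ref)
        assert t.n == 173
        assert t.tp + t.fp == int(idx.sum())
        assert t.tp + t.fn == int(ref.sum())

    def test_index_all_positive_on_negatives(self):
        t = build_contingency([1, 1], [0, 0])
        assert (t.tp, t.fp) == (0, 2)

    @pytest.mark.parametrize("a,b", [([1], []), ([], [])])
    def test_bad_input(self, a, b):
        with pytest.raises(ValueError):
            build_contingency(a, b)


# ---------------------------------------------------------------------------
# diagnostic performance


class TestDiagnosticPerformance:
    def test_study_counts_reproduce_printed_percentages(self, study_table):
        pct = diagnostic_performance(study_table).as_percentages()
        assert pct == {
            "sensitivity": 96.9,
            "specificity": 57.4,
            "ppv": 57.8,
            "npv": 96.9,
            "accuracy": 72.3,
            "fp_rate": 42.6,
            "fn_rate": 3.1,
            "auc_binary": 77.2,
        }

    def test_perfect_classifier(self):
        pct = diagnostic_performance(ContingencyTable(5, 0, 0, 7)).as_percentages()
        assert all(pct[k] == 100.0 for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "auc_binary"))

    def test_balanced_table_all_fifty(self):
        pct = diagnostic_performance(ContingencyTable(1, 1, 1, 1)).as_percentages()
        assert all(
            pct[k] == 50.0
            for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "auc_binary")
        )

    def test_zero_margin_marked_undefined_others_computed(self):
        perf = diagnostic_performance(ContingencyTable(0, 0, 0, 4))
        assert perf.sensitivity is None and perf.ppv is None
        assert perf.specificity == 1.0
        assert perf.accuracy == 1.0
        assert any("sensitivity" in m for m in perf.messages)

    @given(
        st.tuples(
            st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(1, 200)
        )
    )
    def test_identities(self, counts):
        perf = diagnostic_performance(ContingencyTable(*counts))
        if perf.sensitivity is not None:
            assert math.isclose(perf.sensitivity + perf.fn_rate, 1.0)
        if perf.specificity is not None:
            assert math.isclose(perf.specificity + perf.fp_rate, 1.0)
        if perf.auc_binary is not None:
            assert math.isclose(
                perf.auc_binary, (perf.sensitivity + perf.specificity) / 2
            )


# ---------------------------------------------------------------------------
# agreement statistics


def kappa_first_principles(table):
    """Independent transcription of the kappa definition."""
    table = np.asarray(table, float)
    n = table.sum()
    po = sum(table[i, i] for i in range(table.shape[0])) / n
    pe = sum(
        table[i, :].sum() * table[:, i].sum() for i in range(table.shape[0])
    ) / n**2
    return (po - pe) / (1 - pe)


class TestCohenKappa:
    def test_study_agreement_table(self, study_table):
        k = cohen_kappa(study_table.as_array())
        assert round_half_up(k.kappa, 2) == 0.48
        assert k.label == "moderate"
        assert k.p_value < 0.001

    def test_perfect_diagonal(self):
        k = cohen_kappa([[10, 0], [0, 7]])
        assert k.kappa == pytest.approx(1.0)
        assert k.label == "almost perfect"

    def test_independence_table(self):
        k = cohen_kappa([[1, 1], [1, 1]])
        assert k.observed_agreement == pytest.approx(0.5)
        assert k.expected_agreement == pytest.approx(0.5)
        assert k.kappa == pytest.approx(0.0)

    def test_constant_raters_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            cohen_kappa([[5, 0], [0, 0]])

    def test_matches_first_principles_on_random_tables(self, rng):
        for _ in range(25):
            table = rng.integers(1, 40, size=(2, 2))
            k = cohen_kappa(table)
            assert k.kappa == pytest.approx(kappa_first_principles(table), abs=1e-12)

    def test_se_and_pvalue_match_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        for _ in range(10):
            table = rng.integers(1, 40, size=(2, 2))
            ours = cohen_kappa(table)
            ref = sm_kappa(table, return_results=True)
            assert ours.kappa == pytest.approx(ref.kappa, abs=1e-10)
            assert ours.se == pytest.approx(math.sqrt(ref.var_kappa), rel=1e-8)
            assert ours.p_value == pytest.approx(ref.pvalue_two_sided, rel=1e-6)

    def test_invariant_to_simultaneous_label_permutation(self, rng):
        table = rng.integers(1, 30, size=(3, 3))
        perm = [2, 0, 1]
        permuted = table[np.ix_(perm, perm)]
        assert cohen_kappa(table).kappa == pytest.approx(
            cohen_kappa(permuted).kappa, abs=1e-12
        )

    @given(
        st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    )
    def test_bounded(self, counts):
        a, b, c, d = counts
        table = [[a, b], [c, d]]
        n = a + b + c + d
        if n == 0:
            return
        try:
            k = cohen_kappa(table)
        except ValueError:
            return
        assert -1.0 - 1e-12 <= k.kappa <= 1.0 + 1e-12
        assert (k.kappa == pytest.approx(1.0)) == (b == 0 and c == 0)


class TestPercentAgreement:
    def test_diagonal_only(self):
        assert percent_agreement([[7, 0], [0, 5]]) == 1.0

    def test_92_of_96_prints_as_95_8(self):
        p = percent_agreement([[50, 2], [2, 42]])
        assert round_half_up(100 * p, 1) == 95.8

    def test_43_of_46_prints_as_93_5(self):
        p = percent_agreement([[20, 2], [1, 23]])
        assert round_half_up(100 * p, 1) == 93.5


@pytest.mark.parametrize(
    "kappa,label",
    [
        (-0.1, "below negligible"),
        (0.1, "negligible"),
        (0.3, "weak"),
        (0.48, "moderate"),
        (0.7, "substantial"),
        (0.9, "almost perfect"),
        (1.0, "almost perfect"),
    ],
)
def test_landis_koch_bands(kappa, label):
    assert landis_koch_label(kappa) == label


# ---------------------------------------------------------------------------
# rank statistics


def spearman_first_principles(x, y):
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_identity_and_reversal(self):
        x = [3, 1, 4, 1.5, 9]
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, list(-np.asarray(x))) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # d = (0, -1, 1, -1, 1), sum d^2 = 4, rho = 1 - 6*4/(5*24) = 0.8
        assert spearman_rho([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]) == pytest.approx(0.8)

    def test_constant_input_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_matches_rank_correlation_oracle(self, rng):
        for _ in range(25):
            x = rng.integers(0, 6, size=30)  # heavy ties, like ordinal scales
            y = np.clip(x + rng.integers(-2, 3, size=30), 0, 8)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman_rho(x, y) == pytest.approx(
                spearman_first_principles(x, y), abs=1e-12
            )


def mwu_exact_oracle(a, b):
    """Exhaustive two-sided permutation p-value for the U statistic."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * len(b)
    dist = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        dist.append(u)
    dist = np.asarray(dist)
    lo, hi = min(u_obs, n1n2 - u_obs), max(u_obs, n1n2 - u_obs)
    p = float(np.mean((dist <= lo + 1e-9) | (dist >= hi - 1e-9)))
    return u_obs, min(p, 1.0)


class TestMannWhitney:
    def test_identical_singletons(self):
        out = mann_whitney_u([4.0], [4.0])
        assert out.statistic == pytest.approx(0.5)

    def test_complete_separation(self):
        out = mann_whitney_u([1, 2], [3, 4])
        assert out.statistic == 0.0

    def test_u_statistics_sum_to_n1n2(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 30))
            b = rng.normal(size=rng.integers(2, 30))
            ua = mann_whitney_u(a, b).statistic
            ub = mann_whitney_u(b, a).statistic
            assert ua + ub == pytest.approx(len(a) * len(b))

    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(3, 6)))
            b = rng.normal(size=int(rng.integers(3, 7)))
            out = mann_whitney_u(a, b)
            u_oracle, p_oracle = mwu_exact_oracle(a, b)
            assert out.statistic == pytest.approx(u_oracle)
            assert out.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def kruskal_first_principles(groups):
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)
    pos = 0
    h = 0.0
    for g in groups:
        r = ranks[pos : pos + len(g)]
        h += r.sum() ** 2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_all_equal_observations(self):
        out = kruskal_wallis([[2, 2], [2, 2, 2]])
        assert out.statistic == 0.0
        assert out.p_value == 1.0

    def test_two_group_consistency_with_mann_whitney(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(2, 1, 40)
        kw = kruskal_wallis([a, b])
        mw = mann_whitney_u(a, b)
        assert (kw.p_value < 0.05) == (mw.p_value < 0.05)

    def test_matches_first_principles(self, rng):
        for _ in range(20):
            groups = [
                rng.integers(0, 10, size=int(rng.integers(3, 8))).astype(float)
                for _ in range(3)
            ]
            if np.all(np.concatenate(groups) == groups[0][0]):
                continue
            out = kruskal_wallis(groups)
            assert out.statistic == pytest.approx(
                kruskal_first_principles(groups), abs=1e-10
            )

    def test_fewer_than_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


def fisher_oracle(t: ContingencyTable) -> float:
    """Sum hypergeometric probabilities <= the observed table's probability."""
    r1 = t.tp + t.fp
    c1 = t.tp + t.fn
    n = t.n
    dist = hypergeom(n, c1, r1)
    p_obs = dist.pmf(t.tp)
    ks = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = dist.pmf(ks)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_perfect_separation_closed_form(self):
        # only the two extreme tables are as improbable as the observed one
        p = fisher_exact(ContingencyTable(10, 0, 0, 10))
        assert p == pytest.approx(2.0 / math.comb(20, 10), rel=1e-9)

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(25):
            t = ContingencyTable(*(int(v) for v in rng.integers(0, 25, size=4) + [1, 0, 0, 1]))
            assert fisher_exact(t) == pytest.approx(fisher_oracle(t), abs=1e-10)


# ---------------------------------------------------------------------------
# cutoff search and power


class TestOptimalCutoff:
    def test_perfect_separation(self):
        out = optimal_cutoff([1, 2, 9, 10], [False, False, True, True])
        assert out.cutoff == 9
        assert out.youden_j == pytest.approx(1.0)

    def test_tie_breaks_toward_smallest_cutoff(self):
        # cutoffs 5 and 7 both give J = 1
        out = optimal_cutoff([1, 5, 7, 10], [False, True, True, True])
        assert out.cutoff == 5

    def test_degenerate_constant_scores(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = optimal_cutoff([4, 4, 4], [True, False, True])
        assert out.degenerate
        assert out.cutoff == 4
        assert out.youden_j == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            optimal_cutoff([1, 2, 3], [True, True, True])

    def test_per_cutoff_table_is_complete(self):
        out = optimal_cutoff([1, 2, 2, 3], [False, False, True, True])
        assert set(out.table["cutoff"]) == {1, 2, 3}
        assert ((out.table["youden_j"] <= out.youden_j + 1e-12).all())


class TestPower:
    def test_study_power_sentence(self):
        spec = PowerSpec(p0=0.25, p1=0.40, n=100, alpha=0.05)
        assert round_half_up(power_one_sample_proportion(spec), 2) == 0.91

    def test_null_equals_alternative_gives_alpha(self):
        spec = PowerSpec(p0=0.3, p1=0.3, n=200, alpha=0.05)
        assert round_half_up(power_one_sample_proportion(spec), 2) == 0.05

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(p0=0.0, p1=0.4, n=100),
            dict(p0=0.25, p1=1.0, n=100),
            dict(p0=0.25, p1=0.4, n=5),
            dict(p0=0.25, p1=0.4, n=100, alpha=0.0),
        ],
    )
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ValueError):
            PowerSpec(**kwargs)


def test_round_half_up_is_half_away_from_zero():
    assert round_half_up(57.75, 1) == 57.8
    assert round_half_up(0.485, 2) == 0.49
    assert round_half_up(2.5, 0) == 3.0
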