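import itertools
import math

import numpy as np
import pytest
from scipy.special import comb

from zygoquant.stats import (
    GroupedSamples,
    brown_forsythe,
    compare_groups,
    fisher_exact,
    mann_whitney,
    normality_gate,
    significance_stars,
    welch_anova,
)


def gs(*groups, **kw):
    return GroupedSamples({f"g{i}": np.asarray(g, float)
                           for i, g in enumerate(groups)}, **kw)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mannwhitney_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating every rank assignment."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    n_total = 0
    n_as_extreme = 0
    mean_u = len(a) * len(b) / 2
    for idx in itertools.combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for x in grp for y in rest if x > y)
        n_total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u):
            n_as_extreme += 1
    return n_as_extreme / n_total


def fisher_oracle(table):
    """Two-sided Fisher p by enumerating the margin-constrained table space
    and summing hypergeometric probabilities <= the observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

class TestNormalityGate:
    def test_normal_data_usually_passes(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = gs(rng.normal(0, 1, 30), rng.normal(0.5, 1, 30))
            hits += normality_gate(g) == "parametric"
        # both groups must pass Shapiro-Wilk: expected rate 0.95^2 = 90.25%;
        # bound is the expectation minus ~2.5 binomial SD
        assert hits >= 83

    def test_heavy_skew_forces_nonparametric(self):
        rng = np.random.default_rng(3)
        g = gs(np.exp(rng.normal(0, 2, 50)), rng.normal(0, 1, 50))
        assert normality_gate(g) == "nonparametric"

    def test_tiny_group_forces_nonparametric(self):
        g = gs([1.0, 2.0], [0.5, 1.5, 2.5, 3.0])
        assert normality_gate(g) == "nonparametric"


# ---------------------------------------------------------------------------
# compare_groups dispatch
# ---------------------------------------------------------------------------

class TestCompareGroups:
    def test_forced_nonparametric_exact_p_one_third(self):
        res = compare_groups(gs([1.0, 2.0], [3.0, 4.0]))
        assert res.test_name == "mann_whitney_exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        res = compare_groups(gs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res.p_value == pytest.approx(1.0)

    def test_normal_two_groups_dispatch_welch_t(self):
        rng = np.random.default_rng(7)
        res = compare_groups(gs(rng.normal(0, 1, 40), rng.normal(2, 2, 40)))
        assert res.test_name == "welch_t"
        assert res.p_value < 0.001

    def test_three_skewed_groups_dispatch_kruskal(self):
        rng = np.random.default_rng(11)
        res = compare_groups(gs(*[np.exp(rng.normal(0, 2, 25)) for _ in range(3)]))
        assert res.test_name == "kruskal_wallis"

    def test_three_normal_groups_dispatch_welch_anova(self):
        rng = np.random.default_rng(13)
        res = compare_groups(gs(*[rng.normal(m, 1, 30) for m in (0, 0.2, 5)]))
        assert res.test_name == "welch_anova"
        assert res.p_value < 1e-6

    def test_zero_variance_group_falls_back(self):
        rng = np.random.default_rng(17)
        res = compare_groups(gs([2.0, 2.0, 2.0, 2.0, 2.0], rng.normal(0, 1, 20)))
        assert "mann_whitney" in res.test_name
        assert "zero-variance" in res.note or res.normality_gate_used["g0"] is False

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(19)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        p1 = compare_groups(gs(a, b)).p_value
        p2 = compare_groups(gs(b, a)).p_value
        assert p1 == pytest.approx(p2)

    def test_nonparametric_monotone_transform_invariance(self):
        a = np.array([1.0, 5.0, 9.0, 2.0])
        b = np.array([11.0, 30.0, 8.0, 40.0])
        _, p1, _ = mann_whitney(a, b)
        _, p2, _ = mann_whitney(np.exp(a / 5), np.exp(b / 5))
        assert p1 == pytest.approx(p2)


class TestExactMannWhitneyAgainstEnumeration:
    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 5), (3, 4), (4, 4), (5, 5)])
    def test_matches_full_enumeration(self, n1, n2):
        rng = np.random.default_rng(100 * n1 + n2)
        for _ in range(5):
            a = rng.uniform(0, 1, n1)
            b = rng.uniform(0, 1, n2)
            _, p, method = mann_whitney(a, b)
            assert method == "exact"
            assert p == pytest.approx(mannwhitney_exact_oracle(a, b), abs=1e-12)


# ---------------------------------------------------------------------------
# Welch ANOVA and Brown-Forsythe
# ---------------------------------------------------------------------------

class TestWelchAnova:
    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(23)
        samples = [rng.normal(m, s, n) for m, s, n in
                   ((0, 1, 20), (0.5, 3, 35), (1, 0.5, 15))]
        f, p = welch_anova(samples)
        df = pd.DataFrame({
            "y": np.concatenate(samples),
            "g": np.repeat(["a", "b", "c"], [len(s) for s in samples]),
        })
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)


class TestBrownForsythe:
    def test_null_rejection_rate_near_alpha(self):
        rejects = 0
        n_sims = 400
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            res = brown_forsythe(gs(rng.normal(0, 1, 50), rng.normal(0, 1, 50)))
            rejects += res.p_value < 0.05
        assert abs(rejects / n_sims - 0.05) < 0.03

    def test_power_against_25x_variance(self):
        rejects = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = brown_forsythe(gs(rng.normal(0, 1, 50), rng.normal(0, 5, 50)))
            rejects += res.p_value < 0.05
        assert rejects > 95

    def test_identical_constant_groups(self):
        res = brown_forsythe(gs([3.0, 3.0, 3.0], [3.0, 3.0, 3.0]))
        assert res.statistic == 0.0 and res.p_value == 1.0


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_one_sided_hypergeometric_example(self):
        res = fisher_exact([[5, 19], [0, 15]])
        expected = comb(24, 5) / comb(39, 5)
        assert res.p_one_sided == pytest.approx(expected, rel=1e-9)

    def test_identical_rows_no_association(self):
        res = fisher_exact([[4, 9], [4, 9]])
        assert res.p_value == pytest.approx(1.0)

    def test_two_unit_table(self):
        assert fisher_exact([[1, 0], [0, 1]]).p_value == pytest.approx(1.0)

    def test_matches_table_space_enumeration(self, rng):
        # all tables with total <= 12, plus a random sample with totals <= 30
        tables = [
            [[a, b], [c, d]]
            for a in range(6) for b in range(6) for c in range(6) for d in range(6)
            if 0 < a + b + c + d <= 12
        ]
        for _ in range(200):
            t = rng.integers(0, 9, size=4)
            if 0 < t.sum() <= 30:
                tables.append([[int(t[0]), int(t[1])], [int(t[2]), int(t[3])]])
        for t in tables:
            if sum(t[0]) == 0 or sum(t[1]) == 0:
                continue
            assert fisher_exact(t).p_value == pytest.approx(
                min(1.0, fisher_oracle(t)), rel=1e-8), t

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])


def test_significance_star_bands():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(5e-4) == "***"
    assert significance_stars(5e-5) == "****"
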