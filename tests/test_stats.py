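"""Agreement and comparison statistics against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from dixonfgt import (
    bland_altman,
    cohort_compare,
    implied_cor_from_cov,
    paired_t,
    pearson_r,
    rm_anova,
)


# --------------------------- independent oracles ---------------------------

def bland_altman_oracle(pairs):
    d = [a - b for a, b in pairs]
    n = len(d)
    mean_d = sum(d) / n
    var = sum((x - mean_d) ** 2 for x in d) / (n - 1)
    sd = math.sqrt(var)
    xbar = sum((a + b) / 2 for a, b in pairs) / n
    return mean_d, sd, 1.96 * sd, sd / (math.sqrt(2) * xbar) * 100


def pearson_oracle(xs, ys):
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sx = math.sqrt(sum((x - mx) ** 2 for x in xs))
    sy = math.sqrt(sum((y - my) ** 2 for y in ys))
    return cov / (sx * sy)


def paired_t_oracle(pairs):
    from scipy.stats import t as tdist
    d = [a - b for a, b in pairs]
    n = len(d)
    mean_d = sum(d) / n
    sd = math.sqrt(sum((x - mean_d) ** 2 for x in d) / (n - 1))
    t = mean_d / (sd / math.sqrt(n))
    p = 2 * tdist.sf(abs(t), n - 1)
    return t, p


def rm_anova_oracle(matrix):
    """One-way repeated-measures ANOVA by explicit sums of squares."""
    from scipy.stats import f as fdist
    arr = np.asarray(matrix, float)
    n, k = arr.shape
    grand = arr.mean()
    ss_cond = n * ((arr.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((arr.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((arr - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    F = (ss_cond / df_cond) / (ss_err / df_err)
    return F, fdist.sf(F, df_cond, df_err)


# --------------------------------- tests -----------------------------------

class TestBlandAltman:
    def test_identical_pairs(self):
        st = bland_altman([(3.0, 3.0), (4.0, 4.0), (5.0, 5.0)])
        assert st.mean_difference == 0 and st.sd_differences == 0
        assert st.coefficient_of_repeatability == 0
        assert st.coefficient_of_variation_pct == 0

    def test_worked_example(self):
        """Pairs (1,2),(2,1),(3,3): sigma_d = 1, CoR = 1.96, CoV = 35.36%."""
        st = bland_altman([(1, 2), (2, 1), (3, 3)])
        assert st.sd_differences == pytest.approx(1.0)
        assert st.coefficient_of_repeatability == pytest.approx(1.96)
        assert st.coefficient_of_variation_pct == pytest.approx(35.3553, abs=1e-3)
        assert st.limits_of_agreement == pytest.approx((-1.96, 1.96))

    def test_member_swap_flips_only_mean_difference(self):
        pairs = [(1.0, 2.5), (2.0, 1.0), (3.5, 3.0), (4.0, 5.0)]
        a = bland_altman(pairs)
        b = bland_altman([(y, x) for x, y in pairs])
        assert b.mean_difference == pytest.approx(-a.mean_difference)
        assert b.coefficient_of_repeatability == pytest.approx(
            a.coefficient_of_repeatability)
        assert b.coefficient_of_variation_pct == pytest.approx(
            a.coefficient_of_variation_pct)

    def test_scale_behaviour(self):
        pairs = np.array([(1.0, 2.5), (2.0, 1.0), (3.5, 3.0)])
        a = bland_altman(pairs)
        b = bland_altman(3.0 * pairs)
        assert b.coefficient_of_variation_pct == pytest.approx(
            a.coefficient_of_variation_pct)
        assert b.coefficient_of_repeatability == pytest.approx(
            3.0 * a.coefficient_of_repeatability)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            bland_altman([(1.0, 2.0)])
        with pytest.raises(ZeroDivisionError):
            bland_altman([(1.0, -1.0), (-2.0, 2.0)])

    def test_implied_cor_inverts_cov(self):
        pairs = [(30.1, 31.0), (40.2, 38.9), (25.0, 26.3), (55.1, 54.0)]
        st = bland_altman(pairs)
        xbar = np.mean([(a + b) / 2 for a, b in pairs])
        assert implied_cor_from_cov(st.coefficient_of_variation_pct, xbar) == \
            pytest.approx(st.coefficient_of_repeatability, rel=1e-12)


class TestPearson:
    def test_perfect_correlations(self):
        xs = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(xs, xs) == pytest.approx(1.0)
        assert pearson_r(xs, [-x for x in xs]) == pytest.approx(-1.0)

    def test_five_point_oracle(self):
        xs = [1.0, 2.0, 4.0, 5.0, 9.0]
        ys = [2.0, 1.0, 5.0, 4.5, 8.0]
        assert pearson_r(xs, ys) == pytest.approx(pearson_oracle(xs, ys), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairedT:
    def test_constant_differences_rejected(self):
        with pytest.raises(ValueError):
            paired_t([(2.0, 1.0), (3.0, 2.0), (4.0, 3.0)])

    def test_closed_form(self):
        pairs = [(3.0, 1.0), (5.0, 2.0), (4.0, 4.0), (6.0, 3.0)]
        t, p = paired_t(pairs)
        t0, p0 = paired_t_oracle(pairs)
        assert t == pytest.approx(t0, rel=1e-12)
        assert p == pytest.approx(p0, rel=1e-12)

    def test_swapping_order_negates_t(self):
        pairs = [(3.0, 1.0), (5.0, 2.0), (4.0, 4.5), (6.0, 3.0)]
        t1, p1 = paired_t(pairs)
        t2, p2 = paired_t([(b, a) for a, b in pairs])
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)


class TestRMAnova:
    def test_identical_columns_give_zero_f(self):
        m = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        F, p = rm_anova(m)
        assert F == 0.0

    def test_4x3_matrix_matches_sums_of_squares_oracle(self):
        m = np.array([
            [10.0, 12.0, 11.0],
            [20.0, 22.0, 24.0],
            [30.0, 29.0, 35.0],
            [40.0, 38.0, 42.0],
        ])
        F, p = rm_anova(m)
        F0, p0 = rm_anova_oracle(m)
        assert F == pytest.approx(F0, rel=1e-9)
        assert p == pytest.approx(p0, rel=1e-9)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(5, 4)) + np.arange(4)
        F1, _ = rm_anova(m)
        F2, _ = rm_anova(m[:, [2, 0, 3, 1]])
        assert F1 == pytest.approx(F2, rel=1e-9)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            rm_anova(m)


def _cohort_table(rng, n_subjects=8, offsets=None):
    offsets = offsets or {"hr-gre-pd": 0.0, "hr-gre-t1": 3.0, "lr-se-t1": 12.0}
    rows = []
    for s in range(n_subjects):
        base = rng.uniform(15, 65)
        for lat in "LR":
            breast = base + rng.normal(0, 2)
            for ds, off in offsets.items():
                pct = breast + off + rng.normal(0, 0.5)
                total = rng.uniform(300, 700)
                rows.append({
                    "subject": s, "laterality": lat, "dataset": ds,
                    "pct_fgt": pct, "fgt_cm3": pct / 100 * total,
                    "total_cm3": total,
                })
    return pd.DataFrame(rows)


class TestCohortCompare:
    def test_identical_datasets_agree_perfectly(self):
        rng = np.random.default_rng(0)
        table = _cohort_table(rng, offsets={"hr-gre-pd": 0.0})
        dup = table.copy()
        dup["dataset"] = "copy"
        report = cohort_compare(pd.concat([table, dup]), "hr-gre-pd")
        cmp_ = report["comparisons"]["copy_vs_hr-gre-pd"]
        assert cmp_["mean_difference"] == pytest.approx(0.0, abs=1e-12)
        assert cmp_["pearson_r"] == pytest.approx(1.0)

    def test_recovers_known_offsets(self):
        """Synthetic cohorts with injected between-dataset offsets are
        recovered within Monte-Carlo error."""
        rng = np.random.default_rng(12)
        report = cohort_compare(_cohort_table(rng, n_subjects=20), "hr-gre-pd")
        d_t1 = report["comparisons"]["hr-gre-t1_vs_hr-gre-pd"]["mean_difference"]
        d_se = report["comparisons"]["lr-se-t1_vs_hr-gre-pd"]["mean_difference"]
        assert d_t1 == pytest.approx(3.0, abs=0.5)
        assert d_se == pytest.approx(12.0, abs=0.5)
        assert report["anova"]["p"] < 1e-6
        assert "left_vs_right" in report

    def test_missing_reference_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            cohort_compare(_cohort_table(rng), reference_dataset="absent")


class TestBruteForceEquivalence:
    """All statistics match independent implementations on random inputs."""

    def test_hundred_random_inputs(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(4, 12))
            pairs = rng.uniform(1.0, 100.0, size=(n, 2))
            st = bland_altman(pairs)
            md, sd, cor, cov = bland_altman_oracle(pairs.tolist())
            assert st.mean_difference == pytest.approx(md, rel=1e-10, abs=1e-10)
            assert st.sd_differences == pytest.approx(sd, rel=1e-10)
            assert st.coefficient_of_repeatability == pytest.approx(cor, rel=1e-10)
            assert st.coefficient_of_variation_pct == pytest.approx(cov, rel=1e-10)

            xs, ys = rng.uniform(0, 50, size=(2, n))
            assert pearson_r(xs, ys) == pytest.approx(
                pearson_oracle(xs.tolist(), ys.tolist()), rel=1e-10)

            t, p = paired_t(pairs)
            t0, p0 = paired_t_oracle(pairs.tolist())
            assert t == pytest.approx(t0, rel=1e-10)
            assert p == pytest.approx(p0, rel=1e-10)

            m = rng.uniform(0, 10, size=(int(rng.integers(3, 7)),
                                         int(rng.integers(2, 5))))
            F, pf = rm_anova(m)
            F0, pf0 = rm_anova_oracle(m)
            assert F == pytest.approx(F0, rel=1e-10)
            assert pf == pytest.approx(pf0, rel=1e-10)
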