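"""Covariate adjustment, group F-tests, FDR, rank tests, partial correlation.

Dual-route checks: the batched QR-based F-test is validated against
statsmodels OLS/ANOVA, and partial correlation against pingouin and the
recursive two-covariate closed form.
"""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from itertools import combinations
from scipy import stats as sps

from dynconn import stats as gs

DATA = Path(__file__).parent / "data"


class TestCovariateAdjust:
    def test_orthogonal_covariates_give_demeaned_y(self, rng):
        n = 40
        y = rng.standard_normal(n)
        yc = y - y.mean()
        cov = rng.standard_normal((n, 2))
        cov -= cov.mean(axis=0)
        # orthogonalize centered covariates against centered y
        for j in range(2):
            cov[:, j] -= (cov[:, j] @ yc) / (yc @ yc) * yc
        res = gs.covariate_adjust(y, cov)
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-10)

    def test_perfect_linear_fit_gives_zero_residuals(self, rng):
        age = rng.uniform(20, 60, 30)
        y = 3.0 + 0.5 * age
        res = gs.covariate_adjust(y, age.reshape(-1, 1))
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        y = rng.standard_normal(50)
        cov = rng.standard_normal((50, 4))
        res = gs.covariate_adjust(y, cov)
        for j in range(4):
            assert abs(res @ cov[:, j]) < 1e-8


class TestGroupFtest:
    def test_identical_groups_f_zero_p_one(self):
        y = np.tile([1.0, 2.0, 3.0], 3)
        groups = np.repeat(["A", "B", "C"], 3)
        r = gs.group_glm_ftest(np.ones(9), groups)
        assert r.statistic == 0.0 and r.p == 1.0
        del y

    def test_large_shift_detected(self, rng):
        n = 30
        y = np.concatenate([
            rng.standard_normal(n), rng.standard_normal(n) + 10,
            rng.standard_normal(n),
        ])
        groups = np.repeat(["HC", "LTLE", "RTLE"], n)
        r = gs.group_glm_ftest(y, groups)
        assert r.p < 1e-6

    def test_hand_worked_ancova_fixture(self):
        # 9-subject, 3-group ANCOVA toy: group F = 1160/17 (= 68.2353),
        # from SSR/SSE hand computation (residual SS 10/3, group SS 4637/51)
        df = pd.read_csv(DATA / "ancova_toy.tsv", sep="\t")
        r = gs.group_glm_ftest(
            df.y.to_numpy(float), df.group.to_numpy(),
            covariates=df.age.to_numpy(float).reshape(-1, 1),
        )
        assert r.statistic == pytest.approx(1160 / 17, abs=1e-8)
        assert r.p == pytest.approx(2.3483e-4, rel=1e-3)

    def test_batch_matches_statsmodels(self, rng):
        import statsmodels.api as smapi
        from statsmodels.formula.api import ols

        n = 45
        groups = np.repeat(["A", "B", "C"], n // 3)
        cov = rng.standard_normal((n, 2))
        y = rng.standard_normal((n, 5))
        y[:, 0] += (groups == "B") * 1.5
        res = gs.group_ftest_batch(y, groups, cov)
        for j in range(5):
            df = pd.DataFrame({
                "y": y[:, j], "g": groups, "c1": cov[:, 0], "c2": cov[:, 1],
            })
            an = smapi.stats.anova_lm(ols("y ~ C(g) + c1 + c2", df).fit(), typ=2)
            assert res.F[j] == pytest.approx(an.loc["C(g)", "F"], rel=1e-8)
            assert res.p[j] == pytest.approx(an.loc["C(g)", "PR(>F)"], rel=1e-8)


class TestFdrBH:
    def test_stepup_all_rejected(self):
        reject, p_adj = gs.fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert reject.all()
        assert p_adj[-1] == pytest.approx(0.04)

    def test_all_ones(self):
        reject, p_adj = gs.fdr_bh(np.ones(10))
        assert not reject.any()
        np.testing.assert_allclose(p_adj, 1.0)

    def test_single_pvalue_passthrough(self):
        _, p_adj = gs.fdr_bh(np.array([0.03]))
        assert p_adj[0] == pytest.approx(0.03)

    def test_q_monotone_in_bh_ordering(self, rng):
        p = rng.uniform(size=50)
        _, q = gs.fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)


class TestKruskalDunn:
    def test_identical_groups(self):
        y = np.tile([5.0], 9)
        groups = np.repeat(["A", "B", "C"], 3)
        h, p = gs.kruskal_wallis(y, groups)
        assert h == 0.0 and p == 1.0

    def test_fully_separated_groups_attain_max_h(self):
        y = np.array([1, 2, 3, 11, 12, 13, 21, 22, 23], dtype=float)
        groups = np.repeat(["A", "B", "C"], 3)
        h, _ = gs.kruskal_wallis(y, groups)
        # brute-force oracle: maximum H over all rank partitions (n=9, k=3)
        ranks = np.arange(1, 10)
        n = 9
        best = 0.0
        for ga in combinations(range(9), 3):
            rest = [i for i in range(9) if i not in ga]
            for gb in combinations(rest, 3):
                gc = [i for i in rest if i not in gb]
                ss = sum(ranks[list(g)].sum() ** 2 / 3 for g in (ga, gb, gc))
                best = max(best, 12 / (n * (n + 1)) * ss - 3 * (n + 1))
        assert h == pytest.approx(best, abs=1e-10)

    def test_dunn_bonferroni_multiplies_by_pairs(self, rng):
        y = rng.standard_normal(30)
        groups = np.repeat(["A", "B", "C"], 10)
        ph = gs.posthoc_dunn_bonferroni(y, groups)
        assert len(ph) == 3
        np.testing.assert_allclose(
            ph.p_bonferroni, np.minimum(1.0, 3 * ph.p_raw))

    def test_dunn_flags_shifted_group(self, rng):
        y = np.concatenate([rng.standard_normal(15),
                            rng.standard_normal(15) + 8,
                            rng.standard_normal(15)])
        groups = np.repeat(["A", "B", "C"], 15)
        ph = gs.posthoc_dunn_bonferroni(y, groups)
        ab = ph[(ph.group_a == "A") & (ph.group_b == "B")].iloc[0]
        ac = ph[(ph.group_a == "A") & (ph.group_b == "C")].iloc[0]
        assert ab.p_bonferroni < 0.05
        assert ac.p_bonferroni > 0.05


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 40))
        pc = gs.partial_correlation(x, y)
        r, p = sps.pearsonr(x, y)
        assert pc.r == pytest.approx(r, abs=1e-12)
        assert pc.p == pytest.approx(p, rel=1e-8)
        assert pc.df == 38

    def test_linked_variables_detected(self, rng):
        x = rng.standard_normal(50)
        y = x + 0.5 * rng.standard_normal(50)
        cov = rng.standard_normal((50, 3))
        pc = gs.partial_correlation(x, y, cov)
        assert pc.r > 0.5 and pc.p < 1e-4
        assert pc.df == 50 - 2 - 3

    def test_recursive_two_covariate_formula(self):
        # 6-subject toy: partial r from the recursive closed form
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        z = np.array([1.0, 1, 2, 2, 3, 3])

        def partial_r(a, b, c):
            rab = np.corrcoef(a, b)[0, 1]
            rac = np.corrcoef(a, c)[0, 1]
            rbc = np.corrcoef(b, c)[0, 1]
            return (rab - rac * rbc) / np.sqrt((1 - rac**2) * (1 - rbc**2))

        expected = partial_r(x, y, z)
        pc = gs.partial_correlation(x, y, z.reshape(-1, 1))
        assert pc.r == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        df = pd.DataFrame({
            "x": rng.standard_normal(35),
            "y": rng.standard_normal(35),
            "c1": rng.standard_normal(35),
            "c2": rng.standard_normal(35),
        })
        out = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        pc = gs.partial_correlation(
            df.x.to_numpy(), df.y.to_numpy(), df[["c1", "c2"]].to_numpy())
        assert pc.r == pytest.approx(float(out["r"].iloc[0]), abs=1e-10)
        assert pc.p == pytest.approx(float(out["p_val"].iloc[0]), rel=1e-6)


class TestDemographicsTable:
    def _meta(self, rng, shift=0.0):
        n = 15
        rows = []
        for g in ("HC", "LTLE", "RTLE"):
            for i in range(n):
                rows.append({
                    "subject_id": f"{g}{i}", "group": g,
                    "age": float(30 + rng.standard_normal()
                                 + (shift if g == "RTLE" else 0.0)),
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "education": float(13 + rng.standard_normal()),
                    "mean_fd": float(abs(rng.normal(0.08, 0.02))),
                })
        return pd.DataFrame(rows)

    def test_structure_and_detection(self, rng):
        table = gs.demographics_table(self._meta(rng, shift=10.0))
        age = table[table.feature == "age"].iloc[0]
        assert age.test == "anova" and age.p < 1e-6
        assert "+/-" in age["HC"]
        sex = table[table.feature == "sex"].iloc[0]
        assert sex.test == "chi2"

    def test_chi2_hand_computation(self):
        # 2x2 counts [[10,0],[0,10]] -> chi-square 20 without correction
        chi2, p, _, _ = sps.chi2_contingency(
            np.array([[10, 0], [0, 10]]), correction=False)
        assert chi2 == pytest.approx(20.0)

    def test_t_squared_equals_f_for_two_groups(self, rng):
        y = rng.standard_normal(20)
        groups = np.repeat(["A", "B"], 10)
        t, _ = sps.ttest_ind(y[:10], y[10:])
        r = gs.group_glm_ftest(y, groups)
        assert t**2 == pytest.approx(r.statistic, abs=1e-8)
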