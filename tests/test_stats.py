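"""Group statistics: normality gate, FDR (with a hand-coded step-up
oracle), edgewise GLM, covariate-adjusted rank tests, ROC, partial
correlation and the demographics table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dynfc.stats import (
    adjusted_rank_test,
    bh_fdr,
    demographics_table,
    edgewise_glm,
    median_significant_strength,
    normality_gate,
    partial_correlation,
    roc_auc,
    _group_t_ols,
)


def bh_oracle(p, q):
    """Hand-coded Benjamini-Hochberg step-up: compare sorted p_(i)
    against i*q/m and reject all up to the largest passing rank."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    passing = np.flatnonzero(p[order] <= (np.arange(1, m + 1) * q / m))
    reject = np.zeros(m, bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject


class TestNormalityGate:
    def test_level_on_gaussian_samples(self):
        rng = np.random.default_rng(21)
        calls = [normality_gate(rng.standard_normal(200)) for _ in range(50)]
        assert calls.count("normal") >= 45

    def test_power_on_uniform_samples(self):
        rng = np.random.default_rng(22)
        calls = [normality_gate(rng.uniform(0, 1, 500)) for _ in range(50)]
        assert calls.count("non-normal") >= 45

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            assert normality_gate(np.ones(10)) == "non-normal"

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])


class TestBhFdr:
    def test_step_up_matches_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        adj, reject = bh_fdr(p, q=0.05)
        assert reject.sum() == 3
        assert np.array_equal(reject, bh_oracle(p, 0.05))
        assert np.all(adj >= p)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_pvalues_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 60) ** 2
        _, reject = bh_fdr(p, q=0.05)
        assert np.array_equal(reject, bh_oracle(p, 0.05))

    def test_all_ones_reject_nothing(self):
        _, reject = bh_fdr(np.ones(10))
        assert not reject.any()

    def test_single_small_p_rejected(self):
        _, reject = bh_fdr([0.04], q=0.05)
        assert reject[0]

    def test_rejections_monotone_in_q(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 100) ** 3
        counts = [bh_fdr(p, q=q)[1].sum() for q in (0.01, 0.05, 0.1, 0.2)]
        assert counts == sorted(counts)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])


class TestGroupGlm:
    def test_reduces_to_pooled_t_without_covariates(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal((30, 5))
        g = np.repeat([0.0, 1.0], 15)
        _, t, p = _group_t_ols(y, g, None)
        for j in range(5):
            t_ref, p_ref = sps.ttest_ind(y[g == 1, j], y[g == 0, j], equal_var=True)
            assert t[j] == pytest.approx(t_ref, abs=1e-10)
            assert p[j] == pytest.approx(p_ref, abs=1e-10)

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 40
        g = rng.integers(0, 2, n).astype(float)
        cov = np.column_stack([rng.normal(70, 5, n), rng.integers(0, 2, n)])
        y = 0.4 * g + 0.02 * cov[:, 0] + rng.standard_normal(n)
        beta, t, p = _group_t_ols(y[:, None], g, cov)
        X = sm.add_constant(np.column_stack([g, cov]))
        fit = sm.OLS(y, X).fit()
        assert beta[0] == pytest.approx(fit.params[1], abs=1e-10)
        assert t[0] == pytest.approx(fit.tvalues[1], abs=1e-10)
        assert p[0] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_state_skipped_when_too_rare(self, rng):
        from dynfc.metrics import ParticipantStateFC

        state_fc = {}
        man = []
        for i in range(8):
            pid = f"s{i}"
            fc = ParticipantStateFC(pid, k=1)
            # only one patient ever visits the state
            if i != 0:
                fc.matrices[1] = np.eye(3)
                fc.window_counts[1] = 2
            state_fc[pid] = fc
            man.append({"id": pid, "group": "patient" if i < 2 else "control",
                        "age": 70 + i, "sex": "M"})
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = edgewise_glm(state_fc, pd.DataFrame(man), state=1)
        assert out is None


class TestAdjustedRankTest:
    def test_reduces_to_plain_mannwhitney(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(24)
        g = np.repeat(["a", "b"], 12)
        u, p = adjusted_rank_test(y, g)
        ref = sps.mannwhitneyu(y[:12], y[12:], alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_separated_groups(self):
        # frozen from exhaustive enumeration of C(6,3)=20 rankings:
        # complete separation has point probability 2/20 = 0.1 two-sided
        u, p = adjusted_rank_test(
            [1.0, 2.0, 3.0, 10.0, 11.0, 12.0], ["a"] * 3 + ["b"] * 3
        )
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_level_under_covariate_driven_null(self):
        """Values fully explained by age: residualization keeps the
        test at its nominal level."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            age = rng.normal(70, 8, 30)
            y = 0.5 * age + rng.standard_normal(30)
            g = np.repeat(["a", "b"], 15)
            _, p = adjusted_rank_test(y, g, covariates=age[:, None])
            rejections += p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_singular_covariates_rejected(self):
        y = np.arange(10.0)
        g = np.repeat(["a", "b"], 5)
        cov = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="singular"):
            adjusted_rank_test(y, g, covariates=cov)


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], 1.0),
            ([5, 5, 5, 5], [0, 0, 1, 1], 0.5),
            ([0.9, 0.8, 0.85, 0.7], [1, 1, 0, 0], 0.75),
        ],
    )
    def test_reference_values(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_invariant_to_monotone_transform(self, rng):
        s = rng.standard_normal(40)
        y = rng.integers(0, 2, 40)
        if y.sum() in (0, 40):
            y[0] = 1 - y[0]
        assert roc_auc(np.exp(s), y) == pytest.approx(roc_auc(s, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestMedianSignificantStrength:
    def _fc(self, pid, mat, k=1):
        from dynfc.metrics import ParticipantStateFC

        fc = ParticipantStateFC(pid, k)
        fc.matrices[1] = mat
        fc.window_counts[1] = 3
        return fc

    def test_single_edge_returns_value(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.42
        med = median_significant_strength({"p": self._fc("p", m)}, [(0, 1)], 1)
        assert med["p"] == pytest.approx(0.42)

    def test_median_of_three_edges(self):
        m = np.eye(4)
        for (i, j), v in zip([(0, 1), (0, 2), (0, 3)], (0.1, 0.3, 0.8)):
            m[i, j] = m[j, i] = v
        med = median_significant_strength(
            {"p": self._fc("p", m)}, [(0, 1), (0, 2), (0, 3)], 1
        )
        assert med["p"] == pytest.approx(0.3)

    def test_absent_state_participant_excluded(self):
        from dynfc.metrics import ParticipantStateFC

        present = self._fc("a", np.eye(3))
        absent = ParticipantStateFC("b", 1)
        med = median_significant_strength({"a": present, "b": absent}, [(0, 1)], 1)
        assert list(med.index) == ["a"]

    def test_empty_edge_set_rejected(self):
        with pytest.raises(ValueError, match="state 1"):
            median_significant_strength({}, np.empty((0, 2)), 1)


class TestPartialCorrelation:
    def test_no_covariates_is_pearson(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(50)
        y = 0.5 * x + rng.standard_normal(50)
        r, p = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_identical_series_give_unit_r(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(30)
        cov = rng.standard_normal((30, 2))
        r, p = partial_correlation(x, x.copy(), cov)
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_covariate_mediated_association_vanishes(self):
        """x and y both driven by the covariate: partialling it out
        leaves only noise-level correlation."""
        rng = np.random.default_rng(10)
        rs = []
        for _ in range(30):
            z = rng.standard_normal(200)
            x = 2 * z + rng.standard_normal(200)
            y = -1.5 * z + rng.standard_normal(200)
            r, _ = partial_correlation(x, y, z[:, None])
            rs.append(abs(r))
        assert np.mean(rs) < 0.1

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation([1.0, 2], [3.0, 4], np.ones((2, 1)))


class TestDemographicsTable:
    def _manifest(self, rng, n=20, shift=0.0):
        return pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(2 * n)],
                "group": ["patient"] * n + ["control"] * n,
                "age": rng.normal(75, 6, 2 * n),
                "sex": rng.choice(["M", "F"], 2 * n),
                "MMSE": np.r_[rng.normal(21 + shift, 3, n), rng.normal(29, 1, n)],
                "NPI": np.abs(rng.normal(2, 2, 2 * n)),
            }
        )

    def test_identical_groups_give_trivial_tests(self):
        rng = np.random.default_rng(11)
        half = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(10)],
                "age": rng.normal(75, 6, 10),
                "sex": ["M"] * 5 + ["F"] * 5,
                "MMSE": rng.normal(25, 2, 10),
                "NPI": np.abs(rng.normal(2, 2, 10)),
            }
        )
        pat = half.copy(); pat["group"] = "patient"
        con = half.copy(); con["id"] = con["id"] + "c"; con["group"] = "control"
        tab = demographics_table(pd.concat([pat, con], ignore_index=True))
        by = tab.set_index("variable")
        assert by.loc["age", "p"] == pytest.approx(1.0)
        assert by.loc["sex", "statistic"] == 0.0

    def test_t_statistic_matches_pooled_formula(self):
        """Pooled two-sample t computed from first principles."""
        rng = np.random.default_rng(12)
        man = self._manifest(rng)
        tab = demographics_table(man).set_index("variable")
        a = man.loc[man["group"] == "patient", "age"].to_numpy()
        b = man.loc[man["group"] == "control", "age"].to_numpy()
        sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                     / (len(a) + len(b) - 2))
        t_manual = (a.mean() - b.mean()) / (sp * np.sqrt(1 / len(a) + 1 / len(b)))
        assert tab.loc["age", "statistic"] == pytest.approx(t_manual, abs=1e-10)

    def test_balanced_sex_table_gives_zero_chi2(self):
        man = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(40)],
                "group": ["patient"] * 20 + ["control"] * 20,
                "age": 75.0,
                "sex": (["M"] * 10 + ["F"] * 10) * 2,
                "MMSE": np.r_[np.random.default_rng(0).normal(21, 3, 20),
                              np.random.default_rng(1).normal(29, 1, 20)],
                "NPI": np.abs(np.random.default_rng(2).normal(2, 2, 40)),
            }
        )
        tab = demographics_table(man).set_index("variable")
        assert tab.loc["sex", "statistic"] == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        man = pd.DataFrame(
            {"id": ["a"], "group": ["patient"], "age": [70.0],
             "sex": ["M"], "MMSE": [20.0], "NPI": [1.0]}
        )
        with pytest.raises(ValueError, match="control"):
            demographics_table(man)


class TestScalarTestLevels:
    """Type-I error of each scalar test under its null, at alpha=0.05."""

    @pytest.mark.parametrize(
        "test_fn",
        [
            pytest.param(
                lambda rng: sps.ttest_ind(
                    rng.standard_normal(20), rng.standard_normal(20), equal_var=True
                ).pvalue,
                id="pooled-t",
            ),
            pytest.param(
                lambda rng: adjusted_rank_test(
                    rng.standard_normal(40),
                    np.repeat(["a", "b"], 20),
                    rng.standard_normal((40, 2)),
                )[1],
                id="adjusted-rank",
            ),
            pytest.param(
                lambda rng: partial_correlation(
                    rng.standard_normal(40),
                    rng.standard_normal(40),
                    rng.standard_normal((40, 2)),
                )[1],
                id="partial-correlation",
            ),
        ],
    )
    def test_level_within_band(self, test_fn):
        rng = np.random.default_rng(1234)
        n_rep = 600
        rej = sum(test_fn(rng) < 0.05 for _ in range(n_rep)) / n_rep
        assert 0.03 <= rej <= 0.07
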