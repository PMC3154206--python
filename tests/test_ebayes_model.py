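"""Tests of the empirical-Bayes two-group model.

Oracles: direct per-gene two-sample formulas, scipy's classical t-test
for the shrinkage-free limit, the scaled-F generating distribution for
prior recovery, and the reference empirical-Bayes implementation in the
R/Bioconductor package limma on a tiny fixture.
"""

import subprocess
import sys
import textwrap

import numpy as np
import pytest
from scipy import stats

from fcrci import (
    ExpressionMatrix,
    GroupAssignment,
    estimate_prior,
    fit_two_group,
    moderated_t_pvalues,
)
from fcrci.ebayes_model import trigamma_inverse

from conftest import make_dataset


class TestValidation:
    def test_rejects_nonfinite_value_naming_location(self):
        values = np.ones((3, 4))
        values[1, 2] = np.nan
        with pytest.raises(ValueError, match="g1.*s2"):
            ExpressionMatrix(values, ("g0", "g1", "g2"), ("s0", "s1", "s2", "s3"))

    def test_rejects_duplicate_gene_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(np.ones((2, 4)), ("g", "g"), ("a", "b", "c", "d"))

    def test_rejects_group_with_single_sample(self):
        with pytest.raises(ValueError, match="n1=1"):
            GroupAssignment(np.array([1, 2, 2, 2]))

    def test_rejects_label_count_mismatch(self, small_dataset):
        expr, _, _ = small_dataset
        with pytest.raises(ValueError, match="labels"):
            fit_two_group(expr, GroupAssignment(np.array([1, 1, 2, 2])))


class TestFitAgainstDirectFormulas:
    def test_matches_bruteforce_means_and_pooled_variances(self, rng):
        expr, groups, _ = make_dataset(rng, m=50, n1=5, n2=5)
        fit = fit_two_group(expr, groups)
        x1, x2 = expr.values[:, :5], expr.values[:, 5:]
        for j in range(50):
            beta = x2[j].mean() - x1[j].mean()
            s2 = (np.sum((x1[j] - x1[j].mean()) ** 2)
                  + np.sum((x2[j] - x2[j].mean()) ** 2)) / 8.0
            assert fit.beta_hat[j] == pytest.approx(beta, abs=1e-12)
            assert fit.s2[j] == pytest.approx(s2, abs=1e-12)
        assert fit.d == 8.0
        assert fit.unscaled_sd == pytest.approx(np.sqrt(1 / 5 + 1 / 5), abs=1e-15)

    def test_zero_variance_gene_rescued_by_shrinkage(self, rng):
        # heterogeneous gene variances keep the prior df finite
        expr, groups, _ = make_dataset(rng, m=30, n1=3, n2=3,
                                       sigmas=rng.uniform(0.3, 3.0, 30))
        values = expr.values.copy()
        values[0] = [1, 1, 1, 2, 2, 2]
        expr2 = ExpressionMatrix(values, expr.gene_ids, expr.sample_ids)
        fit = fit_two_group(expr2, groups)
        assert fit.beta_hat[0] == pytest.approx(1.0)
        assert fit.s2[0] == 0.0
        assert fit.d0 > 0
        d0, s0, d = fit.d0, fit.s0_sq, fit.d
        assert fit.s2_post[0] == pytest.approx(d0 * s0 / (d0 + d))
        assert fit.se_tilde[0] > 0

    def test_posterior_is_convex_combination(self):
        # d0=4, s0=1, d=4, s2=3 -> equal-weight average = 2
        assert (4 * 1.0 + 4 * 3.0) / 8.0 == 2.0
        rng = np.random.default_rng(3)
        expr, groups, _ = make_dataset(rng, m=80, n1=5, n2=5,
                                       sigmas=rng.uniform(0.5, 2.0, 80))
        fit = fit_two_group(expr, groups)
        lo = np.minimum(fit.s2, fit.s0_sq)
        hi = np.maximum(fit.s2, fit.s0_sq)
        assert np.all(fit.s2_post >= lo - 1e-12)
        assert np.all(fit.s2_post <= hi + 1e-12)
        assert fit.f_star == fit.d0 + fit.d

    def test_moderated_t_between_classical_and_prior_scaled_t(self, rng):
        expr, groups, _ = make_dataset(rng, m=60, n1=5, n2=5,
                                       sigmas=rng.uniform(0.5, 2.0, 60))
        fit = fit_two_group(expr, groups)
        ok = fit.s2 > 0
        t_classical = np.abs(fit.beta_hat / (np.sqrt(fit.s2) * fit.unscaled_sd))[ok]
        t_prior = np.abs(fit.beta_hat / (np.sqrt(fit.s0_sq) * fit.unscaled_sd))[ok]
        t_mod = np.abs(fit.t_mod)[ok]
        assert np.all(t_mod >= np.minimum(t_classical, t_prior) - 1e-10)
        assert np.all(t_mod <= np.maximum(t_classical, t_prior) + 1e-10)


class TestClassicalLimit:
    def test_d0_zero_reproduces_pooled_two_sample_t(self, rng):
        expr, groups, _ = make_dataset(rng, m=40, n1=6, n2=4,
                                       effects={0: 2.0, 1: -1.0})
        fit = fit_two_group(expr, groups, prior_df=0.0)
        res = stats.ttest_ind(expr.values[:, 6:], expr.values[:, :6],
                              axis=1, equal_var=True)
        np.testing.assert_allclose(fit.t_mod, res.statistic, atol=1e-10)
        np.testing.assert_allclose(fit.p_raw, res.pvalue, atol=1e-10)
        assert fit.f_star == 8.0

    def test_d0_zero_with_zero_variance_gene_rejected(self):
        values = np.ones((3, 6))
        values[1] = [0, 1, 2, 3, 4, 5]
        values[2] = [2, 1, 0, 5, 4, 3]
        expr = ExpressionMatrix(values, ("flat", "g1", "g2"), tuple("abcdef"))
        groups = GroupAssignment(np.array([1, 1, 1, 2, 2, 2]))
        with pytest.raises(ValueError, match="flat"):
            fit_two_group(expr, groups, prior_df=0.0)


class TestPriorEstimation:
    def test_equal_variances_give_infinite_prior_df(self):
        d0, s0 = estimate_prior(np.full(20, 3.5), d=8)
        assert np.isinf(d0)
        assert s0 == pytest.approx(3.5, rel=1e-10)

    def test_near_tie_takes_infinite_branch(self):
        d0, _ = estimate_prior(np.array([1.0, 1.0 + 1e-15]), d=8)
        assert np.isinf(d0)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="positive residual variance"):
            estimate_prior(np.zeros(10), d=4)

    def test_recovers_generating_scaled_f_parameters(self):
        # s2 ~ s0^2 * F(d, d0) is the marginal of the variance prior
        d, d0_true, s0_true = 4.0, 4.0, 2.0
        rng = np.random.default_rng(11)
        s2 = s0_true * stats.f.rvs(d, d0_true, size=5000, random_state=rng)
        d0, s0 = estimate_prior(s2, d)
        assert abs(d0 - d0_true) / d0_true < 0.25
        assert abs(s0 - s0_true) / s0_true < 0.10

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma
        for y in (0.01, 0.3, 1.0, 7.5, 300.0):
            x = float(polygamma(1, y))
            assert trigamma_inverse(x) == pytest.approx(y, rel=1e-6)


class TestModeratedPvalues:
    def test_zero_effect_gives_t_zero_p_one(self):
        t, p = moderated_t_pvalues(np.array([0.0]), np.array([0.5]), f_star=10.0)
        assert t[0] == 0.0
        assert p[0] == 1.0

    def test_t_quantile_anchor(self):
        # t = 2.228 on 10 df sits exactly at the two-sided 5% point
        _, p = moderated_t_pvalues(np.array([2.228]), np.array([1.0]), f_star=10.0)
        assert p[0] == pytest.approx(0.05, abs=5e-4)

    def test_infinite_df_uses_normal_tail(self):
        _, p = moderated_t_pvalues(np.array([1.959964]), np.array([1.0]), f_star=np.inf)
        assert p[0] == pytest.approx(0.05, abs=1e-5)

    def test_zero_se_rejected_with_gene_name(self):
        with pytest.raises(ValueError, match="gBad"):
            moderated_t_pvalues(np.array([1.0, 1.0]), np.array([1.0, 0.0]),
                                f_star=8.0, gene_ids=("gOk", "gBad"))


def test_null_pvalues_approximately_uniform():
    """Under a global null with independent genes, raw p-values are ~U(0,1)."""
    crit = 1.628 / np.sqrt(200)  # 1% KS critical value, n=200
    passed = 0
    for seed in range(100):
        rng = np.random.default_rng(900 + seed)
        expr, groups, _ = make_dataset(rng, m=200, n1=10, n2=10)
        fit = fit_two_group(expr, groups)
        ks = stats.kstest(fit.p_raw, "uniform").statistic
        passed += ks < crit
    assert passed >= 95


R_LIMMA_SCRIPT = textwrap.dedent("""
    suppressMessages(library(limma))
    x <- as.matrix(read.table("{expr}", header=TRUE, row.names=1, sep="\\t"))
    design <- cbind(1, rep(c(0, 1), times=c({n1}, {n2})))
    fit <- eBayes(lmFit(x, design))
    out <- data.frame(
      beta = fit$coefficients[, 2],
      se = sqrt(fit$s2.post) * sqrt(fit$cov.coefficients[2, 2]),
      d0 = fit$df.prior,
      s0sq = fit$s2.prior,
      t = fit$t[, 2],
      p = fit$p.value[, 2]
    )
    write.table(format(out, digits=15), "{out}", sep="\\t", quote=FALSE)
""")


def test_fit_matches_limma_reference(tmp_path, rng):
    """The whole fit agrees with the limma empirical-Bayes reference."""
    pd = pytest.importorskip("pandas")
    expr, groups, _ = make_dataset(rng, m=60, n1=5, n2=5,
                                   sigmas=rng.uniform(0.5, 2.0, 60),
                                   effects={0: 1.5, 1: -2.0})
    expr_path = tmp_path / "expr.tsv"
    pd.DataFrame(expr.values, index=list(expr.gene_ids),
                 columns=list(expr.sample_ids)).to_csv(
        expr_path, sep="\t", float_format="%.15g", index_label="gene")
    out_path = tmp_path / "limma.tsv"
    script = R_LIMMA_SCRIPT.format(expr=expr_path, out=out_path, n1=5, n2=5)
    res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert res.returncode == 0, f"Rscript failed: {res.stderr[-2000:]}"
    ref = pd.read_csv(out_path, sep="\t")
    fit = fit_two_group(expr, groups)
    np.testing.assert_allclose(fit.beta_hat, ref["beta"], rtol=1e-10)
    np.testing.assert_allclose(fit.se_tilde, ref["se"], rtol=1e-5)
    assert fit.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
    assert fit.s0_sq == pytest.approx(ref["s0sq"].iloc[0], rel=1e-4)
    np.testing.assert_allclose(fit.t_mod, ref["t"], rtol=1e-5)
    np.testing.assert_allclose(fit.p_raw, ref["p"], rtol=1e-4)
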