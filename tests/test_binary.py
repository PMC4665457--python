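"""Conjugate posterior sampling and BP/BN accuracy for paired binary tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from veribayes import (
    BinaryVerificationTable,
    PriorSpec,
    accuracy_from_parameters,
    binary_accuracy_analysis,
    sample_binary_posterior,
)
from _oracles import plugin_parameters

SEED = 1_234


class TestSampler:
    def test_theta_mean_is_dirichlet_mean(self, table2):
        d = sample_binary_posterior(table2, n_draws=40_000, seed=SEED)
        assert abs(d.theta[:, 1, 1].mean() - 25 / 116) < 0.005

    def test_marginal_phi_mean(self, table2):
        # phi_1. ~ beta(s1.=26, r1.=13)
        d = sample_binary_posterior(table2, n_draws=40_000, seed=SEED)
        assert abs(d.phi_marg1[:, 1].mean() - 26 / 39) < 0.005

    def test_symmetric_cell_is_centred(self):
        t = BinaryVerificationTable(
            s=[[5, 5], [5, 10]], r=[[5, 5], [5, 10]], u=np.zeros((2, 2), int)
        )
        d = sample_binary_posterior(t, n_draws=40_000, seed=SEED)
        assert abs(d.phi[:, 1, 1].mean() - 0.5) < 0.005

    def test_reproducible(self, table2):
        a = sample_binary_posterior(table2, n_draws=500, seed=42)
        b = sample_binary_posterior(table2, n_draws=500, seed=42)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.theta, b.theta)

    def test_theta_sums_to_one(self, table2):
        d = sample_binary_posterior(table2, n_draws=1_000, seed=SEED)
        assert np.allclose(d.theta.sum(axis=(1, 2)), 1.0, atol=1e-12)

    def test_derived_marginals_are_functions_of_joint(self, table2):
        d = sample_binary_posterior(table2, n_draws=1_000, seed=SEED, marginals="derived")
        expect = (d.phi * d.theta).sum(axis=2) / d.theta.sum(axis=2)
        assert np.allclose(d.phi_marg1, expect)

    def test_scipy_cross_check(self, table2):
        """Independent sampler path (scipy.stats) agrees within MC error."""
        from scipy import stats

        d = sample_binary_posterior(table2, n_draws=50_000, seed=SEED)
        rng = np.random.default_rng(SEED + 1)
        theta11 = stats.dirichlet.rvs([31, 31, 29, 25], size=50_000, random_state=rng)[:, 3]
        phi11 = stats.beta.rvs(14, 4, size=50_000, random_state=rng)
        for mine, other in [(d.theta[:, 1, 1], theta11), (d.phi[:, 1, 1], phi11)]:
            se = np.hypot(mine.std() / np.sqrt(mine.size), other.std() / np.sqrt(other.size))
            assert abs(mine.mean() - other.mean()) < 4 * se


class TestAccuracyFromParameters:
    def test_symmetric_parameters(self):
        phi = np.full((2, 2), 0.5)
        theta = np.full((2, 2), 0.25)
        marg = np.array([0.5, 0.5])
        acc = accuracy_from_parameters(phi, theta, marg, marg)
        assert acc.pd == pytest.approx(0.5)
        assert acc.tpfbp == pytest.approx(0.75)
        assert acc.fpfbp == pytest.approx(0.75)
        assert acc.tpfbn == pytest.approx(0.25)
        assert acc.fpfbn == pytest.approx(0.25)

    def test_plugin_oracle_lung_study(self, table2):
        """Direct arithmetic on the posterior-mean parameters."""
        acc = accuracy_from_parameters(*plugin_parameters(table2))
        assert acc.tpfbn == pytest.approx(0.3660, abs=5e-5)
        assert acc.tpfbp == pytest.approx(0.9166, abs=5e-5)
        assert acc.fpfbn == pytest.approx(0.0884, abs=5e-5)
        assert acc.fpfbp == pytest.approx(0.5774, abs=5e-5)
        assert acc.tpf1 == pytest.approx(0.6754, abs=5e-5)

    def test_complete_verification_reduces_to_naive(self):
        """With everyone verified, the BN plug-in TPF is s11 / total diseased."""
        t = BinaryVerificationTable(
            s=[[3, 9], [12, 14]], r=[[18, 13], [9, 4]], u=np.zeros((2, 2), int)
        )
        phi, theta, m1, m2 = plugin_parameters(t)
        acc = accuracy_from_parameters(phi, theta, m1, m2)
        assert acc.tpfbn == pytest.approx(14 / 38)

    @given(
        p=st.floats(0.05, 0.95),
        t11=st.floats(0.05, 0.4),
        t10=st.floats(0.05, 0.4),
        t01=st.floats(0.05, 0.1),
    )
    def test_uninformative_test_identity(self, p, t11, t10, t01):
        """If disease is independent of test 1, its tpf and fpf equal theta_1."""
        t00 = 1.0 - t11 - t10 - t01
        theta = np.array([[t00, t01], [t10, t11]])
        phi = np.full((2, 2), p)
        marg = np.array([p, p])
        acc = accuracy_from_parameters(phi, theta, marg, marg)
        theta1 = t11 + t10
        assert acc.tpf1 == pytest.approx(theta1, rel=1e-9)
        assert acc.fpf1 == pytest.approx(theta1, rel=1e-9)

    def test_degenerate_prevalence_rejected(self):
        phi = np.ones((2, 2))
        theta = np.full((2, 2), 0.25)
        marg = np.ones(2)
        with pytest.raises(ValueError, match="prevalence"):
            accuracy_from_parameters(phi, theta, marg, marg)

    def test_per_draw_invariants(self, table2):
        d = sample_binary_posterior(table2, n_draws=20_000, seed=SEED)
        acc = accuracy_from_parameters(d.phi, d.theta, d.phi_marg1, d.phi_marg2)
        for q in ("tpf1", "fpf1", "tpf2", "fpf2", "tpfbp", "fpfbp", "tpfbn", "fpfbn"):
            x = getattr(acc, q)
            assert np.all((x >= 0) & (x <= 1)), q
        # BP adds non-negative mass to the BN cell, every draw
        assert np.all(acc.tpfbp >= acc.tpfbn)
        assert np.all(acc.fpfbp >= acc.fpfbn)


class TestAnalysis:
    def test_uniform_prior_equals_incremented_table(self, table2):
        bumped = BinaryVerificationTable(s=table2.s + 1, r=table2.r + 1, u=table2.u - 1)
        a = binary_accuracy_analysis(table2, PriorSpec(kind="uniform"), 2_000, seed=9)
        b = binary_accuracy_analysis(bumped, PriorSpec(), 2_000, seed=9)
        for q in a:
            assert a[q].mean == b[q].mean

    def test_posterior_means_near_plugin(self, table2):
        """Ratio-of-means plug-in tracks mean-of-ratios to O(1/n)."""
        summ = binary_accuracy_analysis(table2, PriorSpec(), 45_000, seed=SEED)
        acc = accuracy_from_parameters(*plugin_parameters(table2))
        for q in ("tpf1", "tpf2", "tpfbp", "fpfbp", "tpfbn", "fpfbn"):
            assert abs(summ[q].mean - float(getattr(acc, q))) < 0.01, q
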