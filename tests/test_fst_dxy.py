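"""2D-SFS EM, Hudson/Reynolds FST components, dxy."""

import numpy as np
import pytest
from scipy.optimize import minimize

from glpop.fst_dxy import (dxy, estimate_sfs2d, fst_components, global_fst,
                           window_fst)
from glpop.gl_freq import genotype_likelihoods
from glpop.sfs_div import saf
from glpop.synthdata import (PopulationModel, SimDesign,
                             draw_population_frequencies, simulate_read_counts)


def _point_saf(js, n_classes):
    A = np.zeros((len(js), n_classes))
    A[np.arange(len(js)), js] = 1.0
    return A


def _certain_components(j1, j2, n1, n2, estimator="hudson"):
    """FST components for sites with certain allele counts (point SAFs)."""
    A = _point_saf(j1, 2 * n1 + 1)
    B = _point_saf(j2, 2 * n2 + 1)
    gamma = estimate_sfs2d(A, B)
    chrom = np.array(["c"] * len(j1), dtype=object)
    pos = np.arange(1, len(j1) + 1)
    return fst_components(A, B, gamma, n1, n2, chrom, pos, estimator=estimator)


class TestEstimateSfs2d:
    def test_point_mass(self):
        A = _point_saf([0] * 30, 5)
        B = _point_saf([0] * 30, 7)
        gamma = estimate_sfs2d(A, B)
        assert gamma[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            estimate_sfs2d(np.ones((3, 5)), np.ones((4, 5)))

    def test_matches_direct_likelihood_maximization(self):
        """Tiny instance: EM log-likelihood matches a softmax-parameterized
        scipy maximization of the same mixture likelihood."""
        rng = np.random.default_rng(23)
        A = rng.random((6, 3))
        B = rng.random((6, 3))
        gamma, ll = estimate_sfs2d(A, B, return_loglik=True)

        def negll(theta):
            g = np.exp(theta - theta.max())
            g = (g / g.sum()).reshape(3, 3)
            return -np.log(np.einsum("sj,jk,sk->s", A, g, B)).sum()

        best = min(
            (minimize(negll, rng.standard_normal(9), method="Nelder-Mead",
                      options={"maxiter": 20_000, "xatol": 1e-10, "fatol": 1e-12})
             for _ in range(4)),
            key=lambda r: r.fun,
        )
        em_ll = np.log(np.einsum("sj,jk,sk->s", A, gamma, B)).sum()
        assert em_ll >= -best.fun - 1e-6

    def test_likelihood_monotone(self):
        rng = np.random.default_rng(29)
        A, B = rng.random((200, 6)), rng.random((200, 8))
        gamma, ll = estimate_sfs2d(A, B, return_loglik=True)
        assert (np.diff(ll) >= -1e-9).all()
        assert gamma.sum() == pytest.approx(1.0, abs=1e-12)

    def test_simulation_recovery(self):
        """Spectrum simulated from a known joint prior is recovered with
        small total-variation error."""
        rng = np.random.default_rng(37)
        n1 = n2 = 4
        S = 8000
        # joint prior from correlated frequencies
        p = rng.beta(0.5, 0.5, size=S)
        j1 = rng.binomial(2 * n1, p)
        j2 = rng.binomial(2 * n2, p)
        gamma_star = np.zeros((2 * n1 + 1, 2 * n2 + 1))
        np.add.at(gamma_star, (j1, j2), 1.0)
        gamma_star /= S
        # high-depth data: point SAFs -> EM should match the empirical joint
        A = _point_saf(j1, 2 * n1 + 1)
        B = _point_saf(j2, 2 * n2 + 1)
        gamma = estimate_sfs2d(A, B)
        assert 0.5 * np.abs(gamma - gamma_star).sum() < 0.03


class TestFstComponents:
    def test_fixed_opposite_alleles_fst_one(self):
        comp = _certain_components([0, 0], [20, 20], 10, 10)
        np.testing.assert_allclose(comp.alpha, 1.0, atol=1e-9)
        np.testing.assert_allclose(comp.beta, 1.0, atol=1e-9)
        assert global_fst(comp) == pytest.approx(1.0)

    def test_equal_intermediate_frequency_closed_form(self):
        # p1 = p2 = 0.5 with 2N = 50: alpha = -2(0.25/49), beta = 0.5
        comp = _certain_components([25], [25], 25, 25)
        assert comp.alpha[0] == pytest.approx(-2 * 0.25 / 49, abs=1e-12)
        assert comp.beta[0] == pytest.approx(0.5, abs=1e-12)

    def test_reynolds_fixed_opposite(self):
        comp = _certain_components([0, 0], [20, 20], 10, 10,
                                   estimator="reynolds")
        assert global_fst(comp) == pytest.approx(1.0)
        assert comp.estimator == "reynolds"

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            _certain_components([0], [2], 1, 1)

    def test_balding_nichols_recovery_small(self, small_cohort):
        counts, truth, glm = small_cohort
        g1, g2 = glm.gl[:, :12, :], glm.gl[:, 12:, :]
        A, B = saf(g1), saf(g2)
        gamma = estimate_sfs2d(A, B)
        comp = fst_components(A, B, gamma, 12, 12, glm.chrom, glm.pos)
        assert global_fst(comp) == pytest.approx(0.1, abs=0.03)


class TestWindowFst:
    def test_uniform_sites_window_equals_site(self):
        comp = _certain_components([10] * 5, [40] * 5, 25, 25)
        df = window_fst(comp, window=100_000)
        site_fst = comp.alpha[0] / comp.beta[0]
        assert df["fst"].iloc[0] == pytest.approx(site_fst)

    def test_ratio_of_sums_differs_from_mean_of_ratios(self):
        """Direct 3-site computation: a high-ratio site with a small
        denominator (rare-allele difference) is down-weighted by the
        ratio-of-sums, so it falls below the mean of per-site ratios."""
        comp = _certain_components([0, 25, 25], [5, 25, 25], 25, 25)
        ratio_of_sums = comp.alpha.sum() / comp.beta.sum()
        mean_of_ratios = (comp.alpha / comp.beta).mean()
        assert ratio_of_sums < mean_of_ratios

    def test_concatenation_invariance(self):
        comp = _certain_components([0, 10, 40, 25], [5, 30, 10, 25], 25, 25)
        pooled = global_fst(comp)
        a = comp.alpha.sum()
        b = comp.beta.sum()
        assert pooled == pytest.approx(a / b)
        # splitting into two halves and pooling the sums is identical
        a2 = comp.alpha[:2].sum() + comp.alpha[2:].sum()
        b2 = comp.beta[:2].sum() + comp.beta[2:].sum()
        assert pooled == pytest.approx(a2 / b2)

    def test_window_fst_bounded(self, small_cohort):
        _, _, glm = small_cohort
        g1, g2 = glm.gl[:, :12, :], glm.gl[:, 12:, :]
        A, B = saf(g1), saf(g2)
        gamma = estimate_sfs2d(A, B)
        comp = fst_components(A, B, gamma, 12, 12, glm.chrom, glm.pos)
        df = window_fst(comp)
        assert (df["fst"] <= 1.0).all()


class TestDxy:
    def test_fixed_opposite_is_one(self):
        A = _point_saf([0], 21)
        B = _point_saf([20], 21)
        gamma = estimate_sfs2d(A, B)
        assert dxy(A, B, gamma, 10, 10)[0] == pytest.approx(1.0)

    def test_half_half_is_half(self):
        A = _point_saf([25], 51)
        B = _point_saf([25], 51)
        gamma = estimate_sfs2d(A, B)
        assert dxy(A, B, gamma, 25, 25)[0] == pytest.approx(0.5)

    def test_symmetric_and_non_negative(self, small_cohort):
        _, _, glm = small_cohort
        g1, g2 = glm.gl[:, :12, :], glm.gl[:, 12:, :]
        A, B = saf(g1), saf(g2)
        gamma = estimate_sfs2d(A, B)
        d12 = dxy(A, B, gamma, 12, 12)
        d21 = dxy(B, A, gamma.T, 12, 12)
        np.testing.assert_allclose(d12, d21, atol=1e-10)
        assert (d12 >= 0).all()

    def test_merged_population_dxy_approaches_heterozygosity(self):
        """At c = 0 the two 'populations' are one: window dxy matches the
        realized heterozygosity of the shared frequencies."""
        model = PopulationModel(2, 0.0, 2000, chrom_lengths={"chr1": 100_000})
        truth = draw_population_frequencies(model, 41)
        counts, _ = simulate_read_counts(truth, SimDesign(12, 4.0, 0.005, 41))
        glm = genotype_likelihoods(counts, 0.005)
        g1, g2 = glm.gl[:, :12, :], glm.gl[:, 12:, :]
        A, B = saf(g1), saf(g2)
        gamma = estimate_sfs2d(A, B)
        per_site = dxy(A, B, gamma, 12, 12)
        h = 2 * truth.freqs[:, 0] * (1 - truth.freqs[:, 0])
        assert per_site.mean() == pytest.approx(h.mean(), rel=0.05)


def test_self_fst_centred_on_zero():
    """Split-half of one population: the Hudson ratio-of-sums has no
    systematic deviation from 0 across replicates."""
    vals = []
    for rep in range(50):
        model = PopulationModel(1, 0.0, 600, chrom_lengths={"chr1": 100_000})
        truth = draw_population_frequencies(model, 100 + rep)
        counts, _ = simulate_read_counts(truth, SimDesign(20, 8.0, 0.005, 100 + rep))
        glm = genotype_likelihoods(counts, 0.005)
        g1, g2 = glm.gl[:, :10, :], glm.gl[:, 10:, :]
        A, B = saf(g1), saf(g2)
        gamma = estimate_sfs2d(A, B)
        comp = fst_components(A, B, gamma, 10, 10, glm.chrom, glm.pos)
        vals.append(global_fst(comp))
    assert abs(np.mean(vals)) < 0.01
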