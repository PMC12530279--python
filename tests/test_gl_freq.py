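"""Genotype likelihoods, allele-frequency EM, SNP test, site filters."""

import numpy as np
import pytest

from glpop.containers import ReadCountMatrix
from glpop.gl_freq import (SiteFilterConfig, em_allele_frequency,
                           genotype_likelihoods, loglik_at, site_filters,
                           snp_test)
from glpop.synthdata import (PopulationModel, SimDesign,
                             draw_population_frequencies, simulate_read_counts)


def _counts(nmaj, nmin):
    nmaj = np.atleast_2d(nmaj)
    nmin = np.atleast_2d(nmin)
    s = nmaj.shape[0]
    return ReadCountMatrix(
        np.array([f"c{i}" for i in range(s)], dtype=object),
        np.arange(1, s + 1), np.array(["A"] * s, dtype=object),
        np.array(["C"] * s, dtype=object), nmaj, nmin)


class TestGenotypeLikelihoods:
    def test_no_reads_is_flat(self):
        glm = genotype_likelihoods(_counts([[0]], [[0]]), 0.01)
        assert np.array_equal(glm.gl[0, 0], [1.0, 1.0, 1.0])

    def test_single_major_read_values(self):
        # direct evaluation of the emission product at eps = 0.01
        glm = genotype_likelihoods(_counts([[1]], [[0]]), 0.01)
        unscaled = np.array([0.99, 0.5 * 0.99 + 0.5 * 0.01 / 3, 0.01 / 3])
        np.testing.assert_allclose(glm.gl[0, 0], unscaled / unscaled.max(),
                                   rtol=1e-12)
        np.testing.assert_allclose(glm.gl[0, 0],
                                   [1.0, 0.501684, 0.003367], atol=1e-6)

    def test_two_minor_reads_likelihood_ratio(self):
        glm = genotype_likelihoods(_counts([[0]], [[2]]), 0.01)
        ratio = glm.gl[0, 0, 2] / glm.gl[0, 0, 0]
        assert ratio == pytest.approx((0.99 / (0.01 / 3)) ** 2, rel=1e-9)

    def test_eps_out_of_range(self):
        with pytest.raises(ValueError):
            genotype_likelihoods(_counts([[1]], [[0]]), 0.0)
        with pytest.raises(ValueError):
            genotype_likelihoods(_counts([[1]], [[0]]), 0.8)

    def test_max_scaled(self):
        rng = np.random.default_rng(0)
        c = _counts(rng.integers(0, 6, (20, 8)), rng.integers(0, 6, (20, 8)))
        glm = genotype_likelihoods(c, 0.005)
        np.testing.assert_allclose(glm.gl.max(axis=2), 1.0)


def _certain(genos):
    """Likelihood triples for certain genotypes."""
    gl = np.zeros((1, len(genos), 3))
    for i, g in enumerate(genos):
        gl[0, i, g] = 1.0
    return gl


class TestEmAlleleFrequency:
    def test_certain_genotypes_mean_dosage(self):
        assert em_allele_frequency(_certain([0, 1, 2])).fhat[0] == pytest.approx(0.5, abs=1e-9)
        assert em_allele_frequency(_certain([1, 2])).fhat[0] == pytest.approx(0.75, abs=1e-9)

    def test_all_flat_is_noninformative_fixed_point(self):
        res = em_allele_frequency(np.ones((1, 4, 3)))
        assert res.noninformative[0] and res.converged[0]
        assert res.fhat[0] == pytest.approx(0.1)

    def test_matches_grid_search_oracle(self):
        """EM equals a dense grid-search maximizer of the marginal
        likelihood (step 1e-5) on a simulated low-coverage site."""
        model = PopulationModel(1, 0.0, 1)
        truth = draw_population_frequencies(model, 8)
        truth.freqs[:] = 0.3
        counts, _ = simulate_read_counts(truth, SimDesign(20, 2.0, 0.01, 8))
        gl = genotype_likelihoods(counts, 0.01).gl
        fhat = em_allele_frequency(gl).fhat[0]
        grid = np.linspace(0.0, 1.0, 100_001)
        ll = np.array([loglik_at(gl, f)[0] for f in grid[::100]])
        coarse = grid[::100][np.argmax(ll)]
        fine = np.clip(np.linspace(coarse - 0.01, coarse + 0.01, 2001), 0, 1)
        llf = np.array([loglik_at(gl, f)[0] for f in fine])
        assert abs(fhat - fine[np.argmax(llf)]) < 1e-4

    def test_grid_oracle_many_random_instances(self):
        """100 random simulated sites: EM within 1e-4 of the grid maximizer."""
        rng = np.random.default_rng(21)
        model = PopulationModel(1, 0.0, 100)
        truth = draw_population_frequencies(model, 21)
        truth.freqs[:, 0] = rng.uniform(0.05, 0.95, size=100)
        counts, _ = simulate_read_counts(truth, SimDesign(8, 2.0, 0.01, 21))
        gls = genotype_likelihoods(counts, 0.01).gl
        fhat = em_allele_frequency(gls).fhat
        grid = np.linspace(0, 1, 100_001)
        prior = np.stack([(1 - grid) ** 2, 2 * grid * (1 - grid), grid**2], axis=1)
        # (sites, grid): sum_i log(gl_i . prior_f)
        with np.errstate(divide="ignore"):
            ll = np.log(np.einsum("sng,fg->snf", gls, prior)).sum(axis=1)
        best = grid[np.argmax(ll, axis=1)]
        assert np.abs(fhat - best).max() < 1e-4

    def test_loglik_monotone_over_iterations(self):
        rng = np.random.default_rng(3)
        gl = rng.random((30, 10, 3))
        gl /= gl.max(axis=2, keepdims=True)
        for s in range(gl.shape[0]):
            f = 0.1
            prev = loglik_at(gl[s:s + 1], f)[0]
            for _ in range(60):
                res = em_allele_frequency(gl[s:s + 1], f0=f, max_iter=1)
                f = res.fhat[0]
                cur = loglik_at(gl[s:s + 1], f)[0]
                assert cur >= prev - 1e-10
                prev = cur

    def test_major_minor_relabel_symmetry(self):
        model = PopulationModel(1, 0.0, 200)
        truth = draw_population_frequencies(model, 5)
        counts, _ = simulate_read_counts(truth, SimDesign(12, 2.0, 0.01, 5))
        gl = genotype_likelihoods(counts, 0.01).gl
        f1 = em_allele_frequency(gl).fhat
        f2 = em_allele_frequency(gl[:, :, ::-1]).fhat
        np.testing.assert_allclose(f1, 1.0 - f2, atol=1e-6)

    def test_unbiased_at_study_depth(self):
        """At 1.08x depth and N=30 the estimator is approximately unbiased."""
        for f_true in (0.1, 0.3, 0.5):
            model = PopulationModel(1, 0.0, 2000)
            truth = draw_population_frequencies(model, 17)
            truth.freqs[:] = f_true
            counts, _ = simulate_read_counts(truth, SimDesign(30, 1.08, 0.005, 17))
            gl = genotype_likelihoods(counts, 0.005).gl
            fhat = em_allele_frequency(gl).fhat
            assert abs(fhat.mean() - f_true) < 0.01


class TestSnpTest:
    def test_no_data_gives_p_one(self):
        gl = np.ones((1, 5, 3))
        res = em_allele_frequency(gl)
        lam, p = snp_test(gl, res.fhat)
        assert lam[0] == 0.0 and p[0] == 1.0

    def test_statistic_grows_with_minor_reads(self):
        lams = []
        for n_minor in (1, 2, 4, 8):
            gl = genotype_likelihoods(_counts([[0]], [[n_minor]]), 0.01).gl
            res = em_allele_frequency(gl)
            lam, _ = snp_test(gl, res.fhat)
            lams.append(lam[0])
        assert all(b > a for a, b in zip(lams, lams[1:]))

    def test_monomorphic_sites_rarely_called(self):
        """5000 truly monomorphic sites: the fraction passing p < 1e-6 is
        essentially zero (the chi-square(1) boundary test is conservative)."""
        model = PopulationModel(1, 0.0, 5000)
        truth = draw_population_frequencies(model, 23)
        truth.freqs[:] = 0.0
        counts, _ = simulate_read_counts(truth, SimDesign(20, 1.0, 0.005, 23))
        gl = genotype_likelihoods(counts, 0.005).gl
        res = em_allele_frequency(gl)
        _, p = snp_test(gl, res.fhat)
        assert (p < 1e-6).mean() <= 1e-5


class TestSiteFilters:
    def test_maf_boundary_is_strict(self):
        cfg = SiteFilterConfig()
        # build a frequency result with MAF exactly at the cutoff
        gl = _certain([0, 1, 0, 0, 0, 0, 0, 0, 0, 0])  # 10 inds, dosage sum 1
        res = em_allele_frequency(gl)
        assert res.maf[0] == pytest.approx(0.05, abs=1e-9)
        c = _counts(np.ones((1, 10), dtype=int), np.zeros((1, 10), dtype=int))
        rep = site_filters(c, res, np.array([1e-9]), cfg)
        assert not rep.mask[0] and rep.fail_maf == 1

    def test_empty_input(self):
        c = _counts(np.zeros((0, 3), dtype=int), np.zeros((0, 3), dtype=int))
        res = em_allele_frequency(np.ones((0, 3, 3)))
        rep = site_filters(c, res, np.zeros(0))
        assert rep.mask.size == 0

    def test_hand_constructed_fixture_passes_exactly_four(self):
        """10 sites engineered so exactly 4 clear every filter, verified by
        per-criterion enumeration."""
        rng = np.random.default_rng(2)
        n_ind = 12
        nmaj = np.full((10, n_ind), 2, dtype=int)
        nmin = np.full((10, n_ind), 2, dtype=int)
        # sites 0,1: depth blow-up / dropout -> depth filter fails
        nmaj[0] = 10
        nmin[0] = 10
        nmaj[1] = 0
        nmin[1] = 0
        # site 2: monomorphic (MAF filter + SNP test fail)
        nmin[2] = 0
        nmaj[2] = 4
        # site 3: rare minor allele, MAF below cutoff
        nmin[3] = 0
        nmaj[3] = 4
        nmin[3, 0] = 1
        nmaj[3, 0] = 3
        # site 4: only 5 individuals with data
        nmaj[4] = 0
        nmin[4] = 0
        nmaj[4, :5] = 4
        nmin[4, :5] = 4
        # site 5: depth blow-up on the minor side
        nmin[5] += 10
        # sites 6..9 balanced heterozygous-ish: the four intended passes
        counts = _counts(nmaj, nmin)
        gl = genotype_likelihoods(counts, 0.01).gl
        res = em_allele_frequency(gl)
        _, p = snp_test(gl, res.fhat)
        cfg = SiteFilterConfig(min_individuals=10)
        rep = site_filters(counts, res, p, cfg)
        total = counts.depth.sum(axis=1)
        mean = total.mean()
        expect = ((total >= 0.5 * mean) & (total <= 1.5 * mean)
                  & (res.maf > 0.05) & (p < 1e-6)
                  & ((counts.depth > 0).sum(axis=1) >= 10))
        assert np.array_equal(rep.mask, expect)
        assert rep.mask[6:].all() and not rep.mask[:6].any()
        assert rep.mask.sum() == 4
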