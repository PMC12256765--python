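"""Marginal log-likelihood assembly against brute-force integration."""

from collections import defaultdict

import numpy as np
import pytest

from hnbseq import (
    LikelihoodConfig,
    ParamSet,
    SimDesign,
    marginal_loglik_2l,
    marginal_loglik_3l,
    mvnb_logpmf,
    simulate_gene,
)
from hnbseq.likelihood import _loglik_2l_samplewise


from _oracles import grid_loglik_2l, grid_loglik_3l


@pytest.fixture(scope="module")
def toy_gene_2l():
    params = ParamSet(beta=[-15.2, 0.6, 0.4], phi=0.7, sigma_s=0.4)
    design = SimDesign(
        params=params,
        levels="two",
        n_patients=2,
        visits_per_patient=2,
        n_controls=1,
        n_exons=3,
        seed=5,
    )
    return simulate_gene(design), params


@pytest.fixture(scope="module")
def toy_gene_3l():
    params = ParamSet(beta=[-15.0, 0.5, 0.3], phi=0.8, sigma_s=0.3, sigma_i=0.25)
    design = SimDesign(
        params=params,
        levels="three",
        n_patients=2,
        visits_per_patient=2,
        n_controls=0,
        n_exons=2,
        seed=11,
    )
    return simulate_gene(design), params


class TestTwoLevel:
    def test_sigma_zero_is_exact_pointmass(self, toy_gene_2l):
        gene, params = toy_gene_2l
        p0 = ParamSet(params.beta, params.phi, 0.0)
        expected = sum(
            mvnb_logpmf(y, T, float(x @ p0.beta), p0.phi)
            for _, y, T, x in gene.sample_groups()
        )
        # same quantity, different summation order: agreement to float
        # accumulation error
        assert marginal_loglik_2l(gene, p0) == pytest.approx(expected, rel=1e-12)

    def test_laplace_equals_single_node_aghq(self, study_design_gene):
        params = ParamSet(beta=[-15.4, 0.75, 0.5, 0.32], phi=0.51, sigma_s=0.32)
        lap = marginal_loglik_2l(
            study_design_gene, params, LikelihoodConfig(method="laplace")
        )
        one = marginal_loglik_2l(
            study_design_gene, params, LikelihoodConfig(n_nodes=1)
        )
        assert lap == pytest.approx(one, abs=1e-12)

    def test_matches_grid_oracle(self, toy_gene_2l):
        gene, params = toy_gene_2l
        ll = marginal_loglik_2l(gene, params, LikelihoodConfig(n_nodes=50))
        assert ll == pytest.approx(grid_loglik_2l(gene, params), abs=1e-6)

    def test_vectorized_path_matches_generic_quadrature_path(self, toy_gene_2l):
        gene, params = toy_gene_2l
        cfg = LikelihoodConfig(n_nodes=10)
        assert marginal_loglik_2l(gene, params, cfg) == pytest.approx(
            _loglik_2l_samplewise(gene, params, cfg), abs=1e-6
        )

    def test_rejects_three_level_params(self, toy_gene_2l):
        gene, _ = toy_gene_2l
        p3 = ParamSet([-15.2, 0.6, 0.4], 0.7, 0.3, 0.2)
        with pytest.raises(ValueError):
            marginal_loglik_2l(gene, p3)

    def test_node_convergence(self, study_design_gene):
        params = ParamSet(beta=[-15.4, 0.75, 0.5, 0.32], phi=0.51, sigma_s=0.32)
        ll = {
            n: marginal_loglik_2l(study_design_gene, params, LikelihoodConfig(n_nodes=n))
            for n in (1, 5, 10, 75)
        }
        errs = [abs(ll[n] - ll[75]) for n in (1, 5, 10)]
        assert errs[0] >= errs[1] >= errs[2]
        assert abs(ll[10] - ll[75]) < 1e-4


class TestThreeLevel:
    def test_collapses_to_two_level_when_sigma_i_zero(self, toy_gene_3l):
        gene, params = toy_gene_3l
        p3 = ParamSet(params.beta, params.phi, params.sigma_s, 0.0)
        p2 = ParamSet(params.beta, params.phi, params.sigma_s)
        cfg3 = LikelihoodConfig(n_nodes=10, model_levels="three")
        assert marginal_loglik_3l(gene, p3, cfg3) == pytest.approx(
            marginal_loglik_2l(gene, p2, LikelihoodConfig(n_nodes=10)), abs=1e-8
        )

    def test_single_sample_individuals_symmetric_in_sd_split(self):
        # with one sample per individual only b_i + b_is enters, so
        # swapping (sigma_i, sigma_s) leaves the likelihood unchanged
        params = ParamSet(beta=[-15.0, 0.5, 0.3], phi=0.8, sigma_s=0.3, sigma_i=0.25)
        design = SimDesign(
            params=params,
            levels="three",
            n_patients=0,
            visits_per_patient=2,
            n_controls=5,
            n_exons=3,
            seed=3,
        )
        gene = simulate_gene(design)
        cfg = LikelihoodConfig(n_nodes=25, model_levels="three")
        pa = ParamSet(params.beta, params.phi, 0.1, 0.35)
        pb = ParamSet(params.beta, params.phi, 0.35, 0.1)
        assert marginal_loglik_3l(gene, pa, cfg) == pytest.approx(
            marginal_loglik_3l(gene, pb, cfg), abs=1e-7
        )

    def test_matches_2d_grid_oracle(self, toy_gene_3l):
        gene, params = toy_gene_3l
        ll = marginal_loglik_3l(gene, params, LikelihoodConfig(n_nodes=25,
                                                              model_levels="three"))
        assert ll == pytest.approx(grid_loglik_3l(gene, params), abs=1e-5)

    def test_requires_sigma_i(self, toy_gene_3l):
        gene, _ = toy_gene_3l
        with pytest.raises(ValueError):
            marginal_loglik_3l(gene, ParamSet([-15.0, 0.5, 0.3], 0.8, 0.3))
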