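"""Closed-form pieces: MVNB pmf, marginal moments, correlation calculus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hnbseq import (
    GeneData,
    ParamSet,
    SimDesign,
    between_sample_cor,
    marginal_mean,
    marginal_variance,
    mvnb_logpmf,
    simulate_gene,
    within_sample_cor,
)

from _oracles import gamma_mixture_logpmf


class TestMvnbLogpmf:
    def test_zero_count_closed_form(self):
        # J=1, y=0: pmf is Q^{-phi} = (1 + T e^eta / phi)^{-phi}
        assert mvnb_logpmf([0], [1.0], 0.0, 1.0) == pytest.approx(np.log(0.5))

    def test_matches_gamma_integration_oracle(self):
        assert mvnb_logpmf([3, 1], [1.0, 2.0], 0.5, 0.7) == pytest.approx(
            gamma_mixture_logpmf([3, 1], [1.0, 2.0], 0.5, 0.7), abs=1e-8
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_on_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        J = rng.integers(1, 5)
        y = rng.integers(0, 21, size=J)
        T = rng.uniform(0.2, 3.0, size=J)
        eta = rng.uniform(-1.0, 1.0)
        phi = rng.uniform(0.3, 5.0)
        assert mvnb_logpmf(y, T, eta, phi) == pytest.approx(
            gamma_mixture_logpmf(y, T, eta, phi), abs=1e-8
        )

    def test_normalizes_over_count_space(self):
        T, eta, phi = np.array([1.0, 2.0]), -0.5, 0.7
        tot = sum(
            np.exp(mvnb_logpmf([y1, y2], T, eta, phi))
            for y1 in range(61)
            for y2 in range(61 - y1)
        )
        assert tot == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "y,T,eta,phi",
        [
            ([-1], [1.0], 0.0, 1.0),
            ([0.5], [1.0], 0.0, 1.0),
            ([1], [0.0], 0.0, 1.0),
            ([1], [1.0], 0.0, 0.0),
            ([1], [1.0], 0.0, -2.0),
        ],
    )
    def test_rejects_invalid_inputs(self, y, T, eta, phi):
        with pytest.raises(ValueError):
            mvnb_logpmf(y, T, eta, phi)


class TestMarginalMoments:
    def test_unit_factors(self):
        p = ParamSet(beta=[0.0], phi=1.0, sigma_s=0.0)
        assert marginal_mean(1.0, [1.0], p) == pytest.approx(1.0)

    def test_linear_in_exposure(self, three_level_est, control_x):
        m1 = marginal_mean(1.0e6, control_x, three_level_est)
        assert marginal_mean(2.0e6, control_x, three_level_est) == pytest.approx(2 * m1)

    def test_poisson_limit_variance_equals_mean(self):
        p = ParamSet(beta=[2.0], phi=1e12, sigma_s=0.0)
        E = marginal_mean(3.0, [1.0], p)
        assert marginal_variance(3.0, [1.0], p) == pytest.approx(E, rel=1e-6)

    def test_overdispersion_inequality(self, three_level_est, control_x):
        T = 104 * 1.7e6
        assert marginal_variance(T, control_x, three_level_est) > marginal_mean(
            T, control_x, three_level_est
        )

    def test_dimension_mismatch_rejected(self, three_level_est):
        with pytest.raises(ValueError):
            marginal_mean(1.0, [1.0, 0.0], three_level_est)

    def test_moments_match_simulation(self, three_level_est):
        # 1e6 iid single-exon control draws at the three-level estimates
        n = 1_000_000
        design = SimDesign(
            params=three_level_est,
            levels="three",
            n_patients=0,
            n_controls=n,
            n_exons=1,
            exon_lengths=[104],
            library_sizes=[1.7e6],
            seed=2718,
        )
        y = simulate_gene(design).counts.astype(float)
        x = np.array([1.0, 0, 0, 0])
        E = marginal_mean(104 * 1.7e6, x, three_level_est)
        V = marginal_variance(104 * 1.7e6, x, three_level_est)
        assert y.mean() == pytest.approx(E, rel=0.01)
        assert y.var(ddof=1) == pytest.approx(V, rel=0.05)


class TestCorrelations:
    def test_within_sample_worked_examples(self, three_level_est, control_x):
        f = lambda lib: within_sample_cor(
            104 * lib, 106 * lib, control_x, three_level_est
        )
        assert round(f(1.7e6), 3) == 0.988
        assert round(f(3.5e6), 3) == 0.994

    def test_between_sample_worked_example(self, three_level_est, control_x):
        r = between_sample_cor(
            104 * 1.7e6, control_x, 106 * 3.5e6, control_x, three_level_est
        )
        assert round(r, 3) == 0.024

    def test_two_level_worked_example(self, two_level_est, control_x):
        r = within_sample_cor(104 * 1.7e6, 106 * 1.7e6, control_x, two_level_est)
        assert round(r, 3) == 0.988

    def test_independent_poisson_limit(self):
        p = ParamSet(beta=[0.0], phi=1e12, sigma_s=0.0, sigma_i=0.0)
        assert within_sample_cor(1.0, 2.0, [1.0], p) == pytest.approx(0.0, abs=1e-6)

    def test_between_zero_without_individual_effect(self):
        p = ParamSet(beta=[0.0], phi=0.5, sigma_s=0.4, sigma_i=0.0)
        assert between_sample_cor(1.0, [1.0], 2.0, [1.0], p) == 0.0

    def test_between_requires_three_level(self, two_level_est, control_x):
        with pytest.raises(ValueError, match="three-level"):
            between_sample_cor(1.0, control_x, 2.0, control_x, two_level_est)

    def test_between_increases_with_individual_sd(self, control_x):
        vals = [
            between_sample_cor(
                104 * 1.7e6,
                control_x,
                106 * 1.7e6,
                control_x,
                ParamSet(
                    beta=[-15.4384, 0.75, 0.5, 0.32],
                    phi=0.5112,
                    sigma_s=0.2236,
                    sigma_i=si,
                ),
            )
            for si in (0.1, 0.2, 0.4)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_two_three_level_calculators_coincide(self, control_x):
        # the moment formulas depend on the normal effects only through
        # the total variance, so sigma^2 = sigma_i^2 + sigma_s^2 makes the
        # two- and three-level calculators identical
        si, ss = 0.2321, 0.2236
        p3 = ParamSet(beta=[-15.4, 0.7, 0.5, 0.3], phi=0.51, sigma_s=ss, sigma_i=si)
        p2 = ParamSet(
            beta=[-15.4, 0.7, 0.5, 0.3], phi=0.51, sigma_s=np.sqrt(si**2 + ss**2)
        )
        T1, T2 = 104 * 1.7e6, 106 * 3.5e6
        assert marginal_mean(T1, control_x, p2) == pytest.approx(
            marginal_mean(T1, control_x, p3), rel=1e-14
        )
        assert marginal_variance(T1, control_x, p2) == pytest.approx(
            marginal_variance(T1, control_x, p3), rel=1e-14
        )
        assert within_sample_cor(T1, T2, control_x, p2) == pytest.approx(
            within_sample_cor(T1, T2, control_x, p3), rel=1e-14
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        phi=st.floats(0.05, 50.0),
        sigma_s=st.floats(0.0, 1.0),
        sigma_i=st.floats(0.0, 1.0),
        logT=st.floats(2.0, 9.0),
    )
    def test_correlation_bounds_and_ordering(self, phi, sigma_s, sigma_i, logT):
        p = ParamSet(beta=[-2.0], phi=phi, sigma_s=sigma_s, sigma_i=sigma_i)
        T = 10.0**logT
        x = [1.0]
        w = within_sample_cor(T, T, x, p)
        b = between_sample_cor(T, x, T, x, p)
        assert 0.0 <= w < 1.0
        assert 0.0 <= b < 1.0
        assert w >= b - 1e-12


class TestGeneData:
    def _kwargs(self, **over):
        base = dict(
            gene_id="g",
            individual_id=["i1", "i1"],
            sample_id=["s1", "s1"],
            exon_id=["e1", "e2"],
            counts=[3, 0],
            exposure=[1.0, 2.0],
            covariates=[[1.0, 0.5], [1.0, 0.5]],
        )
        base.update(over)
        return base

    def test_valid_construction(self):
        g = GeneData(**self._kwargs())
        assert g.n_samples == 1 and g.n_obs == 2

    def test_rejects_exon_level_covariates(self):
        with pytest.raises(ValueError, match="sample-level"):
            GeneData(**self._kwargs(covariates=[[1.0, 0.5], [1.0, 0.7]]))

    def test_rejects_duplicate_exon(self):
        with pytest.raises(ValueError, match="duplicate exon"):
            GeneData(**self._kwargs(exon_id=["e1", "e1"]))

    @pytest.mark.parametrize(
        "field,value",
        [("counts", [3, -1]), ("counts", [3, 0.5]), ("exposure", [1.0, 0.0])],
    )
    def test_rejects_bad_rows(self, field, value):
        with pytest.raises(ValueError):
            GeneData(**self._kwargs(**{field: value}))
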