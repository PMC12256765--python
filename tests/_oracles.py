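"""Brute-force integration oracles, independent of the package's quadrature.

All marginal-likelihood checks here integrate on dense trapezoid grids;
the MVNB pmf itself is validated separately against direct Poisson x Gamma
mixture integration (`gamma_mixture_logpmf`).
"""

from collections import defaultdict

import numpy as np
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist


def gamma_mixture_logpmf(y, T, eta, phi, n_grid=200_000, gmax=60.0):
    """Dense fixed-grid integration of the Poisson x Gamma mixture.

    ``int prod_j Poisson(y_j; T_j g e^eta) GammaPDF(g; phi, 1/phi) dg``.
    """
    y = np.asarray(y, float)
    T = np.asarray(T, float)
    g = np.linspace(1e-12, gmax, n_grid)
    mu = T[:, None] * g[None, :] * np.exp(eta)  # (J, G)
    log_pois = (y[:, None] * np.log(mu) - mu - gammaln(y + 1.0)[:, None]).sum(axis=0)
    log_prior = gamma_dist.logpdf(g, a=phi, scale=1.0 / phi)
    w = log_pois + log_prior
    m = w.max()
    return m + np.log(np.trapezoid(np.exp(w - m), g))


def _logpmf_on_grid(y, T, eta, phi):
    """MVNB log-pmf of one sample evaluated at a vector of linear predictors."""
    y = np.asarray(y, float)
    T = np.asarray(T, float)
    eta = np.asarray(eta, float)
    n = y.sum()
    Q = 1.0 + T.sum() * np.exp(eta) / phi
    return (
        gammaln(phi + n)
        - gammaln(phi)
        - gammaln(y + 1.0).sum()
        + (y * np.log(T)).sum()
        - phi * np.log(Q)
        - n * np.log(phi * Q)
        + n * eta
    )


def grid_loglik_2l(gene, params, half_width=8.0, n=4001):
    """Dense-trapezoid oracle for the two-level marginal log-likelihood."""
    sigma = params.sigma_s
    total = 0.0
    for _, y, T, x in gene.sample_groups():
        b = np.linspace(-half_width * sigma, half_width * sigma, n)
        h = _logpmf_on_grid(y, T, float(x @ params.beta) + b, params.phi)
        dens = np.exp(-(b**2) / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))
        m = h.max()
        total += m + np.log(np.trapezoid(np.exp(h - m) * dens, b))
    return total


def grid_loglik_3l(gene, params, n=801, half=6.0):
    """2-D (outer x inner trapezoid) oracle for the three-level likelihood."""
    si, ss = params.sigma_i, params.sigma_s
    by_ind = defaultdict(list)
    for (ind, _), y, T, x in gene.sample_groups():
        by_ind[ind].append((y, T, x))
    bs = None
    total = 0.0
    for groups in by_ind.values():
        bi = np.linspace(-half * si, half * si, n)
        outer = np.zeros(n)
        bs = np.linspace(-half * ss, half * ss, n)
        dens_s = np.exp(-(bs**2) / (2 * ss**2)) / (ss * np.sqrt(2 * np.pi))
        for y, T, x in groups:
            a = float(x @ params.beta)
            h = _logpmf_on_grid(y, T, a + bi[:, None] + bs[None, :], params.phi)
            m = h.max(axis=1, keepdims=True)
            outer += (
                m[:, 0]
                + np.log(np.trapezoid(np.exp(h - m) * dens_s[None, :], bs, axis=1))
            )
        dens_i = np.exp(-(bi**2) / (2 * si**2)) / (si * np.sqrt(2 * np.pi))
        m = outer.max()
        total += m + np.log(np.trapezoid(np.exp(outer - m) * dens_i, bi))
    return total


def bh_stepup_reference(p):
    """Textbook BH: sort, multiply by m/i, enforce monotonicity, cap at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / (np.arange(m) + 1.0)
    monotone = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(monotone, 1.0)
    return out
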