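"""Marginal log-likelihoods of the two- and three-level models.

The likelihood factorizes over clusters: in the two-level model each
sample contributes one 1-D integral of its MVNB pmf against the normal
density of the sample effect; in the three-level model each individual
contributes an outer integral (over the individual effect) of a product
of inner per-sample integrals (over the sample-within-individual
effects).  All integrals are one-dimensional and evaluated by adaptive
Gauss-Hermite quadrature; a single node gives the Laplace approximation.

Because covariates are sample-level, the MVNB log-pmf of a sample depends
on the sample-effect value ``b`` only through simple per-sample totals,
which lets the per-sample integrands, their modes (safeguarded Newton on
analytic derivatives of the strictly concave log-integrand) and the node
evaluations all be computed vectorized across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, logsumexp

from .model import GeneData, ParamSet, mvnb_logpmf
from .quadrature import MAX_NODES, adapt_rule, gh_rule

__all__ = [
    "LikelihoodConfig",
    "marginal_loglik",
    "marginal_loglik_2l",
    "marginal_loglik_3l",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class LikelihoodConfig:
    """How to approximate the marginal likelihood.

    ``method`` is ``"aghq"`` or ``"laplace"``; ``n_nodes`` (ignored for
    Laplace) defaults to 10, beyond which extra nodes buy essentially no
    accuracy on data of this kind.  ``model_levels`` selects the two- or
    three-level hierarchy.
    """

    method: str = "aghq"
    n_nodes: int = 10
    model_levels: str = "two"

    def __post_init__(self) -> None:
        if self.method not in ("aghq", "laplace"):
            raise ValueError(f"unknown method {self.method!r}")
        if not 1 <= int(self.n_nodes) <= MAX_NODES:
            raise ValueError(f"n_nodes must be in [1, {MAX_NODES}]")
        if self.model_levels not in ("two", "three"):
            raise ValueError(f"model_levels must be 'two' or 'three'")

    @property
    def effective_nodes(self) -> int:
        """Laplace is the one-node adaptive rule."""
        return 1 if self.method == "laplace" else int(self.n_nodes)


# ---------------------------------------------------------------------
# vectorized per-sample pieces
# ---------------------------------------------------------------------


def _sample_logpmf_terms(b, a, n, logK, lgconst, phi):
    """MVNB log-pmf of every sample at sample-effect value(s) ``b``.

    All arguments broadcast; ``a`` is the fixed-effect linear predictor,
    ``n`` the total count, ``logK`` the log total exposure and
    ``lgconst`` the eta-independent terms.
    """
    u = a + b + logK - np.log(phi)
    logQ = np.logaddexp(0.0, u)
    return lgconst - phi * logQ - n * (np.log(phi) + logQ) + n * (a + b)


def _sample_modes(a, n, logK, lgconst, phi, var):
    """Mode and curvature of each sample's log-integrand, vectorized.

    The integrand ``h(b) = logpmf(b) - b^2/(2 var)`` (normal constants
    dropped) is strictly concave; Newton from 0 with analytic
    derivatives:

    ``h'(b) = n - (phi + n) sigmoid(u) - b/var``
    ``h''(b) = -(phi + n) sigmoid(u) sigmoid(-u) - 1/var``
    """
    b = np.zeros_like(a)
    for _ in range(100):
        u = a + b + logK - np.log(phi)
        s = expit(u)
        d1 = n - (phi + n) * s - b / var
        d2 = -(phi + n) * s * (1.0 - s) - 1.0 / var
        step = -d1 / d2
        b = b + step
        if np.max(np.abs(step)) < 1e-11 * max(1.0, float(np.max(np.abs(b)))):
            break
    u = a + b + logK - np.log(phi)
    s = expit(u)
    d2 = -(phi + n) * s * (1.0 - s) - 1.0 / var
    return b, d2


def _sample_logintegrals(a, n, logK, lgconst, phi, sigma, nodes, logw):
    """log of each sample's integral over its normal random effect.

    Vectorized across samples; ``sigma = 0`` is handled exactly as the
    degenerate point mass at ``b = 0``.
    """
    if sigma == 0.0:
        return _sample_logpmf_terms(0.0, a, n, logK, lgconst, phi)
    var = sigma**2
    bstar, d2 = _sample_modes(a, n, logK, lgconst, phi, var)
    scale = (-d2) ** -0.5
    bmat = bstar[:, None] + scale[:, None] * nodes[None, :]
    h = (
        _sample_logpmf_terms(bmat, a[:, None], n[:, None], logK[:, None],
                             lgconst[:, None], phi)
        - bmat**2 / (2.0 * var)
        - np.log(sigma)
        - 0.5 * _LOG_2PI
    )
    terms = logw[None, :] + 0.5 * nodes[None, :] ** 2 + 0.5 * _LOG_2PI + h
    return np.log(scale) + logsumexp(terms, axis=1)


def _prepared(data: GeneData, params: ParamSet):
    sm = data.summaries()
    if sm.X.shape[1] != params.beta.size:
        raise ValueError(
            f"design has {sm.X.shape[1]} covariates but beta has "
            f"{params.beta.size}"
        )
    a = sm.X @ params.beta
    n = sm.ysum
    logK = np.log(sm.Tsum)
    lgconst = gammaln(params.phi + n) - gammaln(params.phi) + sm.const
    return sm, a, n, logK, lgconst


# ---------------------------------------------------------------------
# public likelihoods
# ---------------------------------------------------------------------


def marginal_loglik_2l(
    data: GeneData, params: ParamSet, cfg: LikelihoodConfig | None = None
) -> float:
    """Two-level marginal log-likelihood.

    ``sum_s log \\int P_MVNB(y_s | b) N(b; 0, sigma^2) db``, one adaptive
    1-D integral per sample.
    """
    cfg = cfg or LikelihoodConfig()
    if params.sigma_i is not None:
        raise ValueError("two-level likelihood called with a three-level ParamSet")
    sm, a, n, logK, lgconst = _prepared(data, params)
    rule = gh_rule(cfg.effective_nodes)
    vals = _sample_logintegrals(
        a, n, logK, lgconst, params.phi, float(params.sigma_s),
        rule.nodes, np.log(rule.weights),
    )
    return float(np.sum(vals))


def marginal_loglik_3l(
    data: GeneData, params: ParamSet, cfg: LikelihoodConfig | None = None
) -> float:
    """Three-level marginal log-likelihood via nested adaptive quadrature.

    Per individual ``i``:
    ``log L_i = log \\int N(b_i; 0, sigma_i^2)
    prod_s [ \\int P_MVNB(y_is | b_i + b_is) N(b_is; 0, sigma_s^2) db_is ]
    db_i``.
    Inner integrals are evaluated (vectorized across the individual's
    samples) by their own adaptive rules at each outer evaluation point;
    the outer adaptive rule is found on that profile log-integrand.
    ``sigma_i = 0`` collapses exactly to the two-level likelihood.
    """
    cfg = cfg or LikelihoodConfig()
    if params.sigma_i is None:
        raise ValueError("three-level likelihood needs sigma_i in the ParamSet")
    sigma_i = float(params.sigma_i)
    if sigma_i == 0.0:
        flat = ParamSet(params.beta, params.phi, params.sigma_s)
        return marginal_loglik_2l(data, flat, cfg)
    sm, a, n, logK, lgconst = _prepared(data, params)
    rule = gh_rule(cfg.effective_nodes)
    nodes, logw = rule.nodes, np.log(rule.weights)
    sigma_s = float(params.sigma_s)
    phi = params.phi
    total = 0.0
    for code in range(len(sm.ind_ids)):
        idx = sm.ind_codes == code
        ai, ni, logKi, lgi = a[idx], n[idx], logK[idx], lgconst[idx]

        def outer_h(bi: float) -> float:
            inner = _sample_logintegrals(
                ai + bi, ni, logKi, lgi, phi, sigma_s, nodes, logw
            )
            return (
                float(np.sum(inner))
                - bi**2 / (2.0 * sigma_i**2)
                - np.log(sigma_i)
                - 0.5 * _LOG_2PI
            )

        out_rule = adapt_rule(outer_h, rule, start=0.0, fallback_scale=sigma_i)
        total += out_rule.log_integral(outer_h)
    return float(total)


def marginal_loglik(
    data: GeneData, params: ParamSet, cfg: LikelihoodConfig | None = None
) -> float:
    """Dispatch on the hierarchy implied by ``params``/``cfg``."""
    cfg = cfg or LikelihoodConfig(
        model_levels="two" if params.sigma_i is None else "three"
    )
    if cfg.model_levels == "three":
        return marginal_loglik_3l(data, params, cfg)
    return marginal_loglik_2l(data, params, cfg)


def _loglik_2l_samplewise(
    data: GeneData, params: ParamSet, cfg: LikelihoodConfig | None = None
) -> float:
    """Reference two-level likelihood through the generic quadrature API.

    One `adapt_rule` (numeric-derivative mode search) per sample on the
    raw `mvnb_logpmf`; used to cross-check the vectorized path.
    """
    cfg = cfg or LikelihoodConfig()
    if params.sigma_i is not None:
        raise ValueError("two-level likelihood called with a three-level ParamSet")
    sigma = float(params.sigma_s)
    rule = gh_rule(cfg.effective_nodes)
    total = 0.0
    for _, y, T, x in data.sample_groups():
        eta0 = float(x @ params.beta)
        if sigma == 0.0:
            total += mvnb_logpmf(y, T, eta0, params.phi)
            continue

        def h(b: float) -> float:
            return (
                mvnb_logpmf(y, T, eta0 + b, params.phi)
                - b**2 / (2.0 * sigma**2)
                - np.log(sigma)
                - 0.5 * _LOG_2PI
            )

        r = adapt_rule(h, rule, start=0.0, fallback_scale=sigma)
        total += r.log_integral(h)
    return float(total)
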