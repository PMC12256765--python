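"""Gauss-Hermite quadrature, adaptive recentering, and the Laplace limit.

Rules are kept in the probabilists' standardization: nodes and weights
approximate integrals against the standard normal density, so weights sum
to one and a one-node rule degenerates to evaluating at the mean.  An
adaptive rule shifts the nodes to the mode of a log-integrand and scales
them by the curvature there; with a single node this is exactly the
Laplace approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import logsumexp

__all__ = ["QuadratureRule", "gh_rule", "adapt_rule", "laplace_logintegral"]

_LOG_2PI = float(np.log(2.0 * np.pi))

MAX_NODES = 75


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Hermite nodes/weights against a standard-normal kernel.

    ``shift`` and ``scale`` carry the adaptive recentering: evaluation
    points are ``shift + scale * nodes``.  ``fallback`` flags a rule whose
    mode search failed (non-adaptive fallback at the start point).
    """

    nodes: np.ndarray
    weights: np.ndarray
    shift: float = 0.0
    scale: float = 1.0
    fallback: bool = False

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.shape != weights.shape or nodes.size == 0:
            raise ValueError("nodes and weights must be equal-length 1-D vectors")
        if self.scale <= 0 or not np.isfinite(self.scale):
            raise ValueError("scale must be positive")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.size)

    @property
    def points(self) -> np.ndarray:
        return self.shift + self.scale * self.nodes

    def log_integral(self, log_integrand: Callable) -> float:
        """Estimate ``log \\int exp(h(b)) db`` with this (shifted) rule.

        Substituting ``b = shift + scale * z`` and dividing/multiplying by
        the standard normal kernel gives
        ``log scale + logsumexp_i[ log w_i + z_i^2/2 + log(2 pi)/2
        + h(points_i) ]``.
        """
        pts = self.points
        h = np.array([float(log_integrand(float(b))) for b in pts])
        terms = np.log(self.weights) + 0.5 * self.nodes**2 + 0.5 * _LOG_2PI + h
        return float(np.log(self.scale) + logsumexp(terms))


def gh_rule(n: int) -> QuadratureRule:
    """Standardized Gauss-Hermite rule with ``n`` nodes.

    Exact for polynomials of degree ``<= 2n - 1`` against the standard
    normal density; weights sum to 1, nodes are symmetric about 0.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"need at least one node, got {n!r}")
    if n > MAX_NODES:
        raise ValueError(f"node count capped at {MAX_NODES}, got {n}")
    nodes, weights = hermegauss(int(n))
    weights = weights / np.sqrt(2.0 * np.pi)  # hermegauss kernel is e^{-x^2/2}
    return QuadratureRule(nodes=nodes, weights=weights)


def _num_derivs(h: Callable, b: float) -> tuple[float, float, float]:
    # step balances truncation against roundoff in the second difference:
    # much below ~1e-3 the curvature estimate is dominated by cancellation
    # noise (~eps/step^2), which would spoil the Laplace scale
    step = 1e-3 * max(1.0, abs(b))
    f0 = float(h(b))
    fp = float(h(b + step))
    fm = float(h(b - step))
    d1 = (fp - fm) / (2.0 * step)
    d2 = (fp - 2.0 * f0 + fm) / step**2
    return f0, d1, d2


def adapt_rule(
    log_integrand: Callable,
    rule: QuadratureRule,
    start: float = 0.0,
    fallback_scale: float = 1.0,
) -> QuadratureRule:
    """Recenter a rule at the mode/curvature of a log-integrand.

    Finds the mode ``b*`` of ``h`` by safeguarded Newton iteration on
    numeric first/second differences (step-halving keeps ``h``
    non-decreasing; at most 50 iterations, tolerance 1e-8 on ``|h'|``),
    then sets ``shift = b*`` and ``scale = (-h''(b*))^{-1/2}``.  If no
    point of negative curvature is found the returned rule is flagged as a
    non-adaptive fallback centered at ``start`` with ``fallback_scale``.
    """
    if not np.isfinite(start):
        raise ValueError("start must be finite")
    b = float(start)
    f0, d1, d2 = _num_derivs(log_integrand, b)
    converged = False
    for _ in range(50):
        if abs(d1) < 1e-8:
            converged = True
            break
        if d2 < 0:
            step = -d1 / d2
        else:  # uphill unit step while curvature is not yet negative
            step = np.sign(d1) * max(1.0, abs(b))
        # step-halving safeguard
        for _ in range(40):
            b_new = b + step
            f_new = float(log_integrand(b_new))
            if np.isfinite(f_new) and f_new >= f0 - 1e-12:
                break
            step *= 0.5
        else:
            break
        b = b_new
        f0, d1, d2 = _num_derivs(log_integrand, b)
    else:
        converged = abs(d1) < 1e-8
    if not converged or not np.isfinite(d2) or d2 >= 0:
        return replace(rule, shift=float(start), scale=float(fallback_scale),
                       fallback=True)
    return replace(rule, shift=b, scale=float((-d2) ** -0.5), fallback=False)


def laplace_logintegral(log_integrand: Callable, start: float = 0.0) -> float:
    """Laplace approximation of ``log \\int exp(h(b)) db``.

    Gaussian (second-order) approximation at the mode:
    ``h(b*) + log(2 pi)/2 - log(-h''(b*))/2``.  Implemented as the
    one-node adaptive rule, of which it is the exact special case.
    """
    rule = adapt_rule(log_integrand, gh_rule(1), start=start)
    return rule.log_integral(log_integrand)
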