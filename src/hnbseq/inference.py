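"""Wald tests of the visit-effect hypotheses and FDR control.

Three null hypotheses are of interest in the longitudinal design:
``H0123: beta_1 = beta_2 = beta_3 = 0`` (no expression difference between
patients and controls at any visit, 3 df), ``H01: beta_1 = 0``
(pre-treatment difference, 1 df) and ``H03: beta_3 = 0`` (post-treatment
difference, 1 df).  Each is a chi-squared Wald test of ``C beta = 0``;
p-values are adjusted per hypothesis family across genes by
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .estimation import FitResult

__all__ = ["TestResult", "wald_test", "hypothesis_contrast", "bh_adjust",
           "HYPOTHESES"]

HYPOTHESES = ("H0123", "H01", "H03")


@dataclass
class TestResult:
    gene_id: str
    hypothesis: str
    statistic: float
    df: int
    p_raw: float
    p_adj: float | None = None


def hypothesis_contrast(hypothesis: str, coef_names) -> np.ndarray:
    """Contrast matrix selecting the tested visit coefficients.

    Rows select coefficients by covariate name (``visit1``..``visit3``);
    columns span the full fixed-effect vector.
    """
    coef_names = list(coef_names)
    p = len(coef_names)

    def row(name: str) -> np.ndarray:
        if name not in coef_names:
            raise ValueError(f"coefficient {name!r} not in design {coef_names}")
        r = np.zeros(p)
        r[coef_names.index(name)] = 1.0
        return r

    if hypothesis == "H0123":
        return np.vstack([row("visit1"), row("visit2"), row("visit3")])
    if hypothesis == "H01":
        return row("visit1")[None, :]
    if hypothesis == "H03":
        return row("visit3")[None, :]
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


def wald_test(
    fit: FitResult, C: np.ndarray, hypothesis: str = "custom"
) -> TestResult:
    """Chi-squared Wald test of the linear restriction ``C beta = 0``.

    ``W = (C b)' (C V C')^{-1} (C b)`` with ``V`` the beta block of the
    fit's covariance; the reference distribution is chi-squared with
    ``rank(C)`` degrees of freedom.  Refuses non-converged fits (callers
    record the test as missing rather than inventing a p-value).
    """
    if not fit.converged:
        raise ValueError(
            f"gene {fit.gene_id}: fit status {fit.status!r}; test refused"
        )
    C = np.atleast_2d(np.asarray(C, dtype=float))
    beta = fit.params_hat.beta
    if C.shape[1] != beta.size:
        raise ValueError("contrast width does not match beta dimension")
    q = C.shape[0]
    if np.linalg.matrix_rank(C) < q:
        raise ValueError("contrast matrix is not of full row rank")
    V = fit.beta_vcov()
    M = C @ V @ C.T
    cb = C @ beta
    try:
        sol = np.linalg.solve(M, cb)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"gene {fit.gene_id}: contrast covariance singular "
            "(vcov_non_estimable)"
        ) from exc
    W = float(cb @ sol)
    W = max(W, 0.0)
    return TestResult(
        gene_id=fit.gene_id,
        hypothesis=hypothesis,
        statistic=W,
        df=q,
        p_raw=float(chi2.sf(W, q)),
    )


def bh_adjust(
    p_values, q: float = 0.05, m_total: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Missing (NaN) entries are excluded from the number of tests ``m`` and
    come back as NaN / not rejected.  ``m_total`` overrides ``m`` (e.g. to
    count genes whose fit failed as tests that were intended), scaling the
    adjusted p-values by ``m_total / m``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    m = int(valid.sum())
    if m:
        _, adj_valid, _, _ = multipletests(p[valid], alpha=q, method="fdr_bh")
        if m_total is not None and m_total > m:
            # rescale to the intended test count, re-applying the step-up
            # monotonicity and the cap at 1
            order = np.argsort(p[valid])
            scaled = p[valid][order] * m_total / (np.arange(m) + 1.0)
            scaled = np.minimum.accumulate(scaled[::-1])[::-1]
            adj_valid = np.empty(m)
            adj_valid[order] = np.minimum(scaled, 1.0)
        adj[valid] = adj_valid
        reject[valid] = adj_valid <= q
    return adj, reject
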