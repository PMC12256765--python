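"""Marginal maximum-likelihood estimation and fit diagnostics.

The marginal log-likelihood is maximized over working parameters --
``beta`` unconstrained, ``log phi`` and the log random-effect SDs -- by
L-BFGS-B with numeric gradients.  Standard errors come from the inverse
of the numeric observed-information matrix (central differences) at the
optimum; SEs for ``phi`` and the SDs are mapped back to the natural scale
by the delta method.  A fit is classified as ``converged``,
``non_convergence``, ``vcov_non_estimable`` or
``vcov_not_positive_definite``; failures are recorded, never raised, so
per-gene batches can continue.

Random-effect SDs that converge to (numerically) zero are reported as
exactly zero and profiled out of the information matrix: the likelihood
is flat in a variance component sitting on the boundary, so keeping it
would spuriously fail the positive-definiteness check even though the
remaining parameters are perfectly well determined.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize

from .likelihood import LikelihoodConfig, marginal_loglik
from .model import GeneData, ParamSet

__all__ = ["FitResult", "starting_values", "fit_gene"]

STATUSES = (
    "converged",
    "non_convergence",
    "vcov_non_estimable",
    "vcov_not_positive_definite",
)

_LOG_PHI_BOUNDS = (np.log(1e-4), np.log(1e8))
_LOG_SD_BOUNDS = (np.log(1e-6), np.log(10.0))
_SD_BOUNDARY = 1e-3  # natural-scale SD below this is a boundary estimate


@dataclass
class FitResult:
    """Estimates, uncertainties and status of one gene's fit."""

    gene_id: str
    params_hat: ParamSet
    se: dict[str, float]
    vcov: np.ndarray | None
    vcov_names: tuple[str, ...]
    loglik: float
    status: str
    config: LikelihoodConfig
    n_iter: int = 0
    runtime_s: float = float("nan")
    boundary: tuple[str, ...] = ()
    message: str = ""

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    def coef_names(self) -> tuple[str, ...]:
        return tuple(
            n for n in self.vcov_names if not n.startswith(("log_phi", "log_sigma"))
        )

    def beta_vcov(self) -> np.ndarray:
        """Covariance of the fixed effects (beta block of vcov)."""
        if self.vcov is None:
            raise ValueError(f"no covariance available (status={self.status})")
        idx = [
            k
            for k, n in enumerate(self.vcov_names)
            if not n.startswith(("log_phi", "log_sigma"))
        ]
        return self.vcov[np.ix_(idx, idx)]


def starting_values(data: GeneData, levels: str = "two") -> ParamSet:
    """Heuristic starting parameters for the optimizer.

    ``beta`` from a Poisson log-linear GLM with ``log T`` offset;
    ``phi`` by moment-matching the Pearson overdispersion of that fit
    against the marginal variance formula (clipped to [0.01, 100]);
    random-effect SDs start at 0.3.
    """
    y = data.counts.astype(float)
    if y.sum() == 0:
        raise ValueError(f"gene {data.gene_id}: all counts are zero")
    offset = np.log(data.exposure)
    try:
        glm = sm.GLM(y, data.covariates, family=sm.families.Poisson(), offset=offset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm.fit(maxiter=25)
        beta = np.asarray(res.params, dtype=float)
        mu = np.asarray(res.mu, dtype=float)
        if not np.all(np.isfinite(beta)):
            raise ValueError("non-finite GLM coefficients")
    except Exception:
        beta = np.zeros(data.covariates.shape[1])
        beta[0] = float(np.log(y.sum() / data.exposure.sum()))
        mu = data.exposure * np.exp(data.covariates @ beta)
    sigma0 = 0.3
    # Pearson X^2 / df ~ 1 + c * mean(mu) with c the quadratic-excess
    # coefficient e^v (1/phi + 1 - e^{-v}); solve for phi at v = sigma0^2
    df = max(y.size - beta.size, 1)
    disp = float(np.sum((y - mu) ** 2 / np.maximum(mu, 1e-12)) / df)
    c = max(disp - 1.0, 1e-6) / max(float(np.mean(mu)), 1e-12)
    v = sigma0**2
    inv_phi = c * np.exp(-v) - 1.0 + np.exp(-v)
    phi = 1.0 / inv_phi if inv_phi > 0 else 100.0
    phi = float(np.clip(phi, 0.01, 100.0))
    sigma_i = sigma0 if levels == "three" else None
    return ParamSet(beta=beta, phi=phi, sigma_s=sigma0, sigma_i=sigma_i)


def _pack(params: ParamSet) -> tuple[np.ndarray, tuple[str, ...]]:
    names = [f"beta_{k}" for k in range(params.beta.size)]
    theta = list(params.beta)
    theta.append(np.log(params.phi))
    names.append("log_phi")
    theta.append(np.log(max(params.sigma_s, 1e-6)))
    names.append("log_sigma_s")
    if params.sigma_i is not None:
        theta.append(np.log(max(params.sigma_i, 1e-6)))
        names.append("log_sigma_i")
    return np.asarray(theta, dtype=float), tuple(names)


def _unpack(theta: np.ndarray, p: int, three_level: bool) -> ParamSet:
    beta = theta[:p]
    phi = float(np.exp(theta[p]))
    sigma_s = float(np.exp(theta[p + 1]))
    sigma_i = float(np.exp(theta[p + 2])) if three_level else None
    return ParamSet(beta=beta, phi=phi, sigma_s=sigma_s, sigma_i=sigma_i)


def _hessian(f, theta: np.ndarray) -> np.ndarray:
    """Observed information of ``f`` by central differences."""
    m = theta.size
    h = 1e-3 * np.maximum(1.0, np.abs(theta))
    H = np.empty((m, m))
    f0 = f(theta)
    for i in range(m):
        ei = np.zeros(m)
        ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, m):
            ej = np.zeros(m)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej)
                - f(theta + ei - ej)
                - f(theta - ei + ej)
                + f(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_gene(
    data: GeneData,
    cfg: LikelihoodConfig | None = None,
    start: ParamSet | None = None,
    n_starts: int = 1,
    maxiter: int = 500,
    gtol: float = 1e-6,
) -> FitResult:
    """Maximize the marginal likelihood for one gene.

    ``n_starts = 3`` retries from sample-SD starts {0.1, 0.3, 1.0} and
    keeps the best log-likelihood (optimizers can land in different local
    optima).  Optimizer or covariance failures are reported through
    ``status``, never raised.
    """
    cfg = cfg or LikelihoodConfig()
    t0 = time.perf_counter()
    if data.n_samples < 2:
        warnings.warn(
            f"gene {data.gene_id}: fewer than 2 samples; variance parameters "
            "are weakly identified",
            stacklevel=2,
        )
    three = cfg.model_levels == "three"
    start = start or starting_values(data, levels=cfg.model_levels)
    if three and start.sigma_i is None:
        start = ParamSet(start.beta, start.phi, start.sigma_s, 0.3)
    if not three and start.sigma_i is not None:
        start = ParamSet(start.beta, start.phi, start.sigma_s)
    p = start.beta.size

    def negll(theta: np.ndarray) -> float:
        try:
            val = marginal_loglik(data, _unpack(theta, p, three), cfg)
        except FloatingPointError:
            return np.inf
        return -val if np.isfinite(val) else np.inf

    theta0, names = _pack(start)
    bounds = [(-50.0, 50.0)] * p + [_LOG_PHI_BOUNDS]
    bounds += [_LOG_SD_BOUNDS] * (2 if three else 1)

    sd_starts = [None] if n_starts <= 1 else [0.1, 0.3, 1.0][:n_starts]
    best = None
    for sd0 in sd_starts:
        th = theta0.copy()
        if sd0 is not None:
            th[p + 1 :] = np.log(sd0)
        res = minimize(
            negll,
            th,
            method="L-BFGS-B",
            bounds=bounds,
            jac="3-point",  # central differences: forward-difference noise
            # is too coarse to localize the optimum in near-flat variance
            # directions
            # ftol well below gtol so the gradient criterion, not relative
            # f-change, terminates: |loglik| is O(1e3-1e4) and the default
            # ftol would leave ~1e-4 wobble along flat variance ridges
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 5e-15},
        )
        if best is None or res.fun < best.fun:
            best = res
    res = best

    theta_hat = np.asarray(res.x, dtype=float)
    # a line-search abort at the precision floor still counts as converged
    # when the projected gradient is (relatively) negligible
    grad_ok = np.max(np.abs(np.asarray(res.jac))) < 1e-3
    opt_ok = (bool(res.success) or grad_ok) and res.nit < maxiter

    # boundary handling: SDs pinned at (numerical) zero are reported as 0
    # and profiled out of the information matrix
    boundary = []
    for k, name in enumerate(names):
        if name.startswith("log_sigma") and np.exp(theta_hat[k]) < _SD_BOUNDARY:
            boundary.append(name)
        elif name == "log_phi" and (
            theta_hat[k] <= _LOG_PHI_BOUNDS[0] + 1e-8
            or theta_hat[k] >= _LOG_PHI_BOUNDS[1] - 1e-8
        ):
            boundary.append(name)
    params_hat = _unpack(theta_hat, p, three)
    if "log_sigma_s" in boundary:
        params_hat = ParamSet(params_hat.beta, params_hat.phi, 0.0, params_hat.sigma_i)
    if "log_sigma_i" in boundary:
        params_hat = ParamSet(params_hat.beta, params_hat.phi, params_hat.sigma_s, 0.0)
    loglik = float(marginal_loglik(data, params_hat, cfg))

    free = [k for k, n in enumerate(names) if n not in boundary]
    free_names = tuple(names[k] for k in free)

    status = "converged" if opt_ok else "non_convergence"
    vcov = None
    se: dict[str, float] = {}
    if opt_ok:
        def negll_free(th_free: np.ndarray) -> float:
            th = theta_hat.copy()
            th[free] = th_free
            return negll(th)

        H = _hessian(negll_free, theta_hat[free])
        if not np.all(np.isfinite(H)):
            status = "vcov_non_estimable"
        else:
            eig = np.linalg.eigvalsh(H)
            if eig[-1] <= 0 or eig[0] <= 1e-10 * eig[-1]:
                status = "vcov_not_positive_definite"
            else:
                try:
                    vcov = np.linalg.inv(H)
                except np.linalg.LinAlgError:
                    status = "vcov_non_estimable"
    if vcov is not None:
        diag = np.sqrt(np.maximum(np.diag(vcov), 0.0))
        working_se = dict(zip(free_names, diag))
        for k in range(p):
            se[f"beta_{k}"] = working_se.get(f"beta_{k}", np.nan)
        se["phi"] = params_hat.phi * working_se.get("log_phi", 0.0)
        se["sigma_s"] = params_hat.sigma_s * working_se.get("log_sigma_s", 0.0)
        if three:
            se["sigma_i"] = params_hat.sigma_i * working_se.get("log_sigma_i", 0.0)
        if not np.all(np.isfinite(list(se.values()))):
            status, vcov, se = "vcov_non_estimable", None, {}

    return FitResult(
        gene_id=data.gene_id,
        params_hat=params_hat,
        se=se,
        vcov=vcov,
        vcov_names=free_names if vcov is not None else (),
        loglik=loglik,
        status=status,
        config=cfg,
        n_iter=int(res.nit),
        runtime_s=time.perf_counter() - t0,
        boundary=tuple(boundary),
        message=str(res.message),
    )
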