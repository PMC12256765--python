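"""Core data structures and closed-form distributional results.

The model is a per-gene hierarchical negative-binomial (Poisson-gamma-
lognormal) model for exon-level RNA-seq counts.  Counts ``y_sj`` for exon
``j`` of sample ``s`` are conditionally Poisson with rate
``T_sj * gamma_s * exp(x_s' beta + b_s)`` where

* ``T_sj = d_j * l_s`` is a known exposure (exon length x library size),
* ``gamma_s ~ Gamma(phi, 1/phi)`` is a sample-level frailty (mean 1,
  variance ``1/phi``) shared across the exons of a sample, and
* ``b_s ~ Normal(0, sigma^2)`` is a lognormal sample effect.

In the three-level variant the normal effect splits into an individual
effect ``b_i ~ N(0, sigma_i^2)`` plus a sample-within-individual effect
``b_is ~ N(0, sigma_s^2)``.  Integrating the shared gamma frailty out of
the conditionally independent Poissons yields a multivariate negative
binomial (MVNB) distribution for a sample's count vector; this module
implements its log-pmf together with the marginal moment and correlation
calculus implied by the full hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "ParamSet",
    "GeneData",
    "mvnb_logpmf",
    "marginal_mean",
    "marginal_variance",
    "within_sample_cor",
    "between_sample_cor",
]


@dataclass(frozen=True)
class ParamSet:
    """Parameters of the hierarchical NB model.

    Parameters
    ----------
    beta
        Log-scale fixed effects ``(beta_0, ..., beta_p)``; ``beta_0`` is the
        intercept.
    phi
        Gamma overdispersion parameter: the frailty is
        ``Gamma(shape=phi, scale=1/phi)`` so it has mean 1 and variance
        ``1/phi``.  The NB "size" equals ``phi``.
    sigma_s
        Standard deviation of the sample-level normal random effect
        (called ``sigma`` in the two-level model, ``sigma_S`` in the
        three-level one).
    sigma_i
        Standard deviation of the individual-level normal random effect.
        ``None`` means the two-level model.
    """

    beta: np.ndarray
    phi: float
    sigma_s: float
    sigma_i: float | None = None

    def __post_init__(self) -> None:
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if beta.ndim != 1 or beta.size == 0 or not np.all(np.isfinite(beta)):
            raise ValueError("beta must be a finite 1-D vector")
        object.__setattr__(self, "beta", beta)
        if not np.isfinite(self.phi) or self.phi <= 0:
            raise ValueError(f"phi must be a positive real, got {self.phi!r}")
        if not np.isfinite(self.sigma_s) or self.sigma_s < 0:
            raise ValueError(f"sigma_s must be non-negative, got {self.sigma_s!r}")
        if self.sigma_i is not None and (
            not np.isfinite(self.sigma_i) or self.sigma_i < 0
        ):
            raise ValueError(f"sigma_i must be non-negative, got {self.sigma_i!r}")

    @property
    def levels(self) -> int:
        """2 for the sample-only hierarchy, 3 when sigma_i is present."""
        return 2 if self.sigma_i is None else 3

    @property
    def re_variance(self) -> float:
        """Total variance of the normal part of the linear predictor.

        ``sigma^2`` in the two-level model, ``sigma_i^2 + sigma_s^2`` in the
        three-level one; the marginal moment formulas depend on the normal
        effects only through this quantity.
        """
        v = float(self.sigma_s) ** 2
        if self.sigma_i is not None:
            v += float(self.sigma_i) ** 2
        return v

    @property
    def n_coef(self) -> int:
        return int(self.beta.size)


class SampleSummaries(NamedTuple):
    """Per-sample sufficient statistics used by the marginal likelihood."""

    keys: list[tuple[str, str]]  # (individual_id, sample_id), stable order
    X: np.ndarray  # (S, p) sample-level design matrix
    ysum: np.ndarray  # (S,) total count per sample
    Tsum: np.ndarray  # (S,) total exposure per sample
    const: np.ndarray  # (S,) sum_j [ y log T - lgamma(y+1) ]
    ind_codes: np.ndarray  # (S,) individual index, stable order
    ind_ids: list[str]


def _as_int_counts(counts: np.ndarray, what: str = "count") -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError(f"empty {what} vector")
    flt = arr.astype(float)
    if not np.all(np.isfinite(flt)):
        raise ValueError(f"non-finite {what}")
    if np.any(flt < 0) or np.any(flt != np.floor(flt)):
        raise ValueError(f"{what}s must be non-negative integers")
    return flt.astype(np.int64)


@dataclass(frozen=True)
class GeneData:
    """One gene's long-format exon counts.

    Each row is one (individual, sample, exon) observation with a count,
    a strictly positive exposure ``T = exon_length * library_size`` and a
    sample-level covariate vector (including the intercept 1).  Covariates
    must be constant within a sample: they describe the sample, not the
    exon.
    """

    gene_id: str
    individual_id: np.ndarray
    sample_id: np.ndarray
    exon_id: np.ndarray
    counts: np.ndarray
    exposure: np.ndarray
    covariates: np.ndarray  # (n_obs, p), includes the intercept column
    covariate_names: tuple[str, ...] = ()
    exon_length: np.ndarray | None = None
    library_size: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.counts)
        ind = np.asarray(self.individual_id, dtype=object)
        smp = np.asarray(self.sample_id, dtype=object)
        exn = np.asarray(self.exon_id, dtype=object)
        y = _as_int_counts(self.counts)
        T = np.asarray(self.exposure, dtype=float)
        X = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if not (len(ind) == len(smp) == len(exn) == len(T) == n and X.shape[0] == n):
            raise ValueError("all per-observation fields must have equal length")
        if n == 0:
            raise ValueError("a gene needs at least one observation")
        if np.any(~np.isfinite(T)) or np.any(T <= 0):
            raise ValueError("exposures must be strictly positive")
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates must be finite")
        names = tuple(self.covariate_names) or tuple(
            f"x{k}" for k in range(X.shape[1])
        )
        if len(names) != X.shape[1]:
            raise ValueError("covariate_names length does not match design width")
        object.__setattr__(self, "individual_id", ind)
        object.__setattr__(self, "sample_id", smp)
        object.__setattr__(self, "exon_id", exn)
        object.__setattr__(self, "counts", y)
        object.__setattr__(self, "exposure", T)
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "covariate_names", names)
        for attr in ("exon_length", "library_size"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != n or np.any(~np.isfinite(v)) or np.any(v <= 0):
                    raise ValueError(f"{attr} must be positive and match length")
                object.__setattr__(self, attr, v)
        self._validate_groups()

    def _validate_groups(self) -> None:
        seen_exons: dict[tuple, set] = {}
        seen_x: dict[tuple, np.ndarray] = {}
        for i in range(len(self.counts)):
            key = (self.individual_id[i], self.sample_id[i])
            exons = seen_exons.setdefault(key, set())
            if self.exon_id[i] in exons:
                raise ValueError(
                    f"duplicate exon {self.exon_id[i]!r} in sample {key!r}"
                )
            exons.add(self.exon_id[i])
            x = self.covariates[i]
            if key in seen_x:
                if not np.array_equal(seen_x[key], x):
                    raise ValueError(
                        f"covariates vary within sample {key!r}; covariates are "
                        "sample-level, not exon-level"
                    )
            else:
                seen_x[key] = x

    # -- derived views -------------------------------------------------

    @property
    def n_obs(self) -> int:
        return len(self.counts)

    @property
    def sample_keys(self) -> list[tuple[str, str]]:
        keys: list[tuple[str, str]] = []
        seen = set()
        for i in range(self.n_obs):
            key = (self.individual_id[i], self.sample_id[i])
            if key not in seen:
                seen.add(key)
                keys.append(key)
        return keys

    @property
    def n_samples(self) -> int:
        return len(self.sample_keys)

    @property
    def n_individuals(self) -> int:
        return len(dict.fromkeys(self.individual_id.tolist()))

    def sample_groups(self):
        """Yield (key, counts, exposures, covariate-vector) per sample."""
        order: dict[tuple, list[int]] = {}
        for i in range(self.n_obs):
            order.setdefault((self.individual_id[i], self.sample_id[i]), []).append(i)
        for key, idx in order.items():
            idx = np.asarray(idx)
            yield key, self.counts[idx], self.exposure[idx], self.covariates[idx[0]]

    def summaries(self) -> SampleSummaries:
        """Per-sample sufficient statistics for the marginal likelihood.

        Because covariates are sample-level, the linear predictor is shared
        by all exons of a sample, and the MVNB log-pmf depends on the data
        only through the per-sample totals collected here.
        """
        cached = getattr(self, "_summaries_cache", None)
        if cached is not None:
            return cached
        keys, X_rows, ysum, Tsum, const = [], [], [], [], []
        ind_of_key = []
        for key, y, T, x in self.sample_groups():
            keys.append(key)
            X_rows.append(x)
            ysum.append(y.sum())
            Tsum.append(T.sum())
            const.append(float(np.sum(y * np.log(T)) - np.sum(gammaln(y + 1.0))))
            ind_of_key.append(key[0])
        ind_ids = list(dict.fromkeys(ind_of_key))
        code = {g: k for k, g in enumerate(ind_ids)}
        out = SampleSummaries(
            keys=keys,
            X=np.asarray(X_rows, dtype=float),
            ysum=np.asarray(ysum, dtype=float),
            Tsum=np.asarray(Tsum, dtype=float),
            const=np.asarray(const, dtype=float),
            ind_codes=np.asarray([code[g] for g in ind_of_key], dtype=int),
            ind_ids=ind_ids,
        )
        object.__setattr__(self, "_summaries_cache", out)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "individual_id": self.individual_id,
                "sample_id": self.sample_id,
                "exon_id": self.exon_id,
                "count": self.counts,
            }
        )
        if self.exon_length is not None and self.library_size is not None:
            df["exon_length"] = self.exon_length
            df["library_size"] = self.library_size
        else:
            df["exposure"] = self.exposure
        for k, name in enumerate(self.covariate_names):
            if name == "intercept":
                continue
            df[name] = self.covariates[:, k]
        return df


def mvnb_logpmf(counts, exposures, eta: float, phi: float) -> float:
    """Log-pmf of the multivariate negative binomial count vector.

    This is the distribution of a sample's exon counts after integrating
    the shared ``Gamma(phi, 1/phi)`` frailty out of conditionally
    independent ``Poisson(T_j * gamma * e^eta)`` counts:

    ``log P(y) = lgamma(phi + n) - lgamma(phi) - sum_j lgamma(y_j + 1)
    - phi log Q - n log(phi Q) + sum_j y_j (log T_j + eta)``

    with ``n = sum_j y_j`` and ``Q = 1 + phi^{-1} sum_j T_j e^eta``.

    Parameters
    ----------
    counts, exposures
        Equal-length vectors of non-negative integer counts and strictly
        positive exposures.
    eta
        The sample's linear predictor ``x'beta + b`` (shared across exons,
        random effects included).
    phi
        Positive gamma overdispersion parameter.
    """
    y = _as_int_counts(counts)
    T = np.asarray(exposures, dtype=float)
    if T.shape != y.shape:
        raise ValueError("counts and exposures must have the same length")
    if np.any(~np.isfinite(T)) or np.any(T <= 0):
        raise ValueError("exposures must be strictly positive")
    if not np.isfinite(phi) or phi <= 0:
        raise ValueError("phi must be a positive real")
    eta = float(eta)
    n = float(y.sum())
    # log Q = log(1 + exp(eta + log(sum T) - log phi)), computed stably
    logQ = np.logaddexp(0.0, eta + np.log(T.sum()) - np.log(phi))
    out = (
        gammaln(phi + n)
        - gammaln(phi)
        - float(np.sum(gammaln(y + 1.0)))
        - phi * logQ
        - n * (np.log(phi) + logQ)
        + float(np.sum(y * np.log(T)))
        + n * eta
    )
    return float(out)


def _check_x(x, params: ParamSet) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != params.beta.shape:
        raise ValueError(
            f"covariate vector has length {x.size}, expected {params.beta.size}"
        )
    return x


def _overdisp_factor(params: ParamSet) -> float:
    # e^v (1/phi + 1 - e^{-v}) with v the total normal-effect variance;
    # multiplies E^2 in the excess (beyond-Poisson) variance and covariance.
    v = params.re_variance
    return float(np.exp(v) * (1.0 / params.phi + 1.0 - np.exp(-v)))


def marginal_mean(T: float, x, params: ParamSet) -> float:
    """Marginal mean ``T e^{x'beta} e^{v/2}`` of one exon count.

    ``v`` is ``sigma^2`` (two-level) or ``sigma_i^2 + sigma_s^2``
    (three-level): the lognormal random effects inflate the conditional
    mean by ``e^{v/2}``.
    """
    x = _check_x(x, params)
    if not np.isfinite(T) or T <= 0:
        raise ValueError("exposure T must be strictly positive")
    return float(T * np.exp(x @ params.beta) * np.exp(params.re_variance / 2.0))


def marginal_variance(T: float, x, params: ParamSet) -> float:
    """Marginal variance ``E {1 + e^v (1/phi + 1 - e^{-v}) E}``.

    Always at least the mean: both the gamma frailty and the lognormal
    effects overdisperse the counts relative to Poisson.
    """
    E = marginal_mean(T, x, params)
    return float(E * (1.0 + _overdisp_factor(params) * E))


def within_sample_cor(T_j: float, T_k: float, x, params: ParamSet) -> float:
    """Marginal correlation of two exon counts from the same sample.

    ``E_j E_k e^v (1/phi + 1 - e^{-v}) / sqrt(Var_j Var_k)`` — induced by
    the frailty and normal effects the two exons share.
    """
    Ej = marginal_mean(T_j, x, params)
    Ek = marginal_mean(T_k, x, params)
    c = _overdisp_factor(params)
    num = Ej * Ek * c
    den = np.sqrt(marginal_variance(T_j, x, params) * marginal_variance(T_k, x, params))
    return float(num / den)


def between_sample_cor(T_j: float, x_j, T_k: float, x_k, params: ParamSet) -> float:
    """Marginal correlation of counts from two samples of one individual.

    ``E_j E_k (e^{sigma_i^2} - 1) / sqrt(Var_j Var_k)``: only the shared
    individual-level effect correlates counts across samples, so this is
    defined for the three-level model and vanishes when ``sigma_i = 0``.
    """
    if params.sigma_i is None:
        raise ValueError(
            "between-sample correlation requires the three-level model "
            "(sigma_i is absent in this ParamSet)"
        )
    Ej = marginal_mean(T_j, x_j, params)
    Ek = marginal_mean(T_k, x_k, params)
    c = np.exp(float(params.sigma_i) ** 2) - 1.0
    den = np.sqrt(
        marginal_variance(T_j, x_j, params) * marginal_variance(T_k, x_k, params)
    )
    return float(Ej * Ek * c / den)
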