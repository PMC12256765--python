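"""Delimited-text formats, per-gene batch fitting and method comparison.

The input format is a long (tidy) table, one row per exon observation:
``gene_id, individual_id, sample_id, exon_id, count`` plus either
``exon_length`` and ``library_size`` (the exposure is their product) or a
precomputed ``exposure`` column; every remaining column is treated as a
sample-level covariate.  Long format is used because covariates attach to
samples while exposures vary per row.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FitResult, fit_gene
from .inference import HYPOTHESES, bh_adjust, hypothesis_contrast, wald_test
from .likelihood import LikelihoodConfig
from .model import GeneData

__all__ = [
    "read_counts_table",
    "write_counts_table",
    "matrix_to_long",
    "run_batch",
    "summarize_batch",
    "compare_methods",
    "bland_altman_limits",
    "config_label",
    "DataFormatError",
]

logger = logging.getLogger("hnbseq")

_ID_COLUMNS = ["gene_id", "individual_id", "sample_id", "exon_id", "count"]
_RESERVED = set(_ID_COLUMNS) | {"exon_length", "library_size", "exposure"}


class DataFormatError(ValueError):
    """A malformed input table (named row/column in the message)."""


def _fail(row, column, why) -> None:
    raise DataFormatError(f"data row {row}, column {column!r}: {why}")


def read_counts_table(
    path, sep: str | None = None, covariates: list[str] | None = None
) -> list[GeneData]:
    """Read a long-format counts table into per-gene `GeneData`.

    ``sep=None`` sniffs tab vs comma.  ``covariates`` names the covariate
    columns explicitly; by default every non-reserved column is one.  The
    intercept is added automatically.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in _ID_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"missing required column(s): {', '.join(missing)}")
    have_parts = {"exon_length", "library_size"} <= set(df.columns)
    if not have_parts and "exposure" not in df.columns:
        raise DataFormatError(
            "need either 'exon_length' and 'library_size' or an 'exposure' column"
        )
    if covariates is None:
        covariates = [c for c in df.columns if c not in _RESERVED]
    else:
        bad = [c for c in covariates if c not in df.columns]
        if bad:
            raise DataFormatError(f"covariate column(s) not found: {', '.join(bad)}")

    cnt = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[cnt.isna() | (cnt < 0) | (cnt != np.floor(cnt))]
    if len(bad):
        _fail(int(bad[0]), "count", "must be a non-negative integer")
    df["count"] = cnt.astype(np.int64)
    if have_parts:
        for col in ("exon_length", "library_size"):
            v = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[v.isna() | (v <= 0)]
            if len(bad):
                _fail(int(bad[0]), col, "must be a positive number")
            df[col] = v
        df["exposure"] = df["exon_length"] * df["library_size"]
    else:
        v = pd.to_numeric(df["exposure"], errors="coerce")
        bad = df.index[v.isna() | (v <= 0)]
        if len(bad):
            _fail(int(bad[0]), "exposure", "must be a positive number")
        df["exposure"] = v
    for col in covariates:
        v = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[v.isna()]
        if len(bad):
            _fail(int(bad[0]), col, "must be numeric")
        df[col] = v

    genes = []
    names = ("intercept", *covariates)
    for gene_id, sub in df.groupby("gene_id", sort=False):
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[c].to_numpy(float) for c in covariates]
        ) if covariates else np.ones((len(sub), 1))
        try:
            genes.append(
                GeneData(
                    gene_id=str(gene_id),
                    individual_id=sub["individual_id"].astype(str).to_numpy(object),
                    sample_id=sub["sample_id"].astype(str).to_numpy(object),
                    exon_id=sub["exon_id"].astype(str).to_numpy(object),
                    counts=sub["count"].to_numpy(),
                    exposure=sub["exposure"].to_numpy(float),
                    covariates=X,
                    covariate_names=names,
                    exon_length=sub["exon_length"].to_numpy(float)
                    if have_parts
                    else None,
                    library_size=sub["library_size"].to_numpy(float)
                    if have_parts
                    else None,
                )
            )
        except ValueError as exc:
            raise DataFormatError(f"gene {gene_id!r}: {exc}") from exc
    return genes


def matrix_to_long(
    counts: pd.DataFrame,
    exon_lengths: pd.Series,
    samples: pd.DataFrame,
    gene_id: str = "gene",
) -> pd.DataFrame:
    """Convert an exon x sample count matrix to the long input format.

    ``counts`` is indexed by exon id with one column per sample id;
    ``exon_lengths`` maps exon id to length [nt]; ``samples`` is indexed
    by sample id with columns ``individual_id``, ``library_size`` and any
    covariates.  Returns a long table ready for `read_counts_table` /
    `GeneData` construction.
    """
    missing = set(counts.index) - set(exon_lengths.index)
    if missing:
        raise DataFormatError(f"no exon_length for exon(s): {sorted(missing)}")
    missing = set(counts.columns) - set(samples.index)
    if missing:
        raise DataFormatError(f"no sample metadata for: {sorted(missing)}")
    for col in ("individual_id", "library_size"):
        if col not in samples.columns:
            raise DataFormatError(f"samples table lacks column {col!r}")
    long = counts.stack().rename("count").reset_index()
    long.columns = ["exon_id", "sample_id", "count"]
    long.insert(0, "gene_id", gene_id)
    long.insert(1, "individual_id", samples["individual_id"].reindex(
        long["sample_id"]).to_numpy())
    long["exon_length"] = exon_lengths.reindex(long["exon_id"]).to_numpy()
    long["library_size"] = samples["library_size"].reindex(
        long["sample_id"]).to_numpy()
    for col in samples.columns:
        if col not in ("individual_id", "library_size"):
            long[col] = samples[col].reindex(long["sample_id"]).to_numpy()
    return long


def write_counts_table(genes, path, sep: str = "\t") -> None:
    pd.concat([g.to_frame() for g in genes], ignore_index=True).to_csv(
        path, sep=sep, index=False
    )


def config_label(cfg: LikelihoodConfig) -> str:
    return "laplace" if cfg.method == "laplace" else f"aghq{cfg.n_nodes}"


def _coef_name(gene: GeneData, k: int) -> str:
    return gene.covariate_names[k] if k < len(gene.covariate_names) else f"x{k}"


def _fit_row(gene: GeneData, fit: FitResult | None, status: str) -> dict:
    row: dict = {"gene_id": gene.gene_id, "status": status}
    for k in range(gene.covariates.shape[1]):
        name = _coef_name(gene, k)
        row[f"beta_{name}"] = np.nan
        row[f"se_{name}"] = np.nan
    for c in ("phi", "se_phi", "sigma_s", "se_sigma_s", "sigma_i", "se_sigma_i",
              "loglik", "n_iter", "runtime_s"):
        row[c] = np.nan
    if fit is None:
        return row
    for k, b in enumerate(fit.params_hat.beta):
        name = _coef_name(gene, k)
        row[f"beta_{name}"] = b
        row[f"se_{name}"] = fit.se.get(f"beta_{k}", np.nan)
    row["phi"] = fit.params_hat.phi
    row["se_phi"] = fit.se.get("phi", np.nan)
    row["sigma_s"] = fit.params_hat.sigma_s
    row["se_sigma_s"] = fit.se.get("sigma_s", np.nan)
    if fit.params_hat.sigma_i is not None:
        row["sigma_i"] = fit.params_hat.sigma_i
        row["se_sigma_i"] = fit.se.get("sigma_i", np.nan)
    row["loglik"] = fit.loglik
    row["n_iter"] = fit.n_iter
    row["runtime_s"] = fit.runtime_s
    return row


def run_batch(
    genes,
    cfg: LikelihoodConfig | None = None,
    hypotheses=HYPOTHESES,
    q: float = 0.05,
    n_starts: int = 1,
    count_failed_in_m: bool = False,
) -> pd.DataFrame:
    """Fit every gene, test the requested hypotheses, adjust per family.

    One row per gene; per-gene failures are recorded in ``status`` and
    never abort the batch.  BH adjustment runs separately per hypothesis
    family across the genes with a usable test; ``count_failed_in_m``
    instead keeps failed genes in the nominal test count as missing.
    """
    cfg = cfg or LikelihoodConfig()
    genes = list(genes)
    rows, fits = [], []
    for gene in genes:
        try:
            fit = fit_gene(gene, cfg, n_starts=n_starts)
            status = fit.status
        except ValueError as exc:  # degenerate input (e.g. all-zero counts)
            fit, status = None, "degenerate_input"
            logger.warning("gene %s skipped: %s", gene.gene_id, exc)
        fits.append(fit)
        rows.append(_fit_row(gene, fit, status))
        logger.info("gene %s: %s", gene.gene_id, status)
    out = pd.DataFrame(rows)
    out["method"] = cfg.method
    out["n_nodes"] = cfg.effective_nodes

    for hyp in hypotheses:
        W = np.full(len(genes), np.nan)
        df_ = np.full(len(genes), np.nan)
        p = np.full(len(genes), np.nan)
        for i, (gene, fit) in enumerate(zip(genes, fits)):
            if fit is None or not fit.converged:
                continue
            try:
                C = hypothesis_contrast(hyp, gene.covariate_names)
                tr = wald_test(fit, C, hypothesis=hyp)
            except ValueError as exc:
                logger.warning("gene %s, %s: %s", gene.gene_id, hyp, exc)
                continue
            W[i], df_[i], p[i] = tr.statistic, tr.df, tr.p_raw
        m_total = len(genes) if count_failed_in_m else None
        adj, rej = bh_adjust(p, q=q, m_total=m_total)
        out[f"W_{hyp}"] = W
        out[f"df_{hyp}"] = df_
        out[f"p_{hyp}"] = p
        out[f"padj_{hyp}"] = adj
        out[f"reject_{hyp}"] = rej
    logger.info("%s", summarize_batch(out))
    return out


def summarize_batch(results: pd.DataFrame) -> str:
    """One-paragraph footer: fit statuses and per-hypothesis rejections."""
    parts = []
    counts = results["status"].value_counts()
    parts.append(
        "fits: " + ", ".join(f"{k}={int(v)}" for k, v in counts.items())
    )
    for col in results.columns:
        if col.startswith("reject_"):
            hyp = col[len("reject_"):]
            n = int(results[col].fillna(False).sum())
            parts.append(f"{hyp}: {n} rejected at FDR")
    return "; ".join(parts)


def bland_altman_limits(a, b) -> tuple[float, float, float]:
    """Bland-Altman 95% limits of agreement between two estimate vectors.

    Returns ``(mean_d, mean_d - 1.96 sd, mean_d + 1.96 sd)`` with
    ``d = a - b`` and ``sd`` the sample standard deviation (n-1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = a[keep] - b[keep]
    if d.size < 2:
        raise ValueError("need at least two complete pairs")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def compare_methods(
    genes, configs, n_starts: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit each gene under each likelihood config and summarize agreement.

    Returns the long per-gene fit table and a pairwise Bland-Altman table
    (mean difference, 95% limits of agreement, max |difference|) per
    parameter, computed over genes converged under both configs.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError("need at least two configurations to compare")
    labels = [config_label(c) for c in configs]
    if len(set(labels)) < len(labels):
        logger.warning("identical configurations in the grid; report is trivial")
    genes = list(genes)
    frames = []
    for cfg, label in zip(configs, labels):
        sub = run_batch(genes, cfg, hypotheses=(), n_starts=n_starts)
        sub.insert(1, "config", label)
        frames.append(sub)
    fits = pd.concat(frames, ignore_index=True)

    param_cols = [
        c
        for c in fits.columns
        if c.startswith("beta_") or c in ("phi", "sigma_s", "sigma_i")
    ]
    rows = []
    for (la, fa), (lb, fb) in itertools.combinations(zip(labels, frames), 2):
        ok = (fa["status"] == "converged").to_numpy() & (
            fb["status"] == "converged"
        ).to_numpy()
        for col in param_cols:
            a = fa.loc[ok, col].to_numpy(float)
            b = fb.loc[ok, col].to_numpy(float)
            complete = ~(np.isnan(a) | np.isnan(b))
            if complete.sum() < 2:
                continue
            mean, lo, hi = bland_altman_limits(a[complete], b[complete])
            rows.append(
                {
                    "parameter": col,
                    "config_a": la,
                    "config_b": lb,
                    "n": int(complete.sum()),
                    "mean_diff": mean,
                    "lower": lo,
                    "upper": hi,
                    "max_abs_diff": float(np.max(np.abs(a[complete] - b[complete]))),
                }
            )
    return fits, pd.DataFrame(rows)
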