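"""Model-based simulator emulating the motivating study design.

Generates per-gene exon count tables from the exact generative hierarchy:
a lognormal individual effect (three-level only), a lognormal sample
effect, one gamma frailty per sample shared across its exons (this shared
frailty is what induces the within-sample correlation), and conditionally
independent Poisson counts with exposure = exon length x library size.

Defaults mirror the longitudinal design that motivates the model:
29 patients with up to 3 visits plus 13 single-sample controls, 11 exons
per gene with lengths spanning 76-1705 nt, and library sizes between
1.7e6 and 3.5e6 reads.  Covariates are visit indicators (controls all
zero), so ``beta_1..beta_3`` are log fold-changes of patients at each
visit versus controls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .model import GeneData, ParamSet

__all__ = ["SimDesign", "simulate_gene", "simulate_dataset", "gene_param_sampler"]

_MAX_RATE = 1e15  # Poisson rates beyond this indicate runaway parameters


@dataclass(frozen=True)
class SimDesign:
    """Study layout and generative parameters for one simulated gene.

    ``exon_lengths`` / ``library_sizes`` may be given explicitly;
    otherwise lengths are drawn log-uniform on [76, 1705] nt per gene and
    library sizes uniform on [1.7e6, 3.5e6] per sample.  ``levels`` must
    agree with whether ``params.sigma_i`` is present.  ``missing_rate``
    drops patient samples at random (the study discarded 3 of them).
    """

    params: ParamSet
    n_patients: int = 29
    visits_per_patient: int = 3
    n_controls: int = 13
    n_exons: int = 11
    exon_lengths: Sequence[float] | None = None
    library_sizes: Sequence[float] | None = None
    levels: str = "three"
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels not in ("two", "three"):
            raise ValueError("levels must be 'two' or 'three'")
        want_three = self.levels == "three"
        have_three = self.params.sigma_i is not None
        if want_three != have_three:
            raise ValueError(
                f"levels={self.levels!r} inconsistent with params "
                f"(sigma_i {'present' if have_three else 'absent'})"
            )
        if min(self.n_patients, 0) < 0 or min(self.n_controls, 0) < 0:
            raise ValueError("negative group size")
        if self.n_patients + self.n_controls < 1:
            raise ValueError("need at least one individual")
        if self.n_exons < 1 or self.visits_per_patient < 0:
            raise ValueError("need at least one exon")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.exon_lengths is not None:
            L = np.asarray(self.exon_lengths, dtype=float)
            if L.size != self.n_exons or np.any(L <= 0):
                raise ValueError("exon_lengths must be n_exons positive values")
        p = 1 + self.visits_per_patient
        if self.params.beta.size != p:
            raise ValueError(
                f"params.beta has length {self.params.beta.size}; the visit "
                f"design needs {p} (intercept + visit indicators)"
            )

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return ("intercept",) + tuple(
            f"visit{v}" for v in range(1, self.visits_per_patient + 1)
        )


def _layout(design: SimDesign, rng: np.random.Generator):
    """Sample grid: individual / sample ids, visit of each sample."""
    ind, smp, visit = [], [], []
    for i in range(design.n_patients):
        pid = f"P{i + 1:03d}"
        for v in range(1, design.visits_per_patient + 1):
            ind.append(pid)
            smp.append(f"{pid}_v{v}")
            visit.append(v)
    for i in range(design.n_controls):
        cid = f"C{i + 1:03d}"
        ind.append(cid)
        smp.append(f"{cid}_v0")
        visit.append(0)
    keep = np.ones(len(smp), dtype=bool)
    if design.missing_rate > 0:
        patient_rows = np.asarray(visit) > 0
        drop = rng.random(len(smp)) < design.missing_rate
        keep = ~(drop & patient_rows)
        # never drop an individual's last remaining sample entirely? the
        # model copes with singletons, so plain thinning is fine -- but do
        # keep at least one sample overall
        if not keep.any():
            keep[0] = True
    return (
        [g for g, k in zip(ind, keep) if k],
        [s for s, k in zip(smp, keep) if k],
        [v for v, k in zip(visit, keep) if k],
    )


def simulate_gene(
    design: SimDesign,
    rng: np.random.Generator | None = None,
    gene_id: str = "gene_0001",
) -> GeneData:
    """Draw one gene's counts from the generative hierarchy.

    The draw order (layout thinning, exon lengths, library sizes,
    individual normals, sample normals, gamma frailties, Poisson counts)
    is fixed, and the individual-level normals are always drawn and scaled
    by ``sigma_i`` (0 for the two-level model), so a three-level design
    with ``sigma_i = 0`` reproduces the two-level output exactly at the
    same seed.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    params = design.params
    ind, smp, visit = _layout(design, rng)
    S = len(smp)
    J = design.n_exons

    if design.exon_lengths is not None:
        d = np.asarray(design.exon_lengths, dtype=float)
    else:
        d = np.exp(rng.uniform(np.log(76.0), np.log(1705.0), size=J)).round()
    if design.library_sizes is not None:
        lib = np.asarray(design.library_sizes, dtype=float)
        if lib.size == 1:
            lib = np.full(S, lib.item())
        if lib.size != S:
            raise ValueError(f"library_sizes must have one value per sample ({S})")
    else:
        lib = rng.uniform(1.7e6, 3.5e6, size=S)

    p = 1 + design.visits_per_patient
    X = np.zeros((S, p))
    X[:, 0] = 1.0
    for s, v in enumerate(visit):
        if v > 0:
            X[s, v] = 1.0

    ind_ids = list(dict.fromkeys(ind))
    code = {g: k for k, g in enumerate(ind_ids)}
    ind_codes = np.asarray([code[g] for g in ind])

    sigma_i = float(params.sigma_i) if params.sigma_i is not None else 0.0
    b_ind = sigma_i * rng.standard_normal(len(ind_ids))
    b_smp = float(params.sigma_s) * rng.standard_normal(S)
    gam = rng.gamma(shape=params.phi, scale=1.0 / params.phi, size=S)

    eta = X @ params.beta + b_ind[ind_codes] + b_smp  # (S,)
    T = d[None, :] * lib[:, None]  # (S, J)
    rate = T * (gam * np.exp(eta))[:, None]
    if not np.all(np.isfinite(rate)) or np.any(rate > _MAX_RATE):
        raise ValueError("non-finite or runaway Poisson rate; check parameters")
    y = rng.poisson(rate)

    rep = np.repeat(np.arange(S), J)
    exn = np.tile(np.array([f"exon_{j + 1:02d}" for j in range(J)], dtype=object), S)
    return GeneData(
        gene_id=gene_id,
        individual_id=np.asarray(ind, dtype=object)[rep],
        sample_id=np.asarray(smp, dtype=object)[rep],
        exon_id=exn,
        counts=y.ravel(),
        exposure=T.ravel(),
        covariates=X[rep],
        covariate_names=design.covariate_names,
        exon_length=np.tile(d, S),
        library_size=lib[rep],
    )


def gene_param_sampler(
    null_fraction: float = 1.0,
    beta0: float = -15.4,
    effect_sd: float = 0.75,
    levels: str = "two",
    n_visits: int = 3,
) -> Callable[[np.random.Generator], ParamSet]:
    """Per-gene parameter sampler for multi-gene datasets.

    Dispersion ``phi`` is log-uniform on [0.1, 10] and the sample SD
    uniform on [0, 0.6] (three-level: sigma_i uniform on [0, 0.4]);
    a ``1 - null_fraction`` share of genes get nonzero visit effects drawn
    iid ``N(0, effect_sd^2)``.
    """
    if levels not in ("two", "three"):
        raise ValueError("levels must be 'two' or 'three'")

    def sample(rng: np.random.Generator) -> ParamSet:
        beta = np.zeros(1 + n_visits)
        beta[0] = beta0
        if rng.random() >= null_fraction:
            beta[1:] = rng.normal(0.0, effect_sd, size=n_visits)
        phi = float(np.exp(rng.uniform(np.log(0.1), np.log(10.0))))
        sigma_s = float(rng.uniform(0.0, 0.6))
        sigma_i = float(rng.uniform(0.0, 0.4)) if levels == "three" else None
        return ParamSet(beta=beta, phi=phi, sigma_s=sigma_s, sigma_i=sigma_i)

    return sample


def simulate_dataset(
    design: SimDesign,
    n_genes: int,
    effect_spec: Callable[[np.random.Generator], ParamSet] | None = None,
) -> list[GeneData]:
    """Simulate ``n_genes`` independent genes.

    Each gene gets its own substream spawned from ``design.seed`` (so gene
    ``i`` is reproducible in isolation and genes share no draws).  When
    ``effect_spec`` is given it is called first on the gene's stream to
    draw that gene's ParamSet; otherwise all genes use ``design.params``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    children = np.random.SeedSequence(design.seed).spawn(n_genes)
    genes = []
    for g, child in enumerate(children):
        rng = np.random.default_rng(child)
        d = design
        if effect_spec is not None:
            d = replace(design, params=effect_spec(rng))
        genes.append(simulate_gene(d, rng=rng, gene_id=f"gene_{g + 1:04d}"))
    return genes
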