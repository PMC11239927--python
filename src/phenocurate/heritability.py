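"""Entry-mean heritability from a genotype-random fit.

    h2 = sigma2_G / (sigma2_G + sigma2_e / Year)

with ``sigma2_G`` the genetic variance of accessions, ``sigma2_e`` the
average (unweighted over retained years) error variance, and ``Year``
the average number of distinct years each accession was tested.  This is
the repeatability of an accession mean over its typical number of
testing occasions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .mixed_model import ModelSpec, prune_sparse, reml_fit
from .records import Dataset

logger = logging.getLogger(__name__)


@dataclass
class HeritabilityResult:
    """Heritability of one trait at one dataset stage (original or enhanced)."""

    trait: str
    dataset_stage: str
    fit_ok: bool
    sigma2_G: float | None = None
    sigma2_e_mean: float | None = None
    mean_years: float | None = None
    h2: float | None = None
    diagnosis: str | None = None


def mean_years(dataset: Dataset, trait: str) -> float:
    """Average number of distinct years each accession was tested for ``trait``."""
    sub = dataset.df[dataset.df["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait}")
    return float(sub.groupby("accession_id")["year"].nunique().mean())


def entry_mean_h2(sigma2_G: float, sigma2_e_mean: float, mean_years: float) -> float:
    """The entry-mean heritability ratio.

    Strictly increasing in ``sigma2_G`` and ``mean_years``, decreasing in
    ``sigma2_e_mean``; always in [0, 1].
    """
    if sigma2_G < 0 or sigma2_e_mean < 0:
        raise ValueError("variance components must be non-negative")
    if mean_years < 1:
        raise ValueError("mean_years must be >= 1")
    if sigma2_G == 0 and sigma2_e_mean == 0:
        raise ValueError("heritability undefined: both variances are zero")
    return sigma2_G / (sigma2_G + sigma2_e_mean / mean_years)


def heritability_pipeline(
    dataset: Dataset,
    trait: str,
    spec: ModelSpec | None = None,
    dataset_stage: str = "original",
) -> HeritabilityResult:
    """Genotype-random REML fit -> variance components -> entry-mean h2.

    ``mean_years`` is computed on the same (pruned) records the fit used,
    so the enhanced-stage h2 reflects post-removal year counts.  Fit
    failure -- non-convergence, a genetic component pinned at the
    variance floor together with a floored error, or a degenerate design
    -- is reported via ``fit_ok = False`` with a diagnosis, never raised.
    """
    spec = replace(spec or ModelSpec(), genotype_role="random")
    try:
        pruned, _ = prune_sparse(dataset, trait, spec)
        fit = reml_fit(pruned, trait, spec)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return HeritabilityResult(
            trait=trait, dataset_stage=dataset_stage, fit_ok=False, diagnosis=str(exc)
        )
    vc = fit.varcomp
    my = mean_years(pruned, trait)
    if not fit.converged:
        return HeritabilityResult(
            trait=trait,
            dataset_stage=dataset_stage,
            fit_ok=False,
            sigma2_G=vc.sigma2_G,
            sigma2_e_mean=vc.sigma2_e_mean,
            mean_years=my,
            diagnosis="REML did not converge: " + "; ".join(fit.messages),
        )
    if "sigma2_G_at_floor" in vc.flags and "per_year_error_at_floor" in vc.flags:
        return HeritabilityResult(
            trait=trait,
            dataset_stage=dataset_stage,
            fit_ok=False,
            sigma2_G=vc.sigma2_G,
            sigma2_e_mean=vc.sigma2_e_mean,
            mean_years=my,
            diagnosis="genetic and error variances both pinned at the floor",
        )
    h2 = entry_mean_h2(vc.sigma2_G, vc.sigma2_e_mean, my)
    return HeritabilityResult(
        trait=trait,
        dataset_stage=dataset_stage,
        fit_ok=True,
        sigma2_G=vc.sigma2_G,
        sigma2_e_mean=vc.sigma2_e_mean,
        mean_years=my,
        h2=float(h2),
    )
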