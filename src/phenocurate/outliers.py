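"""Robust residual-based outlier screening with family-wise error control.

From a genotype-fixed fit, residuals are standardised by their year's
error SD, centred on the median and rescaled by 1.4826 times the median
absolute deviation (the MAD consistency constant for a normal law).
Two-sided normal p-values of these robust z-scores are then subjected to
a Bonferroni-Holm step-down test at ``alpha`` (default 0.05); flagged
records are removed in a single pass, yielding the "enhanced" dataset.

A leverage-corrected (internally studentised) variant of the scores is
available behind ``studentized=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_model import FitResult, ModelSpec, prune_sparse, reml_fit
from .records import Dataset
from .util import round_half_up

logger = logging.getLogger(__name__)

MAD_RESCALE = 1.4826

Key = tuple[str, int, str]


@dataclass
class OutlierReport:
    """Per-trait outlier screening summary (one row of a Table-3-style report).

    ``n_records_pruned`` counts the records *remaining after* sparse-year
    pruning; ``corrected_size = n_records_pruned - n_outliers`` and
    ``outlier_pct = round(100 * n_outliers / n_records_pruned, 2)`` hold
    by construction.
    """

    trait: str
    n_records: int
    n_accessions: int
    n_records_pruned: int
    n_accessions_pruned: int
    n_outliers: int
    flagged: list[tuple[Key, float, float, float]] = field(default_factory=list)
    fit_converged: bool = True
    failure: str | None = None
    degenerate_spread: bool = False
    # data snapshots for output writing (not part of the summary row)
    source_df: pd.DataFrame | None = None
    corrected_df: pd.DataFrame | None = None

    @property
    def corrected_size(self) -> int:
        return self.n_records_pruned - self.n_outliers

    @property
    def outlier_pct(self) -> float:
        if self.n_records_pruned == 0:
            return 0.0
        return round_half_up(100.0 * self.n_outliers / self.n_records_pruned, 2)

    def summary_row(self) -> dict:
        return {
            "trait": self.trait,
            "n_records": self.n_records,
            "n_accessions": self.n_accessions,
            "n_records_pruned": self.n_records_pruned,
            "n_accessions_pruned": self.n_accessions_pruned,
            "n_outliers": self.n_outliers,
            "outlier_pct": self.outlier_pct,
            "corrected_size": self.corrected_size,
        }


def standardized_scores(
    fit: FitResult, studentized: bool = False
) -> dict[Key, tuple[float, float]]:
    """Robust z-score and two-sided normal p-value per fitted record.

    ``r_k = e_k / sigma_hat_year(k)`` (optionally divided by
    ``sqrt(1 - leverage)`` when ``studentized``), then
    ``z_k = (r_k - median(r)) / (1.4826 * MAD(r))`` and
    ``p_k = 2 * (1 - Phi(|z_k|))``.

    Returns an empty mapping (degenerate spread) when the rescaled MAD is
    zero, i.e. at least half of the residuals coincide.
    """
    if fit.spec.genotype_role != "fixed":
        raise ValueError("outlier scores require a genotype-fixed fit")
    if not fit.converged:
        raise ValueError("outlier scores require a converged fit")
    keys = list(fit.residuals)
    e = np.array([fit.residuals[k] for k in keys])
    sd = np.array([np.sqrt(fit.varcomp.per_year_error[k[1]]) for k in keys])
    r = e / sd
    if studentized:
        lev = np.array([fit.leverages[k] for k in keys])
        r = r / np.sqrt(1.0 - lev)
    m = float(np.median(r))
    mad = MAD_RESCALE * float(np.median(np.abs(r - m)))
    if mad == 0.0:
        logger.warning(
            "degenerate residual spread (rescaled MAD = 0): no outlier scores"
        )
        return {}
    z = (r - m) / mad
    p = 2.0 * stats.norm.sf(np.abs(z))
    return {k: (float(zi), float(pi)) for k, zi, pi in zip(keys, z, p)}


def holm_flags(pvalues: dict[Key, float], alpha: float = 0.05) -> set[Key]:
    """Bonferroni-Holm step-down: flag while ``p_(i) <= alpha / (n - i + 1)``.

    Stops at the first failure; ties in p are ordered by record key so
    the scan is deterministic (the flag decisions themselves do not
    depend on tie order).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not pvalues:
        return set()
    items = sorted(pvalues.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    flagged: set[Key] = set()
    for i, (key, p) in enumerate(items, start=1):
        if p <= alpha / (n - i + 1):
            flagged.add(key)
        else:
            break
    return flagged


def holm_adjusted(pvalues: dict[Key, float]) -> dict[Key, float]:
    """Monotone Holm-adjusted p-values: ``max_{j<=i} min(1, (n-j+1) p_(j))``."""
    items = sorted(pvalues.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    out: dict[Key, float] = {}
    running = 0.0
    for i, (key, p) in enumerate(items, start=1):
        running = max(running, min(1.0, (n - i + 1) * p))
        out[key] = running
    return out


def correct_outliers(
    dataset: Dataset,
    trait: str,
    spec: ModelSpec | None = None,
    alpha: float = 0.05,
    studentized: bool = False,
) -> tuple[Dataset | None, OutlierReport]:
    """Single-pass outlier correction for one trait.

    prune sparse years -> genotype-fixed REML fit -> robust z-scores ->
    Holm flags at ``alpha`` -> remove flagged records.  The returned
    dataset keeps other traits' records untouched; for the screened trait
    it contains the pruned records minus the flagged ones.  On fit
    failure the report carries the failure and no dataset is emitted.
    """
    spec = replace(spec or ModelSpec(), genotype_role="fixed")
    sub = dataset.df[dataset.df["trait"] == trait]
    n_records = len(sub)
    n_accessions = sub["accession_id"].nunique()
    pruned, prune_report = prune_sparse(dataset, trait, spec)
    psub = pruned.df[pruned.df["trait"] == trait]
    report = OutlierReport(
        trait=trait,
        n_records=n_records,
        n_accessions=int(n_accessions),
        n_records_pruned=len(psub),
        n_accessions_pruned=int(psub["accession_id"].nunique()),
        n_outliers=0,
        source_df=dataset.df.copy(),
    )
    try:
        fit = reml_fit(pruned, trait, spec)
        if not fit.converged:
            raise RuntimeError(
                "REML did not converge: " + "; ".join(fit.messages)
            )
    except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
        report.fit_converged = False
        report.failure = str(exc)
        return None, report
    fit.n_records_pruned = prune_report.n_removed

    scores = standardized_scores(fit, studentized=studentized)
    if not scores:
        report.degenerate_spread = True
        enhanced = pruned
        report.corrected_df = enhanced.df[enhanced.df["trait"] == trait].copy()
        return enhanced, report

    pvals = {k: p for k, (_, p) in scores.items()}
    flags = holm_flags(pvals, alpha)
    adjusted = holm_adjusted(pvals)
    report.n_outliers = len(flags)
    report.flagged = sorted(
        (
            (k, scores[k][0], scores[k][1], adjusted[k])
            for k in flags
        ),
        key=lambda row: (row[3], row[0]),
    )
    enhanced = pruned.remove_keys(flags)
    report.corrected_df = enhanced.df[enhanced.df["trait"] == trait].copy()
    return enhanced, report
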