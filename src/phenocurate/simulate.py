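"""Synthetic non-orthogonal multi-year regeneration trials with known truth.

Emulates the structure of historical genebank phenotype data: each
accession is regenerated (and scored) in a small number of distinct
years drawn from a configurable distribution, year effects are shared
random shocks, residual variances differ by year (lognormal across
years, mean pinned to ``sigma2_e_mean``), and a configurable fraction of
records carries a gross error -- a symmetric location shift expressed in
units of that year's residual SD.

All randomness flows through a single ``numpy`` Generator seeded from
``SimConfig.seed``.  Draw order (fixed for reproducibility):

1. accession origins, 2. distinct-year counts ``k_i``, 3. the year subset
of each accession, 4. genotype effects, 5. year effects, 6. per-year
log-variance deviates, 7. residuals, 8. contamination mask, 9. shift signs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .records import Dataset, UNKNOWN_ORIGIN

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_collection",
    "simulate_paperlike",
    "simulate_three_traits",
    "spring_years_pmf",
    "winter_years_pmf",
    "PAPERLIKE_PRESETS",
]


def spring_years_pmf() -> tuple[float, ...]:
    """Distinct-regeneration-year distribution for a spring-type collection.

    Support 1..8 with modes at 1 and 3 years, matching collections whose
    accessions were regenerated in one to eight different years.
    """
    return (0.34, 0.13, 0.27, 0.10, 0.07, 0.045, 0.028, 0.017)


def winter_years_pmf(k_max: int = 28) -> tuple[float, ...]:
    """Distinct-year distribution for a winter-type collection (support 1..k_max).

    Mass concentrated on 2-3 year regeneration cycles with a thin
    geometric tail out to ``k_max`` (long-conserved accessions seen in up
    to ~28 different years).
    """
    head = [0.18, 0.28, 0.26, 0.10, 0.06, 0.04, 0.025, 0.015]
    if k_max <= len(head):
        w = np.asarray(head[:k_max])
        return tuple(w / w.sum())
    tail = 0.8 ** np.arange(1, k_max - len(head) + 1)
    tail *= 0.04 / tail.sum()
    w = np.concatenate([head, tail])
    return tuple(w / w.sum())


_DEFAULT_ORIGINS: dict[str, float] = {
    "MEX": 0.20,
    "RUS": 0.08,
    "CSK": 0.06,
    "DEU": 0.06,
    "USA": 0.04,
    "JPN": 0.04,
    "FRA": 0.03,
    "CAN": 0.03,
    "CZE": 0.03,
    "POL": 0.02,
    UNKNOWN_ORIGIN: 0.03,
    "OTH": 0.38,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated collection (one trait).

    ``years_per_accession_pmf[k-1]`` is the probability that an accession
    is scored in exactly ``k`` distinct years; its support must not
    exceed ``n_years``.  Per-year error variances follow
    ``sigma2_e_mean * exp(tau * z - tau**2 / 2)`` with ``z`` standard
    normal, so their expectation is ``sigma2_e_mean`` for any ``tau``.
    A ``Binomial(N, contamination_rate)`` subset of records is shifted by
    ``+/- shift_sd_multiplier * sigma_j`` (sign random).
    """

    n_accessions: int = 500
    n_years: int = 20
    years_per_accession_pmf: tuple[float, ...] = field(
        default_factory=lambda: winter_years_pmf(8)
    )
    mu: float = 100.0
    sigma2_G: float = 300.0
    sigma2_year: float = 50.0
    sigma2_e_mean: float = 85.0
    tau: float = 0.3
    contamination_rate: float = 0.0
    shift_sd_multiplier: float = 8.0
    origin_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ORIGINS)
    )
    seed: int = 0
    trait: str = "PH"
    growth_habit: str = "winter"
    start_year: int = 1991

    def validate(self) -> None:
        pmf = np.asarray(self.years_per_accession_pmf, float)
        if pmf.ndim != 1 or len(pmf) == 0:
            raise ValueError("years_per_accession_pmf must be a non-empty vector")
        if (pmf < 0).any() or not math.isclose(pmf.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("years_per_accession_pmf must be a probability vector")
        if len(pmf) > self.n_years:
            raise ValueError(
                f"pmf support {len(pmf)} exceeds n_years={self.n_years}"
            )
        if not (0.0 <= self.contamination_rate < 1.0):
            raise ValueError("contamination_rate must be in [0, 1)")
        if min(self.sigma2_G, self.sigma2_year, self.tau) < 0:
            raise ValueError("variance parameters must be non-negative")
        if self.sigma2_e_mean <= 0:
            raise ValueError("sigma2_e_mean must be positive")
        if self.shift_sd_multiplier < 0:
            raise ValueError("shift_sd_multiplier must be non-negative")


@dataclass
class TruthRecord:
    """Simulation ground truth for recovery tests."""

    genotype_effects: dict[str, float]
    year_effects: dict[int, float]
    per_year_error_variance: dict[int, float]
    outlier_indices: set[tuple[str, int, str]]
    true_h2: float
    mean_years: float


def _acc_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"ACC{i:0{width}d}" for i in range(1, n + 1)]


def _draw_design(rng: np.random.Generator, cfg: SimConfig):
    """Origins, distinct-year counts and year subsets (draws 1-3)."""
    origins_pool = list(cfg.origin_weights)
    w = np.asarray([cfg.origin_weights[o] for o in origins_pool], float)
    origins = rng.choice(origins_pool, size=cfg.n_accessions, p=w / w.sum())
    pmf = np.asarray(cfg.years_per_accession_pmf, float)
    pmf = pmf / pmf.sum()
    ks = rng.choice(np.arange(1, len(pmf) + 1), size=cfg.n_accessions, p=pmf)
    year_sets = [
        np.sort(rng.choice(cfg.n_years, size=int(k), replace=False)) for k in ks
    ]
    return origins, ks, year_sets


def simulate_collection(config: SimConfig) -> tuple[Dataset, TruthRecord]:
    """Generate one trait's records ``y = mu + g_i + a_j + e_ij`` plus truth.

    Fully reproducible from ``config.seed``; identical configs yield
    identical datasets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    origins, ks, year_sets = _draw_design(rng, config)
    g = rng.normal(0.0, math.sqrt(config.sigma2_G), config.n_accessions)
    a = rng.normal(0.0, math.sqrt(config.sigma2_year), config.n_years)
    z = rng.standard_normal(config.n_years)
    s2j = config.sigma2_e_mean * np.exp(config.tau * z - config.tau**2 / 2.0)

    acc_ids = _acc_ids(config.n_accessions)
    years = config.start_year + np.arange(config.n_years)

    acc_idx = np.concatenate(
        [np.full(len(ys), i, dtype=int) for i, ys in enumerate(year_sets)]
    )
    yr_idx = np.concatenate(year_sets)
    n_rec = len(yr_idx)
    e = rng.normal(0.0, np.sqrt(s2j[yr_idx]))
    y = config.mu + g[acc_idx] + a[yr_idx] + e

    contaminated = rng.random(n_rec) < config.contamination_rate
    signs = rng.choice([-1.0, 1.0], size=n_rec)
    shift = contaminated * signs * config.shift_sd_multiplier * np.sqrt(s2j[yr_idx])
    y = y + shift

    df = pd.DataFrame(
        {
            "accession_id": [acc_ids[i] for i in acc_idx],
            "year": years[yr_idx],
            "trait": config.trait,
            "value": y,
            "value_type": "single",
        }
    )
    provenance = dict(zip(acc_ids, origins))
    dataset = Dataset(
        df, config.growth_habit, provenance=provenance, validate=False
    )

    keys = list(zip(df["accession_id"], df["year"].astype(int), df["trait"]))
    outlier_keys = {k for k, c in zip(keys, contaminated) if c}
    mean_years = float(np.mean(ks))
    true_h2 = config.sigma2_G / (
        config.sigma2_G + config.sigma2_e_mean / mean_years
    )
    truth = TruthRecord(
        genotype_effects=dict(zip(acc_ids, g.astype(float))),
        year_effects={int(yl): float(v) for yl, v in zip(years, a)},
        per_year_error_variance={
            int(yl): float(v) for yl, v in zip(years, s2j)
        },
        outlier_indices=outlier_keys,
        true_h2=float(true_h2),
        mean_years=mean_years,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# presets at the scale of a real spring/winter wheat collection
# ---------------------------------------------------------------------------

# variance scales per trait follow the magnitude of REML components
# estimated on the historical collections (PH dominated by genetics and
# year, HD by year, TGW smallest overall)
PAPERLIKE_PRESETS: dict[tuple[str, str], SimConfig] = {}


def _register_presets() -> None:
    spring_common = dict(
        n_accessions=1000,
        n_years=40,
        years_per_accession_pmf=spring_years_pmf(),
        growth_habit="spring",
        start_year=1981,
        tau=0.3,
    )
    winter_common = dict(
        n_accessions=3400,
        n_years=60,
        years_per_accession_pmf=winter_years_pmf(28),
        growth_habit="winter",
        start_year=1951,
        tau=0.3,
    )
    scales = {
        ("spring", "HD"): dict(mu=160.0, sigma2_G=17.0, sigma2_year=51.0, sigma2_e_mean=25.0),
        ("spring", "PH"): dict(mu=100.0, sigma2_G=192.0, sigma2_year=75.0, sigma2_e_mean=41.0),
        ("spring", "TGW"): dict(mu=40.0, sigma2_G=23.0, sigma2_year=12.5, sigma2_e_mean=9.4),
        ("winter", "HD"): dict(mu=155.0, sigma2_G=23.0, sigma2_year=28.0, sigma2_e_mean=10.0),
        ("winter", "PH"): dict(mu=105.0, sigma2_G=300.0, sigma2_year=50.0, sigma2_e_mean=87.0),
        ("winter", "TGW"): dict(mu=42.0, sigma2_G=15.0, sigma2_year=9.8, sigma2_e_mean=9.4),
    }
    for (profile, trait), sc in scales.items():
        common = spring_common if profile == "spring" else winter_common
        PAPERLIKE_PRESETS[(profile, trait)] = SimConfig(
            trait=trait, **common, **sc
        )


_register_presets()


def simulate_paperlike(
    profile: str, seed: int, trait: str = "PH"
) -> tuple[Dataset, TruthRecord]:
    """Simulate at the scale of the real spring or winter collection.

    ``spring``: ~1,000 accessions scored in 1-8 distinct years;
    ``winter``: ~3,400 accessions scored in up to ~28 distinct years.
    Variance scales per trait mirror the components observed on the
    historical data.
    """
    key = (profile, trait)
    if key not in PAPERLIKE_PRESETS:
        raise ValueError(
            f"unknown profile/trait {key}; available: {sorted(PAPERLIKE_PRESETS)}"
        )
    return simulate_collection(replace(PAPERLIKE_PRESETS[key], seed=seed))


def simulate_three_traits(
    profile: str, seed: int, missing_rate: float = 0.03
) -> tuple[Dataset, dict[str, TruthRecord]]:
    """Three jointly observed traits on one shared regeneration design.

    The accession-year design (and origins) is drawn once; genotype/year
    effects and residuals are trait-specific.  Each trait cell is then
    independently blanked with probability ``missing_rate`` so the three
    trait columns of the resulting assay table have realistic,
    non-identical missingness.
    """
    base = PAPERLIKE_PRESETS[(profile, "PH")]
    if (profile, "PH") not in PAPERLIKE_PRESETS:
        raise ValueError(f"unknown profile {profile!r}")
    design_rng = np.random.default_rng(seed)
    origins, ks, year_sets = _draw_design(design_rng, replace(base, seed=seed))
    acc_ids = _acc_ids(base.n_accessions)
    years = base.start_year + np.arange(base.n_years)
    acc_idx = np.concatenate(
        [np.full(len(ys), i, dtype=int) for i, ys in enumerate(year_sets)]
    )
    yr_idx = np.concatenate(year_sets)
    n_rec = len(yr_idx)

    frames = []
    truths: dict[str, TruthRecord] = {}
    for t_off, trait in enumerate(("HD", "PH", "TGW")):
        cfg = PAPERLIKE_PRESETS[(profile, trait)]
        rng = np.random.default_rng((seed + 1) * 1000 + t_off)
        g = rng.normal(0.0, math.sqrt(cfg.sigma2_G), cfg.n_accessions)
        a = rng.normal(0.0, math.sqrt(cfg.sigma2_year), cfg.n_years)
        z = rng.standard_normal(cfg.n_years)
        s2j = cfg.sigma2_e_mean * np.exp(cfg.tau * z - cfg.tau**2 / 2.0)
        e = rng.normal(0.0, np.sqrt(s2j[yr_idx]))
        y = cfg.mu + g[acc_idx] + a[yr_idx] + e
        keep = rng.random(n_rec) >= missing_rate
        df = pd.DataFrame(
            {
                "accession_id": [acc_ids[i] for i in acc_idx[keep]],
                "year": years[yr_idx[keep]],
                "trait": trait,
                "value": y[keep],
                "value_type": "single",
            }
        )
        frames.append(df)
        kept_keys = set(
            zip(df["accession_id"], df["year"].astype(int), df["trait"])
        )
        kept_ks = (
            df.groupby("accession_id")["year"].nunique().to_numpy(float)
        )
        mean_years = float(kept_ks.mean())
        truths[trait] = TruthRecord(
            genotype_effects=dict(zip(acc_ids, g.astype(float))),
            year_effects={int(yl): float(v) for yl, v in zip(years, a)},
            per_year_error_variance={
                int(yl): float(v) for yl, v in zip(years, s2j)
            },
            outlier_indices=set(),
            true_h2=float(
                cfg.sigma2_G / (cfg.sigma2_G + cfg.sigma2_e_mean / mean_years)
            ),
            mean_years=mean_years,
        )
    combined = pd.concat(frames, ignore_index=True)
    dataset = Dataset(
        combined,
        base.growth_habit,
        provenance=dict(zip(acc_ids, origins)),
        validate=False,
    )
    return dataset, truths
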