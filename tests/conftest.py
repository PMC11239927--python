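from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phenocurate.mixed_model import ModelSpec, prune_sparse, reml_fit
from phenocurate.records import Dataset
from phenocurate.simulate import SimConfig, simulate_collection

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_dataset(rows, growth_habit="spring", provenance=None):
    """rows: iterable of (accession_id, year, trait, value)."""
    df = pd.DataFrame(rows, columns=["accession_id", "year", "trait", "value"])
    df["value_type"] = "single"
    return Dataset(df, growth_habit, provenance=provenance)


@pytest.fixture(scope="session")
def toy_8rec():
    """3 accessions x 3 years, 8 records (one cell missing)."""
    rows = [
        ("A", 2001, "PH", 10.1),
        ("A", 2002, "PH", 12.3),
        ("A", 2003, "PH", 11.8),
        ("B", 2001, "PH", 14.2),
        ("B", 2002, "PH", 15.9),
        ("B", 2003, "PH", 16.4),
        ("C", 2001, "PH", 13.0),
        ("C", 2002, "PH", 13.7),
    ]
    return make_dataset(rows)


@pytest.fixture(scope="session")
def midsize_sim():
    """A moderately sized heteroscedastic simulation shared across tests."""
    cfg = SimConfig(n_accessions=300, n_years=15, seed=11)
    return simulate_collection(cfg)


@pytest.fixture(scope="session")
def midsize_fixed_fit(midsize_sim):
    ds, _ = midsize_sim
    spec = ModelSpec(genotype_role="fixed")
    pruned, _ = prune_sparse(ds, "PH", spec)
    return reml_fit(pruned, "PH", spec)


@pytest.fixture(scope="session")
def recovery_study():
    """25-seed winter-like parameter-recovery study (genotype random).

    500 accessions, 20 years, sigma2_G = 300, sigma2_year = 50, mean
    per-year error variance 85 with lognormal spread tau = 0.3.
    """
    from phenocurate.heritability import heritability_pipeline

    rows = []
    for seed in range(25):
        cfg = SimConfig(
            n_accessions=500,
            n_years=20,
            sigma2_G=300.0,
            sigma2_year=50.0,
            sigma2_e_mean=85.0,
            tau=0.3,
            seed=seed,
        )
        ds, truth = simulate_collection(cfg)
        hres = heritability_pipeline(ds, "PH")
        assert hres.fit_ok
        rows.append(
            {
                "sigma2_G_hat": hres.sigma2_G,
                "h2_hat": hres.h2,
                "true_h2": truth.true_h2,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def contamination_study():
    """10-seed operating-characteristics study: 3% gross errors at 8 sigma."""
    from phenocurate.outliers import correct_outliers

    rows = []
    for seed in range(10):
        cfg = SimConfig(
            n_accessions=1000,
            n_years=20,
            contamination_rate=0.03,
            shift_sd_multiplier=8.0,
            seed=100 + seed,
        )
        ds, truth = simulate_collection(cfg)
        enhanced, report = correct_outliers(ds, "PH")
        flagged = {k for k, _, _, _ in report.flagged}
        kept = set(
            zip(
                report.corrected_df["accession_id"],
                report.corrected_df["year"].astype(int),
                report.corrected_df["trait"],
            )
        )
        screened = kept | flagged
        injected = truth.outlier_indices & screened
        clean = screened - injected
        rows.append(
            {
                "sensitivity": len(flagged & injected) / len(injected),
                "false_flag_rate": len(flagged - injected) / len(clean),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def null_scan_study():
    """20-seed null study: Gaussian data, no injected outliers."""
    from phenocurate.outliers import correct_outliers

    fracs = []
    for seed in range(20):
        ds, _ = simulate_collection(SimConfig(n_accessions=300, n_years=15, seed=seed))
        _, report = correct_outliers(ds, "PH")
        fracs.append(report.n_outliers / report.n_records_pruned)
    return np.asarray(fracs)
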