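"""REML solver: oracles, equivariances, pruning, BLUEs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phenocurate.mixed_model import (
    ModelSpec,
    _Design,
    _FixedEval,
    _RandomEval,
    compute_blues,
    prune_sparse,
    reml_fit,
)
from phenocurate.records import Dataset
from phenocurate.simulate import SimConfig, simulate_collection, winter_years_pmf

from ._oracles import anova_ems_estimates, grid_search_reml, neg2_reml_direct
from .conftest import make_dataset


def _scaled(ds: Dataset, scale=1.0, shift=0.0) -> Dataset:
    df = ds.df.copy()
    df["value"] = df["value"] * scale + shift
    return Dataset(df, ds.growth_habit, ds.provenance, validate=False)


class TestPruneSparse:
    def test_threshold_one_is_identity(self, toy_8rec):
        pruned, rep = prune_sparse(toy_8rec, "PH", ModelSpec(min_records_per_year=1))
        assert rep.n_removed == 0
        assert pruned.n_records == toy_8rec.n_records

    def test_singleton_year_removed(self):
        rows = [
            ("A", 2001, "PH", 10.0),
            ("B", 2001, "PH", 11.0),
            ("A", 2002, "PH", 12.0),  # only record in 2002
        ]
        ds = make_dataset(rows)
        pruned, rep = prune_sparse(ds, "PH", ModelSpec(min_records_per_year=2))
        assert rep.removed_keys == [("A", 2002, "PH")]
        assert rep.affected_accessions == ["A"]
        assert pruned.n_records == 2

    def test_matches_brute_force_groupby_count(self):
        ds, _ = simulate_collection(
            SimConfig(n_accessions=400, n_years=30,
                      years_per_accession_pmf=winter_years_pmf(20), seed=31)
        )
        spec = ModelSpec(min_records_per_year=2)
        _, rep = prune_sparse(ds, "PH", spec)
        sub = ds.df[ds.df["trait"] == "PH"]
        counts = sub.groupby("year").size()
        expected = int(counts[counts < 2].sum())
        assert rep.n_removed == expected

    def test_all_records_pruned_is_an_error(self):
        ds = make_dataset([("A", 2001, "PH", 10.0), ("B", 2002, "PH", 11.0)])
        with pytest.raises(ValueError, match="removed every record"):
            prune_sparse(ds, "PH", ModelSpec(min_records_per_year=2))


class TestLikelihoodIdentity:
    """The MME-based restricted likelihood equals the dense V-based one."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fixed_and_random_match_dense_oracle(self, toy_8rec, seed):
        d = _Design(toy_8rec, "PH")
        rng = np.random.default_rng(seed)
        s2a = rng.uniform(0.5, 20)
        s2j = rng.uniform(0.5, 10, d.J)
        s2G = rng.uniform(1, 30)
        got_f = _FixedEval(d).neg2_reml(s2a, s2j)
        want_f = neg2_reml_direct(d.y, d.acc, d.yr, d.p, d.J, s2a, s2j)
        assert got_f == pytest.approx(want_f, rel=1e-9)
        got_r = _RandomEval(d).neg2_reml(s2G, s2a, s2j)
        want_r = neg2_reml_direct(d.y, d.acc, d.yr, d.p, d.J, s2a, s2j, s2G)
        assert got_r == pytest.approx(want_r, rel=1e-9)


class TestRemlOracles:
    def test_balanced_2x2_blue_contrast_is_exact(self):
        ds = make_dataset(
            [
                ("A", 2001, "PH", 10.0),
                ("A", 2002, "PH", 12.0),
                ("B", 2001, "PH", 14.0),
                ("B", 2002, "PH", 16.0),
            ]
        )
        spec = ModelSpec(genotype_role="fixed", heteroscedastic=False,
                         min_records_per_year=1)
        fit = reml_fit(ds, "PH", spec)
        contrast = fit.genotype_estimates["B"] - fit.genotype_estimates["A"]
        assert contrast == pytest.approx(4.0, abs=1e-8)

    def test_grid_search_matches_solver_on_8_records(self, toy_8rec):
        spec = ModelSpec(genotype_role="random", heteroscedastic=False,
                         min_records_per_year=1)
        fit = reml_fit(toy_8rec, "PH", spec)
        assert fit.converged
        d = _Design(toy_8rec, "PH")
        vtot = float(np.var(d.y, ddof=1))
        g, a, e = grid_search_reml(d.y, d.acc, d.yr, d.p, d.J,
                                   lo=1e-4 * vtot, hi=10 * vtot)
        assert fit.varcomp.sigma2_G == pytest.approx(g, rel=1e-3)
        assert fit.varcomp.sigma2_year == pytest.approx(a, rel=1e-3)
        assert fit.varcomp.sigma2_e_mean == pytest.approx(e, rel=1e-3)

    def test_balanced_design_matches_anova_ems_estimators(self):
        rng = np.random.default_rng(42)
        p, q = 12, 6
        g = rng.normal(0, 4.0, p)
        a = rng.normal(0, 2.0, q)
        table = 50.0 + g[:, None] + a[None, :] + rng.normal(0, 1.5, (p, q))
        s2G_hat, s2a_hat, s2e_hat = anova_ems_estimates(table)
        assert min(s2G_hat, s2a_hat, s2e_hat) > 0
        rows = [
            (f"G{i:02d}", 2000 + j, "PH", table[i, j])
            for i in range(p)
            for j in range(q)
        ]
        ds = make_dataset(rows)
        spec = ModelSpec(genotype_role="random", heteroscedastic=False)
        fit = reml_fit(ds, "PH", spec)
        assert fit.varcomp.sigma2_G == pytest.approx(s2G_hat, rel=1e-3)
        assert fit.varcomp.sigma2_year == pytest.approx(s2a_hat, rel=1e-3)
        assert fit.varcomp.sigma2_e_mean == pytest.approx(s2e_hat, rel=1e-3)

    def test_matches_statsmodels_mixedlm_homoscedastic(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        ds, _ = simulate_collection(
            SimConfig(n_accessions=25, n_years=8, tau=0.0,
                      years_per_accession_pmf=winter_years_pmf(6), seed=7)
        )
        spec = ModelSpec(genotype_role="fixed", heteroscedastic=False,
                         min_records_per_year=1)
        fit = reml_fit(ds, "PH", spec)
        sub = ds.df[ds.df["trait"] == "PH"]
        X = pd.get_dummies(sub["accession_id"]).astype(float)
        res = statsmodels.MixedLM(
            sub["value"].to_numpy(), X, groups=sub["year"].to_numpy()
        ).fit(reml=True)
        assert fit.varcomp.sigma2_year == pytest.approx(
            float(res.cov_re.iloc[0, 0]), rel=1e-3
        )
        assert fit.varcomp.sigma2_e_mean == pytest.approx(res.scale, rel=1e-3)
        ours = np.array([fit.genotype_estimates[a] for a in X.columns])
        np.testing.assert_allclose(ours, res.fe_params.to_numpy(), atol=1e-3)


class TestEquivariance:
    def test_shift_moves_estimates_not_variances(self, toy_8rec):
        spec = ModelSpec(genotype_role="fixed", heteroscedastic=False,
                         min_records_per_year=1)
        base = reml_fit(toy_8rec, "PH", spec)
        shifted = reml_fit(_scaled(toy_8rec, shift=7.5), "PH", spec)
        for acc in base.genotype_estimates:
            assert shifted.genotype_estimates[acc] == pytest.approx(
                base.genotype_estimates[acc] + 7.5, rel=1e-6
            )
        assert shifted.varcomp.sigma2_year == pytest.approx(
            base.varcomp.sigma2_year, rel=1e-4
        )
        assert shifted.varcomp.sigma2_e_mean == pytest.approx(
            base.varcomp.sigma2_e_mean, rel=1e-4
        )

    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    def test_scale_equivariance(self, scale):
        rows = [
            ("A", 2001, "PH", 10.1), ("A", 2002, "PH", 12.3),
            ("B", 2001, "PH", 14.2), ("B", 2002, "PH", 15.9),
            ("C", 2001, "PH", 13.0), ("C", 2002, "PH", 13.7),
            ("D", 2001, "PH", 11.5), ("D", 2002, "PH", 12.0),
        ]
        ds = make_dataset(rows)
        spec = ModelSpec(genotype_role="fixed", heteroscedastic=False,
                         min_records_per_year=1)
        base = reml_fit(ds, "PH", spec)
        scaled = reml_fit(_scaled(ds, scale=scale), "PH", spec)
        assert scaled.varcomp.sigma2_e_mean == pytest.approx(
            base.varcomp.sigma2_e_mean * scale**2, rel=1e-3
        )
        for acc in base.genotype_estimates:
            assert scaled.genotype_estimates[acc] == pytest.approx(
                base.genotype_estimates[acc] * scale, rel=1e-4
            )
        # standardized residuals are scale-free
        for key, r in base.residuals.items():
            sd = np.sqrt(base.varcomp.per_year_error[key[1]])
            sd_s = np.sqrt(scaled.varcomp.per_year_error[key[1]])
            if abs(r) > 1e-9:
                assert scaled.residuals[key] / sd_s == pytest.approx(r / sd, rel=1e-3)


class TestFitContracts:
    def test_variances_nonnegative_and_loglik_improves(self, midsize_fixed_fit):
        fit = midsize_fixed_fit
        assert fit.converged
        assert fit.varcomp.sigma2_year >= 0
        assert all(v > 0 for v in fit.varcomp.per_year_error.values())
        assert np.isfinite(fit.log_reml)

    def test_residual_defined_for_every_record(self, midsize_sim, midsize_fixed_fit):
        ds, _ = midsize_sim
        spec = ModelSpec()
        pruned, _ = prune_sparse(ds, "PH", spec)
        assert set(midsize_fixed_fit.residuals) == set(
            k for k in pruned.keys() if k[2] == "PH"
        )
        levs = np.array(list(midsize_fixed_fit.leverages.values()))
        assert ((levs >= 0) & (levs < 1)).all()

    def test_too_few_records_raises(self):
        ds = make_dataset([("A", 2001, "PH", 10.0), ("B", 2002, "PH", 12.0)])
        with pytest.raises(ValueError):
            reml_fit(ds, "PH", ModelSpec(genotype_role="random"))

    def test_single_year_fixed_fit_flags_year_variance(self):
        # replicate plot measurements within one year (validate=False keeps
        # the duplicate (accession, year, trait) rows)
        rng = np.random.default_rng(0)
        rows = [
            (acc, 2001, "PH", float(base + rng.normal(0, 1)))
            for acc, base in [("A", 10.0), ("B", 12.0), ("C", 11.0), ("D", 14.0)]
            for _ in range(3)
        ]
        df = pd.DataFrame(rows, columns=["accession_id", "year", "trait", "value"])
        df["value_type"] = "single"
        ds = Dataset(df, "spring", validate=False)
        fit = reml_fit(ds, "PH",
                       ModelSpec(genotype_role="fixed", min_records_per_year=1))
        assert not fit.year_variance_estimable
        assert any("single year" in m for m in fit.messages)


class TestBlues:
    def test_blues_require_fixed_fit(self, toy_8rec):
        spec = ModelSpec(genotype_role="random", heteroscedastic=False,
                         min_records_per_year=1)
        fit = reml_fit(toy_8rec, "PH", spec)
        with pytest.raises(ValueError, match="genotype-fixed"):
            compute_blues(fit)

    def test_balanced_complete_design_blue_is_accession_mean(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"G{i}", 2000 + j, "PH", float(50 + 3 * i + rng.normal(0, 2)))
            for i in range(6)
            for j in range(4)
        ]
        ds = make_dataset(rows)
        spec = ModelSpec(genotype_role="fixed", heteroscedastic=False)
        fit = reml_fit(ds, "PH", spec)
        blues = compute_blues(fit).set_index("accession_id")["blue"]
        means = ds.df.groupby("accession_id")["value"].mean()
        for acc in means.index:
            assert blues[acc] == pytest.approx(means[acc], rel=1e-6)

    def test_solution_matches_dense_mme_solve(self):
        """Full solution vector (incl. singleton-accession BLUEs) against a
        dense mixed-model-equation solve at the converged variances."""
        ds, _ = simulate_collection(
            SimConfig(n_accessions=30, n_years=10,
                      years_per_accession_pmf=winter_years_pmf(4), seed=15)
        )
        spec = ModelSpec(genotype_role="fixed", min_records_per_year=1)
        fit = reml_fit(ds, "PH", spec)
        d = _Design(ds, "PH")
        assert (np.bincount(d.acc) == 1).any(), "fixture should contain singletons"
        s2j = np.array([fit.varcomp.per_year_error[int(y)] for y in d.year_labels])
        n = d.n
        Zg = np.zeros((n, d.p)); Zg[np.arange(n), d.acc] = 1.0
        Za = np.zeros((n, d.J)); Za[np.arange(n), d.yr] = 1.0
        W = np.hstack([Zg, Za])
        Rinv = np.diag(1.0 / s2j[d.yr])
        C = W.T @ Rinv @ W
        C[d.p:, d.p:] += np.eye(d.J) / fit.varcomp.sigma2_year
        sol = np.linalg.solve(C, W.T @ Rinv @ d.y)
        want_beta = dict(zip(d.acc_labels, sol[: d.p]))
        for acc, b in fit.genotype_estimates.items():
            assert b == pytest.approx(want_beta[acc], rel=1e-6, abs=1e-8)
        # BLUE of a singleton accession = its value minus the year BLUP
        singles = [i for i in range(d.p) if (d.acc == i).sum() == 1]
        i = singles[0]
        k = int(np.where(d.acc == i)[0][0])
        acc_id = d.acc_labels[i]
        year = int(d.year_labels[d.yr[k]])
        assert fit.genotype_estimates[acc_id] == pytest.approx(
            d.y[k] - fit.year_effects[year], rel=1e-9
        )

    def test_blue_correlation_exceeds_reliability_bound(self):
        cfg = SimConfig(n_accessions=300, n_years=20, sigma2_G=400.0,
                        sigma2_year=50.0, sigma2_e_mean=85.0, seed=22)
        ds, truth = simulate_collection(cfg)
        spec = ModelSpec(genotype_role="fixed")
        pruned, _ = prune_sparse(ds, "PH", spec)
        fit = reml_fit(pruned, "PH", spec)
        blues = compute_blues(fit)
        g_true = np.array([truth.genotype_effects[a] for a in blues["accession_id"]])
        corr = np.corrcoef(blues["blue"], g_true)[0, 1]
        mean_se2 = float((blues["se"] ** 2).mean())
        bound = np.sqrt(400.0 / (400.0 + mean_se2))
        assert corr > bound - 0.05
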