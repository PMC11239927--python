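"""REML fitting of the two-way genebank model with year-specific error variances.

The observation model for one trait of one growth habit is

    y_ij = mu + g_i + a_j + e_ij

where ``g_i`` is the effect of accession i, ``a_j ~ N(0, sigma2_year)`` the
random effect of harvest year j, and ``e_ij ~ N(0, sigma2_j)`` a residual
whose variance is specific to year j (multi-decade trials are strongly
heteroscedastic).  Two configurations are supported:

* ``genotype_role = "fixed"`` -- accessions enter as fixed effects
  (cell-mean coding, so the estimates are directly the estimable adjusted
  means mu + g_i, i.e. the BLUEs).  Used for outlier screening and for
  reporting per-accession BLUEs.
* ``genotype_role = "random"`` -- accessions enter as
  ``g_i ~ N(0, sigma2_G)``.  Used to obtain the variance components that
  feed entry-mean heritability.

Variance parameters maximise the restricted log-likelihood.  The
likelihood is evaluated through the mixed-model-equations (MME) identity

    -2 l_R = log|R| + log|G| + log|C| + y' P y   (+ const)

where ``C`` is the MME coefficient matrix.  Because every record touches
exactly one accession and one year, the accession block of ``C`` is
diagonal and is absorbed analytically; only a small Schur complement of
the year block (J x J, or (1+J) x (1+J) with a fixed intercept) is ever
factorised.  This makes evaluations O(n + p·J + J^3) and keeps fits on
collections with thousands of accessions cheap.  Optimisation is
quasi-Newton (L-BFGS-B) on log-variances with a positivity floor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .records import Dataset, TRAITS

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)

#: variance floor as a fraction of the total phenotypic variance
FLOOR_FRACTION = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one mixed-model fit.

    Parameters
    ----------
    genotype_role
        ``"fixed"`` (outlier scan / BLUEs) or ``"random"`` (heritability).
    heteroscedastic
        One error variance per retained year if True, a single pooled
        ``sigma2_e`` otherwise.
    min_records_per_year
        Pre-fit pruning threshold: years with fewer records of the trait
        are dropped (default 2, so each retained year can support its own
        error variance).
    max_iter, rel_tol
        Optimiser budget and relative restricted-log-likelihood
        convergence tolerance.
    """

    genotype_role: str = "fixed"
    heteroscedastic: bool = True
    min_records_per_year: int = 2
    max_iter: int = 200
    rel_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.genotype_role not in ("fixed", "random"):
            raise ValueError(f"genotype_role must be fixed|random, got {self.genotype_role!r}")
        if self.min_records_per_year < 1:
            raise ValueError("min_records_per_year must be >= 1")
        if not (0.0 < self.rel_tol < 1.0):
            raise ValueError("rel_tol must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")


@dataclass
class VarianceComponents:
    """Converged variance parameters of one fit."""

    sigma2_year: float
    per_year_error: dict[int, float]
    sigma2_G: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def sigma2_e_mean(self) -> float:
        """Unweighted arithmetic mean of the per-year error variances."""
        return float(np.mean(list(self.per_year_error.values())))

    def sigma2_e_weighted(self, n_per_year: dict[int, int]) -> float:
        """Record-weighted alternative mean of the per-year error variances."""
        w = np.array([n_per_year[y] for y in self.per_year_error], float)
        v = np.array(list(self.per_year_error.values()), float)
        return float((w * v).sum() / w.sum())


@dataclass
class FitResult:
    """Fitted state of one REML run.

    ``genotype_estimates`` hold estimable adjusted means (BLUEs) when
    genotype is fixed and BLUPs when random; ``year_effects`` are always
    year BLUPs.  ``residuals`` are conditional residuals
    ``y - fitted(fixed + random)`` keyed by ``(accession, year, trait)``.
    Non-convergence is a reported state (``converged = False``), never an
    exception.
    """

    trait: str
    spec: ModelSpec
    mu: float
    genotype_estimates: dict[str, float]
    year_effects: dict[int, float]
    residuals: dict[tuple[str, int, str], float]
    leverages: dict[tuple[str, int, str], float]
    varcomp: VarianceComponents
    log_reml: float
    converged: bool
    n_iter: int
    n_records_pruned: int = 0
    genotype_se: dict[str, float] | None = None
    messages: tuple[str, ...] = ()
    year_variance_estimable: bool = True


@dataclass
class PruneReport:
    removed_years: list[int]
    removed_keys: list[tuple[str, int, str]]
    affected_accessions: list[str]

    @property
    def n_removed(self) -> int:
        return len(self.removed_keys)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def prune_sparse(
    dataset: Dataset, trait: str, spec: ModelSpec
) -> tuple[Dataset, PruneReport]:
    """Drop records of ``trait`` in years with too few observations.

    A year-specific error variance needs at least
    ``spec.min_records_per_year`` records in that year; sparser years are
    removed before fitting.  Raises if no record of the trait survives.
    """
    sub = dataset.df[dataset.df["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait}")
    counts = sub.groupby("year").size()
    thin_years = sorted(counts.index[counts < spec.min_records_per_year])
    removed = sub[sub["year"].isin(thin_years)]
    if len(removed) == len(sub):
        raise ValueError(
            f"pruning with min_records_per_year={spec.min_records_per_year} "
            f"removed every record of trait {trait}"
        )
    report = PruneReport(
        removed_years=[int(y) for y in thin_years],
        removed_keys=[
            (r.accession_id, int(r.year), trait) for r in removed.itertuples()
        ],
        affected_accessions=sorted(removed["accession_id"].unique()),
    )
    pruned = dataset.remove_keys(report.removed_keys)
    return pruned, report


# ---------------------------------------------------------------------------
# restricted likelihood machinery
# ---------------------------------------------------------------------------


class _Design:
    """Index arrays of one trait's records, ready for likelihood evaluation."""

    def __init__(self, dataset: Dataset, trait: str):
        sub = dataset.df[dataset.df["trait"] == trait]
        if sub.empty:
            raise ValueError(f"no records for trait {trait}")
        self.y = sub["value"].to_numpy(float)
        self.acc_labels, self.acc = np.unique(
            sub["accession_id"].to_numpy(), return_inverse=True
        )
        self.year_labels, self.yr = np.unique(
            sub["year"].to_numpy(int), return_inverse=True
        )
        self.n = len(self.y)
        self.p = len(self.acc_labels)
        self.J = len(self.year_labels)
        self.n_per_year = np.bincount(self.yr, minlength=self.J)
        self.keys = [
            (a, int(yl), trait)
            for a, yl in zip(sub["accession_id"], sub["year"].astype(int))
        ]


def _cell_weight_matrix(d: _Design, w: np.ndarray) -> np.ndarray:
    """B[i, j] = sum of weights of records of accession i in year j (p x J)."""
    B = np.zeros((d.p, d.J))
    np.add.at(B, (d.acc, d.yr), w)
    return B


def _chol(S: np.ndarray):
    """Cholesky with one jitter retry; None if the system is not PD."""
    try:
        return linalg.cho_factor(S, lower=True, check_finite=False)
    except linalg.LinAlgError:
        jitter = 1e-10 * np.trace(S) / len(S)
        try:
            return linalg.cho_factor(
                S + jitter * np.eye(len(S)), lower=True, check_finite=False
            )
        except linalg.LinAlgError:
            return None


class _FixedEval:
    """Restricted likelihood / solutions for the genotype-fixed model."""

    def __init__(self, d: _Design):
        self.d = d

    def neg2_reml(self, s2a: float, s2j: np.ndarray, full: bool = False):
        d = self.d
        w = 1.0 / s2j[d.yr]
        A = np.bincount(d.acc, weights=w, minlength=d.p)
        B = _cell_weight_matrix(d, w)
        Ainv_B = B / A[:, None]
        S = -B.T @ Ainv_B
        S[np.diag_indices(d.J)] += np.bincount(d.yr, weights=w, minlength=d.J) + 1.0 / s2a
        cS = _chol(S)
        if cS is None:
            return np.inf if not full else None
        bx = np.bincount(d.acc, weights=w * d.y, minlength=d.p)
        bz = np.bincount(d.yr, weights=w * d.y, minlength=d.J)
        u = linalg.cho_solve(cS, bz - Ainv_B.T @ bx, check_finite=False)
        beta = (bx - B @ u) / A
        logdetC = float(np.log(A).sum() + 2.0 * np.log(np.diag(cS[0])).sum())
        yPy = float((w * d.y * d.y).sum() - beta @ bx - u @ bz)
        logR = float(d.n_per_year @ np.log(s2j))
        neg2 = logR + d.J * math.log(s2a) + logdetC + yPy
        if not full:
            return neg2
        Sinv = linalg.cho_solve(cS, np.eye(d.J), check_finite=False)
        GS = Ainv_B @ Sinv
        var_beta = 1.0 / A + np.einsum("ij,ij->i", GS, Ainv_B)
        h = w * (var_beta[d.acc] - 2.0 * GS[d.acc, d.yr] + Sinv[d.yr, d.yr])
        return {
            "neg2": neg2,
            "beta": beta,
            "u_year": u,
            "var_beta": var_beta,
            "leverage": h,
            "p_fixed": d.p,
        }


class _RandomEval:
    """Restricted likelihood / solutions for the genotype-random model."""

    def __init__(self, d: _Design):
        self.d = d

    def neg2_reml(self, s2G: float, s2a: float, s2j: np.ndarray, full: bool = False):
        d = self.d
        w = 1.0 / s2j[d.yr]
        wy = w * d.y
        acc_w = np.bincount(d.acc, weights=w, minlength=d.p)
        yr_w = np.bincount(d.yr, weights=w, minlength=d.J)
        Dg = acc_w + 1.0 / s2G
        B = _cell_weight_matrix(d, w)
        # small block ordered [mu, a_1..a_J]
        U = np.concatenate([acc_w[:, None], B], axis=1)  # p x (1+J)
        V = U / Dg[:, None]
        M = np.zeros((1 + d.J, 1 + d.J))
        M[0, 0] = w.sum()
        M[0, 1:] = yr_w
        M[1:, 0] = yr_w
        M[np.arange(1, 1 + d.J), np.arange(1, 1 + d.J)] = yr_w + 1.0 / s2a
        S = M - V.T @ U
        cS = _chol(S)
        if cS is None:
            return np.inf if not full else None
        r_mu = float(wy.sum())
        r_g = np.bincount(d.acc, weights=wy, minlength=d.p)
        r_a = np.bincount(d.yr, weights=wy, minlength=d.J)
        rhs = np.concatenate([[r_mu], r_a]) - V.T @ r_g
        sol = linalg.cho_solve(cS, rhs, check_finite=False)
        mu_hat, ua = float(sol[0]), sol[1:]
        g = (r_g - acc_w * mu_hat - B @ ua) / Dg
        logdetC = float(np.log(Dg).sum() + 2.0 * np.log(np.diag(cS[0])).sum())
        yPy = float((w * d.y * d.y).sum() - mu_hat * r_mu - g @ r_g - ua @ r_a)
        logR = float(d.n_per_year @ np.log(s2j))
        neg2 = (
            logR + d.p * math.log(s2G) + d.J * math.log(s2a) + logdetC + yPy
        )
        if not full:
            return neg2
        Sinv = linalg.cho_solve(cS, np.eye(1 + d.J), check_finite=False)
        Vs = V @ Sinv
        cinv_gg = 1.0 / Dg + np.einsum("ij,ij->i", Vs, V)
        jj = 1 + d.yr
        h = w * (
            cinv_gg[d.acc]
            + Sinv[0, 0]
            + Sinv[jj, jj]
            + 2.0 * Sinv[0, jj]
            - 2.0 * Vs[d.acc, 0]
            - 2.0 * Vs[d.acc, jj]
        )
        return {
            "neg2": neg2,
            "mu": mu_hat,
            "g": g,
            "u_year": ua,
            "leverage": h,
            "p_fixed": 1,
        }


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _pack_start(d: _Design, spec: ModelSpec, vtot: float) -> tuple[np.ndarray, list[str]]:
    """Method-of-moments starting point on the log scale.

    Total variance is split half residual / half shared; with genotype
    random the shared half is split again between accessions and years.
    Per-year error variances start at the common value.
    """
    names: list[str] = []
    vals: list[float] = []
    if spec.genotype_role == "random":
        vals += [vtot / 2.0, vtot / 4.0]
        names += ["sigma2_G", "sigma2_year"]
        e0 = vtot / 4.0
    else:
        vals.append(vtot / 2.0)
        names.append("sigma2_year")
        e0 = vtot / 2.0
    if spec.heteroscedastic:
        vals += [e0] * d.J
        names += [f"sigma2_e[{int(y)}]" for y in d.year_labels]
    else:
        vals.append(e0)
        names.append("sigma2_e")
    return np.log(np.asarray(vals)), names


def _unpack(x: np.ndarray, d: _Design, spec: ModelSpec):
    v = np.exp(x)
    i = 0
    s2G = None
    if spec.genotype_role == "random":
        s2G = float(v[i])
        i += 1
    s2a = float(v[i])
    i += 1
    if spec.heteroscedastic:
        s2j = v[i : i + d.J]
    else:
        s2j = np.full(d.J, float(v[i]))
    return s2G, s2a, s2j


def reml_fit(dataset: Dataset, trait: str, spec: ModelSpec) -> FitResult:
    """Fit the two-way model for one trait by REML.

    Expects a pruned dataset (see :func:`prune_sparse`).  The restricted
    log-likelihood is maximised over ``sigma2_year``, the per-year (or
    pooled) error variances and, with genotype random, ``sigma2_G``.
    Effect estimates solve the mixed-model equations at the converged
    variances.

    Non-convergence is reported through ``FitResult.converged``; genuine
    contract violations (too few records, single-year random fit) raise.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    d = _Design(dataset, trait)
    if d.n < 3:
        raise ValueError(f"only {d.n} records for {trait}: model not estimable")
    n_varpar = (1 if spec.genotype_role == "random" else 0) + 1 + (
        d.J if spec.heteroscedastic else 1
    )
    df_resid = d.n - (d.p if spec.genotype_role == "fixed" else 1)
    if df_resid < 1:
        raise ValueError(
            f"no residual degrees of freedom ({d.n} records, "
            f"{d.p} accessions, genotype fixed)"
        )
    if spec.genotype_role == "random" and df_resid < n_varpar:
        raise ValueError(
            f"{n_varpar} variance parameters but only {df_resid} residual "
            "degrees of freedom"
        )

    vtot = float(np.var(d.y, ddof=1))
    if vtot <= 0.0:
        vtot = max(abs(d.y).max(), 1.0) * 1e-8  # constant data: nominal scale
    floor = FLOOR_FRACTION * vtot
    x0, names = _pack_start(d, spec, vtot)
    messages: list[str] = []

    ev = _FixedEval(d) if spec.genotype_role == "fixed" else _RandomEval(d)

    year_var_estimable = True
    fixed_s2a = None
    if d.J == 1:
        if spec.genotype_role == "random":
            raise ValueError("single-year data: year variance not estimable")
        # genotype fixed, one year: condition on the year, pin sigma2_year
        year_var_estimable = False
        fixed_s2a = floor
        messages.append("single year: sigma2_year pinned to floor (not estimable)")

    def objective(x: np.ndarray) -> float:
        s2G, s2a, s2j = _unpack(x, d, spec)
        if fixed_s2a is not None:
            s2a = fixed_s2a
        if spec.genotype_role == "random":
            val = ev.neg2_reml(s2G, s2a, s2j)
        else:
            val = ev.neg2_reml(s2a, s2j)
        if not np.isfinite(val):
            # finite, sloped penalty keeps line searches well-behaved near
            # infeasible (numerically non-PD) corners of the bound box
            return 1e12 * (1.0 + float(np.linalg.norm(x - x0)))
        return val

    lo, hi = math.log(floor), math.log(1e8 * vtot)
    bounds = [(lo, hi)] * len(x0)
    f0 = objective(x0)
    # L-BFGS-B with restarts: rerun from the incumbent until the restricted
    # likelihood stops improving (guards against premature line-search exits)
    x_cur, f_cur, n_iter, success = x0, f0, 0, False
    for _ in range(4):
        res = optimize.minimize(
            objective,
            x_cur,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": spec.max_iter, "ftol": spec.rel_tol, "gtol": 1e-6},
        )
        n_iter += int(res.nit)
        success = bool(res.success)
        improved = res.fun < f_cur - spec.rel_tol * (abs(f_cur) + 1.0)
        if res.fun < f_cur:
            x_cur, f_cur = res.x, float(res.fun)
        if not improved:
            break
    if not success:
        # flat-likelihood line searches can abort L-BFGS-B near the optimum;
        # a simplex polish certifies (or finds) the stationary point
        res_nm = optimize.minimize(
            objective,
            x_cur,
            method="Nelder-Mead",
            options={"maxiter": 50 * len(x_cur), "fatol": spec.rel_tol * (abs(f_cur) + 1.0),
                     "xatol": 1e-8},
        )
        n_iter += int(res_nm.nit)
        if res_nm.fun < f_cur:
            x_cur = np.clip(res_nm.x, lo, hi)
            f_cur = float(objective(x_cur))
        success = res_nm.fun >= f_cur - 10 * spec.rel_tol * (abs(f_cur) + 1.0)
    converged = success and np.isfinite(f_cur) and f_cur <= f0 + 1e-9
    if not success:
        messages.append(f"optimizer: {res.message}")
    if f_cur > f0 + 1e-9:
        messages.append("restricted likelihood decreased from the starting point")

    s2G, s2a, s2j = _unpack(x_cur, d, spec)
    if fixed_s2a is not None:
        s2a = fixed_s2a
    flags = []
    if s2a <= floor * (1 + 1e-6):
        flags.append("sigma2_year_at_floor")
    if s2G is not None and s2G <= floor * (1 + 1e-6):
        flags.append("sigma2_G_at_floor")
    if (s2j <= floor * (1 + 1e-6)).any():
        flags.append("per_year_error_at_floor")
    for fl in flags:
        messages.append(f"{fl}: component effectively zero")

    if spec.genotype_role == "random":
        sol = ev.neg2_reml(s2G, s2a, s2j, full=True)
    else:
        sol = ev.neg2_reml(s2a, s2j, full=True)
    if sol is None:
        raise linalg.LinAlgError(
            "working system not positive definite at the reported optimum; "
            f"trace: start={f0:.6g}, end={f_cur:.6g}, nit={n_iter}"
        )

    per_year = {int(y): float(v) for y, v in zip(d.year_labels, s2j)}
    varcomp = VarianceComponents(
        sigma2_year=float(s2a),
        per_year_error=per_year,
        sigma2_G=float(s2G) if s2G is not None else None,
        flags=tuple(flags),
    )
    year_effects = {int(y): float(u) for y, u in zip(d.year_labels, sol["u_year"])}
    residual_fit = np.empty(d.n)
    if spec.genotype_role == "fixed":
        beta = sol["beta"]
        residual_fit = d.y - beta[d.acc] - sol["u_year"][d.yr]
        genotype_estimates = {a: float(b) for a, b in zip(d.acc_labels, beta)}
        genotype_se = {
            a: float(np.sqrt(v)) for a, v in zip(d.acc_labels, sol["var_beta"])
        }
        mu = float(np.mean(beta))
    else:
        g = sol["g"]
        mu = sol["mu"]
        residual_fit = d.y - mu - g[d.acc] - sol["u_year"][d.yr]
        genotype_estimates = {a: float(b) for a, b in zip(d.acc_labels, g)}
        genotype_se = None

    residuals = dict(zip(d.keys, residual_fit.astype(float)))
    leverages = dict(zip(d.keys, np.clip(sol["leverage"], 0.0, 1.0 - 1e-12)))
    log_reml = -0.5 * (sol["neg2"] + (d.n - sol["p_fixed"]) * _LOG2PI)

    return FitResult(
        trait=trait,
        spec=spec,
        mu=mu,
        genotype_estimates=genotype_estimates,
        year_effects=year_effects,
        residuals=residuals,
        leverages=leverages,
        varcomp=varcomp,
        log_reml=float(log_reml),
        converged=converged,
        n_iter=n_iter,
        genotype_se=genotype_se,
        messages=tuple(messages),
        year_variance_estimable=year_var_estimable,
    )


def compute_blues(fit: FitResult) -> pd.DataFrame:
    """Per-accession BLUEs (estimable adjusted means) with standard errors.

    Only defined for genotype-fixed fits: BLUPs from a random fit are
    shrunken predictions, not best linear unbiased *estimates*.
    """
    if fit.spec.genotype_role != "fixed":
        raise ValueError("BLUEs require a genotype-fixed fit (got random: BLUPs)")
    if not fit.converged:
        logger.warning("computing BLUEs from a non-converged fit")
    acc = sorted(fit.genotype_estimates)
    return pd.DataFrame(
        {
            "accession_id": acc,
            "blue": [fit.genotype_estimates[a] for a in acc],
            "se": [fit.genotype_se[a] for a in acc],
        }
    )


def refit(dataset: Dataset, trait: str, spec: ModelSpec, **overrides) -> FitResult:
    """Convenience: prune then fit with optional spec overrides."""
    spec = replace(spec, **overrides) if overrides else spec
    pruned, rep = prune_sparse(dataset, trait, spec)
    fit = reml_fit(pruned, trait, spec)
    fit.n_records_pruned = rep.n_removed
    return fit
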