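# Methods

## The model

`phenocurate` curates long-running genebank regeneration trials: one
phenotypic value per accession per harvest year, collected over decades,
with accessions appearing in differing, partially overlapping sets of
years (a non-orthogonal design, so raw accession means are biased by
year effects). For one trait of one growth habit the observation model is

    y_ij = mu + g_i + a_j + e_ij

with accession effect `g_i`, year effect `a_j ~ N(0, sigma2_year)` and
residual `e_ij ~ N(0, sigma2_j)`. The residual variance is specific to
the year `j`: trials spanning several decades mix instruments, field
sites and climates, and a pooled error variance is untenable. Two
configurations are used:

* **genotype fixed** — for outlier screening and per-accession BLUEs
  (estimable adjusted means `mu + g_i`). Cell-mean coding is used
  internally, so the reported quantities are the adjusted means
  themselves and no identifiability constraint leaks into the output.
* **genotype random** (`g_i ~ N(0, sigma2_G)`) — for the variance
  components feeding entry-mean heritability.

## REML evaluation and optimisation

Variance parameters maximise the restricted log-likelihood. It is
evaluated through the mixed-model-equations identity

    -2 l_R = log|R| + log|G| + log|C| + y' P y  (+ const),

where `C` is the MME coefficient matrix. Every record touches exactly
one accession and one year, so the accession block of `C` is diagonal
and is absorbed analytically; only a Schur complement of the year block
(`J x J`, or `(1+J) x (1+J)` with the fixed intercept) is factorised.
One likelihood evaluation costs `O(n + p J + J^3)` for `p` accessions
and `J` years, which keeps fits with thousands of accessions at
millisecond scale. Unit tests verify this evaluation against an
independent dense route (`log|V| + log|X'V^-1X| + y'Py` via direct
inversion) to machine precision.

Optimisation is L-BFGS-B on log-variances (positivity by construction)
with numerical gradients, restarted from the incumbent until the
restricted likelihood stops improving, and polished by a Nelder–Mead
pass when the line search aborts on a flat likelihood. Numerical
choices:

* starting point: a method-of-moments split of the total variance (half
  residual, half shared; with genotype random the shared half is split
  again), per-year errors initialised at the common value;
* convergence: relative change of `-2 l_R` below `rel_tol` (default
  1e-8), `max_iter` 200 per pass; the restricted likelihood at the
  solution is checked against the starting point and a decrease marks
  the fit unconverged;
* variance floor `1e-10 x` total phenotypic variance; a component pinned
  at the floor is flagged as effectively zero;
* non-PD working systems during a line search return a finite, sloped
  penalty instead of infinity so the search backtracks cleanly;
* heteroscedastic fits require every retained year to carry at least
  `min_records_per_year` records (default 2); sparser years are pruned
  before fitting and reported. With `heteroscedastic=False` a single
  pooled error variance is estimated (used by fast tests and oracles).

Degenerate inputs: fewer than three records, or a genotype-fixed design
with no residual degrees of freedom, raise; single-year data with
genotype fixed are fitted conditioning on that year, with the year
variance pinned and flagged as not estimable. Non-convergence is a
reported state (`converged = False`), never a silent result.

Leverages (diagonal of the observation projection at the converged
variances, computed from the absorbed `C^{-1}` blocks in closed form)
support the internally studentised residual variant.

## Outlier screening

From the genotype-fixed heteroscedastic fit, residuals are standardised
by their year's error SD, centred on the median, and rescaled by
1.4826 × MAD (the consistency constant under normality). Two-sided
normal p-values of these robust z-scores enter a Bonferroni–Holm
step-down test at `alpha = 0.05`; flagged records are removed in a
single pass, producing the *enhanced* dataset. Design choices:

* standardisation uses the per-year error SD without leverage correction
  by default; an internally studentised variant (`studentized=True`)
  divides by `sqrt(1 - h_k)` as well. Both are provided because the two
  descriptions of this family of screens differ on this point.
* a rescaled MAD of zero (at least half the residuals identical) is a
  degenerate-spread condition: no scores, zero flags, event logged;
* single pass, no iteration of the flag set;
* Holm ties are broken by record key, which only fixes output order.

The report row per trait satisfies, by construction,
`corrected_size = n_records_pruned - n_outliers` and
`outlier_pct = round(100 * n_outliers / n_records_pruned, 2)`
(half-up rounding, matching how such tables are printed).

## Entry-mean heritability

    h2 = sigma2_G / (sigma2_G + sigma2_e / Year)

with `sigma2_e` the **unweighted** mean of the per-year error variances
(the record-weighted alternative is exposed as
`VarianceComponents.sigma2_e_weighted`) and `Year` the mean number of
distinct years each accession was tested, computed on the same dataset
stage as the fit (so the enhanced-stage h² uses post-removal counts).
A fit that does not converge, or whose genetic and error components are
both pinned at the floor, yields `fit_ok = False` with a diagnosis
rather than a number — historical data can genuinely defeat the model.

## The synthetic generator

`simulate_collection` emulates the structure of such collections: each
accession is scored in `k` distinct years (`k` drawn from a configurable
pmf, years uniform without replacement), `y = mu + g_i + a_j + e_ij`,
per-year error variances lognormal across years
(`sigma2_e_mean * exp(tau z - tau^2/2)`, mean pinned to
`sigma2_e_mean`), and a `Binomial(N, contamination_rate)` subset of
records shifted by `±shift_sd_multiplier` times that year's error SD —
a gross-error mechanism with a single interpretable knob. One RNG stream
with documented draw order makes every dataset reproducible from its
seed.

Profile presets mirror the two real collections this package is aimed
at: `spring` (~1,000 accessions, 1–8 distinct years, modes at 1 and 3)
and `winter` (~3,400 accessions, 2–3-year cycles with a tail out to ~28
years); per-trait variance scales (HD dominated by year, PH by genetics
and year, TGW smallest) follow the magnitudes observed on such data.
Default study conditions used by the recovery and screening studies:
500–1,000 accessions, 20 years, `sigma2_G = 300`, `sigma2_year = 50`,
`sigma2_e_mean = 85`, `tau = 0.3`, shifts at 8 SD. These sizes keep the
full test suite and the acceptance script at desk scale (tens of
seconds) while leaving sampling error well below the asserted margins.

What the generator does **not** emulate: temporal clustering of
regeneration campaigns, climate or genetic trends across decades, and
trait–trait genetic correlations. Passing recovery tests therefore show
that the estimator chain is correct under the stated generative model,
not that real archives satisfy that model.

## Known limitations

* A residual screen cannot flag gross errors in accessions observed in
  a single year: under the genotype-fixed fit their conditional
  residuals are identically zero, and two-year accessions retain only
  half of any shift per residual. Under regeneration-cycle-realistic
  designs (many one- and two-year accessions) the realised sensitivity
  against 8-SD shifts is therefore ~0.8, not 1.0, while family-wise
  error control keeps false flags near zero. Real gross errors (unit
  and transcription mistakes) are typically far larger than 8 SD.
* Per-year error variances are estimated with the outliers still in the
  data, so heavily contaminated years partially mask their own
  outliers; the global MAD rescale compensates on average but not
  per-year.
* No spatial or replicate-level modelling: the historical archives keep
  one value per accession-year.
* No standard errors for h².
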