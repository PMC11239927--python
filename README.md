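# phenocurate

Curation of historical, multi-year genebank phenotype trials.

Genebanks regenerate their seed holdings in field plots every few years
and score traits — here heading date (HD, days from January 1), plant
height (PH, cm) and thousand grain weight (TGW, g) — at each
regeneration. Decades of such records form a highly unbalanced
("non-orthogonal") genotype-by-year table: every accession is seen in a
different, small set of years, so raw accession means confound genotype
with year, and multi-decade archives are riddled with gross recording
errors and strongly year-dependent error variances. `phenocurate` turns
such archives into analysis-ready data for breeders and researchers.

## What it computes

For each trait, the two-way mixed model

$$y_{ij} = \mu + g_i + a_j + e_{ij}, \qquad
a_j \sim N(0,\sigma^2_{year}), \quad e_{ij} \sim N(0,\sigma^2_j)$$

is fitted by REML with a **year-specific residual variance**
$\sigma^2_j$. The pipeline is:

1. **Prune** years with fewer than 2 records of the trait.
2. **Screen outliers**: with accessions fixed, standardise conditional
   residuals by their year's error SD, centre on the median, rescale by
   1.4826·MAD, and apply a Bonferroni–Holm step-down test at
   α = 0.05; flagged records are removed in one pass, yielding the
   *enhanced* dataset.
3. **BLUEs**: re-fit on the enhanced data and report each accession's
   estimable adjusted mean $\hat\mu + \hat g_i$ with its standard error.
4. **Heritability**: re-fit with accessions random and report the
   entry-mean heritability
   $h^2 = \sigma^2_G \big/ \left(\sigma^2_G + \sigma^2_e/\mathrm{Year}\right)$,
   where $\sigma^2_e$ is the average per-year error variance and
   $\mathrm{Year}$ the mean number of distinct years per accession.
5. **Summaries**: provenance composition (sub-1 % countries grouped as
   "Others"), records by trait and decade, regeneration-year
   histograms, year-effect BLUPs.

A synthetic generator (`phenocurate.simulate`) produces non-orthogonal,
heteroscedastic collections with known genotype/year effects and
injected gross errors, so every stage is verifiable without any external
download. See `docs/methods.md` for the model, algorithms and
limitations.

## Worked example

```python
from phenocurate import (SimConfig, simulate_collection, correct_outliers,
                         heritability_pipeline, ModelSpec, prune_sparse,
                         reml_fit, compute_blues)

cfg = SimConfig(n_accessions=500, n_years=20, sigma2_G=300, sigma2_year=50,
                sigma2_e_mean=85, tau=0.3, contamination_rate=0.03,
                shift_sd_multiplier=8.0, seed=42)
dataset, truth = simulate_collection(cfg)          # 1,453 records, 46 injected
enhanced, report = correct_outliers(dataset, "PH", alpha=0.05)
print(report.n_outliers, report.outlier_pct, report.corrected_size)
# 49 3.37 1404
before = heritability_pipeline(dataset, "PH", dataset_stage="original")
after = heritability_pipeline(enhanced, "PH", dataset_stage="enhanced")
print(f"h2 {before.h2:.3f} -> {after.h2:.3f} (truth {truth.true_h2:.3f})")
# h2 0.777 -> 0.935 (truth 0.911)
pruned, _ = prune_sparse(enhanced, "PH", ModelSpec())
blues = compute_blues(reml_fit(pruned, "PH", ModelSpec()))
print(blues.head(3).to_string(index=False))
# accession_id       blue       se
#      ACC0001 117.503960 7.212609
#      ACC0002 103.069692 3.625825
#      ACC0003  84.565581 3.943629
```

The screen recovers the injected 8-SD shifts at a ~3.4 % flag rate (49
flags against 46 injections, including collateral re-flags of records
whose accession mean was dragged by a gross error), and removing them
lifts the heritability estimate from 0.78 back to the neighbourhood of
the generative truth 0.91 — the same mechanism by which outlier
correction improves heritability on real archives.

The same pipeline runs from the shell:

```bash
phenocurate simulate --profile spring --seed 1 --out data/
phenocurate curate --in data/a_spring_wheat.txt --growth-habit spring \
    --trait all --out curated/
phenocurate herit --in data/a_spring_wheat.txt --growth-habit spring
phenocurate summarize --in data/a_spring_wheat.txt --growth-habit spring
```

`curate` writes, per trait, `Var.comp.<TRAIT>.txt`,
`Outliers.<TRAIT>.txt`, `Data.corrected.<TRAIT>.txt` and
`BLUEs.<TRAIT>.txt`, plus a machine-readable `manifest.json` that
accounts for every input record (fitted / pruned / flagged /
rejected-at-parse).

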