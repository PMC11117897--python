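# endophen

Endophenotype discovery for a clinically defined subgroup of autism spectrum
disorder (ASD). The package implements, as a tested and reusable pipeline,
the analysis chain behind a "Phen1" endophenotype study: clinical
stratification, blood transcriptomic signature construction, transcription
factor (TF) target enrichment, connectivity-style drug repositioning, and
phenotype-microarray energy-metabolism profiling. It is aimed at
computational biologists who want to run, stress-test or adapt this kind of
endophenotype analysis; because the original patient-level data are not
public, a first-class synthetic-data module generates every input with known
ground truth.

## What it computes

**Stratification.** A patient belongs to the Phen1 subgroup iff (i) at least
one physician-documented head-circumference (HC) measure within the first 24
months of life reaches the 75th percentile (HC ≥ 75), and (ii) the record
shows at least one "flare" — appreciable behavioural worsening during an
immune challenge (fever, infection, vaccination, tooth loss, acute
inflammation). `classify_cohort` runs the screening funnel
(screened → documented HC → HC ≥ 75 → flare-assessable → Phen1) and reports
prevalence over all patients with both criteria assessable.

**Transcriptomic signature.** From a gene × sample count matrix with
technical replicates: replicates are collapsed by summation, counts are
normalised by median-of-ratios size factors *s_j*, and each gene *g* is
tested with a negative-binomial Wald GLM,

    K_gj ~ NB(mu_gj, alpha_g),   log(mu_gj) = log(s_j) + beta_0g + beta_g x_j,

where *x_j* indicates the Phen1 group and *beta_g* is the log2 fold change.
Dispersions are method-of-moments estimates shrunk toward a fitted
*a₀ + a₁/μ* trend; p-values are Benjamini–Hochberg adjusted. The ranked
signature keeps genes with median raw count > 10 reads, sorts by log2FC and
takes the top 250 up- and down-regulated genes. Group separation is
validated by PCA on log2-normalised expression, leave-one-out logistic
classification of the first two PCA coordinates, and a label-permutation
test (default 1,000 shuffles).

**TF-target enrichment.** For a target set *T* in a ranked list, the
enrichment score is the signed maximal deviation between the rank ECDFs of
*T* and its complement (two-sample Kolmogorov–Smirnov form); ES > 0 means
targets concentrate among up-regulated genes. Fisher's exact test covers
over-representation of a pathway family among user-flagged enriched
pathways.

**Drug-signature reversal (DGES).** Per-cell-line drug rankings are merged
into a prototype ranked list, weighting each cell line by its zero-clamped
mean Spearman correlation with the others. For disease up/down query sets,
`DGES = (ES_up − ES_down) / 2` on the drug's ranking: +1 is a perfect mimic,
−1 a perfect reverser. A library scan standardises scores to z, reports
two-tailed normal p-values and percentile ranks; the reversed signature
(swap up/down) negates every score exactly.

**Metabolic profiling.** 96-well dual-wavelength plate reads become
per-compound NADH proxies (A590 − A750); compounds indistinguishable from
the no-cell control are removed (one-sided Welch test), group contrasts use
one-way ANOVA with Tukey HSD, profiles are summarised by PCA with
per-compound contributions, and the db-cAMP dose series is normalised to its
zero-dose baseline and tested for a trend.

## Worked example

`examples/` contains one short script per capability. For instance:

```bash
$ python examples/01_screening_funnel.py
screened:                313
documented HC:           89 (28.4%)
HC >= 75th percentile:   46 (51.7%)
flare-assessable HC>=75: 41
Phen1:                   20
both criteria assessable: 84
prevalence: 23.8%
```

The funnel narrows from 313 screened records to 20 Phen1 patients; the
prevalence 23.8% is 20 out of the 84 patients for whom both criteria could
be assessed (41 flare-assessable HC ≥ 75 plus 43 documented HC < 75).

```bash
$ python examples/04_drug_reversal_scan.py
top 5 drugs on the reversed disease signature:
                  score       z      p  percentile
drug
planted_reverser  0.941  12.566  0.000     100.000
drug_1532         0.169   2.280  0.023      99.952
...
planted reverser: z = 12.57, p = 3.24e-36, percentile = 100.0, top 1% = True
```

The drug planted to invert the disease signature attains by far the highest
similarity to the *reversed* disease signature — exactly the behaviour a
repositioning scan relies on — while the 2,099 random drugs form a null
distribution centred at zero.

## Layout

- `src/endophen/stratify.py` — inclusion criteria, screening funnel, comparison-group selection
- `src/endophen/de.py` — replicate collapsing, NB Wald DE, BH, ranked signature, PCA + LOOCV + permutation
- `src/endophen/enrich.py` — signed-KS TF-target enrichment, Fisher over-representation
- `src/endophen/drugsim.py` — prototype ranked lists, DGES, library scans
- `src/endophen/plates.py` — plate profiles, background filter, ANOVA/Tukey, PCA, dose response
- `src/endophen/synthetic.py` — generators for cohorts, counts, drug libraries, plates
- `src/endophen/io.py` — CSV/TSV/MTX/GMT/RNK readers and writers
- `docs/methods.md` — models, assumptions, numerical choices and limitations
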