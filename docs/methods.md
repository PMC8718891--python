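# Methods

## Study design being emulated

The package models a short antibiotic-challenge cohort: 30 healthy adults
take amoxicillin-clavulanate for 3 days; stool is sampled at baseline
(day 0), during treatment (days 1–3) and during recovery (days 7, 14,
28); 16S V4 amplicon sequencing yields an ASV count table; stool diaries
record Bristol Stool Scale scores per episode; and a qPCR assay measures
absolute *F. prausnitzii* and 16S rRNA gene concentrations in baseline
extracts. Thirteen of 30 subjects develop antibiotic-associated diarrhea
(AAD): at least one Bristol 6–7 episode on days 1–3.

## Synthetic-cohort generator

The generator (`aadrisk.simulate`) draws, per subject:

- **Baseline composition.** Ruminococcaceae proportion ~ Beta with group
  mean 0.084 (AAD) or 0.144 (non-AAD) and concentration a+b = 20. The
  remaining mass is split over a fixed family panel — Bacteroidaceae,
  Lachnospiraceae, Enterobacteriaceae, Prevotellaceae, Bifidobacteriaceae
  and an unassigned slot — by a Dirichlet with mean
  (0.30, 0.36, 0.025, 0.115, 0.08, 0.12) and concentration 80.
  Ruminococcaceae is subdivided into Faecalibacterium, Subdoligranulum,
  Ruminococcus and an unassigned genus by a Dirichlet with mean
  (0.671, 0.117, 0.077, 0.135) and concentration 10. Each genus/family
  carries 2–6 ASVs with uniform-Dirichlet subject-specific weights
  (36 ASVs total). The panel means, all concentration parameters and the
  ASV granularity are synthetic choices (the cohort summaries pin only
  the group means); they were picked once to give realistic within-group
  spread (e.g. the genus concentration of 10 reproduces an
  interquartile-range-scale spread in Faecalibacterium's within-family
  share) and are exposed on `CohortConfig`.
- **Treatment phase (days 1–3).** A bloom indicator ~ Bernoulli(10/13 for
  AAD, 5/17 for non-AAD). Bloom subjects get a peak-day Enterobacteriaceae
  proportion ~ Beta with group mean 0.591 / 0.210 (concentration 60) on a
  uniformly chosen peak day, 35% of that level on the other treatment
  days. The non-Enterobacteriaceae remainder is sharpened (p ↦ p^γ,
  renormalized) with γ = 1.6 (AAD) vs 1.15 (non-AAD), so the AAD group
  loses more Shannon diversity during treatment. The bloom-magnitude
  concentration of 60 keeps the Beta draw essentially always above the
  0.10 bloom-calling threshold, so called bloom frequency tracks the
  Bernoulli rate.
- **Recovery (days 7–28).** Day-d composition is a convex combination
  w_d · baseline + (1−w_d) · day-3 composition with w = 0.85, 0.93, 0.97
  on days 7, 14, 28. The study reports recovery by day 7 but no
  kinetics; this schedule is a design choice and configurable.
- **Realized samples.** Each sample's composition is drawn
  Dirichlet(2000 · target) — mean-preserving day-to-day noise — and
  counts are multinomial at a depth ~ Normal(150 087, 14 526²) truncated
  below at 1000 reads. Days are conditionally independent given the
  subject's baseline and phase; within-subject temporal autocorrelation
  beyond the phase structure is not modeled.
- **Diaries.** AAD subjects receive ≥1 watery (Bristol 6–7) episode on
  days 1–3; exactly 4 randomly chosen AAD subjects receive ≥3 watery
  episodes on one day (the early-stop rule); non-AAD subjects receive
  only Bristol 2–5 episodes in that window. Labeling therefore recovers
  the latent groups exactly — the 13-AAD count is a construction, not an
  estimate.
- **qPCR.** log₁₀ *F. prausnitzii* concentration = 7.5 + 0.5·z, with z
  coupled to the subject's baseline Ruminococcaceae proportion through a
  Gaussian copula on the pooled (two-group mixture) margin, using Pearson
  parameter r = 2 sin(π·0.85/6) so the population Spearman equals 0.85.
  Coupling on the pooled margin (rather than per-group margins) is what
  makes the cohort-wide Spearman exact and gives the AAD group its lower
  concentrations. A per-subject biomass deviation (log₁₀ sd 0.15)
  multiplies both targets; Cq values are back-computed through the
  configured standard curves with N(0, 0.15) cycle noise per replicate,
  three replicates per target. The location/scale (7.5/0.5) put the
  cohort across the 2.4 × 10⁷ – 8.0 × 10⁷ GC/µL decision thresholds.

What the generator does **not** emulate: sequence-level artifacts (no
reads, chimeras or denoising), realistic ASV richness (36 ASVs vs
thousands), strain dynamics, diet covariates, or within-subject
autocorrelation. Tests passing on these cohorts show the pipeline
recovers planted parameters under the modeled noise; they do not certify
performance on real sequencing data.

## Analysis components

- **Labeling** (`labeling`): "watery stool" is interpreted as Bristol
  6–7 (configurable to {7}); the protocol's "24-h period" is a calendar
  study day, the diary's resolution. Subjects with no day 1–3 records
  are labeled non-AAD with a warning.
- **Count tables** (`tables`): rarefaction subsamples without replacement
  (multivariate hypergeometric) and drops samples below the requested
  depth; aggregation pools empty rank labels into "Unassigned" and
  conserves counts. The Enterobacteriaceae bloom threshold of 0.10
  relative abundance on any of days 1–3 is a declared convention (it
  separates reported bloom magnitudes from typical baselines), exposed
  as a parameter.
- **Diversity/ordination** (`diversity`): Shannon entropy uses log base
  2 (bits); Jensen–Shannon distance is the square root of the base-2
  divergence, so it lies in [0, 1]. PCoA is classical scaling; negative
  eigenvalues are excluded from coordinates and from the
  proportion-explained denominator (no Lingoes/Cailliez correction).
  PERMANOVA uses pseudo-F with the (1 + count)/(N + 1) p-value
  convention, so p ≥ 1/(N+1) > 0. Baseline clustering treats subjects as
  observations: pairwise distance 1 − Pearson correlation between
  subject abundance vectors, average linkage (scipy), dendrogram cut at
  0.4. Clustering subjects (not ASVs) is an interpretation choice — the
  dendrogram of interest groups individuals.
- **Group statistics** (`group_stats`): Mann–Whitney U p-values are
  exact (full enumeration) when both n ≤ 8 without ties, else normal
  approximation with tie and continuity corrections (continuity is
  configurable). Bonferroni family size defaults to the number of
  (taxon, day) tests actually run and is recorded in the output. IQRs
  are 25th–75th percentiles with linear interpolation.
- **qPCR** (`qpcr`): replicate aggregation by median (mean available);
  efficiency is always recomputed as 10^(−1/slope) − 1 and a warning is
  logged when a supplied value disagrees by more than one percentage
  point — the published curve pairs disagree with this formula (printed
  85.1%/85.4% vs recomputed 87.1%/86.5%), so both are stored and neither
  is used downstream. Extrapolation beyond the fitted dilution range
  (1–10⁷ copies/µL for the default curves) is allowed with a warning.
  "GC/µL" is the canonical unit throughout.
- **Risk model** (`risk`): group densities are normalized by group size,
  so the posterior uses equal group priors; an `equal_priors=False` flag
  provides the group-size-weighted alternative. Min-max anchors come
  from the training cohort and queries outside [0, 1] are scored, not
  clipped. Region masses use the closed-form Gaussian CDF of the mixture;
  the pointwise-ratio mode exists for sensitivity analysis. How the
  published low-vs-high ratio was computed (pointwise vs region,
  priors, bandwidth) is not recoverable, so no numeric reproduction of
  it is claimed — only the direction and approximate magnitude.

## Numerical and testing choices

Problem sizes in the calibration benchmarks — 200 cohort replicates for
abundance means and the Faecalibacterium share, 500 for bloom statistics,
one 10,000-subject baseline-only cohort for the Spearman check, 500
simulations for type-I-error calibration and 200 for power — were chosen
so Monte-Carlo standard errors are small relative to the calibrated
quantities. Statistical-calibration and risk-ratio replicates use
baseline-only cohorts where only baseline data enters the computation.
All randomness flows from explicit integer seeds; per-cohort seeds are
derived linearly modulo 2³¹ − 1.

Known limitations: the power of the baseline Ruminococcaceae contrast at
the cohort's 13-vs-17 sample size is ≈ 0.6 at α = 0.05 under the default
within-group spread (Beta concentration 20) — a single cohort of this
size detects the planted deficit only about three times in five, which
the test suite documents as a failing power benchmark rather than
papering over. Degenerate inputs (all-zero samples, constant vectors,
zero-variance profiles, empty groups) raise errors naming the offending
entity rather than producing silent NaNs.
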