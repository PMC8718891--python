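# aadrisk

Analysis toolkit for studying the link between baseline gut microbiome
composition and **antibiotic-associated diarrhea (AAD)** in short
antibiotic-challenge cohorts. It is written for microbiome researchers who
want a tested, reusable implementation of the full analysis chain: cohort
labeling from stool diaries, 16S ASV count-table summarization, diversity
and ordination, nonparametric group testing, qPCR absolute quantification
of *Faecalibacterium prausnitzii*, and a kernel-density risk predictor —
together with a synthetic-cohort generator that emulates a 30-subject
amoxicillin-clavulanate challenge study (13 AAD / 17 non-AAD, stool
sampled on days 0, 1, 2, 3, 7, 14 and 28).

## The model at the core

A subject is **AAD** if their stool diary records at least one Bristol
Stool Scale type 6–7 episode on treatment days 1–3. Baseline
Ruminococcaceae relative abundance separates groups (the synthetic
cohort is calibrated to group means of 8.4% vs 14.4%), and qPCR-derived
*F. prausnitzii* concentration tracks it (Spearman ρ ≈ 0.85 by a Gaussian
copula with Pearson parameter r = 2·sin(πρ_S/6)).

qPCR quantification inverts the standard curve Cq = a + b·log₁₀(copies)
(*F. prausnitzii*: a = 37.342, b = −3.674) at the triplicate median,
divides by the sample's 16S deviation factor (16S concentration over the
cohort-median 16S concentration, a stool-biomass correction), and scales
by the 100× template dilution.

The risk model min-max-normalizes baseline concentrations over the pooled
cohort and forms one Gaussian kernel density per group,

    f_g(x) = (1/n_g) Σ_i N(x; x_i, h),

with bandwidth h the model's hyperparameter (Silverman's rule by
default). The posterior risk at concentration x is

    P_AAD(x) = f_AAD(x) / (f_AAD(x) + f_non-AAD(x)),

and the region risk ratio compares P(AAD | x < t_low) with
P(AAD | x > t_high) using region-integrated density masses.

Diversity and testing primitives (Shannon entropy in bits, Jensen–Shannon
distance, Bray–Curtis dissimilarity, classical-scaling PCoA, PERMANOVA
with seeded permutations, two-sided Mann–Whitney U with exact enumeration
for small untied samples, Bonferroni correction) are implemented from
their defining formulas and cross-checked against independent oracles in
the test suite.

## Worked example

```bash
python examples/04_qpcr_risk_model.py
```

prints, for the default synthetic cohort (seed 1):

```
F. prausnitzii, AAD: median 1.19e+07 GC/uL
F. prausnitzii, non-AAD: median 2.42e+07 GC/uL
KDE bandwidth (Silverman, normalized scale): 0.044
P(AAD | 1.0e+07 GC/uL) = 0.62
P(AAD | 3.0e+07 GC/uL) = 0.45
P(AAD | 8.0e+07 GC/uL) = 0.25
risk ratio, x < 2.4e7 vs x > 8.0e7 GC/uL: 2.32
```

The AAD group's median baseline *F. prausnitzii* level is roughly half
the non-AAD group's; the posterior AAD probability falls as baseline
concentration rises; and a subject below 2.4 × 10⁷ GC/µL carries about
2.3 times the AAD probability of a subject above 8.0 × 10⁷ GC/µL.
The other example scripts cover simulation and diary labeling
(`01_simulate_and_label.py`), family profiles, group tests and
Enterobacteriaceae bloom calls (`02_taxon_profiles_and_blooms.py`), and
diversity, PCoA, PERMANOVA and baseline clustering
(`03_diversity_and_ordination.py`).

A thin CLI mirrors the library:

```bash
aadrisk simulate --seed 1 --out study/
aadrisk label --diary study/diary.csv --out labels.tsv
aadrisk run --seed 1 --out results/
```

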