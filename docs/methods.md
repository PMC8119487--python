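# Methods

`artakit` implements the audiometric genotype–phenotype workflow used in
studies of autosomal dominant, postlingual progressive hearing loss
(ADHL): pooled cross-sectional modelling of hearing thresholds against
age, summarization of the fitted progression pattern into a categorical
feature array, chi-square comparison of variant-specific patterns, and
pedigree-based ACMG evidence grading. A synthetic cohort generator
provides study-scale data so the whole chain is testable without
patient records.

## Audiometric model

Air-conduction thresholds are handled in dB HL on a kHz frequency grid.
Clinical thresholds measured with the 10-down/5-up search are multiples
of 5 dB and confined to the audiometer output range [−10, 120] dB HL;
readers warn (but do not reject) on non-quantized values, since
digitized historical audiograms often deviate. Binaural thresholds are
per-frequency arithmetic means of the two ears from one session, may
end in 2.5 dB half-steps, and are never re-quantized. Thresholds at
"no response" frequencies are stored at the audiometer maximum with a
censoring flag and enter the regression at that value; excluding them
would bias progression slopes downward.

Interaural symmetry uses a configurable rule, by default: asymmetric if
|left − right| ≥ 15 dB at two or more of 0.5/1/2/4 kHz. Hearing-loss
degree follows the standard clinical bands: normal ≤ 20, mild 21–40,
moderate 41–70, severe 71–90, profound > 90 dB HL, with boundaries
inclusive as printed; the bands partition the whole threshold axis.

## ARTA and annual threshold deterioration

The Age-Related Typical Audiogram (ARTA) model pools binaural
audiograms across subjects and visits — each audiogram is one
observation per frequency, the convention for cross-sectional
progression analyses of multi-family data — and fits, independently at
each frequency f,

    threshold(f) = intercept(f) + ATD(f) · age + ε,

by ordinary least squares. The slope ATD(f) is the annual threshold
deterioration in dB/year; its two-sided t-test on n − 2 degrees of
freedom decides significance at α = 0.05. Typical audiograms are the
fitted lines evaluated at fixed ages, by default every decade from
10 to 80 years (8 ages). The default frequency set is
{0.25, 0.5, 1, 2, 4, 8} kHz.

Numerical choices: a frequency with fewer than 3 points or no age
spread is flagged unfittable rather than silently dropped. A fit with
(numerically) zero residual variance cannot produce a meaningful
standard error; a flat zero-slope line is reported with p = 1 (flat
data reject nothing) and an exact nonzero trend with p = 0.
Predictions are the raw regression lines and may leave the audiometer
range; clipping to [−10, 120] dB HL is available for plotting only,
because the regression line, not its truncation, is the object of
inference. No covariates or robust-regression weights are used; the
model is plain OLS per frequency.

An optional subject-level averaging mode is deliberately absent from
the default path: pooling repeat visits matches the published
convention of counting binaural thresholds, not subjects.

## Threshold feature arrays

A feature array reduces an ARTA to counts of its grid points (8 ages ×
6 frequencies = 48 under defaults) per (degree class × frequency band)
cell. Bands default to a symmetric two-per-band split: lf = {0.25,
0.5}, mf = {1, 2}, hf = {4, 8} kHz; both the band map and the inclusion
of the "normal" class (included by default, 5 × 3 = 15 cells) are
configurable.

Two patterns are compared by a chi-square goodness-of-fit test: the
reference array supplies cell proportions, expected counts are those
proportions scaled to the observed total, and cells with expected
count < 1 are pooled into one remainder cell before computing
χ² = Σ (O − E)²/E with df = (#retained cells − 1). If the remainder
pools only reference-empty cells and the observed array has mass
there, the observed pattern lies outside the reference's support; the
statistic is reported as infinite with p = 0. This is the correct
limit of the test but makes it sensitive near degree-class boundaries:
a fitted array can differ "infinitely" from a noise-free reference
because sampling noise pushed a few grid points across the 90 dB line.
The reference is treated as a fixed external distribution (not
estimated from the observed data), so no further df correction is
applied.

## Pedigree evidence (PM2, PP1, ACMG combining)

PM2 (rarity) is met when every queried population database reports the
variant absent or at allele frequency ≤ 2 × 10⁻⁵ (configurable); the
default suits a fully penetrant dominant disorder.

Co-segregation is counted over informative meioses: parent → offspring
transmissions where the parent is a genotyped heterozygote and the
offspring is genotyped with known affection status. The transmission
that produced the proband is excluded (ascertainment). A meiosis is
concordant when genotype and phenotype agree (het ∧ affected, or
ref ∧ unaffected). Under the default full-penetrance mode any
disagreement is discordant; under the age-dependent mode an unaffected
carrier younger than the family's onset age is set aside as
uninformative, reflecting postlingual onset in the second to fourth
decade. PP1 strength follows the widely used meiosis-count heuristic:
≥ 3 concordant meioses → supporting, ≥ 5 → moderate, ≥ 7 → strong, any
discordant meiosis (full penetrance) → no PP1. The tier table is
configurable; published reports rarely state their exact counting
convention, so these defaults are a documented choice, not a standard.

Criteria are combined by an explicit encoding of the standard
ACMG/AMP rule table over strength counts (very strong / strong /
moderate / supporting on the pathogenic side; stand-alone / strong /
supporting on the benign side). One strong plus one moderate criterion
gives "likely pathogenic" — the combination produced by PM2 with
PP1-strong. Combinations reached by neither side give VUS; combinations
satisfying both sides are contradictory and give VUS. A lone benign-
strong criterion does not reach likely-benign and therefore cannot
create a contradiction.

Obligate-carrier inference for untyped ancestors is not performed;
untyped individuals simply contribute no informative meioses.

The cohort-prevalence helper reports the share of screened families
explained by a gene (4 of 102 families → 3.92 %, the "approximately
4 %" figure).

## Synthetic cohorts

The generator emulates multigenerational ADHL families: a heterozygous
founder, Mendelian transmission with probability 1/2 per meiosis,
married-in spouses homozygous reference, full penetrance above a
variant-specific onset age. Families span a configured number of
generations (≥ 3, default 4); each couple has Poisson-distributed
(mean 3) children, at least one; carrier children and each couple's
first child marry and found a branch, which keeps every family at full
depth without conditioning on genotype. Generation ages are Gaussian
around 85/63/41/19 years (SD 4).

A carrier's true threshold is baseline(f) + ATD(f) · max(0, age −
onset); non-carriers keep a flat 5 dB HL audiogram (no presbyacusis
term, so their fitted slopes test the null). Measurement follows the
clinical instrument: clip the true value to [−10, 120], add independent
per-ear Gaussian noise (SD 7 dB, typical test–retest variability),
clip again, round to the nearest 5 dB. Affected subjects contribute up
to 3 visits 5 years apart, never before onset (patients present once
loss is noticed); unaffected subjects one visit.

Progression profiles: the published per-variant ATD ranges pin the
slope at each range's endpoint frequencies (average profile 0.61 dB/yr
at 8 kHz to 0.75 at 0.25/0.5 kHz; p.Asp185Asn 0.83 at 0.25 kHz to 1.72
at 2 kHz; p.Ser178Leu 0.88 at 4 kHz to 1.08 at 1 kHz; p.His487Leu 0.59
at 4 kHz to 1.03 at 0.5 kHz); slopes at the remaining frequencies are
interpolated once and fixed. Baselines (threshold at onset) are free
parameters — no numerical intercepts are published — chosen once to
match the qualitative description (mild at low/mid frequencies and
moderate at high frequencies early in life, down-sloping), and are
illustrative package defaults, not data. Onset ages use the published
family means (average 17, p.Asp185Asn 16.7, p.Ser178Leu 19.5,
p.His487Leu 35 years).

The default cohort (five 4-generation families, capped at 81 affected
binaural sessions by random subsampling) reproduces the scale of the
pooled published dataset (81 binaural thresholds). Problem sizes in the
test suite (500 recovery replicates, 200 pattern seeds, 1000 regression
oracles) were chosen as the smallest giving stable Monte-Carlo
estimates of the checked rates.

What the generator does not emulate: presbyacusis or noise-induced
phenocopies (the published cohort excluded one such patient),
asymmetric losses, de novo variants, reduced penetrance, assortative
mating, and longitudinal correlation of repeat visits beyond the shared
true trajectory. Passing recovery tests therefore show the estimator is
correct under the stated model, not that real cohorts satisfy that
model.

## Bundled families

The four bundled TBC1D24 families are synthetic reconstructions
(`datasets.py`): topologies consistent with the published counts
(6/12/6/5 affected members, probands in generation IV, three or more
affected generations, concordant segregation throughout, near-zero
population frequencies), built because the original pedigree drawings
are not machine-readable. They validate the evidence chain — each
yields PM2 + PP1-strong → likely pathogenic — but are not the original
families.

## Known limitations

- Cross-sectional OLS treats repeat visits of one subject as
  independent; standard errors are mildly optimistic under
  within-subject correlation. Mixed-effects modelling is out of scope.
- The chi-square comparison against a fixed reference is anticonservative
  when the reference has empty cells near a class boundary (see above).
- Censored (audiometer-maximum) thresholds enter the regression at the
  maximum rather than via a tobit-style likelihood, slightly flattening
  slopes in profound ranges.
- PP1 tiers and the symmetry rule are field heuristics, configurable
  because no single published convention exists.
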