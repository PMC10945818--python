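# Methods

This note documents the models, numerical choices and design decisions in
`bioembed`, and what the synthetic-data generators do and do not emulate.

## Adversity scoring

Each individual receives five binary early-life exposures and their 0–5
sum:

| exposure | rule | boundary handling |
|---|---|---|
| drought | first-year rainfall < 200 mm | strict; exactly 200 mm is not drought |
| maternal loss | mother's death before focal age 4.0 y (years = days/365.25) | strict; death at exactly 4.0 y does not count |
| close sibling | live birth strictly within 1.5 y after the focal birth | strict on both ends |
| low maternal rank | ordinal rank strictly above the cohort's 75th percentile (1 = highest status) | percentile by linear interpolation; ties resolve toward non-adversity |
| large group | group size strictly above the cohort's 75th percentile | same quantile rule |

The quartile reference population is the full supplied cohort, not birth
cohorts or social groups. A missing rank or group size leaves that flag —
and hence the cumulative score — missing; such individuals are excluded
from models that use the score, never imputed. Habitat quality at birth
is a pure function of the birthdate: birth strictly before the home-range
shift date is "low quality".

## QC filtering

Sites are retained when (1) coverage ≥ 5 reads in ≥ 50% of samples,
(2) the methylation fraction has nonzero variance, and (3) the mean
fraction lies strictly inside (0.10, 0.90). Rules apply in that fixed
order and the report attributes each removed site to the first rule it
fails, so attrition accounting is reproducible; constant all-zero or
all-one sites are therefore counted as "invariant" rather than as
hypo-/hyper-methylated. All cuts are parameters. Under the generator's
bimodal baseline defaults this retains roughly a third of simulated
sites, the same order as RRBS practice.

## Binomial mixed model

Counts at one site: `m_i ~ Binomial(r_i, pi_i)`,
`logit(pi_i) = x_i'beta + u_i`, `u ~ N(0, sigma_g^2 K + sigma_e^2 I)`.
Samples with zero coverage are dropped per site. The kinship matrix is
expanded from individuals to samples by index lookup, so repeated samples
of one individual share its diagonal entry.

Estimation is a Laplace approximation: for a candidate variance pair,
`(beta, u)` are jointly maximised by damped Newton steps (step-halving on
the penalized log-likelihood, working-weight floor 1e-10); the Laplace
marginal log-likelihood
`f(beta, u) - 0.5 log|Sigma| - 0.5 log|Sigma^{-1} + W|` is then optimised
over `(log sigma_g^2, log sigma_e^2)` by Nelder–Mead (xatol 1e-2, fatol
1e-4, variance floor 1e-6, ceiling 50). The eigendecomposition of `K` is
computed once per site and reused across variance evaluations. When the
two components are weakly identified (e.g. near-identity kinship) the
likelihood has a flat ridge in one direction; a final simplex whose
function values span < 5e-3 is accepted as converged, since differences
at that scale are far below statistical noise. Fixing both components at
zero switches to an exact IRLS binomial GLM, which matches an
independently coded IRLS oracle to 1e-6 in the tests.

Wald inference per focal term uses
`Var(beta) = (X' V^{-1} X)^{-1}`, `V = W^{-1} + Sigma`, evaluated at the
optimum; `z = beta/se` with two-sided normal p-values.
`h^2 = sigma_g^2/(sigma_g^2 + sigma_e^2)` is reported on the latent logit
scale. Multiple testing uses Benjamini–Hochberg step-up q-values per
focal term, over converged sites only.

Calibration and recovery, verified by the acceptance tests at n = 60
individuals with pedigree kinship and ~30× coverage: type-I error at
nominal 5% stays within [0.03, 0.07] with uniform-looking p-values;
the regression of estimated on true logit effects has slope ≈ 1; and mean
estimated h² for a true value of 0.5 lands near 0.45 — the Laplace
approximation shrinks variance components slightly at these sample
sizes, which we accept rather than correct.

### Designs

Model 1 uses habitat + cumulative adversity + age + sex-nested rank +
technical covariates (batch one-hot with a reference level, conversion
rate, mean depth) and drops samples with a missing rank. Models 2–3 nest
the adversity terms within habitat (`value × habitat indicator`) and
retain missing-rank samples, mean-imputing rank within sex; this keeps
the design full-rank without discarding adversity information, since the
published analysis kept such individuals but did not state its rank
handling. No sex main effect is modelled. Exactly-zero and linearly
dependent design columns are dropped with a warning (greedy rank-
preserving selection after scaling); the focal-term list shrinks
accordingly, e.g. `male_rank` disappears in an all-female cohort.

## Enrichment

Site ids carry 1-based positions; BED tracks are 0-based half-open, and
the conversion lives in one place, so a site at 1-based position 100
overlaps `[99, 100)`. Compartments are made exclusive by a fixed
priority (promoter > CpG island > shore > enhancer > gene body >
unannotated); the chromatin-state segmentation is a partition, assigned
by direct overlap.

The odds ratio is the sample cross-product `ad/bc` — deliberately not a
conditional MLE or continuity-corrected estimate — so a zero cell makes
the ratio inestimable and the result carries `defined=False`, matching
how such overlaps are reported in practice. The p-value is the standard
two-sided Fisher exact test. Cross-predictor overlap uses the
two-threshold rule (10% FDR for one predictor, ≤ 20% for the other, in
either direction); directional concordance is the fraction of overlap
sites with matching effect signs, with its own Fisher test on the 2×2
sign table. Gene-set enrichment is a one-sided hypergeometric
over-representation test with a Bonferroni multiplier equal to the
number of sets tested.

## Habitat prediction

Features are methylation fractions; sites missing in > 20% of samples
are dropped, the remainder mean-imputed and z-scored *within each
training fold only*. For each held-out sample an elastic net
(mixing 0.5 by default; 50-point log-spaced penalty grid chosen by inner
5-fold CV, folds seeded) is fitted on the rest. The reported score is
the centered linear predictor `x'beta` with the intercept omitted:
under leave-one-out the intercept equals the training-fold class
balance, whose fold-to-fold fluctuation anti-correlates perfectly with
the held-out label and drives a null model's AUC toward zero; dropping
it restores a near-0.5 permutation null while leaving the signal
ranking unchanged (with standardized features the intercept carries no
methylation information). A mild pessimistic bias remains — permuted-
label AUCs centre around 0.42–0.45 rather than 0.50, the usual
leave-one-out overfitting anti-correlation. Scores are signed: positive
means predicted born in the low-quality (pre-shift) habitat.

AUC is the Mann–Whitney statistic (ties 0.5), equal to the trapezoidal
area under the ROC points computed at every distinct threshold. The
attenuation test is plain OLS of the low-quality-born samples' scores on
(separately) days since the habitat shift and cumulative days spent in
the low-quality habitat, plus an age control regression.

A caveat documented by a test: under pure ridge, duplicating a feature
column halves that feature's effective penalty, so held-out scores are
only near-invariant (ranking preserved, shifts ~2%), not bit-identical.

Coordinate-descent settings (tol 1e-3, max_iter 1000) are looser than
library defaults; at these sample sizes the induced score differences
are far below the statistical noise of the CV penalty choice, and they
keep an 80-sample, 5000-site leave-one-out run to about two minutes.

## mSTARR-seq calling

Per window, replicate and condition, the statistic is
`log2((rna + 0.5)/sf_rna) - log2((dna + 0.5)/sf_dna)`. Size factors are
median-of-ratios within assay (DNA libraries normalised against DNA
libraries, RNA against RNA, factors rescaled to geometric mean 1).
Total-count size factors were rejected: a minority of strongly active
windows inflates the RNA totals of one condition and shifts every null
window's log-ratio between conditions (~0.4 log2 units in the planted
simulation), wrecking the false-discovery calibration; median-of-ratios
is robust to that composition bias.

Activity per condition is a one-sample t-test of the window's replicate
log-ratios against the genome-wide median log-ratio (the plasmid
self-transcription background), BH-corrected across windows; a window is
regulatory if active in either condition. Methylation dependence is a
Welch t-test between conditions, tested only among regulatory windows
(matching the conditional structure of the original analysis) and
BH-corrected; the sign of the mean difference sets the direction.
Zero-variance windows are skipped with a flag. Swapping condition labels
flips every direction call and leaves dependence q-values unchanged.

On the planted acceptance simulation (1000 windows, 50 active at 8×/1×
multipliers, 6 replicates) this achieves sensitivity 1.0 at empirical
FDR ≈ 4–9%, with every detected truly-dependent window classified as
repressed by methylation. False-positive dependent calls have random
direction, so the overall repressed fraction sits near, not at, 100%.

## Expression concordance

Sites map to every gene body containing them (GTF 1-based inclusive;
multi-gene overlaps kept and flagged). Distance to a gene set is 0
inside a gene body, else bp to the nearest body boundary,
strand-ignored. The per-gene methylation summary is the sign of the most
significant site in the body (configurable to mean-of-signs); this is
crossed with the sign of the gene's expression effect in a Fisher test,
where anti-concordance (methylation up, expression down) appears as a
negative log2 OR. A relative-risk fold-enrichment of
expression-significant genes among genes containing a significant CpG is
reported alongside.

## Synthetic data

All generators draw from named substreams of a single seed
(`SeedSequence` spawn keys), so enabling one generator never perturbs
another's draws, and regeneration from (seed, parameters) is
bit-identical.

* **Pedigree/kinship** — random-mating, 3 generations by default;
  relatedness by the recursive tabular method (twice the kinship
  coefficient), verified against path counting. Analyses that need a
  structured subset take the most recent members, since a founders-only
  subset is an identity matrix under which h² is unidentified.
* **Cohort** — birthdates spanning the habitat shift (25% pre-shift by
  default); drought/maternal-loss/sibling exposures are independent
  Bernoulli draws (default prevalence 0.25) with consistent underlying
  dates and rainfall; rank and group size are drawn continuous, so the
  downstream quartile rule pins those two flags near 25% by
  construction. Exposures are independent of the birth cohort, so the
  cumulative score does not differ by habitat except by noise.
* **Samples** — one sample per individual, with 15% of individuals
  contributing 2–3 longitudinal samples; ~10% of male sample-months lack
  a rank entry (observation gaps), exercising the Model 1 vs Model 2–3
  missing-rank paths.
* **Methylation** — the exact model the scan assumes: bimodal baseline
  logits (modes ±3, an intermediate component), planted per-term logit
  effects, kinship-correlated `g`, i.i.d. `e`, negative-binomial
  coverage (mean 30, dispersion 0.1), binomial methylated counts.
* **Annotations** — a 15-state segmentation tiling each chromosome
  exactly; compartment tracks at configurable genome fractions; shores
  as 2-kb island flanks; gene models emitted as GTF.
* **mSTARR** — negative-binomial DNA, RNA at a basal rate times
  condition-specific activity multipliers for planted active windows.
* **Expression** — genes containing causal CpGs get effects opposing the
  methylation sign with configurable probability; others are null.

What the generators do **not** emulate: read-level artefacts (mapping,
bisulfite conversion chemistry), spatial correlation between neighbouring
CpGs, cell-composition variation, realistic demography or linkage, and
genome-scale site counts. Passing recovery tests therefore demonstrates
the statistical machinery is correct under the assumed model, not that
the model captures every feature of real RRBS data.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to keep the whole
suite in the minutes range: 500 null sites and 200 planted-effect sites
at n = 60 for calibration/recovery; 200 sites at n = 80 for the nested
design; 5 000 sites × 80 samples for the predictor; 1 000 reporter
windows; 10 000 annotated sites; and a 240-site, 50-individual bundle
for the end-to-end determinism check. The generators accept larger sizes
unchanged.

## Known limitations

* Laplace inference mildly shrinks variance components (and hence h²)
  at small n; no bias correction is applied.
* h² is on the latent logit scale; no observed-scale transform.
* Wald p-values rely on asymptotic normality; at very low coverage or
  extreme baselines the scan flags but does not rescue non-converged
  sites.
* The mSTARR backend is a replicate-level log-ratio t-test, not a count
  GLM; the interface would admit a count-GLM backend.
* The elastic-net hyperparameters (mixing 0.5, grid size 50) follow
  common practice rather than a published specification.
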