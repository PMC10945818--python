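# bioembed

Statistical machinery for asking whether early-life adversity leaves a
lasting mark on the adult epigenome — and whether that mark matters.
The package was built around a study design from wild-primate field
research: blood DNA methylation profiled by reduced-representation
bisulfite sequencing (RRBS) in a longitudinally monitored population, with
decades of life-history records supplying each animal's early-life
exposures, plus an in-vitro reporter assay (mSTARR-seq) probing whether
the affected CpG sites can actually drive gene-regulatory changes.

It is aimed at statistical geneticists and molecular ecologists who need a
tested, end-to-end reference implementation of this analysis style —
per-site count-based mixed models with relatedness, nested exposure
designs, enrichment against an assay-defined background, and epigenetic
prediction — together with synthetic-data generators that plant known
truth, so every step can be validated by recovery rather than by eye.

## The model

For methylated counts $m_i$ out of $r_i$ total reads at one CpG site in
sample $i$:

$$m_i \sim \mathrm{Binomial}(r_i, \pi_i), \qquad
\mathrm{logit}(\pi_i) = x_i^\top \beta + u_i,$$

$$u \sim \mathcal{N}\!\left(0,\; \sigma_g^2 K + \sigma_e^2 I\right),$$

where $K$ is the pairwise genetic relatedness (kinship) matrix expanded to
sample level, $\sigma_g^2$ is pedigree-structured variance on the logit
scale, $\sigma_e^2$ is residual overdispersion, and
$h^2 = \sigma_g^2 / (\sigma_g^2 + \sigma_e^2)$ is the narrow-sense
heritability of the latent methylation level. Fitting uses a Laplace
approximation (joint Newton updates for $\beta$ and $u$, Nelder–Mead on
the two log-variances); Wald tests per focal term use
$\mathrm{Var}(\hat\beta) = (X^\top V^{-1} X)^{-1}$ with
$V = W^{-1} + \sigma_g^2 K + \sigma_e^2 I$.

Three fixed-effect designs mirror the study's modelling sequence:

* **Model 1** — habitat quality at birth + cumulative early adversity
  (0–5 exposures) + age + dominance rank nested within sex + technical
  covariates;
* **Model 2** — cumulative adversity *nested within habitat quality*
  (`adversity_low = cumulative × 1[born in low-quality habitat]`, and the
  high-quality analogue);
* **Model 3** — each of the five adversity components (drought, maternal
  loss, close-in-age sibling, low maternal rank, large group) nested
  within habitat quality.

Around the scan sit: QC filtering of the count matrix to the analyzable
site set; Benjamini–Hochberg FDR per focal term; Fisher's-exact enrichment
of hit sets across genomic compartments and chromatin states against the
tested-site background; leave-one-out elastic-net prediction of the birth
cohort from methylation fractions with ROC/AUC and a temporal-attenuation
regression; mSTARR-seq window calling (activity per methylation condition,
then methylation dependence); and gene-level methylation–expression
sign-concordance tests.

## Worked example

Fit the binomial mixed model at one simulated CpG site with a planted
habitat-cohort effect of +0.8 on the logit scale:

```python
import numpy as np
import pandas as pd

from bioembed import fit_site
from bioembed.simulate import simulate_methylation, simulate_pedigree

pedigree, kinship = simulate_pedigree(n_founders=30, n_generations=3, seed=11)
n = 60
K = kinship.K[-n:, -n:]

born_low = (np.arange(n) < 15).astype(float)
predictors = pd.DataFrame({"habitat_low": born_low})
counts, truth = simulate_methylation(
    K, predictors, n_sites=1, causal_effects={"habitat_low": (1, 0.8)},
    sigma2_g=0.3, sigma2_e=0.2, baseline_weights=(0, 1, 0), seed=11,
)

X = pd.DataFrame({"intercept": np.ones(n), "habitat_low": born_low})
result = fit_site(counts.meth[0], counts.total[0], X, K)
print(result.summary())
```

```
Binomial mixed model (Laplace)
  nobs: 60   converged: True
  sigma2_g: 0.2225   sigma2_e: 0.1354   h2: 0.622   loglik: -893.81
  term                    beta        se        z     P>|z|
  intercept            -1.4015    0.1586   -8.837   9.8e-19
  habitat_low           0.7596    0.2151    3.532  0.000413
```

The planted cohort effect (true $\beta = 0.8$) is recovered as
$\hat\beta = 0.76 \pm 0.22$ with a clearly significant Wald test; the
variance components sum near the simulated total (0.5), with the split
between $\sigma_g^2$ and $\sigma_e^2$ noisy at $n = 60$, as expected.

The full pipeline (simulation → QC → scans → enrichment → prediction →
mSTARR → concordance) runs from the command line:

```bash
bioembed all --set outdir=results/demo --set seed=1
```

Each stage writes its outputs under `outdir` plus a `manifest.json`
recording the seed, a configuration hash, and per-stage row counts;
rerunning with the same configuration reproduces every file byte for
byte.

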