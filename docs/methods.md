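# Methods

`sigdecon` implements a pipeline for deriving cell-type transcriptional
signatures from heterogeneous reference RNA-seq data, estimating cell-type
fractions in bulk tumor profiles, relating those fractions to
progression-free survival, and benchmarking the whole chain on simulated
mixtures with a planted survival association. This note records the models,
the defaults and why they were chosen, and the limits of what the synthetic
experiments can show.

## Abundance model

For replicate $j$ of cell type $t$ and gene $g$ the observed count is
modelled as negative-binomial,

$$y_{gj} \sim \mathrm{NB}(\mu_{gt}\, s_j,\ \phi_g), \qquad
\operatorname{Var} = m + \phi m^2,$$

where $s_j$ is the replicate's effective library size (raw library size
times its TMM factor, divided by $10^6$), so $\mu_{gt}$ is on a common
TMM-normalized counts-per-million scale, and $\phi_g$ is a per-gene
dispersion shared across cell types (the edgeR-style mean/dispersion
parameterization, used consistently throughout the package).

A gene-level log-normal prior on $\mu$, shared across cell types, supplies
the incomplete-data behaviour: its location and scale are the empirical
mean and spread of the gene's per-type log abundances (scale floored at
1.0 on the log scale, so the prior stays weakly informative when replicate
data exist; pairs with no observations report the prior itself, with a
default scale of 2.0 when the spread cannot be estimated). Dispersion is a
per-gene moment estimator pooled across cell types and shrunk toward the
across-gene median with 10 pseudo-observations; this moderation stabilises
genes with few replicates without distorting well-observed ones.

Inference is exact one-dimensional quadrature: with $\phi_g$ plugged in,
the posterior over $\log\mu$ is evaluated on a 241-point grid spanning
±8 approximate posterior standard deviations around a precision-weighted
data/prior blend, and the reported posterior mean and 2.5/97.5% quantiles
are computed from the normalized grid weights. This is more accurate than
a Laplace approximation at essentially the same cost and requires no MCMC;
a sampler backend could be slotted in but is not shipped. On synthetic data
with known means the 95% intervals cover the truth for ~94% of
(type, gene) pairs (`tests/test_acceptance.py`), the small deficit being
the price of the plug-in dispersion.

Internal hierarchy nodes (e.g. "immune") are fitted as cell types in their
own right on the pooled replicates of their leaf descendants. The pooled
data are a mixture across leaves, so node-level dispersions are understated
and node intervals are, if anything, slightly narrow; marker selection only
uses them for within-level ranking, where this bias is shared by both sides
of every comparison.

## Marker selection and the signature matrix

Two cell types $a, b$ at the same hierarchy level are compared through the
credible-interval separation

$$\mathrm{gap}(a, b; g) = \mathrm{ci}_{2.5}(a, g) - \mathrm{ci}_{97.5}(b, g),$$

positive exactly when $a$'s expected abundance credibly exceeds $b$'s.
For every *ordered* pair of siblings (both directions are evaluated) the
genes with positive gap are ranked (ties broken lexicographically by gene
identifier, making the output fully deterministic) and the top $k$ kept —
$k = 5, 10, 20$ at levels 1, 2, 3. Broad compartments therefore get a few
strong markers while terminal activation states get deeper coverage. The
union over all pairs, with per-selection provenance (level, winner, loser,
gap), is the signature gene list; the signature matrix holds the posterior
mean abundance of each marker gene in each *leaf* cell type, on the same
TMM/CPM scale.

Note an intrinsic ceiling: a type whose comparisons all happen at level 1
can contribute at most ~$k{=}5$ of its markers per pairwise direction, so
planted-marker *recall* is only a meaningful measure when the per-level
budget exceeds the number of planted markers. The recall tests use an
all-leaves-at-level-3 hierarchy ($k = 20 >$ 10 planted markers per type)
for exactly this reason.

## Deconvolution

`deconvolve` follows the CIBERSORT scheme: restrict the mixture and the
signature to shared genes (at least 50% of signature genes must be present),
z-score the signature matrix globally and each mixture vector individually,
fit a linear-kernel ν-SVR for ν ∈ {0.25, 0.5, 0.75}, keep the ν with the
lowest reconstruction RMSE, clip negative coefficients to zero and
renormalize to a simplex. The global z-scoring makes the result invariant
to the mixture's overall scale, so counts (after TMM/CPM) and TPM inputs
are both acceptable. Quantile normalization — the array-era CIBERSORT
default — is deliberately omitted, the standard practice for RNA-seq
inputs. The permutation p-value of the original algorithm is not
implemented: only the inferred proportions are consumed downstream.
The solver is exact (libsvm; tolerance 1e-4, iteration cap 10^6 with a
surfaced error), so the stage is deterministic.

## Survival statistics

Median splits label a sample H when its value strictly exceeds the median,
ties going to L — the rule is arbitrary but fixed, for determinism.
Kaplan–Meier curves, the k-group log-rank (Mantel–Cox) chi-square and Cox
partial-likelihood fits (Efron tie handling) are delegated to `lifelines`,
and Benjamini–Hochberg adjustment to `statsmodels`; the test suite checks
each against an independent brute-force implementation of the defining
formulas (product-limit recursion, observed-vs-expected hypergeometric
table, step-up minimum, Newton–Raphson on the partial likelihood) to 1e-6
or better. The BH family is whatever set of tests one pipeline invocation
produces, and is recorded alongside the q-values. Gene-vs-fraction
correlation defaults to Pearson on log1p-transformed expression (Spearman
optional); the choice is stored in the output metadata, and zero-variance
features yield an explicit "undefined" marker rather than an error.

## Simulation benchmark

One benchmark *run* plants a survival association in a single cell type:

1. survival times are drawn with replacement from a clinical pool
   (synthetic by default: exponential, scale 1000 days, 70% event rate,
   400 records — a plausible lower-grade-glioma-like progression-free
   survival profile);
2. per sample $i$, Dirichlet mean $m_i$ satisfies
   $\operatorname{logit} m_i[\text{var}] = \operatorname{logit}(1/K) + S z_i$
   with $z_i$ the standardized time; the other $K{-}1$ types share the
   remaining mass equally; proportions are drawn from
   $\mathrm{Dirichlet}(c\, m_i)$ with total concentration $c = 100$
   (per-type sd ≈ 0.03 around a mean of 0.125 — moderate biological
   spread). A survival-proportion slope needs a scale to be meaningful; placing it on
   the logit of the Dirichlet mean keeps proportions in (0,1) for any S
   and makes S unit-free;
3. mixtures are composed per sample from one uniformly drawn reference
   replicate per type (CPM scale), optionally blended with a fraction P of
   a foreign profile absent from the signature;
4. a seeded random half of the samples is censored at half its survival
   time; the rest are events;
5. mixtures are TMM/CPM-scaled, deconvolved, and the logit-transformed
   estimated fractions (offset: half the smallest nonzero fraction,
   floor 1e-6) enter a multiple Cox regression;
6. pooling runs (the variable type cycles round-robin, 63 runs per
   condition), scores $1 - p$ against the planted labels yield the ROC and
   its AUC. A fixed α would give a single operating point; sweeping the
   threshold over pooled p-values traces the full curve and contains the
   α = 0.05 call as one point.

Seeds fan out per run from the condition seed via `SeedSequence`, so every
condition is exactly reproducible and conditions compared at the same seed
are paired.

**A finding worth recording:** feeding the *true* simulated proportions to
the Cox stage ("oracle mode") does not outperform the deconvolved
estimates — at S = 1, N = 250 we measure oracle AUC ≈ 0.87 vs ≈ 0.92
estimated, and at S = 0.6 the oracle is near chance. Exact proportions lie
on the simplex, so each logit covariate is a smooth function of the other
K−1; the joint Wald tests then have almost no unique variance to work
with. Deconvolution noise breaks this compositional degeneracy. The
intuition that estimation can only lose information is wrong here, and the
benchmark's AUC should be read as a property of the whole
composition-plus-regression chain, not of deconvolution accuracy alone.

## Synthetic data: what it does and does not emulate

The generator plants, per leaf type, 10 disjoint marker genes at 8× a
shared baseline of 50 expected counts, NB dispersion 0.1, 10 replicates
per type, log-uniform library-size factors in [0.5, 2] (exercising the
TMM normalizer), over 400 genes. These defaults are the conditions under
which all quantitative claims in the test suite hold. Missingness (the
incomplete-data case) is injected as explicit (type, gene) flags rather
than by deleting matrix entries.

Not emulated: read-level data, batch effects between source studies,
gene–gene correlation, zero inflation, and realistic marker effect-size
distributions (real markers are not uniformly 8× elevated). Passing tests
therefore demonstrate that the machinery is correct and well-calibrated
under its own assumptions, not that the signature would achieve the same
accuracy on real tumor cohorts.

## Numerical choices and degenerate inputs

- TMM: reference sample is the library whose log size is closest to the
  mean log size; 30%/5% two-sided trims on M/A over doubly-expressed
  genes; precision weights from the delta-method variance; factors
  normalized to geometric mean 1. All-zero samples are a named error;
  samples with no usable genes fall back to factor 1.
- Grid quadrature: 241 points, ±8 sd — wide enough that truncation error
  is far below the reported quantile resolution.
- Cox: near-collinear covariates trigger a flagged ridge refit
  (penalizer 0.1) instead of a silent failure; Newton exits tightened to
  solver precision so fits agree with an independent implementation to
  1e-6.
- PCA components are sign-fixed (largest-magnitude loading positive) for
  reproducible outputs; t-SNE/UMAP are deliberately out of scope.
- Degenerate median splits (constant factor), empty strata, all-censored
  Cox inputs, constant mixtures and insufficient gene overlap all raise
  informative errors naming the offending object.

## Problem sizes

Test-suite and acceptance runs use the defaults above: 8 cell types ×
400 genes × 80 replicates for signature derivation, N = 250 samples and
63 runs per benchmark condition, 200 simulations for the Cox null
calibration and 500 (type, gene) pairs for interval coverage. These sizes
were chosen so that every statistical check operates in the regime its
asymptotics assume while the complete pipeline remains runnable on a
laptop-class single core in minutes.
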