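# sigdecon

Cell-type transcriptional signatures from heterogeneous reference RNA-seq,
signature-based bulk deconvolution, survival stratification, and a
survival-coupled simulation benchmark.

## The problem

Tumor bulk RNA-seq mixes malignant cells with immune and stromal
infiltrate. To ask whether the abundance of a particular immune phenotype
(say, an activated NK-cell state) predicts patient outcome, one needs:
(i) a *signature matrix* — marker genes × cell types — derived from
reference transcriptomes of purified cell populations; (ii) a
*deconvolution* step estimating per-sample cell-type fractions from the
signature; (iii) *survival statistics* relating fractions to
progression-free survival; and (iv) a *benchmark* establishing that the
chain can detect a known, planted association. `sigdecon` implements all
four for researchers building and validating such pipelines.

## The models in brief

- **Abundance**: counts are negative-binomial,
  `y ~ NB(mu * s_j, phi_g)` with `Var = m + phi m^2`, fitted per
  (cell type, gene) on a TMM-normalized CPM scale with a gene-level
  log-normal prior shared across types — so incomplete data (pairs with
  few or zero replicates) degrade gracefully to wide credible intervals.
  Posterior means and 95% credible intervals come from exact 1-D grid
  quadrature.
- **Markers**: for every ordered pair of sibling cell types in a 3-level
  differentiation hierarchy, genes are ranked by interval separation
  `ci_low(a) - ci_high(b)` and the top 5/10/20 (levels 1/2/3) positive-gap
  genes are kept; the union is the signature gene list.
- **Deconvolution**: CIBERSORT-style linear ν-SVR
  (ν ∈ {0.25, 0.5, 0.75}, best reconstruction kept) on z-scored
  signature/mixture, negative weights clipped, renormalized to a simplex.
- **Survival**: median-split (ties → L) Kaplan–Meier curves, log-rank
  tests, Benjamini–Hochberg adjustment, two-factor (L/L, L/H, H/L, H/H)
  strata, gene-vs-fraction correlations.
- **Benchmark**: Dirichlet proportions whose variable-type mean follows
  `logit(1/K) + S·z` in standardized survival time; replicate-sampled
  mixtures with optional foreign-cell contamination P; half-sample
  censoring; multiple Cox on logit fractions; pooled ROC/AUC against the
  planted variable type (63 runs per condition).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import sigdecon as sd

hierarchy = sd.load_default_hierarchy()          # 8 leaves, 3 levels
ref = sd.generate_reference(sd.GenerativeSpec(seed=7), hierarchy)
posterior = sd.fit_abundance_model(ref, nodes="all")
markers = sd.select_markers(posterior, hierarchy)
signature = sd.build_signature_matrix(posterior, markers, hierarchy)
print(len(markers.genes), signature.shape)
```

prints `71 (71, 8)`: 71 marker genes were selected for the 8 cell types
(planted markers of the deep NK/T states are recovered in full; broad
level-1 types contribute their top-5 per pairwise comparison). Deconvolving
100 simulated mixtures with this signature
(`analysis/03_deconvolve_cohort.py`) recovers true fractions with
per-type Pearson r ≥ 0.975 and mean absolute error 0.016.

The `analysis/` drivers run the complete study end to end, writing tables
under `results/`:

| script | what it does |
|---|---|
| `01_simulate_inputs.py` | reference counts/labels/hierarchy, clinical pool, foreign profile |
| `02_fit_signature.py` | NB posterior, marker provenance, signature matrix |
| `03_deconvolve_cohort.py` | mixture cohort + recovery table |
| `04_survival_analysis.py` | KM/log-rank/BH per cell type, two-factor strata, correlations |
| `05_benchmark_power.py` | AUC over a (S, P) grid, 63 runs per condition (~10 min) |
| `06_validate_signature.py` | marker-restricted PCA + silhouette per hierarchy scope |

Run them in order from `analysis/` (e.g. `python 01_simulate_inputs.py`).

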