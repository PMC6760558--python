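# Methods

This note documents the statistical procedures, the synthetic study design,
the numerical conventions, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Analysis model

**ETS subtyping.** Tumors are called ETS+ when any marker gene (ERG, ETV1,
ETV4, ETV5, FLI1) exceeds a per-marker cutpoint computed over tumor samples
as `median + k·MAD` with k = 3. The MAD is normal-consistent (scaled by
1.4826), the standard outlier-calling convention; with an unscaled MAD the
same k would imply a far more permissive cut. Fusion-driven marker
overexpression is strongly bimodal, which is what makes outlier calling
work: the high mode must clear a cutpoint whose MAD is inflated by the
carriers themselves (up to ~20% of tumors for ERG). When a marker's MAD is
zero the rule falls back to a fixed cutpoint if one is supplied, otherwise
it refuses to call. Externally provided ETS labels always take precedence
over calling unless the caller explicitly overrides — cohorts of this kind
usually arrive with validated subtype labels.

**Differential expression.** Per gene, a two-tailed Mann–Whitney U test.
Exact enumeration is used when the pooled sample is ≤ 12 and untied;
otherwise the tie-corrected normal approximation with continuity correction
(both via `scipy.stats.mannwhitneyu`). Multiplicity is handled with
Benjamini–Hochberg step-up q-values (statsmodels). A gene is called
differential only under the dual criterion q < 0.05 **and** |log2 FC| above
the platform floor: 0.585 on the RNA-seq scale, 0.05 on the compressed
microarray scale. Fold change is the difference of group means of log2
values — the conventional mean-based definition behind such thresholds.
The cross-cohort intersection additionally requires the **same direction**
in both cohorts; the direction split of the overlap is then a partition,
which is what makes the reported up-in-ETS+ / up-in-ETS− counts sum to the
overlap size.

**AR-target annotation.** Distance is measured from the TSS to the nearest
edge of a binding site (0 when the site covers the TSS; coordinates 0-based
half-open throughout, with the gap to a site entirely left of the TSS
measured to its last covered base). The default window is ±25 kb of the TSS
(symmetric). The literature convention for this rule is ambiguous between
"within 25 kb of the promoter" and "25 kb downstream of the site"; symmetric
is the more standard reading and is the default, and a strand-aware
`downstream_only` mode (site 3′ of the TSS) is provided. When several
ChIP-seq datasets are pooled, `min_sources` controls how many distinct
datasets must contribute a qualifying site (default 1 — pooling without an
intersection requirement).

**Subtractive categorization.** Each AR-target gene is tested per stratum
against adjacent normals with the same dual criterion. The direction pair
(ETS− vs normal, ETS+ vs normal) maps to: (up, ns) → ETS− Up, (dn, ns) →
ETS− Dn, (ns, up) → ETS+ Up, (ns, dn) → ETS+ Dn, (up, up) → both Up,
(ns, ns) → removed. The remaining patterns — (dn, dn), (up, dn), (dn, up) —
are reported as an explicit `other_pattern` bucket rather than silently
dropped. Removal defaults to "ns in both strata"; a pooled-tumors-vs-normal
removal test is available as an option, since either reading of "not
different between tumors and normal" is defensible.

**Over-representation.** The up-lists are fixed, unranked gene lists, for
which the well-posed enrichment computation is the upper-tail hypergeometric
test against a background universe, BH-adjusted across sets. The universe
defaults to all genes tested for DE in the relevant cohort. Running-sum
(weighted-KS) enrichment is deliberately out of scope: it is defined for
ranked profiles, not for a discrete list.

**Signature scoring.** The gene-set submatrix is gene-centered (covariance
PCA — genes are *not* variance-standardized, since standardization would
change the explained-variance fraction; correlation PCA is exposed as a
flag) and factored by SVD. The per-sample score is the projection on the
first right-singular direction, sign-oriented to correlate positively with
the set's mean centered expression. Model quality is PC1's explained
variance `s₁²/Σsᵢ²` and the ratio `s₁²/s₂²`. Calibration draws `n_null`
random gene sets of the same size uniformly from all genes in the matrix
(expressed-gene filtering is the caller's responsibility) and reports the
percentile of the observed statistics as the fraction of null draws
*strictly* below — ties break toward the conservative side. The default
`n_null` = 10,000 resolves percentiles to 0.01; studies at desk scale in
this package use 1,000–2,000.

**Survival.** Median split with ties to the low group (documented, since
with ties "high = strictly above the median" is the only unambiguous rule);
Kaplan–Meier product-limit curves and the standard two-group log-rank test
(lifelines), with events processed before censorings at tied times.

## The synthetic study

The generator plants everything the analysis is supposed to find:

* **Design**: two cohorts sharing one gene space — an RNA-seq-like cohort
  and a microarray-like cohort — each with ETS+ tumors, ETS− tumors and
  adjacent normals (defaults 50/50/30 per cohort), 2,000 genes.
* **Baseline**: per-gene log2 baseline ~ N(8, 1.5); i.i.d. within-group
  noise SD 0.6 (RNA-seq scale).
* **Platform distortion**: the microarray cohort applies a per-gene affine
  compression (slope ~ N(0.25, 0.05), intercept ~ N(5, 0.5)) plus noise
  SD 0.25, so fold changes shrink by ≈ 4× — which is exactly why the
  microarray fold-change floor is 0.05 rather than 0.585 — and the
  cross-platform fold-change correlation is high but below 1.
* **Categories**: `n_per_category` genes per category shifted by
  ±`effect_size` (default 1.5 log2) in the designated stratum relative to
  normal; both-up genes rise in both strata but by (e, 2e) so they remain
  differential *between* strata too.
* **Markers**: each ETS+ tumor overexpresses one driver (ERG 40%, ETV1 25%,
  ETV4 20%, FLI1 15%) by `marker_shift` = 7 log2 units. The shift is
  deliberately independent of `effect_size`: fusion overexpression is
  bimodal and much larger than typical DE effects, and MAD-outlier calling
  needs the carrier mode to clear a contamination-inflated cutpoint.
* **Pathway coherence**: the ETS+ Up block carries a WNT-like per-tumor
  latent activity and the ETS− Up block a metabolic-like one (loading 0.4).
  The loading was derived from the variance arithmetic so that planted
  genes still pass the DE stage reliably at the design boundary (effect
  1.0, 30/group): the latent factor adds variance to exactly the genes it
  makes coherent, and a loading of 1 would cost ~20% of DE power there.
* **Geometry**: one pseudo-chromosome, genes every 120 kb, one 300-bp AR
  site placed 0.5–20 kb 3′ of the TSS for exactly the AR-target genes
  (default 30% of genes, always including planted and decoy genes). The
  spacing guarantees non-targets are > 50 kb from every site, so the
  annotation stage has an exact recoverable truth in both window modes.
* **Decoys**: AR-bound genes with tumor ≡ normal distributions — the set
  the subtractive step must remove. Because such genes cannot differ
  between the strata either, they can never enter the cross-cohort overlap;
  decoy-removal performance is therefore assessed by running the category
  stage on the full AR-target list, while the pipeline's default funnel
  categorizes only overlap ∩ targets.
* **Survival**: BCR times are exponential with log-hazard =
  (per-stratum coefficient) × (WNT-like latent activity), baseline median
  24 months, independent uniform censoring on 6–48 months (short-follow-up
  regime). Defaults plant the hazard in ETS+ only (coefficient 1) and none
  in ETS− (0), so the analysis should find BCR stratification in ETS+ and a
  null in ETS−.
* **Reproducibility**: one RNG stream per artifact, all spawned from the
  master seed — adding an output never perturbs the others, and a fixed
  seed reproduces every file bitwise.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: count-level RNA-seq noise and library-size
effects, batch structure, tumor-purity dilution, correlated co-expression
beyond the two planted factors, gene-length or GC biases, non-exponential
hazards, and informative censoring. Results on synthetic cohorts certify
the *pipeline logic and calibration*, not biological discovery power.

## Numerical conventions and problem sizes

* BH q-values are clipped at 1 and returned in input order; q ≥ p always.
* Mann–Whitney p-values are clipped at 1 (continuity correction can push
  the two-sided approximation slightly above 1 at dead-center statistics).
* The PC1/PC2 ratio is +inf for a numerically rank-1 submatrix.
* Genes on chromosomes with no binding sites are non-targets with an
  undefined (NaN) distance, not errors.
* A zero-variance signature submatrix and an all-equal score vector are
  refused rather than scored.
* Null-calibration percentiles are computed against a shared null that is
  an order of magnitude larger than the number of scored draws (2,000 vs
  200 in the calibration study): the shared null's empirical-CDF error
  shifts all percentiles coherently, and with a small null this makes a
  KS uniformity check anti-conservative. For the same reason the
  calibration matrix uses a gene pool (3,000) large enough that random
  15-gene sets rarely share genes — set overlap correlates the draws and
  likewise inflates the KS statistic.
* Monte Carlo sizes in the shipped studies: 20 replicates × 1,000 genes for
  FDR control under the null; 1,000 replicates for log-rank size (the
  ±0.02 tolerance needs Monte Carlo error well inside it) and 200 for
  power; 1,000 random sets for planted-signature percentiles; 10 random
  geometries for annotation exactness. These sizes keep the full
  verification run at a few minutes on one CPU while leaving each check's
  sampling error small against its tolerance.

## Known limitations

* The subtyping rule assumes marker bimodality; on a cohort where a marker
  is continuously distributed, MAD-outlier calling will split its upper
  tail arbitrarily. Fixed cutpoints should be preferred when the assay has
  validated thresholds.
* The two platforms are assumed to share one gene-identifier namespace;
  cross-platform ID mapping is the caller's responsibility.
* Fold-change floors are conventions, not estimates; on a platform with a
  different dynamic range they must be re-specified.
* The five-way categorization inherits the dual criterion's discreteness: a
  gene hovering at q ≈ 0.05 in one stratum can flip category between
  nearby datasets. The `other_pattern` bucket makes such flips visible
  rather than silent.
* ORA treats genes as exchangeable; set-size-dependent biases (e.g., longer
  genes being easier to call differential) are not modeled.
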