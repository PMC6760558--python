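# etsar

Discovery of ETS-status-dependent androgen-receptor (AR) transcriptional
programs in prostate cancer expression cohorts.

## The problem

Roughly 70% of prostate tumors carry a translocation that places an ETS-family
transcription factor (*ERG*, *ETV1/4/5*, *FLI1*) under the androgen-responsive
*TMPRSS2* promoter ("ETS+" tumors). ETS− tumors also express AR and grow in an
androgen-dependent way, yet the AR target repertoire they use is different.
`etsar` implements the complete analysis chain for characterizing that
difference from bulk expression cohorts:

1. **ETS subtyping** — a tumor is ETS+ when any ETS marker gene is an
   expression outlier (per-marker cutpoint `median + k·MAD`, k = 3, or fixed
   cutpoints supplied externally).
2. **Differential expression** — per gene, a two-tailed Mann–Whitney U test
   between ETS+ and ETS− tumors, Benjamini–Hochberg FDR across genes, and a
   dual significance rule: `q < 0.05` **and** `|log2 FC|` above a
   platform-specific floor (0.585 for RNA-seq-scale data, 0.05 for
   compressed-scale microarray data).
3. **Cross-cohort concordance** — the overlap of two cohorts' significant
   genes with the *same* direction, plus the Pearson correlation of their
   fold changes.
4. **Direct AR-target annotation** — a gene is a direct AR target when an AR
   ChIP-seq binding site lies within 25 kb of its TSS (symmetric by default;
   a strand-aware downstream-only mode is provided).
5. **Subtractive categorization** — each AR-target gene is tested per ETS
   stratum against adjacent-normal tissue; genes not different from normal in
   either stratum are *removed*, survivors fall into five categories:
   ETS− Up, ETS− Dn, ETS+ Up, ETS+ Dn, both Up.
6. **Over-representation analysis** — upper-tail hypergeometric test of the
   stratum-specific up-lists against GMT gene-set collections.
7. **PC1 signature scoring** — a pathway is summarized per sample by the
   first principal component of its (gene-centered) expression submatrix;
   the model's PC1 explained variance and PC1/PC2 ratio are calibrated
   against the empirical null of random same-size gene sets.
8. **Biochemical recurrence (BCR)** — samples are median-split on a
   signature score; Kaplan–Meier curves and a two-group log-rank test
   compare high vs low within an ETS stratum.

Real cohorts of this design are controlled-access, so the package ships a
first-class synthetic cohort generator (`etsar.simulate`) that emulates the
full study — two ETS strata with stratum-specific AR-target shifts, two
platforms with different noise and scale, binding sites placed by
construction, planted coherent pathway signatures, and BCR times whose
hazard follows a planted signature — with a recoverable ground truth for
every stage.

## Worked example

Run the whole funnel on a synthetic study with 26 planted genes per category,
one extra both-up gene and 29 AR-bound decoys (131 genes with a true
category):

```bash
cat > study.yaml <<'YAML'
simulation:
  n_per_category: 26
  n_extra_both_up: 1
  n_decoys: 29
  seed: 7
n_null: 1000
seed: 7
YAML
etsar run-all --config study.yaml --out results/
```

The printed summary (abridged):

```json
{
  "n_genes": 2000,
  "de_rnaseq":     {"n_significant": 132, "pct_significant": 6.6},
  "de_microarray": {"n_significant": 134, "pct_significant": 6.7},
  "overlap": {"n_overlap": 130, "n_up_ets_pos": 79, "n_up_ets_neg": 51,
              "fc_correlation": 0.9625},
  "n_ar_targets": 600,
  "n_categorized": 130,
  "category_counts": {"ets_neg_up": 25, "ets_neg_dn": 26, "ets_pos_up": 26,
                      "ets_pos_dn": 26, "both_up": 27, "removed": 0,
                      "other_pattern": 0},
  "enrichment_top": {"ets_pos": {"set": "wnt_like"},
                     "ets_neg": {"set": "metabolic_like"}},
  "signatures": {"wnt_like": {"pc1_var_pct": 67.88, "pc_ratio": 26.35,
                              "null_pc1_percentile": 100.0}},
  "logrank": [{"set_name": "wnt_like", "stratum": "ets_pos",
               "chi2": 15.44, "p": 8.5e-05, "n_high": 25, "n_low": 25}, ...]
}
```

Reading it: 6.6% / 6.7% of genes are differential between the ETS strata per
cohort; 130 genes replicate with concordant direction across the two
platforms (fold-change r = 0.96); after the AR-target filter and the
subtractive step, 130 of the 131 planted genes land in the five categories.
The planted WNT-like pathway is the top enriched set in the ETS+ up-list,
its PC1 explains 68% of variance — better than 100% of 1000 random gene
models — and its median-split score stratifies biochemical recurrence in the
ETS+ stratum (log-rank p = 8.5e-05) but not in ETS−, where the planted
hazard coefficient is zero.

Every stage is also a library call (`run_de`, `intersect_cohorts`,
`annotate_targets`, `categorize`, `run_ora`, `score_signature`,
`bcr_by_median_score`) and a CLI subcommand (`etsar simulate / subtype / de /
intersect / artargets / categorize / ora / score / bcr`); run
`etsar --help` for the formats each one reads and writes.

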