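"""End-to-end orchestration of the ETS-dependent AR-program analysis.

The chain mirrors the discovery funnel: ETS subtyping -> differential
expression in both cohorts -> direction-concordant intersection ->
AR-target filter -> subtractive categorization against adjacent normal ->
over-representation of the up-lists -> PC1 signature scoring with a
random-gene null -> median-split biochemical-recurrence analysis per ETS
stratum.  Every threshold, seed and stage count lands in a manifest and a
summary so "what was run" is never implicit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as _io
from .artargets import AnnotationParams, annotate_targets
from .categories import categorize, category_counts, normal_median_normalize
from .de import DEConfig, intersect_cohorts, run_de
from .enrichment import run_ora
from .scoring import score_signature
from .simulate import (
    SimulatedCohort,
    SimulationConfig,
    config_to_dict,
    simulate_cohort,
    truth_gene_sets,
)
from .subtyping import SubtypingRule, apply_subtyping
from .survival import bcr_by_median_score

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One config object covering every stage.

    Either ``simulation`` (generate the study) or ``data_dir`` (read a
    directory previously written by :meth:`SimulatedCohort.save`) supplies
    the inputs.
    """

    simulation: SimulationConfig | None = None
    data_dir: str | None = None
    de_rnaseq: DEConfig = field(default_factory=DEConfig)
    de_microarray: DEConfig = field(default_factory=DEConfig)
    subtyping: SubtypingRule = field(default_factory=SubtypingRule)
    resubtype: bool = False          # override provided ETS labels with calls
    annotation_params: AnnotationParams = field(default_factory=AnnotationParams)
    categorize_scope: str = "funnel"  # 'funnel' (overlap & targets) or 'all_targets'
    removal: str = "per_stratum"
    gmt_path: str | None = None       # enrichment collection; default from truth
    signature_sets: list[str] = field(default_factory=lambda: ["wnt_like", "metabolic_like"])
    n_null: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.data_dir is None):
            raise ValueError("exactly one of simulation / data_dir must be set")
        if self.categorize_scope not in ("funnel", "all_targets"):
            raise ValueError(f"unknown categorize_scope {self.categorize_scope!r}")


def load_cohort(data_dir) -> SimulatedCohort:
    """Read a cohort directory written by :meth:`SimulatedCohort.save`."""
    d = Path(data_dir)
    truth_path = d / "ground_truth.tsv"
    truth = None
    if truth_path.exists():
        # the 'null' category label must not parse as NaN
        truth = pd.read_csv(truth_path, sep="\t", index_col=0, keep_default_na=False)
        for col in ("is_ar_target", "is_decoy", "is_marker"):
            if truth[col].dtype == object:
                truth[col] = truth[col].map({"True": True, "False": False})
    return SimulatedCohort(
        expr_rnaseq=_io.read_expression(d / "expr_rnaseq.tsv", "rnaseq"),
        expr_microarray=_io.read_expression(d / "expr_microarray.tsv", "microarray"),
        annotation=_io.read_annotation(d / "annotation.tsv"),
        gene_models=_io.read_gene_models(d / "gene_models.tsv"),
        binding_sites=_io.read_bed(d / "ar_sites.bed", source="ar_sites"),
        survival=_io.read_survival(d / "survival.tsv"),
        truth=truth,
        config=None,
    )


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Run every stage, write result tables + manifest, return the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    current = stage("inputs")
    try:
        if config.simulation is not None:
            cohort = simulate_cohort(config.simulation)
        else:
            cohort = load_cohort(config.data_dir)

        current = stage("subtyping")
        annotation = apply_subtyping(
            cohort.expr_rnaseq, cohort.annotation, config.subtyping,
            override=config.resubtype,
        )
        annotation = apply_subtyping(
            cohort.expr_microarray, annotation, config.subtyping,
            override=config.resubtype,
        )

        current = stage("differential_expression")
        de_a = run_de(cohort.expr_rnaseq, annotation, config.de_rnaseq)
        de_b = run_de(cohort.expr_microarray, annotation, config.de_microarray)
        de_a.to_csv(out / "de_rnaseq.tsv", sep="\t", index=False)
        de_b.to_csv(out / "de_microarray.tsv", sep="\t", index=False)

        current = stage("intersection")
        overlap = intersect_cohorts(de_a, de_b)
        overlap.table.to_csv(out / "overlap.tsv", sep="\t", index=False)

        current = stage("ar_target_annotation")
        targets = annotate_targets(cohort.gene_models, cohort.binding_sites,
                                   config.annotation_params)
        targets.to_csv(out / "targets.tsv", sep="\t")
        target_genes = targets.index[targets["is_target"]].tolist()

        current = stage("categorization")
        if config.categorize_scope == "funnel":
            cat_genes = [g for g in overlap.overlap_genes if g in set(target_genes)]
        else:
            cat_genes = target_genes
        categories = categorize(
            cohort.expr_rnaseq, annotation, cat_genes,
            config.de_rnaseq, removal=config.removal,
        )
        categories.to_csv(out / "categories.tsv", sep="\t")
        counts = category_counts(categories)
        normalized = normal_median_normalize(cohort.expr_rnaseq, annotation)
        kept = categories.index[categories["category"] != "removed"]
        _io.write_expression(normalized.subset_genes(kept), out / "heatmap_matrix.tsv")

        current = stage("enrichment")
        if config.gmt_path is not None:
            collection = _io.read_gmt(config.gmt_path)
        elif cohort.truth is not None:
            collection = truth_gene_sets(cohort.truth, seed=config.seed)
        else:
            collection = None
        enrichment_top = {}
        if collection is not None:
            universe = cohort.expr_rnaseq.gene_ids
            for direction, tag in (("up_in_ets_pos", "ets_pos"), ("up_in_ets_neg", "ets_neg")):
                up = [g for g in overlap.overlap_genes
                      if overlap.table.set_index("gene_id").loc[g, "direction"] == direction]
                if len(up) == 0:
                    continue
                ora = run_ora(up, universe, collection)
                ora.to_csv(out / f"enrichment_up_{tag}.tsv", sep="\t", index=False)
                enrichment_top[tag] = {
                    "set": str(ora.iloc[0]["set_name"]), "q": float(ora.iloc[0]["q"])
                }

        current = stage("signature_scoring")
        tumor_ids = annotation.loc[
            (annotation["tissue"] == "tumor") & (annotation["cohort"] == "cohort_a"),
            "sample_id",
        ].tolist()
        tumor_expr = cohort.expr_rnaseq.subset_samples(tumor_ids)
        score_results = {}
        if collection is not None:
            for set_name in config.signature_sets:
                if set_name not in collection.sets:
                    continue
                sig = score_signature(
                    tumor_expr, set_name, collection.sets[set_name],
                    n_null=config.n_null, seed=config.seed,
                )
                sig.sample_scores.rename("pc1_score").to_frame().to_csv(
                    out / f"scores_{set_name}.tsv", sep="\t", index_label="sample_id"
                )
                score_results[set_name] = sig

        current = stage("survival")
        logrank_rows = []
        for set_name, sig in score_results.items():
            for stratum in ("ets_pos", "ets_neg"):
                ids = annotation.loc[
                    (annotation["ets_status"] == stratum)
                    & annotation["sample_id"].isin(cohort.survival["sample_id"]),
                    "sample_id",
                ]
                surv = cohort.survival[cohort.survival["sample_id"].isin(ids)]
                scores = sig.sample_scores[sig.sample_scores.index.isin(ids)]
                if len(scores) < 4 or surv["event"].sum() == 0:
                    continue
                _, curves, lr = bcr_by_median_score(scores, surv)
                for lab, curve in curves.items():
                    curve.to_frame().assign(group=lab).to_csv(
                        out / f"km_{set_name}_{stratum}_{lab}.tsv", sep="\t", index=False
                    )
                logrank_rows.append((set_name, stratum, lr.chi2, lr.p, *lr.n_per_group))
        logrank = pd.DataFrame(
            logrank_rows,
            columns=["set_name", "stratum", "chi2", "p", "n_high", "n_low"],
        )
        logrank.to_csv(out / "logrank.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    summary = {
        "n_genes": len(cohort.expr_rnaseq.gene_ids),
        "de_rnaseq": {
            "n_significant": int((de_a["direction"] != "ns").sum()),
            "pct_significant": round(
                100.0 * (de_a["direction"] != "ns").mean(), 3
            ),
        },
        "de_microarray": {
            "n_significant": int((de_b["direction"] != "ns").sum()),
            "pct_significant": round(
                100.0 * (de_b["direction"] != "ns").mean(), 3
            ),
        },
        "overlap": {
            "n_overlap": overlap.n_overlap,
            "n_up_ets_pos": overlap.n_up_ets_pos,
            "n_up_ets_neg": overlap.n_up_ets_neg,
            "fc_correlation": round(overlap.fc_correlation, 4)
            if overlap.n_overlap >= 2 else None,
        },
        "n_ar_targets": len(target_genes),
        "n_categorization_input": len(cat_genes),
        "category_counts": {k: int(v) for k, v in counts.items()},
        "n_categorized": int(counts.drop("removed").sum()),
        "enrichment_top": enrichment_top,
        "signatures": {
            name: {
                "pc1_var_pct": round(100.0 * sig.pc1_var_frac, 2),
                "pc_ratio": round(sig.pc_ratio, 3),
                "null_pc1_percentile": sig.null_pc1_percentile,
                "null_ratio_percentile": sig.null_ratio_percentile,
            }
            for name, sig in score_results.items()
        },
        "logrank": logrank.to_dict(orient="records"),
    }

    manifest = {
        "package": "etsar 0.1.0",
        "seed": config.seed,
        "simulation": config_to_dict(config.simulation) if config.simulation else None,
        "data_dir": config.data_dir,
        "de_rnaseq": {"q_max": config.de_rnaseq.q_max,
                      "fc_min": config.de_rnaseq.resolve_fc_min("rnaseq")},
        "de_microarray": {"q_max": config.de_microarray.q_max,
                          "fc_min": config.de_microarray.resolve_fc_min("microarray")},
        "subtyping": {"markers": config.subtyping.marker_genes,
                      "method": config.subtyping.threshold_method,
                      "k": config.subtyping.k, "resubtype": config.resubtype},
        "annotation": {"window_bp": config.annotation_params.window_bp,
                       "mode": config.annotation_params.mode,
                       "min_sources": config.annotation_params.min_sources},
        "categorize_scope": config.categorize_scope,
        "removal": config.removal,
        "survival": {"split": "median, ties to low"},
        "n_null": config.n_null,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
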