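"""Synthetic two-platform prostate-cancer cohort with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* two tumor strata (ETS+ / ETS-) plus adjacent-normal tissue, profiled on
  two emulated platforms (an RNA-seq-like cohort and a microarray-like
  cohort with compressed dynamic range), sharing one gene id space;
* planted AR-target genes shifted by ``effect_size`` log2 units in a
  designated stratum relative to normal, one block per each of the five
  ETS-dependent categories (ETS- up/down, ETS+ up/down, both up);
* ETS+ tumors overexpressing one ETS-family marker gene each (ERG, ETV1,
  ETV4 or FLI1) by ``marker_shift`` log2 units, which drives subtyping;
* AR binding sites placed within 25 kb downstream of the TSS for exactly
  the AR-target genes, on a single pseudo-chromosome with genes spaced
  120 kb apart so windows never collide;
* two planted coherent pathway signatures (a non-canonical-WNT-like factor
  on the ETS+ Up block, a metabolic-like factor on the ETS- Up block)
  realised as a per-tumor latent activity with configurable loading;
* biochemical-recurrence times drawn from an exponential model whose
  log-hazard is a per-stratum coefficient times the WNT-like latent
  activity, with uniform censoring.

One RNG stream per output artifact, all spawned from the master seed, so
adding outputs never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GeneSetCollection,
    validate_annotation,
    validate_binding_sites,
    validate_gene_models,
    validate_survival,
)

CATEGORIES = ("ets_neg_up", "ets_neg_dn", "ets_pos_up", "ets_pos_dn", "both_up")
MARKER_GENES = ("ERG", "ETV1", "ETV4", "ETV5", "FLI1")

#: driver subtype frequencies among ETS+ tumors (ETV5 fusions are too rare
#: to plant) and label frequencies among ETS- tumors
_POS_SUBTYPE_P = {"ERG": 0.40, "ETV1": 0.25, "ETV4": 0.20, "FLI1": 0.15}
_NEG_SUBTYPE_P = {"SPOP": 0.35, "FOXA1": 0.20, "IDH1": 0.10, "other": 0.35}

_GENE_SPACING = 120_000
_TSS_OFFSET = 60_000
_SITE_WIDTH = 300
_SITE_MIN_GAP = 500
_SITE_MAX_GAP = 20_000
_SOURCES = ("chipseq_a", "chipseq_b", "chipseq_c")

_STREAMS = (
    "baseline", "assignment", "geometry", "subtypes", "latent",
    "expr_rnaseq", "expr_microarray", "platform", "survival", "decoys",
)


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`simulate_cohort`.

    Defaults encode a desk-scale two-cohort study: 50/50 tumors per ETS
    stratum plus 30 adjacent normals per cohort, 2000 genes, 26 planted
    genes per category at a 1.5 log2 effect.
    """

    n_tumor_ets_pos: int = 50
    n_tumor_ets_neg: int = 50
    n_normal: int = 30
    n_genes: int = 2000
    n_per_category: int = 26
    n_extra_both_up: int = 0
    n_decoys: int = 0
    effect_size: float = 1.5
    noise_sd_rnaseq: float = 0.6
    noise_sd_microarray: float = 0.25
    frac_ar_bound: float = 0.3
    marker_shift: float = 7.0
    platform_slope: float = 0.25
    platform_slope_jitter: float = 0.05
    signature_loading: float = 0.4
    hazard_coef_ets_pos: float = 1.0
    hazard_coef_ets_neg: float = 0.0
    median_followup_months: float = 24.0
    censor_months: tuple[float, float] = (6.0, 48.0)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        n_planted = 5 * self.n_per_category + self.n_extra_both_up
        if any(n < 2 for n in (self.n_tumor_ets_pos, self.n_tumor_ets_neg, self.n_normal)):
            raise ValueError("all sample-group counts must be >= 2")
        if self.n_genes < 1 or self.n_per_category < 0 or self.n_decoys < 0:
            raise ValueError("gene counts must be non-negative (n_genes >= 1)")
        if 5 * self.n_per_category > self.n_genes:
            raise ValueError("5 * n_per_category must be <= n_genes")
        if n_planted + self.n_decoys + len(MARKER_GENES) > self.n_genes:
            raise ValueError("planted + decoy + marker genes exceed n_genes")
        if not (0.0 < self.frac_ar_bound < 1.0):
            raise ValueError("frac_ar_bound must lie in (0, 1)")
        n_bound = int(round(self.frac_ar_bound * self.n_genes))
        if n_bound < n_planted + self.n_decoys:
            raise ValueError(
                "frac_ar_bound leaves too few AR-bound genes for the planted "
                f"categories and decoys ({n_bound} < {n_planted + self.n_decoys})"
            )
        if self.effect_size < 0 or self.noise_sd_rnaseq <= 0 or self.noise_sd_microarray <= 0:
            raise ValueError("effect_size must be >= 0 and noise SDs > 0")
        return self


@dataclass
class SimulatedCohort:
    """All artifacts of one simulated study plus the planted ground truth."""

    expr_rnaseq: ExpressionMatrix
    expr_microarray: ExpressionMatrix
    annotation: pd.DataFrame
    gene_models: pd.DataFrame
    binding_sites: pd.DataFrame
    survival: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig
    latent: pd.DataFrame = field(repr=False, default=None)

    def save(self, out_dir) -> None:
        from pathlib import Path
        from . import io as _io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_expression(self.expr_rnaseq, out / "expr_rnaseq.tsv")
        _io.write_expression(self.expr_microarray, out / "expr_microarray.tsv")
        _io.write_annotation(self.annotation, out / "annotation.tsv")
        _io.write_gene_models(self.gene_models, out / "gene_models.tsv")
        _io.write_bed(self.binding_sites, out / "ar_sites.bed")
        _io.write_survival(self.survival, out / "survival.tsv")
        self.truth.to_csv(out / "ground_truth.tsv", sep="\t")


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full two-cohort study with recoverable ground truth."""
    config.validate()
    rngs = _spawn_rngs(config.seed)

    gene_ids = list(MARKER_GENES) + [f"G{i:05d}" for i in range(config.n_genes - len(MARKER_GENES))]
    n_genes = len(gene_ids)

    # --- planted category / AR-target assignment -------------------------
    non_marker_idx = rngs["assignment"].permutation(np.arange(len(MARKER_GENES), n_genes))
    category = np.array(["null"] * n_genes, dtype=object)
    cursor = 0
    for cat in CATEGORIES:
        take = config.n_per_category + (config.n_extra_both_up if cat == "both_up" else 0)
        category[non_marker_idx[cursor:cursor + take]] = cat
        cursor += take
    planted_mask = category != "null"

    is_target = planted_mask.copy()
    n_bound = int(round(config.frac_ar_bound * n_genes))
    extra = n_bound - int(is_target.sum())
    pool = non_marker_idx[cursor:]                      # nulls, shuffled
    is_target[pool[:extra]] = True

    truth = pd.DataFrame(
        {
            "category": category,
            "is_ar_target": is_target,
            "is_decoy": False,
            "is_marker": [g in MARKER_GENES for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # --- genome geometry and AR binding sites -----------------------------
    strands = rngs["geometry"].choice(["+", "-"], size=n_genes)
    tss = _TSS_OFFSET + np.arange(n_genes) * _GENE_SPACING
    gene_models = pd.DataFrame(
        {"gene_id": gene_ids, "chrom": "chr1", "tss": tss, "strand": strands}
    )
    binding_sites = _place_sites(gene_models, is_target, rngs["geometry"])

    # --- expression -------------------------------------------------------
    baseline = rngs["baseline"].normal(8.0, 1.5, size=n_genes)
    shift_neg = np.zeros(n_genes)
    shift_pos = np.zeros(n_genes)
    e = config.effect_size
    shift_neg[category == "ets_neg_up"] += e
    shift_neg[category == "ets_neg_dn"] -= e
    shift_pos[category == "ets_pos_up"] += e
    shift_pos[category == "ets_pos_dn"] -= e
    # both-up genes rise in both strata but by different amounts, so they
    # stay differential between the strata as well as against normal
    shift_neg[category == "both_up"] += e
    shift_pos[category == "both_up"] += 2 * e

    wnt_rows = np.flatnonzero(category == "ets_pos_up")
    met_rows = np.flatnonzero(category == "ets_neg_up")
    marker_row = {g: i for i, g in enumerate(gene_ids) if g in MARKER_GENES}

    frames, annot_rows, latent_rows = {}, [], []
    for cohort, prefix in (("cohort_a", "A"), ("cohort_b", "B")):
        groups = [
            ("ets_pos", f"{prefix}_TP", config.n_tumor_ets_pos),
            ("ets_neg", f"{prefix}_TN", config.n_tumor_ets_neg),
            ("normal", f"{prefix}_N", config.n_normal),
        ]
        cols, signal_cols = [], []
        for status, stem, count in groups:
            for i in range(count):
                sid = f"{stem}{i:03d}"
                cols.append(sid)
                col = baseline.copy()
                if status == "normal":
                    annot_rows.append((sid, cohort, "adjacent_normal", "unknown", "none"))
                else:
                    col = col + (shift_pos if status == "ets_pos" else shift_neg)
                    if status == "ets_pos":
                        subtype = rngs["subtypes"].choice(
                            list(_POS_SUBTYPE_P), p=list(_POS_SUBTYPE_P.values())
                        )
                        col[marker_row[subtype]] += config.marker_shift
                    else:
                        subtype = rngs["subtypes"].choice(
                            list(_NEG_SUBTYPE_P), p=list(_NEG_SUBTYPE_P.values())
                        )
                    a_wnt, a_met = rngs["latent"].normal(size=2)
                    col[wnt_rows] += config.signature_loading * a_wnt
                    col[met_rows] += config.signature_loading * a_met
                    annot_rows.append((sid, cohort, "tumor", status, subtype))
                    latent_rows.append((sid, cohort, status, a_wnt, a_met))
                signal_cols.append(col)
        frames[cohort] = (cols, np.column_stack(signal_cols))

    cols_a, signal_a = frames["cohort_a"]
    cols_b, signal_b = frames["cohort_b"]

    values_a = signal_a + rngs["expr_rnaseq"].normal(0.0, config.noise_sd_rnaseq, signal_a.shape)
    slope = rngs["platform"].normal(config.platform_slope, config.platform_slope_jitter, n_genes)
    slope = np.clip(slope, 0.05, None)
    intercept = rngs["platform"].normal(5.0, 0.5, n_genes)
    values_b = (
        slope[:, None] * signal_b
        + intercept[:, None]
        + rngs["expr_microarray"].normal(0.0, config.noise_sd_microarray, signal_b.shape)
    )

    expr_a = ExpressionMatrix(pd.DataFrame(values_a, index=gene_ids, columns=cols_a), "rnaseq")
    expr_b = ExpressionMatrix(pd.DataFrame(values_b, index=gene_ids, columns=cols_b), "microarray")

    annotation = validate_annotation(
        pd.DataFrame(annot_rows, columns=["sample_id", "cohort", "tissue", "ets_status", "subtype"])
    )
    latent = pd.DataFrame(latent_rows, columns=["sample_id", "cohort", "ets_status", "a_wnt", "a_met"])

    # --- biochemical recurrence for cohort-a tumors -----------------------
    lat_a = latent[latent["cohort"] == "cohort_a"]
    coef = np.where(
        lat_a["ets_status"] == "ets_pos", config.hazard_coef_ets_pos, config.hazard_coef_ets_neg
    )
    survival = simulate_bcr(
        scores=pd.Series(lat_a["a_wnt"].to_numpy(), index=lat_a["sample_id"]),
        hazard_coef=coef,
        rng=rngs["survival"],
        median_months=config.median_followup_months,
        censor_months=config.censor_months,
    )

    cohort = SimulatedCohort(
        expr_rnaseq=expr_a,
        expr_microarray=expr_b,
        annotation=annotation,
        gene_models=validate_gene_models(gene_models),
        binding_sites=validate_binding_sites(binding_sites),
        survival=survival,
        truth=truth,
        config=config,
        latent=latent,
    )
    if config.n_decoys:
        cohort = plant_decoys(config.n_decoys, cohort, rng=rngs["decoys"])
    return cohort


def _place_sites(gene_models: pd.DataFrame, is_target: np.ndarray,
                 rng: np.random.Generator) -> pd.DataFrame:
    """One AR site within 25 kb downstream (3') of each target gene's TSS.

    Gene spacing (120 kb) guarantees non-target genes are >50 kb from every
    site.
    """
    rows = []
    for _, g in gene_models.loc[is_target].iterrows():
        gap = int(rng.integers(_SITE_MIN_GAP, _SITE_MAX_GAP + 1))
        if g["strand"] == "+":
            start = int(g["tss"]) + gap
            end = start + _SITE_WIDTH
        else:
            end = int(g["tss"]) - gap + 1
            start = end - _SITE_WIDTH
        rows.append((g["chrom"], start, end, rng.choice(_SOURCES)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "source"])


def plant_decoys(n: int, cohort: SimulatedCohort,
                 rng: np.random.Generator | None = None) -> SimulatedCohort:
    """Flag ``n`` AR-bound null genes as subtraction-step decoys.

    Null genes already have identical tumor and adjacent-normal
    distributions by construction, so the decoy set is exactly the set the
    subtractive stage should remove; this op marks which AR-bound nulls
    play that role in the ground truth.  ``n = 0`` leaves the cohort
    unchanged.
    """
    if n == 0:
        return cohort
    if rng is None:
        rng = _spawn_rngs(cohort.config.seed)["decoys"]
    truth = cohort.truth
    eligible = truth.index[
        (truth["category"] == "null") & truth["is_ar_target"]
        & ~truth["is_marker"] & ~truth["is_decoy"]
    ]
    if len(eligible) < n:
        raise ValueError(f"only {len(eligible)} AR-bound null genes available for {n} decoys")
    chosen = rng.permutation(eligible.to_numpy())[:n]
    truth = truth.copy()
    truth.loc[chosen, "is_decoy"] = True
    return SimulatedCohort(
        expr_rnaseq=cohort.expr_rnaseq,
        expr_microarray=cohort.expr_microarray,
        annotation=cohort.annotation,
        gene_models=cohort.gene_models,
        binding_sites=cohort.binding_sites,
        survival=cohort.survival,
        truth=truth,
        config=cohort.config,
        latent=cohort.latent,
    )


def simulate_bcr(scores: pd.Series, hazard_coef, rng,
                 median_months: float = 24.0,
                 censor_months: tuple[float, float] = (6.0, 48.0)) -> pd.DataFrame:
    """Exponential BCR times with log-hazard ``hazard_coef * score``.

    ``hazard_coef`` may be a scalar or a per-sample array.  Censoring is
    independent uniform on ``censor_months`` (short follow-up regime).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    scores = pd.Series(scores)
    base_rate = np.log(2.0) / median_months
    rate = base_rate * np.exp(np.asarray(hazard_coef, dtype=float) * scores.to_numpy())
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(censor_months[0], censor_months[1], size=len(scores))
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return validate_survival(
        pd.DataFrame(
            {
                "sample_id": scores.index.astype(str),
                "time_months": np.maximum(time, 1e-3),
                "event": event,
            }
        )
    )


def simulate_signature_matrix(n_genes: int, n_samples: int, set_size: int,
                              loading: float, noise_sd: float,
                              seed: int) -> tuple[ExpressionMatrix, list[str]]:
    """Background matrix with one planted coherent gene set.

    The ``set_size`` planted genes share a per-sample latent activity with
    the given loading on top of i.i.d. noise; all other genes are pure
    noise.  Used for signature-scoring calibration studies.
    """
    if set_size > n_genes:
        raise ValueError("set_size exceeds n_genes")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    values = 8.0 + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    activity = rng.normal(size=n_samples)
    set_rows = rng.choice(n_genes, size=set_size, replace=False)
    values[set_rows] += loading * activity
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), "rnaseq")
    return expr, [gene_ids[i] for i in sorted(set_rows)]


def truth_gene_sets(truth: pd.DataFrame, n_random_sets: int = 20,
                    set_size: int = 26, seed: int = 0) -> GeneSetCollection:
    """Pathway collection derived from the planted truth.

    ``wnt_like`` is the ETS+ Up block, ``metabolic_like`` the ETS- Up
    block; random same-size sets drawn from null genes serve as negative
    controls for over-representation analysis.
    """
    rng = np.random.default_rng(seed)
    sets = {
        "wnt_like": truth.index[truth["category"] == "ets_pos_up"].tolist(),
        "metabolic_like": truth.index[truth["category"] == "ets_neg_up"].tolist(),
    }
    nulls = truth.index[(truth["category"] == "null") & ~truth["is_marker"]].to_numpy()
    for i in range(n_random_sets):
        take = rng.choice(nulls, size=min(set_size, len(nulls)), replace=False)
        sets[f"random_{i:02d}"] = sorted(take.tolist())
    return GeneSetCollection(name="synthetic_pathways", sets=sets)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["censor_months"] = list(d["censor_months"])
    return d
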