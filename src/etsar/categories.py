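"""Subtractive categorization of AR-target genes against adjacent normal.

Each AR-target gene is tested stratum-by-stratum against adjacent-normal
tissue (same Mann–Whitney + BH-FDR + fold-change dual criterion as the
ETS+ vs ETS- stage).  The (ETS- direction, ETS+ direction) pair then maps
to one of five categories — ETS- Up, ETS- Dn, ETS+ Up, ETS+ Dn, both Up —
with genes not significantly different from normal in either stratum
``removed`` (the subtraction step) and the remaining sign patterns
reported explicitly as ``other_pattern`` rather than silently dropped.
"""

from __future__ import annotations

import pandas as pd

from .de import DEConfig, two_group_table

#: (direction vs normal in ETS-, direction vs normal in ETS+) -> category
CATEGORY_MAP = {
    ("up", "ns"): "ets_neg_up",
    ("dn", "ns"): "ets_neg_dn",
    ("ns", "up"): "ets_pos_up",
    ("ns", "dn"): "ets_pos_dn",
    ("up", "up"): "both_up",
    ("ns", "ns"): "removed",
    ("dn", "dn"): "other_pattern",
    ("up", "dn"): "other_pattern",
    ("dn", "up"): "other_pattern",
}

CATEGORY_ORDER = [
    "ets_neg_up", "ets_neg_dn", "ets_pos_up", "ets_pos_dn", "both_up",
    "removed", "other_pattern",
]


def tumor_vs_normal(expr, annotation: pd.DataFrame, stratum: str,
                    config: DEConfig | None = None,
                    genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene direction of a tumor stratum relative to adjacent normal.

    ``stratum`` is ``'ets_pos'``, ``'ets_neg'`` or ``'pooled'`` (all
    tumors).  Returns a table indexed by gene_id with u_stat, p, q, log2fc
    (tumor minus normal) and direction in {up, dn, ns}.
    """
    config = config or DEConfig()
    annot = annotation[annotation["sample_id"].isin(expr.sample_ids)]
    normals = annot.loc[annot["tissue"] == "adjacent_normal", "sample_id"].tolist()
    if len(normals) < 2:
        raise ValueError("need >=2 adjacent_normal samples")
    tumors = annot[annot["tissue"] == "tumor"]
    if stratum != "pooled":
        tumors = tumors[tumors["ets_status"] == stratum]
    tumor_ids = tumors["sample_id"].tolist()
    if len(tumor_ids) < 2:
        raise ValueError(f"need >=2 tumor samples in stratum {stratum!r}")

    sub = expr if genes is None else expr.subset_genes(genes)
    table = two_group_table(
        sub.data[tumor_ids].to_numpy(), sub.data[normals].to_numpy(), sub.gene_ids,
        config.q_max, config.resolve_fc_min(expr.platform), labels=("up", "dn"),
    )
    return table.set_index("gene_id")


def assign_categories(target_genes, dir_neg: pd.Series, dir_pos: pd.Series) -> pd.DataFrame:
    """Map per-stratum vs-normal directions to the five ETS-dependent categories.

    ``target_genes`` is the AR-target gene list; both direction series
    must cover it.  Returns a table indexed by gene_id with
    ``ets_neg_vs_normal``, ``ets_pos_vs_normal`` and ``category``.
    """
    target_genes = list(target_genes)
    for name, series in (("ETS-", dir_neg), ("ETS+", dir_pos)):
        missing = [g for g in target_genes if g not in series.index]
        if missing:
            raise ValueError(
                f"gene(s) absent from {name} vs-normal directions: {missing[:5]}"
            )
    rows = []
    for g in target_genes:
        pattern = (str(dir_neg.loc[g]), str(dir_pos.loc[g]))
        rows.append((g, *pattern, CATEGORY_MAP[pattern]))
    return pd.DataFrame(
        rows, columns=["gene_id", "ets_neg_vs_normal", "ets_pos_vs_normal", "category"]
    ).set_index("gene_id")


def categorize(expr, annotation: pd.DataFrame, target_genes,
               config: DEConfig | None = None,
               removal: str = "per_stratum") -> pd.DataFrame:
    """Full subtractive stage: vs-normal tests per stratum, then mapping.

    ``removal='per_stratum'`` removes genes that are ns against normal in
    BOTH strata; ``removal='pooled'`` instead removes genes that are ns in
    a pooled all-tumors vs normal test (directions still come from the
    per-stratum tests).
    """
    if removal not in ("per_stratum", "pooled"):
        raise ValueError(f"unknown removal mode {removal!r}")
    target_genes = list(target_genes)
    dir_neg = tumor_vs_normal(expr, annotation, "ets_neg", config, genes=target_genes)
    dir_pos = tumor_vs_normal(expr, annotation, "ets_pos", config, genes=target_genes)
    table = assign_categories(target_genes, dir_neg["direction"], dir_pos["direction"])
    if removal == "pooled":
        pooled = tumor_vs_normal(expr, annotation, "pooled", config, genes=target_genes)
        ns_pooled = pooled["direction"] == "ns"
        table.loc[ns_pooled[ns_pooled].index.intersection(table.index), "category"] = "removed"
    table["log2fc_vs_normal_ets_neg"] = dir_neg["log2fc"]
    table["log2fc_vs_normal_ets_pos"] = dir_pos["log2fc"]
    return table


def category_counts(table: pd.DataFrame) -> pd.Series:
    counts = table["category"].value_counts()
    return counts.reindex(CATEGORY_ORDER, fill_value=0)


def normal_median_normalize(expr, annotation: pd.DataFrame):
    """Subtract each gene's median over adjacent-normal samples (heatmap scale)."""
    from .core import ExpressionMatrix

    annot = annotation[annotation["sample_id"].isin(expr.sample_ids)]
    normals = annot.loc[annot["tissue"] == "adjacent_normal", "sample_id"].tolist()
    if not normals:
        raise ValueError("no adjacent_normal samples to normalize against")
    medians = expr.data[normals].median(axis=1)
    return ExpressionMatrix(expr.data.sub(medians, axis=0), expr.platform)
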