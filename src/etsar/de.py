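"""Two-group differential expression with FDR and fold-change gating.

Per gene: a two-tailed Mann–Whitney U test (exact enumeration for small
untied inputs, tie-corrected normal approximation with continuity
correction otherwise), Benjamini–Hochberg adjustment across genes, and a
dual significance criterion — q below ``q_max`` AND absolute log2 fold
change above ``fc_min``.  The fold-change floor is platform-specific:
0.585 for the RNA-seq regime, 0.05 for the compressed microarray regime.

Cross-cohort concordance intersects two DE tables, requiring significance
with the SAME direction in both cohorts, and reports the Pearson
correlation of fold changes over the overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: platform-specific |log2 FC| floors for the dual significance criterion
PLATFORM_FC_MIN = {"rnaseq": 0.585, "microarray": 0.05}

_EXACT_MAX_N = 12


@dataclass
class DEConfig:
    q_max: float = 0.05
    fc_min: float | None = None  # None -> platform default

    def __post_init__(self) -> None:
        if not (0.0 < self.q_max < 1.0):
            raise ValueError("q_max must lie in (0, 1)")
        if self.fc_min is not None and self.fc_min < 0:
            raise ValueError("fc_min must be >= 0")

    def resolve_fc_min(self, platform: str) -> float:
        if self.fc_min is not None:
            return self.fc_min
        return PLATFORM_FC_MIN[platform]


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U for x, p).

    Uses exact enumeration when the pooled size is <= 12 and there are no
    ties, otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= _EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def two_group_table(values_a: np.ndarray, values_b: np.ndarray,
                    gene_ids, q_max: float, fc_min: float,
                    labels: tuple[str, str] = ("up", "dn")) -> pd.DataFrame:
    """Gene-wise DE of group a vs group b (rows = genes).

    log2fc is mean(a) - mean(b); direction is ``labels[0]`` when log2fc is
    positive and the dual criterion holds, ``labels[1]`` when negative,
    else 'ns'.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if values_a.shape[1] < 2 or values_b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    n_total = values_a.shape[1] + values_b.shape[1]
    if n_total <= _EXACT_MAX_N:
        stats_p = np.array([mann_whitney(a, b) for a, b in zip(values_a, values_b)])
        u, p = stats_p[:, 0], stats_p[:, 1]
    else:
        res = stats.mannwhitneyu(
            values_a, values_b, alternative="two-sided", method="asymptotic", axis=1
        )
        u, p = np.asarray(res.statistic, float), np.minimum(np.asarray(res.pvalue, float), 1.0)
    q = bh_fdr(p)
    log2fc = values_a.mean(axis=1) - values_b.mean(axis=1)
    direction = np.where(
        (q < q_max) & (np.abs(log2fc) > fc_min),
        np.where(log2fc > 0, labels[0], labels[1]),
        "ns",
    )
    return pd.DataFrame(
        {"gene_id": list(gene_ids), "u_stat": u, "p": p, "q": q,
         "log2fc": log2fc, "direction": direction}
    )


def run_de(expr, annotation: pd.DataFrame, config: DEConfig | None = None) -> pd.DataFrame:
    """ETS+ vs ETS- differential expression over the tumor samples of ``expr``.

    Directions are ``up_in_ets_pos`` / ``up_in_ets_neg`` / ``ns``; log2fc
    is ETS+ mean minus ETS- mean.
    """
    config = config or DEConfig()
    annot = annotation[annotation["sample_id"].isin(expr.sample_ids)]
    tumors = annot[annot["tissue"] == "tumor"]
    pos = tumors.loc[tumors["ets_status"] == "ets_pos", "sample_id"].tolist()
    neg = tumors.loc[tumors["ets_status"] == "ets_neg", "sample_id"].tolist()
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(f"need >=2 samples per ETS stratum (got {len(pos)} ETS+, {len(neg)} ETS-)")
    fc_min = config.resolve_fc_min(expr.platform)
    table = two_group_table(
        expr.data[pos].to_numpy(), expr.data[neg].to_numpy(), expr.gene_ids,
        config.q_max, fc_min, labels=("up_in_ets_pos", "up_in_ets_neg"),
    )
    n_sig = int((table["direction"] != "ns").sum())
    logger.info(
        "DE (%s): %d/%d genes differential (%.1f%%) at q<%g, |log2FC|>%g",
        expr.platform, n_sig, len(table), 100.0 * n_sig / len(table), config.q_max, fc_min,
    )
    return table


@dataclass
class CrossCohortConcordance:
    """Direction-concordant significant overlap of two DE tables."""

    overlap_genes: list[str]
    n_overlap: int
    n_up_ets_pos: int
    n_up_ets_neg: int
    fc_correlation: float
    table: pd.DataFrame = field(repr=False, default=None)


def intersect_cohorts(de_a: pd.DataFrame, de_b: pd.DataFrame) -> CrossCohortConcordance:
    """Genes significant with the same direction in both cohorts.

    Fold-change correlation (Pearson) is computed over the overlap genes;
    NaN when the overlap has fewer than 2 genes.
    """
    shared = set(de_a["gene_id"]) & set(de_b["gene_id"])
    if not shared:
        raise ValueError("cohorts share no gene ids")
    a = de_a.set_index("gene_id")
    b = de_b.set_index("gene_id")
    idx = [g for g in a.index if g in shared]
    sig = [
        g for g in idx
        if a.loc[g, "direction"] != "ns" and a.loc[g, "direction"] == b.loc[g, "direction"]
    ]
    fc_a = a.loc[sig, "log2fc"].to_numpy()
    fc_b = b.loc[sig, "log2fc"].to_numpy()
    corr = float(np.corrcoef(fc_a, fc_b)[0, 1]) if len(sig) >= 2 else float("nan")
    n_pos = int((a.loc[sig, "direction"] == "up_in_ets_pos").sum())
    table = pd.DataFrame(
        {"gene_id": sig,
         "direction": a.loc[sig, "direction"].to_numpy(),
         "log2fc_a": fc_a, "log2fc_b": fc_b}
    )
    return CrossCohortConcordance(
        overlap_genes=sig,
        n_overlap=len(sig),
        n_up_ets_pos=n_pos,
        n_up_ets_neg=len(sig) - n_pos,
        fc_correlation=corr,
        table=table,
    )
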