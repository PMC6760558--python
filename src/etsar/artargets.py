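"""Direct AR-target annotation: binding-site proximity to gene TSSs.

A gene is a direct AR target when a binding site lies within ``window_bp``
of its TSS (default 25 kb).  Distance is 0 for a site overlapping the TSS,
otherwise the gap between the TSS and the nearest covered base of the
site.  ``symmetric`` mode (default) accepts sites on either side of the
TSS; ``downstream_only`` additionally requires the site to lie 3' of the
TSS with respect to the gene's strand.  ``min_sources`` requires
qualifying sites from that many distinct ChIP-seq datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import validate_binding_sites, validate_gene_models


@dataclass
class AnnotationParams:
    window_bp: int = 25_000
    mode: str = "symmetric"  # or "downstream_only"
    min_sources: int = 1

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if self.mode not in ("symmetric", "downstream_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_sources < 1:
            raise ValueError("min_sources must be >= 1")


def annotate_targets(gene_models: pd.DataFrame, sites: pd.DataFrame,
                     params: AnnotationParams | None = None) -> pd.DataFrame:
    """Per-gene AR-target call with supporting-source count and distance.

    Returns a table indexed by gene_id with columns ``is_target``,
    ``n_supporting_sources`` (distinct site sources with a qualifying
    site) and ``min_distance_bp`` (nearest mode-eligible site distance;
    NaN when no eligible site exists on the gene's chromosome).  Genes on
    chromosomes without sites are simply non-targets.
    """
    params = params or AnnotationParams()
    validate_gene_models(gene_models)
    validate_binding_sites(sites)

    result = pd.DataFrame(
        {"is_target": False, "n_supporting_sources": 0, "min_distance_bp": np.nan},
        index=pd.Index(gene_models["gene_id"], name="gene_id"),
    )

    for chrom, chrom_sites in sites.groupby("chrom", sort=False):
        genes = gene_models[gene_models["chrom"] == chrom]
        if genes.empty:
            continue
        tss = genes["tss"].to_numpy()[:, None]                 # (G, 1)
        strand = genes["strand"].to_numpy()[:, None]
        start = chrom_sites["start"].to_numpy()[None, :]       # (1, S)
        end = chrom_sites["end"].to_numpy()[None, :]
        source = chrom_sites["source"].to_numpy()

        overlap = (start <= tss) & (tss < end)
        dist = np.where(
            overlap, 0,
            np.where(tss < start, start - tss, tss - end + 1),
        )
        if params.mode == "downstream_only":
            # 3' of the TSS: higher coordinates for '+', lower for '-';
            # sites overlapping the TSS always qualify
            downstream = np.where(strand == "+", start >= tss, end <= tss + 1)
            eligible = overlap | downstream
        else:
            eligible = np.ones_like(overlap, dtype=bool)

        dist_eligible = np.where(eligible, dist, np.iinfo(np.int64).max)
        min_dist = dist_eligible.min(axis=1)
        qualifying = eligible & (dist <= params.window_bp)
        n_sources = np.array(
            [len(set(source[row])) for row in qualifying]
        )
        gidx = genes["gene_id"].to_numpy()
        result.loc[gidx, "min_distance_bp"] = np.where(
            min_dist == np.iinfo(np.int64).max, np.nan, min_dist.astype(float)
        )
        result.loc[gidx, "n_supporting_sources"] = n_sources
        result.loc[gidx, "is_target"] = n_sources >= params.min_sources

    return result
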