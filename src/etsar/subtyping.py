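"""ETS+/ETS- status calling from outlier expression of ETS-family genes.

A tumor is ETS+ when any marker gene (ERG, ETV1, ETV4, ETV5, FLI1 by
default) exceeds a per-marker cutpoint; all other tumors are ETS-.  The
default rule is MAD outlier calling — cutpoint = median + k * MAD across
tumor samples, with a normal-consistent MAD (scale 1.4826) and k = 3 —
matching the field's usual treatment of fusion-driven marker
overexpression as strongly bimodal outlier expression.  A fixed-cutpoint
mode reproduces externally supplied thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

DEFAULT_MARKERS = ["ERG", "ETV1", "ETV4", "ETV5", "FLI1"]


@dataclass
class SubtypingRule:
    marker_genes: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))
    threshold_method: str = "mad_outlier"  # or "fixed"
    k: float = 3.0
    fixed_cutpoints: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.threshold_method not in ("mad_outlier", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.k <= 0:
            raise ValueError("MAD multiplier k must be > 0")
        if self.threshold_method == "fixed" and not self.fixed_cutpoints:
            raise ValueError("fixed threshold_method requires fixed_cutpoints")


def marker_cutpoints(expr, rule: SubtypingRule) -> pd.Series:
    """Per-marker cutpoints over the (tumor-only) matrix columns."""
    missing = [g for g in rule.marker_genes if g not in expr.data.index]
    if missing:
        raise ValueError(f"marker gene(s) absent from matrix: {', '.join(missing)}")
    cuts = {}
    for g in rule.marker_genes:
        x = expr.data.loc[g].to_numpy()
        if rule.threshold_method == "fixed":
            if g not in rule.fixed_cutpoints:
                raise ValueError(f"no fixed cutpoint supplied for marker {g!r}")
            cuts[g] = float(rule.fixed_cutpoints[g])
            continue
        mad = median_abs_deviation(x, scale="normal")
        if mad == 0.0:
            if rule.fixed_cutpoints and g in rule.fixed_cutpoints:
                cuts[g] = float(rule.fixed_cutpoints[g])
                continue
            raise ValueError(
                f"zero MAD for marker {g!r} and no fixed cutpoint to fall back on"
            )
        cuts[g] = float(np.median(x) + rule.k * mad)
    return pd.Series(cuts)


def call_ets_status(expr, rule: SubtypingRule | None = None) -> pd.DataFrame:
    """Assign ETS status to every tumor sample in ``expr``.

    ``expr`` must be restricted to tumor samples.  Returns a table with
    columns ``sample_id``, ``ets_status`` and ``driving_marker`` (the
    marker with the highest MAD-scaled exceedance for ETS+ samples, empty
    for ETS-).  Every sample receives exactly one status.
    """
    rule = rule or SubtypingRule()
    cuts = marker_cutpoints(expr, rule)
    sub = expr.data.loc[rule.marker_genes]
    # scale exceedance per marker so drivers are comparable across markers
    scale = {}
    for g in rule.marker_genes:
        mad = median_abs_deviation(sub.loc[g].to_numpy(), scale="normal")
        scale[g] = mad if mad > 0 else 1.0
    exceed = sub.sub(cuts, axis=0).div(pd.Series(scale), axis=0)

    records = []
    for sid in sub.columns:
        col = exceed[sid]
        over = col[col > 0]
        if len(over):
            records.append((sid, "ets_pos", over.idxmax()))
        else:
            records.append((sid, "ets_neg", ""))
    return pd.DataFrame(records, columns=["sample_id", "ets_status", "driving_marker"])


def apply_subtyping(expr, annotation: pd.DataFrame,
                    rule: SubtypingRule | None = None,
                    override: bool = False) -> pd.DataFrame:
    """Fill in ets_status for tumor samples of an annotation table.

    Precomputed statuses are kept unless ``override`` is set — externally
    supplied labels (the analogue of dataset-provided subtyping) win over
    calling.
    """
    annotation = annotation.copy()
    tumor_ids = annotation.loc[annotation["tissue"] == "tumor", "sample_id"]
    tumor_ids = [s for s in tumor_ids if s in expr.data.columns]
    need = annotation["sample_id"].isin(tumor_ids)
    if not override:
        need &= annotation["ets_status"] == "unknown"
    if need.any():
        calls = call_ets_status(expr.subset_samples(tumor_ids), rule)
        call_map = dict(zip(calls["sample_id"], calls["ets_status"]))
        annotation.loc[need, "ets_status"] = annotation.loc[need, "sample_id"].map(call_map)
    return annotation
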