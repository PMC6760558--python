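"""Core domain types shared by every pipeline stage.

The substrate of the analysis is a genes x samples matrix of log2
expression values plus per-sample annotation (cohort, tissue, ETS fusion
status, molecular subtype), gene TSS models, AR ChIP-seq binding sites,
gene-set collections and a biochemical-recurrence survival table.

Tabular types are thin dataclass wrappers around pandas objects with
validation at construction; genomic coordinates are 0-based half-open
throughout (BED-native).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLATFORMS = ("rnaseq", "microarray")
TISSUES = ("tumor", "adjacent_normal")
ETS_STATUSES = ("ets_pos", "ets_neg", "unknown")
ETS_POS_SUBTYPES = ("ERG", "ETV1", "ETV4", "FLI1")
ETS_NEG_SUBTYPES = ("SPOP", "FOXA1", "IDH1", "other")
SUBTYPES = ETS_POS_SUBTYPES + ETS_NEG_SUBTYPES + ("none",)

ANNOTATION_COLUMNS = ["sample_id", "cohort", "tissue", "ets_status", "subtype"]
GENE_MODEL_COLUMNS = ["gene_id", "chrom", "tss", "strand"]
BINDING_SITE_COLUMNS = ["chrom", "start", "end", "source"]
SURVIVAL_COLUMNS = ["sample_id", "time_months", "event"]


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {', '.join(map(str, dup[:5]))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with a platform tag.

    ``data`` rows are gene ids, columns are sample ids.  Values must be
    finite; duplicate ids are rejected.  ``platform`` selects the
    platform-specific fold-change regime downstream ('rnaseq' or
    'microarray').
    """

    data: pd.DataFrame
    platform: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.platform)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.platform)


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample annotation table and return it.

    Required columns: sample_id, cohort, tissue, ets_status, subtype.
    Enforces the subtype -> ETS status implication for tumor samples
    (ERG/ETV1/ETV4/FLI1 are ETS+ drivers; SPOP/FOXA1/IDH1/other are ETS-).
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing column(s): {', '.join(missing)}")
    _check_unique(df["sample_id"], "sample")
    for col, allowed in [("tissue", TISSUES), ("ets_status", ETS_STATUSES), ("subtype", SUBTYPES)]:
        bad = set(df[col]) - set(allowed)
        if bad:
            raise ValueError(f"invalid {col} value(s): {sorted(map(str, bad))}")
    pos = df["subtype"].isin(ETS_POS_SUBTYPES)
    neg = df["subtype"].isin(ETS_NEG_SUBTYPES)
    if (pos & (df["ets_status"] == "ets_neg")).any() or (neg & (df["ets_status"] == "ets_pos")).any():
        bad_ids = df.loc[
            (pos & (df["ets_status"] == "ets_neg")) | (neg & (df["ets_status"] == "ets_pos")),
            "sample_id",
        ].tolist()
        raise ValueError(f"subtype contradicts ets_status for sample(s): {bad_ids[:5]}")
    return df


def validate_gene_models(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene models missing column(s): {', '.join(missing)}")
    _check_unique(df["gene_id"], "gene")
    if (df["tss"].to_numpy() < 0).any():
        raise ValueError("TSS coordinates must be non-negative")
    bad = set(df["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"malformed strand value(s): {sorted(map(str, bad))}")
    return df


def validate_binding_sites(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BINDING_SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"binding sites missing column(s): {', '.join(missing)}")
    bad = df["start"] >= df["end"]
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise ValueError(f"binding site start >= end at record {i}: "
                         f"{df.iloc[i]['chrom']}:{df.iloc[i]['start']}-{df.iloc[i]['end']}")
    if (df["start"].to_numpy() < 0).any():
        raise ValueError("binding site coordinates must be non-negative")
    return df


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival table missing column(s): {', '.join(missing)}")
    _check_unique(df["sample_id"], "sample")
    if (df["time_months"].to_numpy() <= 0).any():
        raise ValueError("survival times must be positive")
    return df


@dataclass
class GeneSetCollection:
    """Named collection of gene sets (GMT semantics).

    ``sets`` maps set name to a list of unique member gene ids; empty sets
    are rejected.
    """

    name: str
    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {set_name!r} is empty")
            _check_unique(members, f"member (set {set_name!r})")

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.sets.items()}
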