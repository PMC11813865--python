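"""Tab-separated on-disk formats for count matrices and sample metadata.

Counts: first column is the gene identifier, remaining columns are samples,
header row carries sample identifiers. Missing (masked) entries serialize as
``NA``. Metadata: one row per sample with columns ``sample_id, cohort,
subject_id, timepoint, sex, ams_c`` (a derived ``severe_ams`` column is
accepted and regenerated on read).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

META_COLUMNS = ["sample_id", "cohort", "subject_id", "timepoint", "sex", "ams_c"]

SEVERE_AMS_C = 1.4  # AMS-C cerebral factor score at or above which AMS is severe


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample count table; gene IDs become the index."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.has_duplicates:
        raise ValueError(f"duplicate gene identifiers in {path}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample identifiers in {path}")
    if (df.fillna(0).to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


def read_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata {path} lacks columns {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample_id in {path}")
    meta = meta.set_index("sample_id", drop=False)
    meta.index.name = None
    meta["severe_ams"] = meta["ams_c"] >= SEVERE_AMS_C
    return meta


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    cols = META_COLUMNS + (["severe_ams"] if "severe_ams" in meta.columns else [])
    meta.to_csv(path, sep="\t", index=False, columns=cols)
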