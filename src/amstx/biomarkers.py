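"""Four-contrast biomarker taxonomy and same-direction cross-cohort replication.

The four categories compare the study's four sample groups (AMS+/AMS- at
SL/HA):

* ``diagnostic``  — AMS+ vs AMS- among HA samples (unpaired, sex-adjusted);
* ``predictive``  — AMS+ vs AMS- among SL samples (unpaired, sex-adjusted);
* ``pathogenic``  — SL -> HA within AMS+ subjects (paired, subject-blocked);
* ``protective``  — SL -> HA within AMS- subjects (paired, subject-blocked).

A gene replicates across cohorts when it passes the DEG thresholds
(p < 0.05, |log2FC| > 0.7 by default) in both cohorts with the same fold
change sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import diffexpr
from .preprocess import NormFactors, tmm_factors

log = logging.getLogger(__name__)

CATEGORIES = ("diagnostic", "predictive", "pathogenic", "protective")


@dataclass(frozen=True)
class ContrastSpec:
    """One category's sample selection: timepoint filter, grouping, pairing."""

    category: str
    timepoint: str | None  # restrict to SL or HA (unpaired contrasts)
    severe: bool | None  # restrict to one AMS phenotype (paired contrasts)
    paired: bool

    @classmethod
    def for_category(cls, category: str) -> "ContrastSpec":
        specs = {
            "diagnostic": cls("diagnostic", timepoint="HA", severe=None, paired=False),
            "predictive": cls("predictive", timepoint="SL", severe=None, paired=False),
            "pathogenic": cls("pathogenic", timepoint=None, severe=True, paired=True),
            "protective": cls("protective", timepoint=None, severe=False, paired=True),
        }
        if category not in specs:
            raise ValueError(f"unknown category {category!r}")
        return specs[category]

    def select(self, meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
        """Samples entering the contrast plus the boolean group vector.

        Unpaired: group = severe AMS. Paired: group = HA timepoint, with
        only complete SL/HA subject pairs retained.
        """
        if self.paired:
            sel = meta[meta["severe_ams"] == self.severe]
            per_subject = sel.groupby("subject_id")["timepoint"].nunique()
            complete = per_subject[per_subject == 2].index
            sel = sel[sel["subject_id"].isin(complete)]
            if len(complete) < 2:
                raise ValueError(
                    f"{self.category}: fewer than 2 subjects with both timepoints"
                )
            group = sel["timepoint"] == "HA"
        else:
            sel = meta[meta["timepoint"] == self.timepoint]
            group = sel["severe_ams"].astype(bool)
            if group.sum() == 0 or (~group).sum() == 0:
                raise ValueError(
                    f"{self.category}: a contrast group is empty "
                    f"({int(group.sum())} AMS+ vs {int((~group).sum())} AMS-)"
                )
        return sel, group


def run_contrast(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: ContrastSpec,
    cohort: str | None = None,
    prior_df: float = 10.0,
    offsets: NormFactors | None = None,
    max_zero_fraction: float = 0.9,
) -> pd.DataFrame:
    """Differential expression for one category in one cohort.

    Returns the per-gene table (log2FC, PV, FDR, direction) with the
    category and cohort recorded in ``DataFrame.attrs``.
    """
    sel, group = contrast.select(meta)
    sub = counts[sel.index.tolist()]
    sub = diffexpr.testable_genes(sub, max_zero_fraction)
    n_dropped = len(counts) - len(sub)
    if n_dropped:
        log.info(
            "%s/%s: excluding %d mostly-zero genes from testing",
            cohort,
            contrast.category,
            n_dropped,
        )
    if offsets is None:
        offsets = tmm_factors(sub)
    design = diffexpr.make_design(
        sel, group, adjust_sex=not contrast.paired, pair_by_subject=contrast.paired
    )
    disp = diffexpr.estimate_dispersions(sub, design, offsets, prior_df=prior_df)
    result = diffexpr.fit_contrast(sub, design, disp, offsets)
    result.attrs.update(
        category=contrast.category,
        cohort=cohort,
        common_dispersion=disp.common,
        prior_df=prior_df,
    )
    return result


@dataclass(frozen=True)
class BiomarkerSet:
    """Genes replicating in both cohorts for one category.

    ``table`` is indexed by gene with per-cohort columns
    ``log2FC_<cohort>, PV_<cohort>, FDR_<cohort>`` plus the shared
    ``direction``.
    """

    category: str
    cohorts: tuple[str, str]
    table: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def common_degs(
    a: pd.DataFrame,
    b: pd.DataFrame,
    p_max: float = 0.05,
    lfc_min: float = 0.7,
    category: str = "unspecified",
    cohorts: tuple[str, str] = ("A", "B"),
) -> BiomarkerSet:
    """Same-direction cross-cohort replication filter.

    Keeps genes passing ``PV < p_max`` and ``|log2FC| > lfc_min`` (both
    strict) in both per-cohort results with matching fold-change sign.
    Gene universes are intersected first (mismatch logged).
    """
    shared = a.index.intersection(b.index)
    if len(shared) < max(len(a), len(b)):
        log.info(
            "common_degs: gene universes differ (%d vs %d; %d shared)",
            len(a),
            len(b),
            len(shared),
        )
    da = diffexpr.call_degs(a.loc[shared], p_max, lfc_min)
    db = diffexpr.call_degs(b.loc[shared], p_max, lfc_min)
    both = da.index.intersection(db.index)
    same_sign = [g for g in both if da.at[g, "direction"] == db.at[g, "direction"]]
    table = pd.DataFrame(
        {
            f"log2FC_{cohorts[0]}": da.loc[same_sign, "log2FC"],
            f"PV_{cohorts[0]}": da.loc[same_sign, "PV"],
            f"FDR_{cohorts[0]}": da.loc[same_sign, "FDR"],
            f"log2FC_{cohorts[1]}": db.loc[same_sign, "log2FC"],
            f"PV_{cohorts[1]}": db.loc[same_sign, "PV"],
            f"FDR_{cohorts[1]}": db.loc[same_sign, "FDR"],
            "direction": da.loc[same_sign, "direction"],
        }
    )
    table.index.name = "gene"
    return BiomarkerSet(category=category, cohorts=cohorts, table=table)


def direction_counts(bset: BiomarkerSet) -> tuple[int, int]:
    """(n_up, n_down) by the shared fold-change direction."""
    n_up = int((bset.table["direction"] == "up").sum())
    return n_up, len(bset) - n_up


def converged_genes(sets: list[BiomarkerSet]) -> pd.DataFrame:
    """Category-membership table across biomarker sets.

    Returns genes x categories booleans with an ``n_categories`` column;
    genes appearing in at least two categories are the converged markers.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 biomarker sets")
    all_genes = sorted(set().union(*(s.genes for s in sets)))
    out = pd.DataFrame(index=pd.Index(all_genes, name="gene"))
    for s in sets:
        out[s.category] = out.index.isin(s.genes)
    out["n_categories"] = out.sum(axis=1).astype(int)
    return out


def incidence_summary(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort severe-AMS incidence at subject level.

    Percentages are rounded to the nearest integer (5/18 -> 28, 5/10 -> 50).
    """
    per_subject = meta.groupby(["cohort", "subject_id"])["severe_ams"].nunique()
    if (per_subject > 1).any():
        bad = per_subject[per_subject > 1].index.tolist()
        raise ValueError(f"subjects with conflicting severity flags: {bad}")
    subjects = meta.drop_duplicates("subject_id")
    grouped = subjects.groupby("cohort")["severe_ams"]
    out = pd.DataFrame(
        {"n_severe": grouped.sum().astype(int), "n_total": grouped.count()}
    )
    out["percent"] = (100.0 * out["n_severe"] / out["n_total"]).round().astype(int)
    return out
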