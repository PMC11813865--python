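"""Published per-cohort statistics for the AMS candidate biomarker genes.

These are the printed per-gene p-values (PV), BH-adjusted FDRs and log2 fold
changes reported for the two cohorts of the underlying altitude study — the
diagnostic candidates (AMS+ vs AMS- at high altitude) and the predictive
candidates (AMS+ vs AMS- at sea level). They serve as worked-example inputs
for the replication filter: applying :func:`amstx.biomarkers.common_degs` at
the study thresholds (p < 0.05, |log2FC| > 0.7, same direction) retains all
11 genes of each list, with a 3-up / 8-down split for the predictive list,
and the two lists share FOLR3, DRAXIN and TNNT1.

Cohort keys: ``PikesPeak`` (discovery, 18 subjects) and ``Chamber``
(validation, 10 subjects).
"""

from __future__ import annotations

import pandas as pd

_COLS = ["PV_PikesPeak", "FDR_PikesPeak", "log2FC_PikesPeak", "PV_Chamber", "FDR_Chamber", "log2FC_Chamber"]

_DIAGNOSTIC = {
    # gene: (PV_pp, FDR_pp, log2FC_pp, PV_ch, FDR_ch, log2FC_ch)
    "ISG15": (1.95e-03, 1.0, -0.851, 2.38e-05, 0.103, -1.260),
    "HLA-DQB1": (1.08e-05, 0.136, -1.092, 2.11e-03, 1.0, -0.773),
    "LOC101927999": (9.64e-05, 1.0, -1.313, 3.15e-03, 1.0, -0.728),
    "HBA2": (1.50e-04, 1.0, 3.091, 1.53e-02, 1.0, 0.841),
    "HBA1": (2.08e-04, 1.0, 3.483, 2.64e-03, 1.0, 1.153),
    "FOLR3": (1.65e-03, 1.0, -1.183, 1.35e-11, 1.69e-07, -2.923),
    "SIGLEC1": (4.91e-03, 1.0, -0.959, 2.08e-12, 2.60e-08, -2.545),
    "GAS6": (5.28e-03, 1.0, -0.843, 1.62e-02, 1.0, -0.861),
    "TNNT1": (2.77e-02, 1.0, 0.755, 7.54e-06, 9.41e-02, 1.952),
    "DRAXIN": (3.74e-02, 1.0, -0.818, 2.05e-03, 1.0, -1.267),
    "PDE5A": (4.43e-02, 1.0, 0.755, 1.99e-03, 1.0, 1.145),
}

_PREDICTIVE = {
    "DUSP2": (1.51e-05, 1.89e-01, 0.890, 3.45e-03, 1.0, 0.760),
    "HLA-DQA1": (2.71e-05, 3.39e-01, -1.161, 5.68e-03, 1.0, -0.957),
    "COL5A3": (3.20e-05, 4.00e-01, -1.510, 1.06e-02, 1.0, -0.921),
    "TNNT1": (3.65e-05, 4.57e-01, 1.176, 1.07e-07, 1.34e-03, 2.077),
    "KIF19": (1.37e-04, 1.0, 1.128, 2.20e-04, 1.0, 1.447),
    "C1QB": (6.71e-04, 1.0, -1.158, 3.76e-02, 1.0, -0.935),
    "DDX11L2": (1.03e-03, 1.0, -1.004, 2.86e-03, 1.0, -1.352),
    "ZNF595": (1.25e-03, 1.0, -0.778, 8.33e-03, 1.0, -0.988),
    "DRAXIN": (1.11e-02, 1.0, -0.836, 1.29e-02, 1.0, -1.096),
    "FOLR3": (2.15e-02, 1.0, -0.822, 5.54e-09, 6.94e-05, -2.635),
    "S100B": (4.05e-02, 1.0, -0.782, 1.02e-04, 1.0, -2.041),
}

# published severe-AMS incidence: (n_severe, n_subjects) per cohort
INCIDENCE = {"PikesPeak": (5, 18), "Chamber": (5, 10)}


def _table(data: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(data, orient="index", columns=_COLS)
    df.index.name = "gene"
    return df


def diagnostic_candidates() -> pd.DataFrame:
    """Printed statistics for the diagnostic candidate genes (HA contrast)."""
    return _table(_DIAGNOSTIC)


def predictive_candidates() -> pd.DataFrame:
    """Printed statistics for the predictive candidate genes (SL contrast)."""
    return _table(_PREDICTIVE)


def per_cohort_results(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a candidate table into the two per-cohort DE result frames."""
    out = []
    for cohort in ("PikesPeak", "Chamber"):
        df = pd.DataFrame(
            {
                "log2FC": table[f"log2FC_{cohort}"],
                "PV": table[f"PV_{cohort}"],
                "FDR": table[f"FDR_{cohort}"],
            }
        )
        df["direction"] = (df["log2FC"] > 0).map({True: "up", False: "down"})
        out.append(df)
    return out[0], out[1]
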