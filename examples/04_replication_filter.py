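"""Cross-cohort replication on the published candidate-gene statistics.

The package ships the published per-cohort p-values and log2 fold changes
for the diagnostic (high-altitude) and predictive (sea-level) candidate
genes. Applying the same-direction replication filter at the study
thresholds reproduces the published counts: 11 diagnostic and 11 predictive
biomarkers (3 up / 8 down), converging on FOLR3, DRAXIN and TNNT1.
"""

from amstx import biomarkers, reference

diag = biomarkers.common_degs(
    *reference.per_cohort_results(reference.diagnostic_candidates()),
    category="diagnostic", cohorts=("PikesPeak", "Chamber"),
)
print(f"diagnostic candidates retained: {len(diag)}")
print(diag.table[["log2FC_PikesPeak", "log2FC_Chamber", "direction"]])

pred = biomarkers.common_degs(
    *reference.per_cohort_results(reference.predictive_candidates()),
    category="predictive", cohorts=("PikesPeak", "Chamber"),
)
n_up, n_down = biomarkers.direction_counts(pred)
print(f"\npredictive candidates retained: {len(pred)} ({n_up} up, {n_down} down)")

conv = biomarkers.converged_genes([diag, pred])
shared = conv.index[conv["n_categories"] >= 2].tolist()
print(f"\ngenes in both categories (predisposition markers): {shared}")
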