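"""Preprocess one cohort: QC filter, low-count imputation, TMM, PCA check.

Samples with more than 20% low counts (raw count < 10) are dropped; the
remaining low counts are treated as missing and imputed from the 5 nearest
samples; TMM scaling factors normalize for composition bias; a PCA report
flags outlying samples without removing them.
"""

from amstx import preprocess, simulate

study = simulate.generate_study(simulate.SimConfig(seed=42))
raw = study.counts["PikesPeak"]

filtered = preprocess.filter_samples(raw)
masked = preprocess.mask_low_counts(filtered)
frac = masked.isna().to_numpy().mean()
print(f"samples kept: {filtered.shape[1]} of {raw.shape[1]}")
print(f"masked (low-count) entries: {100 * frac:.2f}% of the matrix")

imputed = preprocess.knn_impute(masked, k=5)
counts = imputed.round().astype(int)
print(f"genes after dropping fully-missing rows: {counts.shape[0]}")

factors = preprocess.tmm_factors(counts)
print("\nTMM factors (geometric mean 1; values near 1 mean balanced libraries):")
print(factors.tmm.describe()[["min", "mean", "max"]])

logcpm = preprocess.log_cpm(counts, factors)
report = preprocess.pca_outlier_check(logcpm)
print(f"\nPCA outlier check: {len(report.flagged)} samples flagged "
      f"beyond {report.sd_limit} SD on PC1/PC2")
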