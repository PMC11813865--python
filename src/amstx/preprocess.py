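"""Count preprocessing: sample QC, low-count masking + KNN imputation,
TMM normalization factors, log-CPM, and a PCA outlier check.

The QC rule removes samples whose fraction of low counts (raw count < 10)
strictly exceeds 20%; surviving low counts are treated as missing and imputed
from the K nearest samples. Normalization follows the trimmed-mean-of-M-values
scheme: per-sample scaling factors from doubly trimmed, precision-weighted
gene-wise log ratios against a reference sample, rescaled to geometric mean 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_LOW_THRESHOLD = 10
DEFAULT_MAX_LOW_FRACTION = 0.2


@dataclass(frozen=True)
class NormFactors:
    """Per-sample library sizes, TMM factors, and effective library sizes."""

    lib_size: pd.Series  # raw column sums
    tmm: pd.Series  # geometric mean 1 after rescaling

    @property
    def effective_lib_size(self) -> pd.Series:
        return self.lib_size * self.tmm


def filter_samples(
    counts: pd.DataFrame,
    low_threshold: int = DEFAULT_LOW_THRESHOLD,
    max_low_fraction: float = DEFAULT_MAX_LOW_FRACTION,
) -> pd.DataFrame:
    """Drop samples whose low-count fraction strictly exceeds the limit.

    A count is "low" when strictly below ``low_threshold``; a sample at
    exactly ``max_low_fraction`` is retained. The gene set never changes.
    """
    frac_low = (counts < low_threshold).mean(axis=0)
    bad = frac_low[frac_low > max_low_fraction]
    if len(bad) == len(counts.columns):
        raise ValueError(
            "all samples fail the low-count filter; fractions: "
            + ", ".join(f"{s}={f:.3f}" for s, f in bad.items())
        )
    for s, f in bad.items():
        log.info("filter_samples: removing %s (low-count fraction %.3f)", s, f)
    return counts.drop(columns=bad.index)


def mask_low_counts(
    counts: pd.DataFrame, low_threshold: int = DEFAULT_LOW_THRESHOLD
) -> pd.DataFrame:
    """Replace entries strictly below the threshold with missing values."""
    masked = counts.where(counts >= low_threshold)
    n_masked = int(masked.isna().to_numpy().sum())
    log.info(
        "mask_low_counts: %d of %d entries masked (%.2f%%)",
        n_masked,
        masked.size,
        100.0 * n_masked / masked.size,
    )
    return masked


def knn_impute(masked: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Fill missing entries from the K nearest samples.

    Sample-to-sample distance is the mean squared difference of
    ``log2(count + 1)`` over genes observed in both samples (mean, not sum,
    so attrition-shortened overlaps stay comparable). A missing entry is
    replaced by the average of the same gene's values in the k nearest
    samples among those observing the gene. Genes observed in no sample are
    dropped with a warning.
    """
    n_samples = masked.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n_samples:
        raise ValueError(f"k={k} must be smaller than the sample count {n_samples}")

    all_missing = masked.isna().all(axis=1)
    if all_missing.any():
        log.warning(
            "knn_impute: dropping %d genes with no observed values: %s",
            int(all_missing.sum()),
            list(masked.index[all_missing][:10]),
        )
        masked = masked.loc[~all_missing]

    values = masked.to_numpy(dtype=float)
    obs = ~np.isnan(values)
    logv = np.log2(np.where(obs, values, 0.0) + 1.0)

    # pairwise mean squared difference over co-observed genes
    dist = np.zeros((n_samples, n_samples))
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            shared = obs[:, i] & obs[:, j]
            if not shared.any():
                raise ValueError(
                    f"samples {masked.columns[i]} and {masked.columns[j]} "
                    "share no observed genes"
                )
            d = logv[shared, i] - logv[shared, j]
            dist[i, j] = dist[j, i] = float(np.mean(d * d))

    out = values.copy()
    order = np.argsort(dist, axis=1, kind="stable")  # row i: samples by proximity
    miss_rows, miss_cols = np.nonzero(~obs)
    for g, j in zip(miss_rows, miss_cols):
        neighbors = [i for i in order[j] if i != j and obs[g, i]]
        if not neighbors:  # unreachable: all-missing genes were dropped
            raise ValueError(f"gene {masked.index[g]} observed in no other sample")
        use = neighbors[:k]
        out[g, j] = float(np.mean(values[g, use]))
    return pd.DataFrame(out, index=masked.index, columns=masked.columns)


def _tmm_reference_column(counts: np.ndarray) -> int:
    """Sample whose 75th-percentile count fraction is closest to the mean."""
    lib = counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        q75 = np.quantile(counts, 0.75, axis=0) / lib
    return int(np.argmin(np.abs(q75 - q75.mean())))


def tmm_factors(
    counts: pd.DataFrame,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    reference: str | None = None,
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors against a reference sample.

    For each sample, gene-wise log2 ratios (M) and average log2 abundances
    (A) against the reference are computed on genes nonzero in both; the top
    and bottom ``trim_M`` by M-rank and ``trim_A`` by A-rank are discarded,
    and the factor is 2 ** (precision-weighted mean of the surviving M),
    weights from the binomial delta method. Factors are rescaled to
    geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    values = counts.to_numpy(dtype=float)
    lib = values.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    if reference is None:
        ref = _tmm_reference_column(values)
    else:
        ref = counts.columns.get_loc(reference)

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        factors[j] = 2.0 ** _tmm_log_ratio(
            values[:, j], values[:, ref], lib[j], lib[ref], trim_M, trim_A
        )
    factors /= np.exp(np.mean(np.log(factors)))
    tmm = pd.Series(factors, index=counts.columns, name="tmm")
    lib_size = pd.Series(lib, index=counts.columns, name="lib_size")
    return NormFactors(lib_size=lib_size, tmm=tmm)


def _tmm_log_ratio(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_M: float,
    trim_A: float,
) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError("sample shares no nonzero genes with the reference")
    o, r = obs[keep], ref[keep]
    M = np.log2((o / n_obs) / (r / n_ref))
    A = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    n = M.size
    from scipy.stats import rankdata

    rM, rA = rankdata(M), rankdata(A)
    loM, hiM = np.floor(n * trim_M) + 1, n - np.floor(n * trim_M)
    loA, hiA = np.floor(n * trim_A) + 1, n - np.floor(n * trim_A)
    kept = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not kept.any() or w[kept].sum() == 0:
        return 0.0
    f = float(np.sum(M[kept] / w[kept]) / np.sum(1.0 / w[kept]))
    return 0.0 if abs(f) < 1e-10 else f


def log_cpm(
    counts: pd.DataFrame, factors: NormFactors, prior_count: float = 0.5
) -> pd.DataFrame:
    """log2 counts per million on effective library sizes, with a prior count.

    ``log2((count + prior) / (effective_lib + 2 * prior) * 1e6)`` — strictly
    increasing in the count for a fixed sample and invariant to jointly
    doubling counts and library size.
    """
    eff = factors.effective_lib_size.reindex(counts.columns)
    if (eff <= 0).any() or eff.isna().any():
        raise ValueError("nonpositive or missing effective library size")
    denom = eff.to_numpy() + 2.0 * prior_count
    return pd.DataFrame(
        np.log2((counts.to_numpy(dtype=float) + prior_count) / denom * 1e6),
        index=counts.index,
        columns=counts.columns,
    )


def prepare_counts(
    counts: pd.DataFrame,
    low_threshold: int = DEFAULT_LOW_THRESHOLD,
    max_low_fraction: float = DEFAULT_MAX_LOW_FRACTION,
    k: int = 5,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
) -> tuple[pd.DataFrame, NormFactors, pd.DataFrame]:
    """Standard preprocessing chain for one cohort.

    filter -> mask -> KNN impute -> round to integer (the NB likelihood
    needs integer counts; the imputed fraction is small, so rounding error
    is below count noise) -> TMM -> log-CPM. Returns (integer counts,
    normalization factors, log-CPM matrix).
    """
    filtered = filter_samples(counts, low_threshold, max_low_fraction)
    imputed = knn_impute(mask_low_counts(filtered, low_threshold), k=k)
    counts_int = imputed.round().astype(int)
    factors = tmm_factors(counts_int, trim_M, trim_A)
    return counts_int, factors, log_cpm(counts_int, factors)


@dataclass(frozen=True)
class PCAReport:
    coordinates: pd.DataFrame  # samples x (PC1, PC2)
    flagged: list[str]
    sd_limit: float


def pca_outlier_check(log_expr: pd.DataFrame, sd_limit: float = 3.0) -> PCAReport:
    """Flag samples beyond ``sd_limit`` SDs on PC1 or PC2; report only."""
    if log_expr.shape[1] < 3:
        raise ValueError("PCA outlier check needs at least 3 samples")
    X = log_expr.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :2] * S[:2]
    sds = coords.std(axis=0, ddof=1)
    sds[sds == 0] = 1.0
    flagged_mask = (np.abs(coords) > sd_limit * sds).any(axis=1)
    coordinates = pd.DataFrame(coords, index=log_expr.columns, columns=["PC1", "PC2"])
    flagged = list(log_expr.columns[flagged_mask])
    if flagged:
        log.info("pca_outlier_check: flagged samples %s", flagged)
    return PCAReport(coordinates=coordinates, flagged=flagged, sd_limit=sd_limit)
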