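"""Sex-adjusted negative-binomial differential expression.

Per-gene NB log-link GLMs are fitted by iteratively reweighted least squares,
vectorized across genes (one design matrix, gene-specific working weights),
with the log effective library size as offset. Dispersions are estimated by
Cox-Reid adjusted profile likelihood (APL): a common dispersion maximizing
the mean APL across genes, gene-wise maximizers, and shrunk values that
maximize the gene APL plus a ``prior_df``-weighted common APL — small-sample
designs underestimate dispersion, so shrinkage toward the common value with a
substantial prior weight is the default. Contrast p-values come from the
likelihood-ratio chi-square test (1 df); multiple testing is
Benjamini-Hochberg within contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .preprocess import NormFactors

log = logging.getLogger(__name__)

LN2 = np.log(2.0)
MAX_ABS_LOG2FC = 30.0  # coefficient clamp for separated / all-zero groups
_BETA_CLAMP = MAX_ABS_LOG2FC * LN2
_PHI_GRID = np.geomspace(1e-4, 4.0, 25)
_POISSON_PHI = 1e-8  # below this the Poisson likelihood is used


@dataclass(frozen=True)
class DesignSpec:
    """Design matrix with a designated contrast column.

    ``matrix`` is samples x coefficients; ``contrast_index`` names the single
    coefficient whose likelihood-ratio test and log2 fold change are reported.
    """

    matrix: np.ndarray
    coef_names: tuple[str, ...]
    contrast_index: int
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.matrix, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.coef_names):
            raise ValueError("design matrix shape inconsistent with coefficient names")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                "design matrix is rank deficient (confounded covariates): "
                f"columns {self.coef_names}"
            )
        if not 0 <= self.contrast_index < X.shape[1]:
            raise ValueError("contrast_index out of range")

    @property
    def reduced_matrix(self) -> np.ndarray:
        return np.delete(self.matrix, self.contrast_index, axis=1)

    @property
    def residual_df(self) -> int:
        return self.matrix.shape[0] - self.matrix.shape[1]


def make_design(
    meta: pd.DataFrame,
    group: pd.Series,
    adjust_sex: bool = True,
    pair_by_subject: bool = False,
) -> DesignSpec:
    """Build [intercept | blocks/sex | group] for the samples in ``meta``.

    ``group`` is a boolean Series (True = second level of the contrast).
    Paired designs add subject indicator columns; sex is then omitted
    because it is constant within subject and hence collinear.
    """
    n = len(meta)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    if pair_by_subject:
        subjects = sorted(meta["subject_id"].unique())
        for s in subjects[1:]:
            cols.append((meta["subject_id"] == s).to_numpy(float))
            names.append(f"subject[{s}]")
    elif adjust_sex:
        sex = (meta["sex"] == "W").to_numpy(float)
        if sex.min() == sex.max():
            # single-sex subset: the covariate is constant and carries no
            # information, so it is dropped rather than breaking the fit
            log.info("make_design: sex constant in this contrast; covariate dropped")
        else:
            cols.append(sex)
            names.append("sexW")
    cols.append(group.reindex(meta.index).to_numpy(float))
    names.append("group")
    return DesignSpec(
        matrix=np.column_stack(cols),
        coef_names=tuple(names),
        contrast_index=len(names) - 1,
        sample_ids=tuple(meta.index),
    )


@dataclass(frozen=True)
class DispersionEstimates:
    common: float
    genewise: pd.Series
    shrunk: pd.Series
    prior_df: float


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB log likelihood; phi broadcast per gene (column vector)."""
    phi = np.broadcast_to(np.atleast_1d(phi)[:, None], Y.shape)
    mu = np.clip(mu, 1e-12, None)
    pois = Y * np.log(mu) - mu - gammaln(Y + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / phi
        nb = (
            gammaln(Y + inv)
            - gammaln(inv)
            - gammaln(Y + 1.0)
            + Y * np.log(phi * mu)
            - (Y + inv) * np.log1p(phi * mu)
        )
    ll = np.where(phi <= _POISSON_PHI, pois, nb)
    return ll.sum(axis=1)


def _irls_fit(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float | np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized NB IRLS: returns (beta G x P, mu G x N, loglik G, converged G)."""
    G, N = Y.shape
    P = X.shape[1]
    phi_col = np.broadcast_to(np.atleast_1d(np.asarray(phi, float)), (G,))[:, None]
    if beta0 is None:
        # one WLS step on the log-linearized response
        z0 = np.log(Y + 0.5) - offset[None, :]
        XtX = X.T @ X + 1e-10 * np.eye(P)
        beta = (np.linalg.solve(XtX, X.T @ z0.T)).T
    else:
        beta = beta0.copy()
    beta = np.clip(beta, -_BETA_CLAMP, _BETA_CLAMP)
    eye = 1e-10 * np.eye(P)
    ll_old = np.full(G, -np.inf)
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset[None, :], -40.0, 40.0)
        mu = np.exp(eta)
        W = mu / (1.0 + phi_col * mu)
        z = (eta - offset[None, :]) + (Y - mu) / np.clip(mu, 1e-12, None)
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X) + eye
        XtWz = np.einsum("np,gn,gn->gp", X, W, z)
        beta_new = np.clip(
            np.linalg.solve(XtWX, XtWz[..., None])[..., 0], -_BETA_CLAMP, _BETA_CLAMP
        )
        active = ~converged
        beta[active] = beta_new[active]
        eta = np.clip(beta @ X.T + offset[None, :], -40.0, 40.0)
        mu = np.exp(eta)
        ll = _nb_loglik(Y, mu, phi_col[:, 0])
        converged |= np.abs(ll - ll_old) < tol * (np.abs(ll) + 1.0)
        ll_old = ll
        if converged.all():
            break
    eta = np.clip(beta @ X.T + offset[None, :], -40.0, 40.0)
    mu = np.exp(eta)
    return beta, mu, _nb_loglik(Y, mu, phi_col[:, 0]), converged


def _adjusted_profile_loglik(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cox-Reid APL per gene at a single dispersion; returns (apl, beta)."""
    beta, mu, ll, _ = _irls_fit(Y, X, offset, phi, beta0=beta0)
    W = mu / (1.0 + phi * mu)
    XtWX = np.einsum("np,gn,nq->gpq", X, W, X) + 1e-10 * np.eye(X.shape[1])
    _, logdet = np.linalg.slogdet(XtWX)
    return ll - 0.5 * logdet, beta


def _quadratic_refine(grid: np.ndarray, values: np.ndarray, idx: int) -> float:
    """Parabolic max in log-phi around a grid argmax (interior points only)."""
    if idx == 0 or idx == len(grid) - 1:
        return float(grid[idx])
    x = np.log(grid[idx - 1 : idx + 2])
    y = values[idx - 1 : idx + 2]
    denom = (y[0] - 2 * y[1] + y[2])
    if denom >= 0 or not np.isfinite(denom):
        return float(grid[idx])
    xstar = x[1] - 0.5 * (y[2] - y[0]) / denom * (x[2] - x[0]) / 2.0
    xstar = float(np.clip(xstar, x[0], x[2]))
    return float(np.exp(xstar))


def estimate_dispersions(
    counts: pd.DataFrame,
    design: DesignSpec,
    offsets: NormFactors,
    prior_df: float = 10.0,
    phi_grid: np.ndarray = _PHI_GRID,
) -> DispersionEstimates:
    """Common, gene-wise, and shrunk NB dispersions by Cox-Reid APL.

    The shrunk value maximizes ``APL_g(phi) + (prior_df / residual_df) *
    mean_APL(phi)`` and is constrained to lie between the gene-wise and
    common maximizers, so ``prior_df -> inf`` drives every gene to the
    common value.
    """
    if prior_df <= 0:
        raise ValueError("prior_df must be positive")
    Y, X, offset = _align(counts, design, offsets)
    all_zero = Y.sum(axis=1) == 0
    if all_zero.any():
        raise ValueError(
            f"{int(all_zero.sum())} all-zero genes; filter before dispersion estimation"
        )
    G = Y.shape[0]
    K = len(phi_grid)
    apl = np.empty((G, K))
    beta = None
    for k, phi in enumerate(phi_grid):  # warm-start along the grid
        apl[:, k], beta = _adjusted_profile_loglik(Y, X, offset, float(phi), beta)

    mean_apl = apl.mean(axis=0)
    k_common = int(np.argmax(mean_apl))
    common = _quadratic_refine(phi_grid, mean_apl, k_common)

    k_gene = np.argmax(apl, axis=1)
    genewise = np.array(
        [_quadratic_refine(phi_grid, apl[g], k_gene[g]) for g in range(G)]
    )

    weight = prior_df / max(design.residual_df, 1)
    obj = apl + weight * mean_apl[None, :]
    k_shrunk = np.argmax(obj, axis=1)
    shrunk = np.array(
        [_quadratic_refine(phi_grid, obj[g], k_shrunk[g]) for g in range(G)]
    )
    lo = np.minimum(genewise, common)
    hi = np.maximum(genewise, common)
    shrunk = np.clip(shrunk, lo, hi)

    idx = counts.index
    return DispersionEstimates(
        common=float(common),
        genewise=pd.Series(genewise, index=idx, name="phi_genewise"),
        shrunk=pd.Series(shrunk, index=idx, name="phi_shrunk"),
        prior_df=float(prior_df),
    )


def _align(
    counts: pd.DataFrame, design: DesignSpec, offsets: NormFactors
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ids = list(design.sample_ids)
    Y = counts[ids].to_numpy(dtype=float)
    if (Y < 0).any():
        raise ValueError("negative counts")
    eff = offsets.effective_lib_size.reindex(ids)
    if eff.isna().any() or (eff <= 0).any():
        raise ValueError("missing or nonpositive effective library sizes")
    return Y, np.asarray(design.matrix, dtype=float), np.log(eff.to_numpy())


def fit_contrast(
    counts: pd.DataFrame,
    design: DesignSpec,
    dispersions: DispersionEstimates,
    offsets: NormFactors,
) -> pd.DataFrame:
    """Per-gene contrast test: log2FC, LRT p-value, BH FDR, direction.

    Non-convergent genes are flagged and assigned p = 1; coefficients are
    clamped at |log2FC| <= 30 for separated groups.
    """
    Y, X, offset = _align(counts, design, offsets)
    phi = dispersions.shrunk.reindex(counts.index).to_numpy()
    if np.isnan(phi).any():
        raise ValueError("dispersions missing for some genes")
    beta_full, _, ll_full, conv_full = _irls_fit(Y, X, offset, phi)
    Xr = design.reduced_matrix
    _, _, ll_red, conv_red = _irls_fit(Y, Xr, offset, phi)
    lrt = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
    pval = chi2.sf(lrt, df=1)
    converged = conv_full & conv_red
    pval = np.where(converged, pval, 1.0)
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    log2fc = np.clip(
        beta_full[:, design.contrast_index] / LN2, -MAX_ABS_LOG2FC, MAX_ABS_LOG2FC
    )
    return pd.DataFrame(
        {
            "log2FC": log2fc,
            "PV": pval,
            "FDR": bh_adjust(pval),
            "direction": np.where(log2fc > 0, "up", "down"),
            "converged": converged,
        },
        index=counts.index.rename("gene"),
    )


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    result: pd.DataFrame, p_max: float = 0.05, lfc_min: float = 0.7
) -> pd.DataFrame:
    """DEGs at strict thresholds: PV < p_max and |log2FC| > lfc_min."""
    keep = (result["PV"] < p_max) & (result["log2FC"].abs() > lfc_min)
    return result.loc[keep]


def testable_genes(counts: pd.DataFrame, max_zero_fraction: float = 0.9) -> pd.DataFrame:
    """Drop genes with zero counts in more than ``max_zero_fraction`` of samples."""
    frac_zero = (counts == 0).mean(axis=1)
    kept = counts.loc[frac_zero <= max_zero_fraction]
    return kept
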