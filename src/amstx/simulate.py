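"""Synthetic two-cohort paired SL/HA RNA-seq count studies with planted signal.

The generator emulates a two-cohort altitude-exposure design: each subject
contributes a sea-level (SL) and a high-altitude (HA) PBMC sample, a subset of
subjects develops severe acute mountain sickness (AMS-C >= 1.4), and four
disjoint gene sets carry planted log2 fold changes matching the four
biomarker contrasts:

* ``diagnostic``  — shifted only in (severe, HA) samples;
* ``predictive``  — shifted in severe subjects at both timepoints;
* ``pathogenic``  — shifted SL->HA in severe subjects;
* ``protective``  — shifted SL->HA in every subject.

Counts are negative binomial with mean ``libsize x gene mean x planted
effects x sex effect`` and a global dispersion phi (variance = mu + phi mu^2).
Attrition entries remove individual samples, never genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import SEVERE_AMS_C

CATEGORIES = ("diagnostic", "predictive", "pathogenic", "protective")


def ams_severity(ams_c: float) -> bool:
    """Severe AMS iff the AMS-C cerebral factor score is >= 1.4 (inclusive)."""
    if ams_c < 0:
        raise ValueError(f"AMS-C score must be nonnegative, got {ams_c}")
    return ams_c >= SEVERE_AMS_C


@dataclass(frozen=True)
class SignalSpec:
    """One planted gene set: size, |log2FC| magnitude, fraction upregulated."""

    n_genes: int = 0
    log2fc: float = 0.0
    frac_up: float = 0.5

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("signal set size must be nonnegative")
        if self.log2fc < 0:
            raise ValueError("log2FC magnitude must be nonnegative")
        if not 0.0 <= self.frac_up <= 1.0:
            raise ValueError("frac_up must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """One cohort: subject count, severe-AMS count, sex mix, and attrition.

    ``attrition`` lists ``(subject_index, timepoint)`` pairs whose sample is
    never emitted, mimicking dropouts and QC failures.
    """

    name: str
    n_subjects: int
    n_severe: int
    frac_women: float = 0.25
    attrition: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.n_severe > self.n_subjects:
            raise ValueError("n_severe cannot exceed n_subjects")
        if self.n_severe < 2 or self.n_subjects - self.n_severe < 2:
            raise ValueError("each cohort needs >= 2 subjects per AMS group")
        if not 0.0 <= self.frac_women <= 1.0:
            raise ValueError("frac_women must lie in [0, 1]")
        for idx, tp in self.attrition:
            if not 0 <= idx < self.n_subjects:
                raise ValueError(f"attrition references invalid subject {idx}")
            if tp not in ("SL", "HA"):
                raise ValueError(f"attrition timepoint must be SL or HA, got {tp}")


def default_cohorts() -> tuple[CohortSpec, CohortSpec]:
    """Two cohorts replicating the study's sample accounting.

    PikesPeak: 18 subjects (5 severe), fully paired -> 36 samples.
    Chamber: 10 subjects (5 severe) with attrition -> 9 SL + 7 HA samples,
    leaving 4 severe subjects with an HA sample (the published test split
    of 4 positives / 12 negatives).
    """
    return (
        CohortSpec("PikesPeak", n_subjects=18, n_severe=5, frac_women=5 / 18),
        CohortSpec(
            "Chamber",
            n_subjects=10,
            n_severe=5,
            frac_women=2 / 10,
            attrition=((4, "HA"), (5, "HA"), (6, "HA"), (7, "SL")),
        ),
    )


def default_signal_sets() -> dict[str, SignalSpec]:
    # magnitudes anchored to the published candidate-gene log2FCs (0.7-3.5)
    return {
        "diagnostic": SignalSpec(20, 2.0),
        "predictive": SignalSpec(15, 1.5),
        "pathogenic": SignalSpec(25, 1.5),
        "protective": SignalSpec(15, 1.2),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full simulation specification; see module docstring for semantics."""

    n_genes: int = 2000
    cohorts: tuple[CohortSpec, ...] = field(default_factory=default_cohorts)
    baseline_log_mean_mu: float = 5.0  # natural-log gene abundance
    baseline_log_mean_sd: float = 1.2
    dispersion: float = 0.1  # NB phi, variance = mu + phi mu^2
    # when set (> 1), gene-wise phi ~ inverse-gamma(shape) with mean `dispersion`
    dispersion_shape: float | None = None
    libsize_log_sd: float = 0.15
    sex_effect_lfc: float = 1.0
    n_sex_genes: int = 50
    signal_sets: dict[str, SignalSpec] = field(default_factory=default_signal_sets)
    low_count_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.dispersion <= 0:
            raise ValueError("n_genes and dispersion must be positive")
        if self.baseline_log_mean_sd < 0 or self.libsize_log_sd < 0:
            raise ValueError("scale parameters must be nonnegative")
        if self.dispersion_shape is not None and self.dispersion_shape <= 1:
            raise ValueError("dispersion_shape must exceed 1 (finite mean)")
        if not 0.0 <= self.low_count_fraction < 1.0:
            raise ValueError("low_count_fraction must lie in [0, 1)")
        unknown = set(self.signal_sets) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown signal categories: {sorted(unknown)}")
        n_signal = sum(s.n_genes for s in self.signal_sets.values())
        if n_signal + self.n_sex_genes > self.n_genes:
            raise ValueError(
                "signal sets plus sex-effect genes exceed n_genes "
                f"({n_signal} + {self.n_sex_genes} > {self.n_genes})"
            )

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StudyData:
    """Generated study: per-cohort count matrices, metadata, planted truth."""

    counts: dict[str, pd.DataFrame]  # cohort name -> genes x samples
    meta: pd.DataFrame  # one row per emitted sample
    planted: dict[str, dict[str, float]]  # category -> {gene_id: signed log2FC}
    config: SimConfig


def _assign_signal_genes(
    config: SimConfig, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Disjoint planted gene sets with signed log2 effects (deterministic order)."""
    planted: dict[str, dict[str, float]] = {}
    cursor = 0
    for cat in CATEGORIES:
        spec = config.signal_sets.get(cat, SignalSpec())
        genes = {}
        for j in range(spec.n_genes):
            gid = f"G{cursor + j:05d}"
            sign = 1.0 if rng.random() < spec.frac_up else -1.0
            genes[gid] = sign * spec.log2fc
        planted[cat] = genes
        cursor += spec.n_genes
    return planted


def _cohort_meta(cohort: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Per-sample metadata for one cohort; severe subjects come first."""
    n_women = int(round(cohort.frac_women * cohort.n_subjects))
    sexes = np.array(["W"] * n_women + ["M"] * (cohort.n_subjects - n_women))
    rng.shuffle(sexes)
    rows = []
    dropped = set(cohort.attrition)
    for i in range(cohort.n_subjects):
        severe = i < cohort.n_severe
        if severe:
            ams_c = SEVERE_AMS_C + abs(rng.normal(0.4, 0.3))
        else:
            ams_c = rng.uniform(0.0, 1.3)
        subject = f"{cohort.name}_S{i:02d}"
        for tp in ("SL", "HA"):
            if (i, tp) in dropped:
                continue
            rows.append(
                {
                    "sample_id": f"{subject}_{tp}",
                    "cohort": cohort.name,
                    "subject_id": subject,
                    "timepoint": tp,
                    "sex": sexes[i],
                    "ams_c": round(float(ams_c), 3),
                    "severe_ams": severe,
                }
            )
    meta = pd.DataFrame(rows)
    meta = meta.set_index("sample_id", drop=False)
    meta.index.name = None
    return meta


def generate_study(config: SimConfig) -> StudyData:
    """Draw the full two-cohort study; reproducible for a fixed config seed."""
    rng = np.random.default_rng(config.seed)
    gene_ids = np.array([f"G{i:05d}" for i in range(config.n_genes)])

    planted = _assign_signal_genes(config, rng)
    n_signal = sum(len(g) for g in planted.values())
    sex_genes = set(gene_ids[n_signal : n_signal + config.n_sex_genes])

    base_log_mean = rng.normal(
        config.baseline_log_mean_mu, config.baseline_log_mean_sd, config.n_genes
    )
    # planted genes are hemoglobin-like: abundant, so the planted fold change
    # is identifiable rather than censored by the low-count mask downstream
    if n_signal:
        base_log_mean[:n_signal] = config.baseline_log_mean_mu + np.abs(
            rng.normal(0.0, config.baseline_log_mean_sd, n_signal)
        )
    # force a tail of genes into the <10-count regime to exercise imputation,
    # drawn from the non-signal remainder so planted effects stay detectable
    n_low = int(config.low_count_fraction * config.n_genes)
    if n_low:
        free = np.arange(n_signal + config.n_sex_genes, config.n_genes)
        low_idx = rng.choice(free, size=min(n_low, free.size), replace=False)
        base_log_mean[low_idx] = np.log(rng.uniform(0.5, 4.0, low_idx.size))

    if config.dispersion_shape is None:
        phi = np.full(config.n_genes, config.dispersion)
    else:  # inverse-gamma gene-wise dispersions with mean `dispersion`
        shape = config.dispersion_shape
        phi = (config.dispersion * (shape - 1.0)) / rng.gamma(shape, 1.0, config.n_genes)

    log2fc = {cat: np.zeros(config.n_genes) for cat in CATEGORIES}
    pos = {g: i for i, g in enumerate(gene_ids)}
    for cat, genes in planted.items():
        for gid, effect in genes.items():
            log2fc[cat][pos[gid]] = effect
    sex_mask = np.array([g in sex_genes for g in gene_ids], dtype=float)

    counts: dict[str, pd.DataFrame] = {}
    metas = []
    for cohort in config.cohorts:
        meta = _cohort_meta(cohort, rng)
        metas.append(meta)
        libsize = np.exp(rng.normal(0.0, config.libsize_log_sd, len(meta)))
        cols = np.empty((config.n_genes, len(meta)), dtype=np.int64)
        for j, (_, row) in enumerate(meta.iterrows()):
            severe, ha = row["severe_ams"], row["timepoint"] == "HA"
            effect = np.zeros(config.n_genes)
            if severe and ha:
                effect += log2fc["diagnostic"]
            if severe:
                effect += log2fc["predictive"]
            if severe and ha:
                effect += log2fc["pathogenic"]
            if ha:
                effect += log2fc["protective"]
            if row["sex"] == "W":
                effect += config.sex_effect_lfc * sex_mask
            mu = libsize[j] * np.exp(base_log_mean) * np.exp2(effect)
            # NB(mu, phi) as gamma-poisson: shape 1/phi, scale phi*mu
            lam = rng.gamma(1.0 / phi, phi * mu)
            cols[:, j] = rng.poisson(lam)
        counts[cohort.name] = pd.DataFrame(
            cols, index=gene_ids, columns=meta["sample_id"].to_numpy()
        )
    meta_all = pd.concat(metas)
    return StudyData(counts=counts, meta=meta_all, planted=planted, config=config)
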