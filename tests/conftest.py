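import logging

import numpy as np
import pandas as pd
import pytest

from amstx import biomarkers, preprocess, simulate

logging.getLogger("amstx").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_study():
    """One default two-cohort study, shared read-only across tests."""
    return simulate.generate_study(simulate.SimConfig(seed=11))


@pytest.fixture(scope="session")
def prepared_study(default_study):
    """Preprocessed cohorts: name -> (integer counts, NormFactors, log-CPM)."""
    return {
        name: preprocess.prepare_counts(mat)
        for name, mat in default_study.counts.items()
    }


def run_diagnostic_replication(config):
    """Full per-cohort DE + cross-cohort replication for the diagnostic contrast."""
    study = simulate.generate_study(config)
    results = []
    spec = biomarkers.ContrastSpec.for_category("diagnostic")
    for name, mat in study.counts.items():
        counts_int, factors, _ = preprocess.prepare_counts(mat)
        meta_c = study.meta[study.meta["cohort"] == name]
        results.append(
            biomarkers.run_contrast(counts_int, meta_c, spec, cohort=name, offsets=factors)
        )
    return study, biomarkers.common_degs(*results, category="diagnostic")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_counts(rng, n_genes=60, n_samples=4, lam_range=(5, 400)) -> pd.DataFrame:
    """Small random integer count matrix for oracle comparisons."""
    lam = rng.uniform(*lam_range, size=(n_genes, 1))
    vals = rng.poisson(lam * rng.uniform(0.7, 1.4, size=n_samples))
    return pd.DataFrame(
        vals,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
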