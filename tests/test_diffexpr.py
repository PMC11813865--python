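"""NB-GLM differential expression: dispersion estimation, contrast fitting,
BH correction and DEG calling, with simulation and analytic oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import bh_stepup_bruteforce

from amstx import diffexpr
from amstx.diffexpr import DesignSpec, DispersionEstimates
from amstx.preprocess import NormFactors


def unit_factors(sample_ids, lib=None):
    lib = pd.Series(1e6 if lib is None else lib, index=sample_ids, dtype=float)
    return NormFactors(lib_size=lib, tmm=pd.Series(1.0, index=sample_ids))


def two_group_design(n_per_group, with_sex=False):
    n = 2 * n_per_group
    ids = tuple(f"s{i}" for i in range(n))
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "subject_id": ids,
            "sex": (["M", "W"] * n)[:n] if with_sex else ["M"] * n,
        },
        index=ids,
    )
    group = pd.Series([False] * n_per_group + [True] * n_per_group, index=ids)
    return diffexpr.make_design(meta, group, adjust_sex=with_sex)


def nb_counts(rng, mu, phi, size):
    if phi <= 0:
        return rng.poisson(mu, size=size)
    return rng.poisson(rng.gamma(1.0 / phi, phi * mu, size=size))


class TestDesign:
    def test_confounded_covariate_rejected(self):
        ids = ["a", "b", "c", "d"]
        meta = pd.DataFrame(
            {"sample_id": ids, "subject_id": ids, "sex": ["M", "M", "W", "W"]},
            index=ids,
        )
        group = pd.Series([False, False, True, True], index=ids)
        with pytest.raises(ValueError, match="rank deficient"):
            diffexpr.make_design(meta, group, adjust_sex=True)

    def test_paired_design_blocks_by_subject(self):
        ids = [f"s{i}" for i in range(6)]
        meta = pd.DataFrame(
            {
                "sample_id": ids,
                "subject_id": ["p1", "p1", "p2", "p2", "p3", "p3"],
                "sex": ["M"] * 6,
            },
            index=ids,
        )
        group = pd.Series([False, True] * 3, index=ids)
        design = diffexpr.make_design(meta, group, pair_by_subject=True)
        assert design.matrix.shape == (6, 4)  # intercept + 2 subjects + group
        assert design.coef_names[-1] == "group"


class TestDispersions:
    def test_poisson_counts_give_near_zero_common_dispersion(self):
        rng = np.random.default_rng(0)
        design = two_group_design(10)
        counts = pd.DataFrame(
            rng.poisson(150, size=(500, 20)),
            columns=list(design.sample_ids),
        )
        disp = diffexpr.estimate_dispersions(
            counts, design, unit_factors(design.sample_ids, lib=counts.sum(axis=0))
        )
        assert disp.common < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(1)
        design = two_group_design(10)
        counts = pd.DataFrame(
            nb_counts(rng, 200.0, 0.2, size=(500, 20)),
            columns=list(design.sample_ids),
        )
        disp = diffexpr.estimate_dispersions(
            counts, design, unit_factors(design.sample_ids, lib=counts.sum(axis=0))
        )
        assert 0.1 <= disp.common <= 0.3

    def test_huge_prior_df_collapses_to_common(self):
        rng = np.random.default_rng(2)
        design = two_group_design(6)
        counts = pd.DataFrame(
            nb_counts(rng, 120.0, 0.1, size=(120, 12)),
            columns=list(design.sample_ids),
        )
        factors = unit_factors(design.sample_ids, lib=counts.sum(axis=0))
        disp = diffexpr.estimate_dispersions(counts, design, factors, prior_df=1e6)
        assert np.max(np.abs(disp.shrunk.to_numpy() - disp.common)) < 1e-4

    def test_shrunk_lies_between_genewise_and_common(self):
        rng = np.random.default_rng(3)
        design = two_group_design(8)
        counts = pd.DataFrame(
            nb_counts(rng, 90.0, 0.15, size=(150, 16)),
            columns=list(design.sample_ids),
        )
        factors = unit_factors(design.sample_ids, lib=counts.sum(axis=0))
        disp = diffexpr.estimate_dispersions(counts, design, factors, prior_df=5)
        lo = np.minimum(disp.genewise, disp.common) - 1e-12
        hi = np.maximum(disp.genewise, disp.common) + 1e-12
        assert ((disp.shrunk >= lo) & (disp.shrunk <= hi)).all()


class TestFitContrast:
    def _fit(self, counts, design, phi=0.05, lib=None):
        lib = counts.sum(axis=0) if lib is None else lib
        factors = unit_factors(design.sample_ids, lib=lib)
        disp = DispersionEstimates(
            common=phi,
            genewise=pd.Series(phi, index=counts.index),
            shrunk=pd.Series(phi, index=counts.index),
            prior_df=10,
        )
        return diffexpr.fit_contrast(counts, design, disp, factors)

    def test_twofold_gene_estimates_log2fc_one(self):
        rng = np.random.default_rng(4)
        design = two_group_design(40)
        counts = pd.DataFrame(
            np.concatenate(
                [
                    nb_counts(rng, 1000.0, 0.01, size=(30, 40)),
                    nb_counts(rng, 2000.0, 0.01, size=(30, 40)),
                ],
                axis=1,
            ),
            columns=list(design.sample_ids),
        )
        res = self._fit(counts, design, phi=0.01, lib=1.0)
        # equal offsets, group B at exactly twice the mean
        assert np.abs(res["log2FC"].mean() - 1.0) < 0.05

    def test_contrast_sign_flip_negates_log2fc(self):
        rng = np.random.default_rng(5)
        design = two_group_design(6)
        flipped = DesignSpec(
            matrix=np.column_stack(
                [design.matrix[:, 0], 1 - design.matrix[:, -1]]
            ),
            coef_names=("intercept", "group"),
            contrast_index=1,
            sample_ids=design.sample_ids,
        )
        counts = pd.DataFrame(
            nb_counts(rng, 100.0, 0.1, size=(50, 12)),
            columns=list(design.sample_ids),
        )
        a = self._fit(counts, design)
        b = self._fit(counts, flipped)
        assert np.allclose(a["log2FC"], -b["log2FC"], atol=1e-6)
        assert np.allclose(a["PV"], b["PV"], atol=1e-9)

    def test_poisson_limit_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        design = two_group_design(5)
        counts = pd.DataFrame(
            rng.poisson([80, 200, 45], size=(10, 3)).T,
            columns=list(design.sample_ids),
        )
        res = self._fit(counts, design, phi=0.0)
        X = design.matrix
        Xr = design.reduced_matrix
        for g in range(3):
            y = counts.iloc[g].to_numpy()
            full = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            red = sm.GLM(y, Xr, family=sm.families.Poisson()).fit()
            lrt = 2 * (full.llf - red.llf)
            from scipy.stats import chi2

            assert res["PV"].iloc[g] == pytest.approx(chi2.sf(lrt, 1), abs=1e-6)
            assert res["log2FC"].iloc[g] == pytest.approx(
                full.params[-1] / np.log(2), abs=1e-6
            )

    def test_all_zero_group_clamped_and_flagged(self):
        design = two_group_design(3)
        counts = pd.DataFrame(
            [[40, 50, 45, 0, 0, 0]], columns=list(design.sample_ids)
        )
        res = self._fit(counts, design, phi=0.1, lib=1000.0)
        assert abs(res["log2FC"].iloc[0]) <= diffexpr.MAX_ABS_LOG2FC


class TestBH:
    def test_hand_stepup_example(self):
        out = diffexpr.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert diffexpr.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        assert np.allclose(diffexpr.bh_adjust([1.0] * 5), 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust([])

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_bruteforce_stepup(self, pvals):
        p = np.array(pvals)
        assert np.allclose(diffexpr.bh_adjust(p), bh_stepup_bruteforce(p), atol=1e-12)

    def test_monotone_on_sorted_sequence(self, rng):
        p = np.sort(rng.uniform(size=200))
        adj = diffexpr.bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()


class TestCallDegs:
    @pytest.mark.parametrize(
        "pv,lfc,called",
        [
            (4.43e-2, 0.755, True),  # marginally significant, passes both
            (0.04, 0.5, False),  # fails fold change
            (0.05, 2.0, False),  # p boundary is strict
            (0.01, 0.7, False),  # lfc boundary is strict
        ],
    )
    def test_threshold_rules(self, pv, lfc, called):
        res = pd.DataFrame(
            {"log2FC": [lfc], "PV": [pv], "FDR": [pv], "direction": ["up"]},
            index=["g"],
        )
        assert (len(diffexpr.call_degs(res)) == 1) is called

    def test_partition_by_direction(self):
        res = pd.DataFrame(
            {
                "log2FC": [1.0, -1.2, 0.1],
                "PV": [0.01, 0.02, 0.001],
                "FDR": [0.1, 0.1, 0.1],
                "direction": ["up", "down", "up"],
            },
            index=["a", "b", "c"],
        )
        degs = diffexpr.call_degs(res)
        assert set(degs.index) == {"a", "b"}
        assert degs.loc["a", "direction"] == "up"
        assert degs.loc["b", "direction"] == "down"
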