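"""The NB differential-expression engine: normalization, dispersion, Wald
contrasts, BH adjustment, DEG thresholds and FPKM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from arftargets import de
from arftargets.simulate import SimulationConfig, generate_counts, generate_design


def _counts(matrix, samples=None):
    matrix = np.asarray(matrix)
    samples = samples or [f"s{i}" for i in range(matrix.shape[1])]
    return pd.DataFrame(
        matrix, index=[f"g{i}" for i in range(matrix.shape[0])], columns=samples
    )


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        c = _counts([[10, 10], [5, 5], [100, 100]])
        assert np.allclose(de.size_factors(c), [1.0, 1.0])

    def test_doubled_sample_splits_geometrically(self):
        """B = 2*A for every gene -> factors (1/sqrt2, sqrt2)."""
        c = _counts([[10, 20], [7, 14], [100, 200], [3, 6]])
        s = de.size_factors(c)
        assert np.allclose(s, [2**-0.5, 2**0.5], rtol=1e-12)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            de.size_factors(_counts([[0, 0], [0, 0]]))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        scalars=st.lists(
            st.floats(min_value=0.2, max_value=5.0), min_size=2, max_size=6
        )
    )
    def test_recovers_scalar_multiples_of_common_profile(self, scalars):
        """Samples that are exact scalar multiples of one profile recover
        those scalars up to a global constant."""
        profile = np.array([10.0, 40.0, 160.0, 640.0, 25.0])
        mat = np.round(np.outer(profile, scalars))
        c = _counts(mat)
        s = de.size_factors(c).to_numpy()
        ratio = s / scalars
        assert np.allclose(ratio, ratio[0], rtol=0.15)


class TestBenjaminiHochberg:
    def test_hand_worked_step_up(self):
        padj = de.bh_adjust(np.array([0.01, 0.02, 0.03, 0.5]))
        assert np.allclose(padj, [0.04, 0.04, 0.04, 0.5])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        p=st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200
        )
    )
    def test_matches_independent_step_up_oracle(self, p):
        p = np.array(p)
        ours = de.bh_adjust(p)
        _, oracle, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, oracle, atol=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_monotone_and_dominates_p_in_rank_order(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=100)
        padj = de.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-15).all()
        assert (padj >= p - 1e-15).all()
        assert ((padj >= 0) & (padj <= 1)).all()


class TestDispersion:
    def _simulate(self, alpha, n_reps, n_genes, seed=0, means=(50.0, 200.0)):
        cfg = SimulationConfig(
            n_genes=n_genes,
            n_replicates=n_reps,
            class_fractions={},
            dispersion=alpha,
            baseline_mean_range=means,
            library_size_factor_range=(1.0, 1.0),
            seed=seed,
        )
        return generate_counts(cfg)

    def test_recovers_planted_dispersion(self):
        """Median estimate within 25% of the simulated alpha=0.2 at deep
        replication."""
        counts, design, _ = self._simulate(0.2, 12, 2000, seed=3)
        s = de.size_factors(counts)
        alpha = de.estimate_dispersion(counts, design, s)
        assert float(alpha.median()) == pytest.approx(0.2, rel=0.25)

    def test_poisson_data_concentrates_near_floor(self):
        rng = np.random.default_rng(0)
        design = generate_design(6)
        mu = rng.uniform(50, 500, size=500)
        counts = pd.DataFrame(
            rng.poisson(mu[:, None], size=(500, len(design))),
            index=[f"g{i}" for i in range(500)],
            columns=design.index,
        )
        s = de.size_factors(counts)
        alpha = de.estimate_dispersion(counts, design, s)
        assert float(alpha.median()) < 5e-3

    def test_constant_counts_floor(self):
        design = generate_design(3)
        counts = pd.DataFrame(
            np.full((10, len(design)), 7),
            index=[f"g{i}" for i in range(10)],
            columns=design.index,
        )
        s = de.size_factors(counts)
        alpha = de.estimate_dispersion(counts, design, s)
        assert (alpha == de.DISPERSION_FLOOR).all()

    def test_requires_replication(self):
        design = generate_design(1)
        counts = pd.DataFrame(
            np.ones((3, len(design)), dtype=int),
            index=list("abc"),
            columns=design.index,
        )
        with pytest.raises(ValueError):
            de.estimate_dispersion(counts, design, de.size_factors(counts))


class TestWaldContrast:
    def _fixture(self, seed=0, n_genes=300, **kw):
        cfg = SimulationConfig(n_genes=n_genes, class_fractions={}, seed=seed, **kw)
        counts, design, _ = generate_counts(cfg)
        s = de.size_factors(counts)
        a = de.estimate_dispersion(counts, design, s)
        return counts, design, s, a

    def test_identical_groups_give_zero_lfc(self):
        """Duplicating the same counts into both groups yields log2FC = 0
        exactly and an unremarkable p-value."""
        counts, design, s, a = self._fixture()
        dup = counts.copy()
        for r in (1, 2, 3):
            dup[f"ett_mock_r{r}"] = counts[f"WT_mock_r{r}"]
        s2 = pd.Series(1.0, index=counts.columns)
        ct = de.nb_wald_contrast(dup, design, s2, a, ("ett", "mock"), ("WT", "mock"))
        assert (ct.table["log2FC"] == 0).all()
        assert (ct.table["p"] > 0.5).all()

    def test_antisymmetry_under_group_swap(self):
        counts, design, s, a = self._fixture(seed=2)
        fwd = de.nb_wald_contrast(counts, design, s, a, ("ett", "IAA"), ("WT", "IAA"))
        rev = de.nb_wald_contrast(counts, design, s, a, ("WT", "IAA"), ("ett", "IAA"))
        assert np.allclose(fwd.table["log2FC"], -rev.table["log2FC"], atol=1e-8)
        assert np.allclose(fwd.table["p"], rev.table["p"], atol=1e-10)

    def test_recovers_planted_fold_change(self):
        """Mean estimated log2FC within +-0.3 of the planted 2.0 over 500
        planted genes."""
        cfg = SimulationConfig(
            n_genes=1000,
            class_fractions={"ETT_specific": 0.5},
            dispersion=0.1,
            seed=4,
        )
        counts, design, truth = generate_counts(cfg)
        s = de.size_factors(counts)
        a = de.estimate_dispersion(counts, design, s)
        ct = de.nb_wald_contrast(counts, design, s, a, ("ett", "mock"), ("WT", "mock"))
        planted = truth.table[truth.table["class_label"] == "ETT_specific"]
        est = ct.table.loc[planted.index, "log2FC"]
        true = planted[f"true_lfc_ett_vs_WT_mock"]
        assert float((est - true).mean()) == pytest.approx(0.0, abs=0.3)

    def test_matches_statsmodels_glm(self):
        """Estimates and Wald statistics agree with an independent NB-GLM
        fit (statsmodels, log link, size-factor offsets, fixed alpha)."""
        import statsmodels.api as sm

        counts, design, s, a = self._fixture(seed=5, n_genes=40)
        ct = de.nb_wald_contrast(counts, design, s, a, ("ett", "mock"), ("WT", "mock"))
        ids_a = design.index[(design.genotype == "ett") & (design.treatment == "mock")]
        ids_b = design.index[(design.genotype == "WT") & (design.treatment == "mock")]
        ids = list(ids_a) + list(ids_b)
        X = np.column_stack([np.ones(6), [1, 1, 1, 0, 0, 0]])
        offset = np.log(s.reindex(ids).to_numpy())
        for gene in counts.index[:25]:
            y = counts.loc[gene, ids].to_numpy()
            if y.sum() == 0 or y[:3].sum() == 0 or y[3:].sum() == 0:
                continue
            fam = sm.families.NegativeBinomial(alpha=float(a[gene]))
            fit = sm.GLM(y, X, family=fam, offset=offset).fit()
            lfc_sm = fit.params[1] / np.log(2)
            z_sm = fit.params[1] / fit.bse[1]
            assert ct.table.at[gene, "log2FC"] == pytest.approx(lfc_sm, abs=1e-4)
            assert ct.table.at[gene, "stat"] == pytest.approx(z_sm, rel=1e-3, abs=1e-4)

    def test_zero_group_is_capped_not_infinite(self):
        design = generate_design(2)
        mat = np.zeros((2, len(design)), dtype=int)
        ett_cols = [i for i, sid in enumerate(design.index) if sid.startswith("ett_mock")]
        wt_cols = [i for i, sid in enumerate(design.index) if sid.startswith("WT_")]
        mat[0, ett_cols] = 50
        mat[0, wt_cols] = 40  # keep size factors computable
        mat[1, :] = 20
        counts = pd.DataFrame(mat, index=["hit", "flat"], columns=design.index)
        s = pd.Series(1.0, index=design.index)
        a = pd.Series(0.1, index=counts.index)
        ct = de.nb_wald_contrast(counts, design, s, a, ("ett", "mock"), ("arf4", "mock"))
        assert ct.table.at["hit", "log2FC"] == de.LOG2FC_CAP
        assert ct.table.at["hit", "p"] == 1.0

    def test_all_zero_genes_excluded_from_testing_and_bh(self):
        counts, design, s, a = self._fixture(seed=6, n_genes=50)
        counts.iloc[0] = 0
        ct = de.nb_wald_contrast(counts, design, s, a, ("ett", "mock"), ("WT", "mock"))
        assert counts.index[0] in ct.excluded
        assert counts.index[0] not in ct.table.index
        assert len(ct.table) == 49

    def test_invalid_groups_rejected(self):
        counts, design, s, a = self._fixture()
        with pytest.raises(ValueError):
            de.nb_wald_contrast(counts, design, s, a, ("ett", "mock"), ("ett", "mock"))

    def test_null_type_i_roughly_nominal(self):
        """Engineering check: raw p<0.05 fraction near nominal on null data
        (the calibrated gate lives in the acceptance suite)."""
        counts, design, s, a = self._fixture(seed=8, n_genes=2000)
        ct = de.nb_wald_contrast(counts, design, s, a, ("arf4", "IAA"), ("WT", "IAA"))
        frac = float((ct.table["p"] < 0.05).mean())
        assert 0.03 < frac < 0.07
        assert int((ct.table["padj"] < 0.05).sum()) <= 3


class TestDegSet:
    def _table(self):
        from conftest import make_contrast

        return make_contrast(
            "ett_arf4_vs_WT_mock",
            ["CLE19", "CRC", "flat"],
            log2fc=[2.39, -0.44, 0.1],
            padj=[0.01, 0.01, 0.9],
        )

    def test_thresholds_and_direction(self):
        s = de.deg_set(self._table(), tau_fdr=0.05, tau_lfc=1.0)
        assert set(s.genes) == {"CLE19"}
        assert s.directions["CLE19"] == 1

    def test_significant_subfold_gene_excluded_by_fold_gate(self):
        s = de.deg_set(self._table(), tau_fdr=0.05, tau_lfc=1.0)
        assert "CRC" not in s
        s2 = de.deg_set(self._table(), tau_fdr=0.05, tau_lfc=None)
        assert "CRC" in s2 and s2.directions["CRC"] == -1

    def test_all_nonsignificant_gives_empty_set(self):
        t = self._table()
        t.table["padj"] = 1.0
        assert len(de.deg_set(t)) == 0

    def test_invalid_fdr_rejected(self):
        with pytest.raises(ValueError):
            de.deg_set(self._table(), tau_fdr=1.5)


class TestFpkm:
    def test_closed_form(self):
        counts = _counts([[10], [0]])
        counts.iloc[1, 0] = 10**6 - 10  # make the total 1e6
        lengths = pd.Series([1000.0, 500.0], index=counts.index)
        f = de.compute_fpkm(counts, lengths)
        assert f.iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_zero_fpkm_and_scale_invariance(self):
        counts = _counts([[0, 0], [10, 20], [90, 180]])
        lengths = pd.Series([100.0, 1000.0, 2000.0], index=counts.index)
        f = de.compute_fpkm(counts, lengths)
        assert (f.iloc[0] == 0).all()
        f2 = de.compute_fpkm(counts * 2, lengths)
        pd.testing.assert_frame_equal(f, f2)

    def test_missing_length_and_zero_total_rejected(self):
        counts = _counts([[1, 0], [2, 0]])
        with pytest.raises(ValueError):
            de.compute_fpkm(counts, pd.Series([100.0], index=[counts.index[0]]))
        lengths = pd.Series([100.0, 100.0], index=counts.index)
        with pytest.raises(ValueError):
            de.compute_fpkm(counts, lengths)
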