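"""QC, normalization, pseudobulk, dot-plot and clustering tests."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

import iriskit as ik
from iriskit import synthetic as syn
from iriskit.atlas import QCThresholds, cluster_atlas, dotplot_stats

from conftest import small_config


def make_adata(counts, genes=None, cell_type=None, condition="untreated"):
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = genes or [f"g{i}" for i in range(g)]
    obs = pd.DataFrame(
        {
            "library_id": "lib1",
            "condition": condition,
            "replicate": 1,
            "cell_type": cell_type if cell_type is not None else ["a"] * n,
        },
        index=[f"bc{i}" for i in range(n)],
    )
    return ad.AnnData(X=sparse.csr_matrix(counts), obs=obs,
                      var=pd.DataFrame(index=genes))


class TestQCFilter:
    def test_low_count_nucleus_removed(self):
        # 450 transcripts -> below the 500-transcript floor
        counts = np.zeros((2, 3), int)
        counts[0] = [440, 10, 0]   # 450 total
        counts[1] = [990, 10, 0]   # 1000 total, 0% mito
        adata = make_adata(counts, genes=["gA", "gB", "mt-Nd1"])
        kept, report = ik.qc_filter(adata)
        assert kept.n_obs == 1
        assert report.per_nucleus.loc["bc0", "reasons"] == "low_count"

    def test_boundaries_are_retained(self):
        # exactly 500 total with exactly 1.0% mito; exactly 6000 total
        counts = np.zeros((2, 3), int)
        counts[0] = [495, 0, 5]     # 500 total, 1.0% mito
        counts[1] = [6000, 0, 0]    # 6000 total
        adata = make_adata(counts, genes=["gA", "gB", "mt-Nd1"])
        kept, report = ik.qc_filter(adata)
        assert kept.n_obs == 2
        assert report.n_removed == 0

    def test_matches_exhaustive_rescan(self):
        """Retained set equals a brute-force per-nucleus scan on a random
        50-gene x 200-nucleus matrix."""
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 200, size=(200, 50))
        genes = [f"g{i}" for i in range(48)] + ["mt-Nd1", "mt-Cytb"]
        adata = make_adata(counts, genes=genes)
        thresholds = QCThresholds(max_mito_fraction=0.05,
                                  min_transcripts=4500, max_transcripts=5500)
        kept, _ = ik.qc_filter(adata, thresholds)
        expected = []
        for i in range(200):
            total = counts[i].sum()
            mito = counts[i, 48] + counts[i, 49]
            if (mito / total <= 0.05) and (4500 <= total <= 5500):
                expected.append(f"bc{i}")
        assert list(kept.obs_names) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(30, size=(100, 30))
        genes = [f"g{i}" for i in range(29)] + ["mt-Nd1"]
        adata = make_adata(counts, genes=genes)
        t = QCThresholds(max_mito_fraction=0.03, min_transcripts=800,
                         max_transcripts=1000)
        once, _ = ik.qc_filter(adata, t)
        twice, report = ik.qc_filter(once, t)
        assert list(once.obs_names) == list(twice.obs_names)
        assert report.n_removed == 0

    def test_planted_violators_exactly_removed(self, atlas_cfg, lib_untreated_1):
        """The generator's planted QC tail is exactly the removed set."""
        adata, truth = lib_untreated_1
        _, report = ik.qc_filter(adata)
        planted = np.array([r != "" for r in truth.qc_reason])
        removed = ~report.per_nucleus["retained"].to_numpy()
        np.testing.assert_array_equal(planted, removed)

    def test_missing_mito_set_is_error(self):
        adata = make_adata(np.ones((3, 3), int), genes=["a", "b", "c"])
        with pytest.raises(ValueError, match="mitochondrial"):
            ik.qc_filter(adata)

    def test_bad_thresholds_raise(self):
        with pytest.raises(ValueError):
            QCThresholds(max_mito_fraction=1.5)
        with pytest.raises(ValueError):
            QCThresholds(min_transcripts=6000, max_transcripts=500)


class TestNormalize:
    def test_single_expressed_gene_hits_log_scale(self):
        adata = make_adata([[0, 0, 7]], genes=["a", "b", "c"])
        norm = ik.normalize(adata, scale=10_000)
        assert norm.X[0, 2] == pytest.approx(np.log1p(10_000))

    def test_scale_equal_to_total_gives_log_counts(self):
        counts = np.array([[2, 3, 5]])
        adata = make_adata(counts)
        norm = ik.normalize(adata, scale=10.0)
        np.testing.assert_allclose(
            np.asarray(norm.X.todense()).ravel(), np.log1p([2, 3, 5])
        )

    def test_three_by_three_hand_table(self):
        counts = np.array([[1, 0, 3], [0, 2, 2], [5, 5, 0]])
        adata = make_adata(counts)
        norm = ik.normalize(adata, scale=100.0)
        expected = np.log1p(counts * 100.0 / counts.sum(axis=1, keepdims=True))
        np.testing.assert_allclose(np.asarray(norm.X.todense()), expected)

    def test_zero_total_nucleus_is_error(self):
        adata = make_adata([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="zero total"):
            ik.normalize(adata)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_zero_pattern_and_delogged_totals(self, seed):
        """Normalization preserves the sparsity pattern, and the de-logged
        values of each nucleus sum to the scale factor."""
        rng = np.random.default_rng(seed)
        counts = rng.poisson(0.8, size=(12, 30))
        counts[np.all(counts == 0, axis=1), 0] = 1  # no zero-total nuclei
        adata = make_adata(counts)
        norm = ik.normalize(adata, scale=5000.0)
        x = np.asarray(norm.X.todense())
        np.testing.assert_array_equal(x > 0, counts > 0)
        np.testing.assert_allclose(np.expm1(x).sum(axis=1), 5000.0)


class TestPseudobulk:
    def test_single_cell_group_equals_delogged_values(self):
        counts = np.array([[4, 0, 6]])
        norm = ik.normalize(make_adata(counts))
        profile = ik.pseudobulk(norm, min_cells=1)
        np.testing.assert_allclose(
            profile.group("a", "untreated").to_numpy(),
            np.expm1(np.asarray(norm.X.todense())).ravel(),
        )

    def test_two_cell_group_is_arithmetic_mean(self):
        counts = np.array([[4, 0, 6], [1, 2, 3]])
        norm = ik.normalize(make_adata(counts))
        profile = ik.pseudobulk(norm, min_cells=1)
        delog = np.expm1(np.asarray(norm.X.todense()))
        np.testing.assert_allclose(
            profile.group("a", "untreated").to_numpy(), delog.mean(axis=0)
        )

    def test_all_zero_gene_averages_zero(self):
        counts = np.array([[4, 0], [7, 0]])
        norm = ik.normalize(make_adata(counts))
        profile = ik.pseudobulk(norm, min_cells=1)
        assert profile.group("a", "untreated").iloc[1] == 0.0

    def test_merged_group_is_weighted_mean_of_subgroups(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(5, size=(30, 10)) + 1
        types = ["a"] * 10 + ["b"] * 20
        norm = ik.normalize(make_adata(counts, cell_type=types))
        profile = ik.pseudobulk(norm, min_cells=1)
        merged = ik.normalize(make_adata(counts, cell_type=["ab"] * 30))
        profile_m = ik.pseudobulk(merged, min_cells=1)
        weighted = (
            10 * profile.group("a", "untreated")
            + 20 * profile.group("b", "untreated")
        ) / 30
        np.testing.assert_allclose(
            profile_m.group("ab", "untreated").to_numpy(), weighted.to_numpy()
        )

    def test_small_groups_flagged(self):
        counts = np.ones((3, 4), int)
        norm = ik.normalize(make_adata(counts))
        profile = ik.pseudobulk(norm, min_cells=10)
        assert ("a", "untreated") in profile.flagged


class TestDotPlot:
    def test_absent_gene_scores_zero(self):
        counts = np.array([[0, 5], [0, 3]])
        norm = ik.normalize(make_adata(counts, cell_type=["a", "b"]))
        stats = dotplot_stats(norm, genes=["g0"], cell_types=["a", "b"])
        assert (stats["pct_expressing"] == 0).all()
        assert (stats["scaled_mean"] == 0).all()

    def test_two_type_z_scores_are_plus_minus_one(self):
        """A gene expressed only in one of two displayed types scores pct
        {100, 0} and scaled mean {+1, -1} under population-sd z-scoring."""
        counts = np.array([[5, 1], [4, 1], [0, 1], [0, 1]])
        norm = ik.normalize(make_adata(counts, cell_type=["a", "a", "b", "b"]))
        stats = dotplot_stats(norm, genes=["g0"], cell_types=["a", "b"])
        by_type = stats.set_index("cell_type")
        assert by_type.loc["a", "pct_expressing"] == 100.0
        assert by_type.loc["b", "pct_expressing"] == 0.0
        assert by_type.loc["a", "scaled_mean"] == pytest.approx(1.0)
        assert by_type.loc["b", "scaled_mean"] == pytest.approx(-1.0)

    def test_pct_invariant_to_normalization_scale(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(1.0, size=(40, 8)) + np.eye(40, 8, dtype=int)
        types = ["a"] * 20 + ["b"] * 20
        s1 = dotplot_stats(ik.normalize(make_adata(counts, cell_type=types), 100.0),
                           genes=["g0", "g1"], cell_types=["a", "b"])
        s2 = dotplot_stats(ik.normalize(make_adata(counts, cell_type=types), 1e6),
                           genes=["g0", "g1"], cell_types=["a", "b"])
        np.testing.assert_allclose(s1["pct_expressing"], s2["pct_expressing"])

    def test_marker_scaled_mean_peaks_in_home_type(self):
        """Planted marker programs attain their maximal scaled mean in the
        marker's own population."""
        cfg = small_config(seed=5)
        adata, _ = syn.generate_counts(cfg, "untreated", seed=5)
        norm = ik.normalize(adata)
        markers = {"dilator": "Adra1a", "stroma1": "Sox10", "iris_pe": "Zic1"}
        stats = dotplot_stats(norm, genes=list(markers.values()),
                              cell_types=cfg.cell_type_names)
        for home, gene in markers.items():
            sub = stats[stats["gene"] == gene].set_index("cell_type")
            assert sub["scaled_mean"].idxmax() == home


class TestClusterAtlas:
    def test_two_separated_populations_recovered(self):
        cfg = small_config(seed=6)
        adata, _ = syn.generate_counts(cfg, "untreated", seed=6)
        keep = adata.obs["cell_type"].isin(["dilator", "iris_pe"]).to_numpy()
        sub = adata[keep].copy()
        norm = ik.normalize(sub)
        labels = cluster_atlas(norm, n_pcs=10, k_neighbors=10, seed=0)
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(norm.obs["cell_type"].astype(str), labels)
        assert labels.nunique() == 2
        assert ari == pytest.approx(1.0)

    def test_homogeneous_population_is_one_cluster(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(2.0, size=(300, 60)) + 1
        norm = ik.normalize(make_adata(counts))
        labels = cluster_atlas(norm, n_pcs=10, k_neighbors=15, seed=0)
        assert labels.nunique() == 1

    def test_too_few_nuclei_raise(self):
        counts = np.ones((5, 10), int)
        norm = ik.normalize(make_adata(counts))
        with pytest.raises(ValueError, match="n_pcs"):
            cluster_atlas(norm, n_pcs=10)
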