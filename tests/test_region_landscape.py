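"""Signal matrices, clustering, fold changes, differential regions, k-means."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from heptadnet.core_intervals import IntervalSet, PeakCollection
from heptadnet.region_landscape import (
    SignalMatrix,
    build_signal_matrix,
    cluster_landscape,
    diff_enriched_regions,
    kmeans_pe_profiles,
    pairwise_lfc,
    select_specific_regions,
)
from heptadnet.synthetic_data import (
    simulate_replicate_signals,
    simulate_signal_matrix,
)


def steps_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


class TestSignalMatrix:
    def test_constant_track(self):
        regions = IntervalSet(["c"] * 3, [0, 100, 200], [50, 150, 250])
        track = steps_df([("c", 0, 300, 2.5)])
        m = build_signal_matrix(regions, {("S", "X"): track})
        assert np.allclose(m.values.to_numpy(), 2.5)

    def test_zero_track_and_log(self):
        regions = IntervalSet(["c"], [0], [100])
        m = build_signal_matrix(regions, {("S", "X"): steps_df([("c", 500, 600, 9.0)])}, log=True)
        assert m.values.iloc[0, 0] == 0.0  # log2(0+1)

    def test_hand_integration(self):
        # 5 steps x 3 regions; means computed by hand
        track = steps_df(
            [("c", 0, 10, 1.0), ("c", 10, 20, 3.0), ("c", 30, 40, 2.0),
             ("c", 40, 50, 4.0), ("c", 60, 70, 10.0)]
        )
        regions = IntervalSet(["c"] * 3, [0, 25, 55], [20, 45, 65])
        m = build_signal_matrix(regions, {("S", "X"): track})
        v = m.values.to_numpy()[:, 0]
        # region 1: (10*1 + 10*3)/20 = 2.0
        # region 2: (5*0 + 10*2 + 5*4)/20 = 2.0
        # region 3: (5*0 + 5*10)/10 = 5.0
        assert v == pytest.approx([2.0, 2.0, 5.0])

    def test_per_region_vector_input(self):
        regions = IntervalSet(["c"] * 2, [0, 10], [5, 15])
        m = build_signal_matrix(regions, {("S", "X"): np.array([1.0, 2.0])})
        assert list(m.values[("S", "X")]) == [1.0, 2.0]


class TestClustering:
    def test_separated_blobs_fully_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (60, 4)), rng.normal(20, 1, (60, 4))])
        regions = IntervalSet(["c"] * 120, np.arange(120) * 10, np.arange(120) * 10 + 5)
        df = pd.DataFrame(X, columns=pd.MultiIndex.from_tuples(
            [("t", str(i)) for i in range(4)], names=["track", "cell_type"]))
        matrix = SignalMatrix(regions, df.clip(lower=0), "log2p1")
        clustering = cluster_landscape(matrix, k_neighbors=10, seed=0)
        truth = np.repeat([0, 1], 60)
        assert adjusted_rand_score(truth, clustering.labels) == 1.0

    def test_label_determinism_and_embedding_shape(self):
        matrix, labels = simulate_signal_matrix(n_regions=300, seed=5)
        logm = matrix.log_normalized()
        c1 = cluster_landscape(logm, seed=5)
        c2 = cluster_landscape(logm, seed=5)
        assert np.array_equal(c1.labels, c2.labels)
        assert c1.embedding.shape == (300, 2)

    def test_planted_archetypes_recovered(self):
        matrix, labels = simulate_signal_matrix(n_regions=1_000, n_classes=4, seed=2)
        clustering = cluster_landscape(matrix.log_normalized(), seed=2)
        assert adjusted_rand_score(labels, clustering.labels) >= 0.8

    def test_requires_log_and_valid_k(self):
        matrix, _ = simulate_signal_matrix(n_regions=50, seed=1)
        with pytest.raises(ValueError, match="log-normalized"):
            cluster_landscape(matrix)
        with pytest.raises(ValueError, match="k_neighbors"):
            cluster_landscape(matrix.log_normalized(), k_neighbors=50)


class TestLfc:
    def _matrix(self):
        regions = IntervalSet(["c"] * 3, [0, 10, 20], [5, 15, 25])
        df = pd.DataFrame(
            {("F", "A"): [3.0, 1.0, 0.0], ("F", "B"): [1.0, 1.0, 7.0]},
        )
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["track", "cell_type"])
        return SignalMatrix(regions, df, "raw")

    def test_values_and_antisymmetry(self):
        m = self._matrix()
        ab = pairwise_lfc(m, "A", "B", pseudocount=1.0)["F"].to_numpy()
        ba = pairwise_lfc(m, "B", "A", pseudocount=1.0)["F"].to_numpy()
        assert ab == pytest.approx([1.0, 0.0, -3.0])
        assert np.allclose(ab, -ba)

    def test_missing_track_rejected(self):
        with pytest.raises(ValueError):
            pairwise_lfc(self._matrix(), "A", "C")


class TestSelectSpecific:
    def test_uniform_matrix_selects_nothing(self):
        regions = IntervalSet(["c"] * 4, np.arange(4) * 100, np.arange(4) * 100 + 50)
        df = pd.DataFrame({("ATAC", "A"): np.ones(4), ("ATAC", "B"): np.ones(4)})
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["track", "cell_type"])
        matrix = SignalMatrix(regions, df, "raw")
        peaks = [PeakCollection("F1", "A", regions), PeakCollection("F2", "A", regions)]
        sel, _ = select_specific_regions(matrix, peaks, "A")
        assert len(sel) == 0

    def test_monotone_in_lfc_min(self):
        rng = np.random.default_rng(3)
        n = 200
        regions = IntervalSet(["c"] * n, np.arange(n) * 100, np.arange(n) * 100 + 50)
        df = pd.DataFrame({
            ("ATAC", "A"): rng.lognormal(1, 1, n),
            ("ATAC", "B"): rng.lognormal(0, 1, n),
        })
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["track", "cell_type"])
        matrix = SignalMatrix(regions, df, "raw")
        peaks = [PeakCollection(f, "A", regions) for f in ("F1", "F2")]
        sizes = [
            len(select_specific_regions(matrix, peaks, "A", lfc_min=t)[0])
            for t in (0.5, 1.0, 2.0, 4.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_unknown_cell_rejected(self):
        regions = IntervalSet(["c"], [0], [10])
        df = pd.DataFrame({("ATAC", "A"): [1.0]})
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["track", "cell_type"])
        with pytest.raises(ValueError):
            select_specific_regions(SignalMatrix(regions, df, "raw"), [], "Z")


class TestDiffEnriched:
    def test_identical_cells_yield_nothing(self):
        regions, a, _, _ = simulate_replicate_signals(200, 3, 0.0, seed=4)
        kept, _ = diff_enriched_regions(regions, a, a.copy())
        assert len(kept) == 0

    def test_bh_adjustment_example(self):
        # p = (.01,.02,.03,.04), m=4 -> BH adjusted all 0.04
        from statsmodels.stats.multitest import multipletests

        _, padj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        assert padj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_type_i_and_power(self):
        regions0, a0, b0, _ = simulate_replicate_signals(2_000, 3, 0.0, seed=6)
        kept0, _ = diff_enriched_regions(regions0, a0, b0)
        assert len(kept0) / 2_000 <= 0.07
        regions1, a1, b1, enriched = simulate_replicate_signals(2_000, 3, 0.1, fold=4.0, seed=6)
        _, table = diff_enriched_regions(regions1, a1, b1)
        assert table.loc[enriched, "significant"].mean() >= 0.8
        assert (table.loc[enriched & table["significant"], "direction"] == "a>b").all()

    def test_replicate_free_fallback_runs(self):
        regions, a, b, enriched = simulate_replicate_signals(500, 1, 0.05, fold=8.0, seed=7)
        _, table = diff_enriched_regions(regions, a, b)
        assert table["p_value"].between(0, 1).all()

    def test_replicate_count_validated(self):
        regions, a, b, _ = simulate_replicate_signals(10, 2, 0.0, seed=1)
        with pytest.raises(ValueError):
            diff_enriched_regions(regions, a[:, :0], b)


class TestKmeansProfiles:
    def test_planted_archetypes(self):
        rng = np.random.default_rng(8)
        n = 60
        prom = np.vstack([
            rng.normal(10, 0.5, (n, 3)), rng.normal(0, 0.5, (n, 3)),
            rng.normal(10, 0.5, (n, 3)), rng.normal(0, 0.5, (n, 3)),
        ])
        enh = np.vstack([
            rng.normal(0, 0.5, (n, 3)), rng.normal(10, 0.5, (n, 3)),
            rng.normal(10, 0.5, (n, 3)), rng.normal(0, 0.5, (n, 3)),
        ])
        labels = kmeans_pe_profiles(prom, enh, k=4, seed=0)
        truth = np.repeat([0, 1, 2, 3], n)
        assert adjusted_rand_score(truth, labels) == 1.0
        # C1 (label 0) must be the promoter-enriched profile
        assert prom[labels == 0].mean() == pytest.approx(10, abs=0.5)

    def test_duplicated_rows_share_labels(self):
        rng = np.random.default_rng(9)
        P = rng.normal(size=(20, 2))
        E = rng.normal(size=(20, 2))
        labels = kmeans_pe_profiles(np.vstack([P, P]), np.vstack([E, E]), k=3, seed=1)
        assert np.array_equal(labels[:20], labels[20:])

    def test_k_validation(self):
        with pytest.raises(ValueError):
            kmeans_pe_profiles(np.ones((3, 2)), np.ones((3, 2)), k=4)
        with pytest.raises(ValueError):
            kmeans_pe_profiles(np.ones((3, 2)), np.ones((3, 2)), k=1)
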