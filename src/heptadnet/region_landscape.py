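"""Chromatin-landscape analyses over accessible regions.

Covers: signal matrices (mean per-bp coverage per region per track),
k-nearest-neighbour graph + Louvain community detection with a decorative 2D
embedding, pairwise log2 fold-change overlays between cell types, selection
of cell-type-specific regions (differential accessibility + multi-factor
occupancy), a simplified differential-enrichment test producing DEH region
sets, and k-means profiling of promoter-enhancer signal vectors.

The differential-enrichment stage is a deliberately simple, fully documented
stand-in for a dedicated differential-binding package: per region the summed
factor signal is compared between two cell types across replicate tracks
with a moderated t-test on log2 signal (per-region variances shrunk toward a
pooled prior by empirical Bayes, the standard small-replicate treatment in
this field), Benjamini-Hochberg adjusted. Plain Welch t and Mann-Whitney
variants are kept as options; externally computed DEH BED files can be
supplied downstream to bypass the stage entirely.
"""
from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.neighbors import kneighbors_graph

from .core_intervals import IntervalSet, PeakCollection

__all__ = [
    "SignalMatrix",
    "LandscapeClustering",
    "read_bedgraph",
    "build_signal_matrix",
    "cluster_landscape",
    "pairwise_lfc",
    "select_specific_regions",
    "diff_enriched_regions",
    "kmeans_pe_profiles",
]


@dataclass
class SignalMatrix:
    """Regions x tracks matrix of mean per-bp coverage.

    Columns are a (track, cell_type) MultiIndex; ``transform`` records
    whether values are raw or log2(x+1)-normalized.
    """

    regions: IntervalSet
    values: pd.DataFrame
    transform: str = "raw"

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.values):
            raise ValueError("regions/values row mismatch")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("non-finite signal values")

    def log_normalized(self) -> "SignalMatrix":
        if self.transform == "log2p1":
            return self
        return SignalMatrix(self.regions, np.log2(self.values + 1.0), "log2p1")

    def tracks(self) -> list[tuple[str, str]]:
        return list(self.values.columns)


@dataclass
class LandscapeClustering:
    labels: np.ndarray
    embedding: np.ndarray  # (n, 2), visualization only
    k_neighbors: int
    resolution: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    if np.any(df["start"] >= df["end"]):
        raise ValueError(f"{path}: bedGraph step with start >= end")
    return df


def _mean_coverage(regions: IntervalSet, steps: pd.DataFrame) -> np.ndarray:
    """Mean per-bp coverage of each region under a step function.

    Positions not covered by any step count as zero. Uses a cumulative
    integral per chromosome and two searchsorted lookups per region.
    """
    out = np.zeros(len(regions))
    by_chrom = dict(tuple(steps.groupby("chrom", sort=False)))
    for chrom, grp in by_chrom.items():
        sel = np.flatnonzero(regions.chroms == chrom)
        if len(sel) == 0:
            continue
        grp = grp.sort_values("start")
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        v = grp["value"].to_numpy()
        cum = np.concatenate([[0.0], np.cumsum(v * (e - s))])

        def integral(x):
            idx = np.searchsorted(s, x, side="right") - 1
            base = cum[np.maximum(idx + 1, 0)]
            # subtract the uncovered tail of the step containing/preceding x
            inside = idx >= 0
            over = np.zeros_like(base)
            over[inside] = v[idx[inside]] * np.clip(
                e[idx[inside]] - x[inside], 0, e[idx[inside]] - s[idx[inside]]
            )
            return base - over

        lo = regions.starts[sel]
        hi = regions.ends[sel]
        out[sel] = (integral(hi) - integral(lo)) / (hi - lo)
    return out


def build_signal_matrix(
    regions: IntervalSet,
    tracks: dict[tuple[str, str], "str | Path | pd.DataFrame | np.ndarray"],
    log: bool = False,
) -> SignalMatrix:
    """Assemble the regions x tracks matrix.

    ``tracks`` maps (track, cell_type) to a bedGraph path, a step DataFrame
    (chrom/start/end/value), or a precomputed per-region value vector.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    cols = {}
    for key, src in tracks.items():
        if isinstance(src, (str, Path)):
            cols[key] = _mean_coverage(regions, read_bedgraph(src))
        elif isinstance(src, pd.DataFrame):
            cols[key] = _mean_coverage(regions, src)
        else:
            arr = np.asarray(src, dtype=float)
            if len(arr) != len(regions):
                raise ValueError(f"track {key}: per-region vector length mismatch")
            cols[key] = arr
    values = pd.DataFrame(cols)
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["track", "cell_type"])
    matrix = SignalMatrix(regions, values, "raw")
    return matrix.log_normalized() if log else matrix


def cluster_landscape(
    matrix: SignalMatrix,
    k_neighbors: int = 15,
    resolution: float = 0.5,
    seed: int = 0,
    embedding: str = "pca",
) -> LandscapeClustering:
    """Louvain communities on the kNN graph of regions, plus a 2D embedding.

    Cluster labels never depend on the embedding. ``embedding`` is "pca"
    (fast, exact) or "umap" (the field's usual display); both are
    visualization-only.

    The default resolution (0.5) targets coarse signal archetypes: Louvain
    never merges disconnected kNN components, but at resolution 1 it tends
    to subdivide large homogeneous components (the modularity resolution
    limit); lower it further for coarser, raise it for finer substructure.
    """
    import igraph as ig

    if matrix.transform != "log2p1":
        raise ValueError("cluster_landscape expects a log-normalized matrix")
    X = matrix.values.to_numpy()
    n = len(X)
    if n < 2:
        raise ValueError("need >= 2 regions")
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_regions={n}")
    adj = kneighbors_graph(X, k_neighbors, mode="connectivity", include_self=False)
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = ig.Graph(n=n, edges=edges)
    _pyrandom.seed(seed)  # igraph draws from Python's random module
    communities = graph.community_multilevel(resolution=resolution)
    labels = np.asarray(communities.membership, dtype=np.int64)

    if embedding == "pca":
        from sklearn.decomposition import PCA

        emb = PCA(n_components=2, random_state=seed).fit_transform(X)
    elif embedding == "umap":
        from umap import UMAP  # deferred: heavy import

        emb = UMAP(n_components=2, random_state=seed).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding {embedding!r}")
    return LandscapeClustering(labels, np.asarray(emb), k_neighbors, resolution, seed)


def pairwise_lfc(
    matrix: SignalMatrix, cell_a: str, cell_b: str, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-region, per-track log2((a + pc) / (b + pc)); antisymmetric in a,b.

    Computed on raw coverage; pass a raw matrix.
    """
    if matrix.transform != "raw":
        raise ValueError("pairwise_lfc expects raw (untransformed) signal")
    tracks = sorted({t for t, c in matrix.values.columns})
    out = {}
    for t in tracks:
        if (t, cell_a) not in matrix.values.columns or (t, cell_b) not in matrix.values.columns:
            raise ValueError(f"track {t!r} missing for {cell_a!r} or {cell_b!r}")
        a = matrix.values[(t, cell_a)].to_numpy()
        b = matrix.values[(t, cell_b)].to_numpy()
        out[t] = np.log2((a + pseudocount) / (b + pseudocount))
    return pd.DataFrame(out)


def select_specific_regions(
    matrix: SignalMatrix,
    peak_collections: list[PeakCollection],
    cell_type: str,
    lfc_min: float = 1.0,
    occupancy_min_factors: int = 2,
    accessibility_track: str = "ATAC",
    pseudocount: float = 1.0,
) -> tuple[IntervalSet, pd.DataFrame]:
    """Regions specific to ``cell_type``: accessibility LFC >= lfc_min against
    every other cell type AND >= ``occupancy_min_factors`` factors with a peak
    there in the target cell type.

    ``peak_collections`` are the target cell type's per-factor peaks. Returns
    the selected regions and a per-region justification table.
    """
    if lfc_min <= 0 or occupancy_min_factors <= 0:
        raise ValueError("thresholds must be > 0")
    cells = sorted({c for t, c in matrix.values.columns if t == accessibility_track})
    if cell_type not in cells:
        raise ValueError(f"unknown cell type {cell_type!r} (have {cells})")
    others = [c for c in cells if c != cell_type]
    n = len(matrix.regions)
    lfc_ok = np.ones(n, dtype=bool)
    just = {"region_index": np.arange(n)}
    for other in others:
        lfc = pairwise_lfc(matrix, cell_type, other, pseudocount)[accessibility_track].to_numpy()
        just[f"lfc_vs_{other}"] = lfc
        lfc_ok &= lfc >= lfc_min

    n_bound = np.zeros(n, dtype=int)
    for col in peak_collections:
        if col.cell_type != cell_type:
            continue
        n_bound += matrix.regions.overlaps_point_set(col.peaks).astype(int)
    just["n_factors_bound"] = n_bound
    selected = lfc_ok & (n_bound >= occupancy_min_factors)
    just["selected"] = selected
    table = pd.DataFrame(just)
    return matrix.regions.take(np.flatnonzero(selected)), table


def _moderated_t_pvalues(la: np.ndarray, lb: np.ndarray) -> np.ndarray:
    """limma-style moderated t on log2 signal.

    Per-region pooled variances are shrunk toward a fitted inverse-chi-square
    prior (d0, s0 estimated by Smyth's method of moments on log variances);
    the statistic is referred to a t distribution with d + d0 df.
    """
    from scipy.special import digamma, polygamma

    na, nb = la.shape[1], lb.shape[1]
    d = na + nb - 2
    va = la.var(axis=1, ddof=1) if na > 1 else np.zeros(len(la))
    vb = lb.var(axis=1, ddof=1) if nb > 1 else np.zeros(len(lb))
    s2 = ((na - 1) * va + (nb - 1) * vb) / d
    s2 = np.maximum(s2, 1e-12)
    e = np.log(s2) - digamma(d / 2) + np.log(d / 2)
    target = max(np.var(e, ddof=1) - polygamma(1, d / 2), 0.0)
    if target <= 1e-8:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    else:
        # invert trigamma(d0/2) = target by Newton on x = d0/2
        x = 0.5 + 1.0 / target
        for _ in range(50):
            f = polygamma(1, x) - target
            x -= f / polygamma(2, x)
            x = max(x, 1e-3)
        d0 = 2 * x
        s0_sq = float(np.exp(np.mean(e) + digamma(x) - np.log(x)))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = 1e6
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    tstat = (la.mean(axis=1) - lb.mean(axis=1)) / np.sqrt(s2_post * (1 / na + 1 / nb))
    return 2 * stats.t.sf(np.abs(tstat), df_total)


def diff_enriched_regions(
    regions: IntervalSet,
    signal_a: np.ndarray,
    signal_b: np.ndarray,
    fdr_max: float = 0.05,
    method: str = "auto",
) -> tuple[IntervalSet, pd.DataFrame]:
    """Differentially enriched regions between two cell types (DEH stand-in).

    ``signal_a``/``signal_b``: (n_regions, n_replicates) summed factor signal
    per replicate. ``method``: "moderated" (empirical-Bayes t on log2(x+1),
    the default via "auto" for >= 2 replicates per group), "ttest" (plain
    Welch), "ranksum" (Mann-Whitney; needs >= 4 replicates per group to reach
    useful p-values), or "zscore" (normal approximation on the log2
    difference, scaled by its robust spread across regions — the
    replicate-free fallback). Candidate regions should be pre-filtered to
    >= 2 bound factors.
    """
    from statsmodels.stats.multitest import multipletests

    a = np.atleast_2d(np.asarray(signal_a, dtype=float))
    b = np.atleast_2d(np.asarray(signal_b, dtype=float))
    if a.ndim == 2 and a.shape[0] == 1 and len(regions) > 1:
        a = a.T
    if b.ndim == 2 and b.shape[0] == 1 and len(regions) > 1:
        b = b.T
    if a.shape[0] != len(regions) or b.shape[0] != len(regions):
        raise ValueError("signal rows must match region count")
    if a.shape[1] < 1 or b.shape[1] < 1:
        raise ValueError("need >= 1 replicate track per cell type")
    if method == "auto":
        method = "moderated" if min(a.shape[1], b.shape[1]) >= 2 else "zscore"
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    if method == "moderated":
        pvals = _moderated_t_pvalues(la, lb)
    elif method == "ttest":
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    elif method == "ranksum":
        pvals = np.array(
            [stats.mannwhitneyu(la[i], lb[i], alternative="two-sided").pvalue
             for i in range(len(regions))]
        )
    elif method == "zscore":
        delta = la.mean(axis=1) - lb.mean(axis=1)
        scale = 1.4826 * np.median(np.abs(delta - np.median(delta)))
        scale = scale if scale > 0 else 1.0
        pvals = 2 * stats.norm.sf(np.abs(delta - np.median(delta)) / scale)
    else:
        raise ValueError(f"unknown method {method!r}")
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # zero-variance ties -> no call
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    direction = np.where(la.mean(axis=1) >= lb.mean(axis=1), "a>b", "b>a")
    keep = padj < fdr_max
    table = pd.DataFrame(
        {
            "region_index": np.arange(len(regions)),
            "mean_log2_a": la.mean(axis=1),
            "mean_log2_b": lb.mean(axis=1),
            "p_value": pvals,
            "p_adjusted": padj,
            "direction": direction,
            "significant": keep,
        }
    )
    return regions.take(np.flatnonzero(keep)), table


def kmeans_pe_profiles(
    promoter_signal: np.ndarray,
    enhancer_signal: np.ndarray,
    k: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """k-means over concatenated promoter+enhancer signal vectors.

    Labels are renumbered by decreasing promoter-mean signal so cluster 0
    (C1) is the promoter-enriched profile. k-means++ initialization with 10
    restarts, best inertia kept.
    """
    P = np.atleast_2d(np.asarray(promoter_signal, dtype=float))
    E = np.atleast_2d(np.asarray(enhancer_signal, dtype=float))
    if P.shape[0] != E.shape[0]:
        raise ValueError("promoter/enhancer row mismatch")
    n = P.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"n_pairs={n} < k={k}")
    X = np.hstack([P, E])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    prom_mean = np.array([P[raw == c].mean() if np.any(raw == c) else -np.inf for c in range(k)])
    order = np.argsort(-prom_mean, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw]
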