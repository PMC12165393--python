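"""Spike trains to persistence barcodes.

The preprocessing chain mirrors the standard population-topology recipe:
Gaussian-smoothed spike trains binned at 10 ms, every 5th population
vector retained, the most active vectors selected, PCA to six dimensions,
density-filtered farthest-point downsampling, then Vietoris-Rips
persistence up to H2.  Spike-time jittering perturbs each spike by an
independent zero-mean Gaussian before the chain runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .barcodes import BarcodeSet
from .gridsim import SpikeData
from .rips import rips_persistence

__all__ = [
    "PopulationMatrix",
    "TdaConfig",
    "smooth_and_bin",
    "select_vectors",
    "pca_reduce",
    "downsample",
    "persistence",
    "jitter",
    "run_tda",
    "umap_view",
]


@dataclass
class PopulationMatrix:
    """Smoothed population activity: rows are time samples, columns neurons."""

    values: np.ndarray  # (T, N), nonnegative
    times: np.ndarray   # (T,) seconds

    def __post_init__(self):
        if self.values.shape[0] != len(self.times):
            raise ValueError("row count must match sample times")


@dataclass
class TdaConfig:
    """Parameters of the spike-train -> barcode chain."""

    kernel_sigma: float = 0.200  # smoothing kernel width, s
    bin_size: float = 0.010      # fine bin, s
    stride: int = 5              # keep every stride-th population vector
    n_select: int = 15000        # most-active vectors retained
    selection: str = "top_activity"  # or "random"
    pca_dims: int = 6
    n_points: int = 1200         # final cloud size for persistence
    density_k: int = 15          # k-NN for the density filter
    density_drop: float = 0.10   # quantile of lowest-density points dropped
    metric: str = "euclidean"
    maxdim: int = 2
    seed: int | None = None      # used by random selection / maxmin start

    def asdict(self) -> dict:
        return asdict(self)


def smooth_and_bin(spikes: SpikeData, kernel_sigma: float = 0.050,
                   bin_size: float = 0.010, stride: int = 5) -> PopulationMatrix:
    """Per neuron: spike deltas binned on the fine grid, convolved with a
    normalized Gaussian kernel, then every ``stride``-th sample retained.
    The kernel conserves mass, so each row sum integrates spike counts."""
    if spikes.n_neurons == 0:
        raise ValueError("empty population")
    t0, t1 = spikes.span
    edges = np.arange(t0, t1 + bin_size, bin_size)
    nbins = len(edges) - 1
    sig_bins = kernel_sigma / bin_size
    mat = np.empty((nbins, spikes.n_neurons))
    for i, s in enumerate(spikes.spikes):
        counts, _ = np.histogram(s, bins=edges)
        mat[:, i] = gaussian_filter1d(counts.astype(float), sig_bins,
                                      mode="constant")
    times = edges[:-1] + bin_size / 2.0
    return PopulationMatrix(mat[::stride], times[::stride])


def select_vectors(M: PopulationMatrix, k: int = 15000,
                   mode: str = "top_activity", seed=None) -> PopulationMatrix:
    """The k most active population vectors (largest row sum, ties in time
    order), or k vectors uniformly at random without replacement."""
    n = M.values.shape[0]
    if k >= n:
        return PopulationMatrix(M.values.copy(), M.times.copy())
    if mode == "top_activity":
        act = M.values.sum(axis=1)
        # stable sort => earlier rows win ties
        idx = np.sort(np.argsort(-act, kind="stable")[:k])
    elif mode == "random":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=k, replace=False))
    else:
        raise ValueError("mode must be 'top_activity' or 'random'")
    return PopulationMatrix(M.values[idx], M.times[idx])


def pca_reduce(M: PopulationMatrix, dims: int = 6):
    """Centered PCA projection onto the leading ``dims`` axes.

    Returns (cloud, explained_variance_ratio); rank-deficient data is
    zero-padded to ``dims`` components.
    """
    X = M.values
    if X.shape[0] <= dims:
        raise ValueError("need more vectors than target dimensions")
    ncomp = min(dims, X.shape[1])
    pca = PCA(n_components=ncomp, svd_solver="full")
    Y = pca.fit_transform(X)
    if ncomp < dims:
        Y = np.pad(Y, ((0, 0), (0, dims - ncomp)))
    return Y, pca.explained_variance_ratio_


def downsample(cloud: np.ndarray, n: int = 1200, density_k: int = 15,
               density_drop: float = 0.10, seed=None) -> np.ndarray:
    """Density-filtered farthest-point (maxmin) downsampling.

    Points in the lowest ``density_drop`` quantile of k-NN density (largest
    distance to the k-th neighbor) are discarded, then greedy maxmin
    selection picks ``n`` well-spread points.  The maxmin start point is
    drawn from ``seed``, making the result reproducible.
    """
    npts = cloud.shape[0]
    if n >= npts:
        return cloud.copy()
    keep = cloud
    if density_drop > 0 and npts > density_k + 1:
        nn = NearestNeighbors(n_neighbors=density_k + 1).fit(cloud)
        dist, _ = nn.kneighbors(cloud)
        radius = dist[:, -1]  # distance to k-th neighbor; small = dense
        cutoff = np.quantile(radius, 1.0 - density_drop)
        keep = cloud[radius <= cutoff]
        if keep.shape[0] < n:
            keep = cloud
    rng = np.random.default_rng(seed)
    m = keep.shape[0]
    start = int(rng.integers(m))
    chosen = np.empty(n, dtype=int)
    chosen[0] = start
    mind = np.linalg.norm(keep - keep[start], axis=1)
    for i in range(1, n):
        nxt = int(np.argmax(mind))
        chosen[i] = nxt
        d = np.linalg.norm(keep - keep[nxt], axis=1)
        np.minimum(mind, d, out=mind)
    return keep[chosen]


def persistence(cloud: np.ndarray, maxdim: int = 2,
                metric: str = "euclidean",
                threshold: float | None = None) -> BarcodeSet:
    """Vietoris-Rips barcodes of the reduced point cloud."""
    return rips_persistence(cloud, maxdim=maxdim, threshold=threshold,
                            metric=metric)


def jitter(spikes: SpikeData, delta_t: float, seed=None,
           clip: bool = True) -> SpikeData:
    """Independent zero-mean Gaussian offsets of sd ``delta_t`` added to
    every spike time.  Per-neuron counts are preserved; spikes leaving the
    recording span are clipped to it (or dropped with ``clip=False``)."""
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    if delta_t == 0:
        return SpikeData([s.copy() for s in spikes.spikes], spikes.span)
    rng = np.random.default_rng(seed)
    t0, t1 = spikes.span
    out = []
    for s in spikes.spikes:
        moved = s + rng.normal(0.0, delta_t, size=len(s))
        if clip:
            moved = np.clip(moved, t0, t1)
        else:
            moved = moved[(moved >= t0) & (moved <= t1)]
        out.append(np.sort(moved))
    return SpikeData(out, spikes.span)


def run_tda(spikes: SpikeData, config: TdaConfig | None = None,
            return_stages: bool = False):
    """The full chain: smooth/bin -> select -> PCA -> downsample -> Rips.

    Returns the BarcodeSet, or (BarcodeSet, stage_log) with the stage
    parameters and shapes when ``return_stages`` is set.
    """
    cfg = config or TdaConfig()
    M = smooth_and_bin(spikes, cfg.kernel_sigma, cfg.bin_size, cfg.stride)
    sel = select_vectors(M, cfg.n_select, cfg.selection, seed=cfg.seed)
    cloud, evr = pca_reduce(sel, cfg.pca_dims)
    reduced = downsample(cloud, cfg.n_points, cfg.density_k,
                         cfg.density_drop, seed=cfg.seed)
    bset = persistence(reduced, cfg.maxdim, cfg.metric)
    if not return_stages:
        return bset
    log = cfg.asdict()
    log.update(n_raw_vectors=M.values.shape[0],
               n_selected=sel.values.shape[0],
               explained_variance_ratio=[float(x) for x in evr],
               n_cloud=int(reduced.shape[0]))
    return bset, log


def umap_view(cloud: np.ndarray, n_neighbors: int = 1000, min_dist: float = 0.5,
              n_components: int = 3, metric: str = "cosine", seed=None):
    """3D UMAP embedding of the population cloud, for visualization only."""
    import umap  # heavy optional dependency, imported lazily

    reducer = umap.UMAP(n_neighbors=min(n_neighbors, cloud.shape[0] - 1),
                        min_dist=min_dist, n_components=n_components,
                        metric=metric, random_state=seed)
    return reducer.fit_transform(cloud)
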