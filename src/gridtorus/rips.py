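"""Vietoris-Rips persistent cohomology up to H2.

Computes persistence barcodes of a Euclidean point cloud (or a precomputed
distance matrix) for homology dimensions 0, 1 and 2:

* H0 by Kruskal union-find over the sorted edges;
* H1 and H2 by coboundary ("persistent cohomology") matrix reduction over
  Z/2, processing columns in decreasing filtration order with the two
  standard accelerations: *clearing* (simplices that were pivots one
  dimension down are skipped as columns) and the *emergent-pair shortcut*
  (a column whose pivot cofacet has the same diameter is paired
  immediately, without building the full column).

Simplices are indexed in the combinatorial number system; the filtration
orders simplices by diameter, ties broken by decreasing index.  The default
filtration cutoff is the enclosing radius ``min_i max_j d(i, j)``, at which
the complex becomes a cone, so every finite bar is exact and only H0 keeps
one essential (truncated) bar.  Zero-persistence pairs are dropped.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.typed import Dict, List
from numba.core import types

from .barcodes import Barcode, BarcodeSet

__all__ = ["rips_persistence", "enclosing_radius"]


def enclosing_radius(dmat: np.ndarray) -> float:
    """min over points of the max distance to any other point."""
    return float(dmat.max(axis=1).min())


@njit(cache=True)
def _binom_table(n, kmax):
    b = np.zeros((n + 1, kmax + 1), dtype=np.int64)
    for i in range(n + 1):
        b[i, 0] = 1
        for k in range(1, min(i, kmax) + 1):
            b[i, k] = b[i - 1, k - 1] + b[i - 1, k]
    return b


@njit(cache=True)
def _vertices_of(idx, dim, n, binom, out):
    """Decode the ``dim+1`` vertices (decreasing) of simplex ``idx``."""
    r = idx
    v = n - 1
    for t in range(dim + 1):
        k = dim + 1 - t
        # largest v with binom[v, k] <= r
        while binom[v, k] > r:
            v -= 1
        out[t] = v
        r -= binom[v, k]
        v -= 1
    return out


@njit(cache=True)
def _key_less(d1, i1, d2, i2):
    """Ordering of column entries by reverse filtration position:
    diameter descending, ties index ascending.  The last entry under this
    order — the earliest cofacet in the filtration (min diameter, ties max
    index) — is the reduction pivot of the anti-transposed boundary."""
    if d1 != d2:
        return d1 > d2
    return i1 < i2


@njit(cache=True)
def _sort_entries(idxs, diams):
    """In-place insertion sort of column entries by the entry order."""
    for i in range(1, len(idxs)):
        ci, cd = idxs[i], diams[i]
        j = i - 1
        while j >= 0 and _key_less(cd, ci, diams[j], idxs[j]):
            idxs[j + 1] = idxs[j]
            diams[j + 1] = diams[j]
            j -= 1
        idxs[j + 1] = ci
        diams[j + 1] = cd


@njit(cache=True)
def _symdiff(ai, ad, bi, bd):
    """Z/2 sum (symmetric difference) of two sorted columns."""
    na, nb = len(ai), len(bi)
    oi = np.empty(na + nb, dtype=np.int64)
    od = np.empty(na + nb, dtype=np.float64)
    p = q = m = 0
    while p < na and q < nb:
        if ai[p] == bi[q]:
            p += 1
            q += 1
        elif _key_less(ad[p], ai[p], bd[q], bi[q]):
            oi[m] = ai[p]; od[m] = ad[p]; p += 1; m += 1
        else:
            oi[m] = bi[q]; od[m] = bd[q]; q += 1; m += 1
    while p < na:
        oi[m] = ai[p]; od[m] = ad[p]; p += 1; m += 1
    while q < nb:
        oi[m] = bi[q]; od[m] = bd[q]; q += 1; m += 1
    return oi[:m], od[:m]


@njit(cache=True)
def _coboundary(verts_desc, diam, D, binom, n, threshold, out_idx, out_diam):
    """Cofacets of a simplex within the filtration cutoff.

    Writes (index, diameter) of each cofacet into the out buffers and
    returns the count.
    """
    d1 = len(verts_desc)
    m = 0
    for w in range(n - 1, -1, -1):
        member = False
        for t in range(d1):
            if verts_desc[t] == w:
                member = True
                break
        if member:
            continue
        cdiam = diam
        for t in range(d1):
            dv = D[w, verts_desc[t]]
            if dv > cdiam:
                cdiam = dv
        if cdiam > threshold:
            continue
        # index of the cofacet: insert w into the descending vertex list
        idx = np.int64(0)
        pos = 0
        for t in range(d1):
            if verts_desc[t] > w:
                idx += binom[verts_desc[t], d1 + 1 - t]
                pos += 1
            else:
                idx += binom[verts_desc[t], d1 - t]
        idx += binom[w, d1 + 1 - pos]
        out_idx[m] = idx
        out_diam[m] = cdiam
        m += 1
    return m


@njit(cache=True)
def _order_columns_desc(diams):
    """Processing order for columns: diameter descending, ties index
    ascending (reverse filtration order).  Relies on the columns being
    generated in ascending index order, which a stable sort preserves
    within tie runs."""
    return np.argsort(-diams, kind="mergesort")


@njit(cache=True)
def _reduce_dimension(D, binom, n, dim, col_idx, col_diam, threshold):
    """Coboundary reduction of one dimension's columns.

    ``col_idx``/``col_diam`` are the (already clearing-filtered) d-simplex
    columns in any order.  Returns the finite bars, the essential births,
    and the pivot dictionary (cofacet index -> column position) used for
    clearing dimension ``dim + 1``.
    """
    order = _order_columns_desc(col_diam)
    ncols = len(order)

    pivot_of = Dict.empty(types.int64, types.int64)
    store_id = np.full(ncols, -2, dtype=np.int64)  # -2 unused, -1 implicit
    stored_idx = List()
    stored_diam = List()
    # typed-list bootstrap so numba can infer the element type
    stored_idx.append(np.empty(0, dtype=np.int64))
    stored_diam.append(np.empty(0, dtype=np.float64))

    births = np.empty(ncols, dtype=np.float64)
    deaths = np.empty(ncols, dtype=np.float64)
    nbars = 0
    ess = np.empty(ncols, dtype=np.float64)
    ness = 0

    verts = np.empty(dim + 1, dtype=np.int64)
    buf_idx = np.empty(n, dtype=np.int64)
    buf_diam = np.empty(n, dtype=np.float64)

    for oo in range(ncols):
        j = order[oo]
        s_idx = col_idx[j]
        s_diam = col_diam[j]
        _vertices_of(s_idx, dim, n, binom, verts)

        # Emergent-pair scan: cofacet indices decrease as the added vertex
        # decreases, so scanning vertices downward visits cofacets in
        # decreasing index order and the first cofacet with the column's own
        # diameter is exactly the reduction pivot (min diameter, ties max
        # index).  If it is unregistered the pair has zero persistence and
        # the column never needs to be built.
        emergent = False
        for w in range(n - 1, -1, -1):
            member = False
            for t in range(dim + 1):
                if verts[t] == w:
                    member = True
                    break
            if member:
                continue
            cdiam = s_diam
            for t in range(dim + 1):
                dv = D[w, verts[t]]
                if dv > cdiam:
                    cdiam = dv
            if cdiam == s_diam:
                # this cofacet is the pivot
                pidx = np.int64(0)
                pos = 0
                for t in range(dim + 1):
                    if verts[t] > w:
                        pidx += binom[verts[t], dim + 2 - t]
                        pos += 1
                    else:
                        pidx += binom[verts[t], dim + 1 - t]
                pidx += binom[w, dim + 2 - pos]
                if pidx not in pivot_of:
                    pivot_of[pidx] = j
                    store_id[j] = -1
                    emergent = True
                break
        if emergent:
            continue

        m = _coboundary(verts, s_diam, D, binom, n, threshold, buf_idx, buf_diam)
        if m == 0:
            ess[ness] = s_diam
            ness += 1
            continue
        # full reduction
        wi = buf_idx[:m].copy()
        wd = buf_diam[:m].copy()
        _sort_entries(wi, wd)
        while True:
            if len(wi) == 0:
                ess[ness] = s_diam
                ness += 1
                break
            piv_i = wi[-1]
            piv_d = wd[-1]
            if piv_i in pivot_of:
                j2 = pivot_of[piv_i]
                sid = store_id[j2]
                if sid >= 0:
                    oi = stored_idx[sid]
                    od = stored_diam[sid]
                else:
                    _vertices_of(col_idx[j2], dim, n, binom, verts)
                    m2 = _coboundary(verts, col_diam[j2], D, binom, n,
                                     threshold, buf_idx, buf_diam)
                    oi = buf_idx[:m2].copy()
                    od = buf_diam[:m2].copy()
                    _sort_entries(oi, od)
                wi, wd = _symdiff(wi, wd, oi, od)
            else:
                pivot_of[piv_i] = j
                stored_idx.append(wi.copy())
                stored_diam.append(wd.copy())
                store_id[j] = len(stored_idx) - 1
                if piv_d > s_diam:
                    births[nbars] = s_diam
                    deaths[nbars] = piv_d
                    nbars += 1
                break

    return births[:nbars], deaths[:nbars], ess[:ness], pivot_of


@njit(cache=True)
def _h0_and_edges(D, n, binom, threshold):
    """Union-find H0 plus the list of non-tree edges (dim-1 columns)."""
    nmax = binom[n, 2]
    eidx = np.empty(nmax, dtype=np.int64)
    ediam = np.empty(nmax, dtype=np.float64)
    m = 0
    for j in range(1, n):
        for i in range(j):
            d = D[i, j]
            if d <= threshold:
                eidx[m] = binom[j, 2] + i
                ediam[m] = d
                m += 1
    eidx = eidx[:m]
    ediam = ediam[:m]
    # ascending filtration order with ties by index descending: stable-sort
    # the index-reversed arrays, then map positions back
    rev = np.argsort(ediam[::-1].copy(), kind="mergesort")
    asc = m - 1 - rev

    parent = np.arange(n)
    deaths0 = np.empty(n, dtype=np.float64)
    nd = 0
    is_tree = np.zeros(m, dtype=np.bool_)
    verts = np.empty(2, dtype=np.int64)
    for t in range(m):
        e = asc[t]
        _vertices_of(eidx[e], 1, n, binom, verts)
        a, b = verts[0], verts[1]
        ra = a
        while parent[ra] != ra:
            ra = parent[ra]
        rb = b
        while parent[rb] != rb:
            rb = parent[rb]
        # path compression
        while parent[a] != ra:
            a, parent[a] = parent[a], ra
        while parent[b] != rb:
            b, parent[b] = parent[b], rb
        if ra != rb:
            parent[ra] = rb
            deaths0[nd] = ediam[e]
            nd += 1
            is_tree[e] = True
    ncomp = 0
    for v in range(n):
        if parent[v] == v:
            ncomp += 1
    keep = ~is_tree
    return deaths0[:nd], ncomp, eidx[keep], ediam[keep]


@njit(cache=True)
def _all_triangles(D, n, binom, threshold, cleared):
    nmax = binom[n, 3]
    tidx = np.empty(nmax, dtype=np.int64)
    tdiam = np.empty(nmax, dtype=np.float64)
    m = 0
    for k in range(2, n):
        bk = binom[k, 3]
        for j in range(1, k):
            djk = D[j, k]
            if djk > threshold:
                continue
            bj = bk + binom[j, 2]
            for i in range(j):
                d = djk
                dik = D[i, k]
                if dik > d:
                    d = dik
                dij = D[i, j]
                if dij > d:
                    d = dij
                if d > threshold:
                    continue
                idx = bj + i
                if idx in cleared:
                    continue
                tidx[m] = idx
                tdiam[m] = d
                m += 1
    return tidx[:m], tdiam[:m]


@njit(cache=True)
def _rips_core(D, threshold, maxdim):
    n = D.shape[0]
    binom = _binom_table(n, maxdim + 3)
    deaths0, ncomp, e_idx, e_diam = _h0_and_edges(D, n, binom, threshold)
    b1 = np.empty(0, dtype=np.float64)
    d1 = np.empty(0, dtype=np.float64)
    ess1 = np.empty(0, dtype=np.float64)
    b2 = np.empty(0, dtype=np.float64)
    d2 = np.empty(0, dtype=np.float64)
    ess2 = np.empty(0, dtype=np.float64)
    if maxdim >= 1 and n >= 3:
        b1, d1, ess1, piv1 = _reduce_dimension(D, binom, n, 1, e_idx, e_diam,
                                               threshold)
        if maxdim >= 2 and n >= 4:
            t_idx, t_diam = _all_triangles(D, n, binom, threshold, piv1)
            b2, d2, ess2, _ = _reduce_dimension(D, binom, n, 2, t_idx, t_diam,
                                                threshold)
    return deaths0, ncomp, b1, d1, ess1, b2, d2, ess2


def rips_persistence(points: np.ndarray, maxdim: int = 2,
                     threshold: float | None = None,
                     metric: str = "euclidean") -> BarcodeSet:
    """Barcodes of the Vietoris-Rips filtration of a point cloud.

    Parameters
    ----------
    points : (n, d) coordinates, or (n, n) distance matrix with
        ``metric="precomputed"``.
    maxdim : largest homology dimension (0-2).
    threshold : filtration cutoff; defaults to the enclosing radius, which
        yields exact finite bars.  Classes still alive at the cutoff are
        truncated there and flagged on the barcode.
    """
    points = np.ascontiguousarray(points, dtype=np.float64)
    if not np.isfinite(points).all():
        raise ValueError("point cloud contains non-finite values")
    if metric == "precomputed":
        D = points
    elif metric == "euclidean":
        sq = np.sum(points**2, axis=1)
        D = sq[:, None] + sq[None, :] - 2.0 * (points @ points.T)
        np.maximum(D, 0.0, out=D)
        np.sqrt(D, out=D)
        np.fill_diagonal(D, 0.0)
    else:
        raise ValueError(f"unsupported metric: {metric}")
    if not np.isfinite(D).all():
        raise ValueError("point cloud contains non-finite values")
    if not 0 <= maxdim <= 2:
        raise ValueError("maxdim must be 0, 1 or 2")
    n = D.shape[0]
    if threshold is None:
        threshold = enclosing_radius(D) if n > 1 else 0.0
    deaths0, ncomp, b1, d1, ess1, b2, d2, ess2 = _rips_core(
        D, float(threshold), maxdim)

    h0_rows = [(0.0, dth) for dth in sorted(deaths0) if dth > 0]
    h0_rows += [(0.0, threshold)] * ncomp  # essential components, truncated
    h1_rows = sorted(zip(b1, d1)) + [(b, threshold) for b in ess1 if threshold > b]
    h2_rows = sorted(zip(b2, d2)) + [(b, threshold) for b in ess2 if threshold > b]
    return BarcodeSet(
        h0=Barcode(0, h0_rows, truncated=True),
        h1=Barcode(1, h1_rows, truncated=len(ess1) > 0),
        h2=Barcode(2, h2_rows, truncated=len(ess2) > 0),
        max_filtration=float(threshold),
    )
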