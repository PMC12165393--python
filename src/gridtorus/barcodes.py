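"""Persistence barcodes and the degree of toroidality.

A barcode is a multiset of (birth, death) filtration intervals for one
homology dimension.  The degree of toroidality of a barcode set is

    Gamma_d = 1 - dB_hat(tau_d, tau_d_ref),   d in {1, 2}

where ``dB_hat`` is the bottleneck distance between barcodes rescaled by
their internal spread u(P) (the largest sup-norm difference between any two
bars), and the reference barcode is an idealized torus barcode: two long
bars in H1 and one long bar in H2, every other bar shrunk to the minimum
bar length of its dimension.  Gamma ranges from 0 (nothing torus-like) to
1 (the reference itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

__all__ = [
    "Bar",
    "Barcode",
    "BarcodeSet",
    "ToroidalityScore",
    "ReferenceMode",
    "bar_distance",
    "bottleneck_distance",
    "scale_factor",
    "normalized_bottleneck",
    "make_reference",
    "toroidality",
    "h1h2_gap",
    "relative_difference",
]


class DegenerateBarcodeError(ValueError):
    """Raised when an operation needs a nonempty barcode with nonzero scale."""


@dataclass(frozen=True)
class Bar:
    """A single persistence interval; ``death >= birth``, both finite."""

    birth: float
    death: float

    def __post_init__(self):
        if not (np.isfinite(self.birth) and np.isfinite(self.death)):
            raise ValueError("bar endpoints must be finite (truncate inf at ingest)")
        if self.death < self.birth:
            raise ValueError(f"death {self.death} < birth {self.birth}")

    @property
    def persistence(self) -> float:
        return self.death - self.birth


class Barcode:
    """All persistence intervals of one homology dimension.

    Stored as an (n, 2) float array of (birth, death) rows.  ``truncated``
    records whether any originally-infinite death was clipped to the max
    filtration value at ingest.
    """

    def __init__(self, dimension: int, bars: Iterable | np.ndarray = (),
                 truncated: bool = False):
        if dimension < 0:
            raise ValueError("homology dimension must be >= 0")
        arr = np.asarray(
            [(b.birth, b.death) if isinstance(b, Bar) else tuple(b) for b in bars],
            dtype=float,
        ).reshape(-1, 2)
        if arr.size and (arr[:, 1] < arr[:, 0]).any():
            raise ValueError("every bar needs death >= birth")
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("non-finite bar endpoints; truncate before building")
        self.dimension = int(dimension)
        self.array = arr
        self.truncated = bool(truncated)

    # -- container conveniences -------------------------------------------
    def __len__(self) -> int:
        return self.array.shape[0]

    def __iter__(self):
        return (Bar(b, d) for b, d in self.array)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Barcode) and self.dimension == other.dimension
                and self.array.shape == other.array.shape
                and bool(np.array_equal(self._sorted(), other._sorted())))

    def _sorted(self) -> np.ndarray:
        order = np.lexsort((self.array[:, 1], self.array[:, 0]))
        return self.array[order]

    @property
    def births(self) -> np.ndarray:
        return self.array[:, 0]

    @property
    def deaths(self) -> np.ndarray:
        return self.array[:, 1]

    @property
    def lengths(self) -> np.ndarray:
        return self.array[:, 1] - self.array[:, 0]

    def rescaled(self, factor: float) -> "Barcode":
        """Divide every birth and death by ``factor``."""
        if factor <= 0:
            raise ValueError("rescaling factor must be positive")
        return Barcode(self.dimension, self.array / factor, self.truncated)

    def longest(self, k: int = 1) -> np.ndarray:
        """Indices of the ``k`` longest bars, ties broken by earlier birth
        then input order."""
        n = len(self)
        if k > n:
            raise DegenerateBarcodeError(
                f"insufficient bars for reference: need {k}, have {n}")
        # lexsort keys, last key is primary: longest first, then earlier
        # birth, then input order
        order = np.lexsort((np.arange(n), self.births, -self.lengths))
        return order[:k]


@dataclass
class BarcodeSet:
    """Barcodes in dimensions 0, 1 and 2 from one persistence run."""

    h0: Barcode
    h1: Barcode
    h2: Barcode
    max_filtration: float | None = None

    def __post_init__(self):
        if (self.h0.dimension, self.h1.dimension, self.h2.dimension) != (0, 1, 2):
            raise ValueError("BarcodeSet dimensions must be exactly (0, 1, 2)")

    def __getitem__(self, dim: int) -> Barcode:
        return {0: self.h0, 1: self.h1, 2: self.h2}[dim]


class ReferenceMode(str, Enum):
    data = "data"
    self_ = "self"


@dataclass
class ToroidalityScore:
    """(Gamma1, Gamma2) with the provenance of the reference barcode."""

    gamma1: float
    gamma2: float
    reference_mode: str = "data"
    undefined: bool = False

    def as_tuple(self) -> tuple[float, float]:
        return (self.gamma1, self.gamma2)


# ---------------------------------------------------------------------------
# distances


def bar_distance(p: Bar | Sequence[float], q: Bar | Sequence[float]) -> float:
    """Sup-norm distance between two bars:
    ``max(|birth_p - birth_q|, |death_p - death_q|)``."""
    pb, pd = (p.birth, p.death) if isinstance(p, Bar) else p
    qb, qd = (q.birth, q.death) if isinstance(q, Bar) else q
    return max(abs(pb - qb), abs(pd - qd))


def _cost_matrix(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Pairwise sup-norm costs between bars of P (rows) and Q (cols)."""
    db = np.abs(P[:, None, 0] - Q[None, :, 0])
    dd = np.abs(P[:, None, 1] - Q[None, :, 1])
    return np.maximum(db, dd)


def _feasible(cost: np.ndarray, diag_p: np.ndarray, diag_q: np.ndarray,
              t: float) -> bool:
    """Is there a perfect matching using only pairs of cost <= t?

    Left nodes: bars of P then diagonal slots of Q; right nodes: bars of Q
    then diagonal slots of P.  Diagonal-to-diagonal pairs cost 0.
    """
    n1, n2 = cost.shape
    size = n1 + n2
    rows, cols = np.nonzero(cost <= t)
    blocks = [np.stack([rows, cols], axis=1)]
    ip = np.nonzero(diag_p <= t)[0]
    blocks.append(np.stack([ip, n2 + ip], axis=1))           # P_i -- diag(P_i)
    iq = np.nonzero(diag_q <= t)[0]
    blocks.append(np.stack([n1 + iq, iq], axis=1))           # diag(Q_j) -- Q_j
    dp, dq = np.meshgrid(np.arange(n1, size), np.arange(n2, size))
    blocks.append(np.stack([dp.ravel(), dq.ravel()], axis=1))  # diag -- diag
    edges = np.concatenate(blocks, axis=0)
    graph = csr_matrix(
        (np.ones(len(edges), dtype=np.int8), (edges[:, 0], edges[:, 1])),
        shape=(size, size),
    )
    match = maximum_bipartite_matching(graph, perm_type="column")
    return bool((match >= 0).all())


def _feasible_bijection(cost: np.ndarray, t: float) -> bool:
    n1, n2 = cost.shape
    rows, cols = np.nonzero(cost <= t)
    graph = csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                       shape=(n1, n2))
    match = maximum_bipartite_matching(graph, perm_type="column")
    return bool((match >= 0).all())


def bottleneck_distance(P: Barcode, Q: Barcode, allow_diagonal: bool = True) -> float:
    """Bottleneck distance between two barcodes of the same dimension.

    Minimal over matchings of the maximal matched-pair sup-norm cost.  With
    ``allow_diagonal`` (the standard definition) unmatched bars may pair
    with the diagonal at cost ``persistence / 2``; without it only
    bijections between equal-cardinality barcodes are allowed.

    The minimum is found by binary search over the candidate costs (all
    pairwise and diagonal costs), checking feasibility with a bipartite
    matching at each threshold.
    """
    if P.dimension != Q.dimension:
        raise ValueError("barcodes must share a homology dimension")
    a, b = P.array, Q.array
    if not allow_diagonal:
        if len(a) != len(b):
            raise ValueError("cardinality mismatch")
        if len(a) == 0:
            return 0.0
        cost = _cost_matrix(a, b)
        cands = np.unique(cost)
        lo, hi = 0, len(cands) - 1
        if _feasible_bijection(cost, cands[lo]):
            return float(cands[lo])
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if _feasible_bijection(cost, cands[mid]):
                hi = mid
            else:
                lo = mid
        return float(cands[hi])

    if len(a) == 0 and len(b) == 0:
        return 0.0
    diag_p = (a[:, 1] - a[:, 0]) / 2.0 if len(a) else np.empty(0)
    diag_q = (b[:, 1] - b[:, 0]) / 2.0 if len(b) else np.empty(0)
    cost = (_cost_matrix(a, b) if len(a) and len(b)
            else np.empty((len(a), len(b))))
    cands = np.unique(np.concatenate([cost.ravel(), diag_p, diag_q, [0.0]]))
    lo, hi = 0, len(cands) - 1
    if _feasible(cost, diag_p, diag_q, cands[lo]):
        return float(cands[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _feasible(cost, diag_p, diag_q, cands[mid]):
            hi = mid
        else:
            lo = mid
    return float(cands[hi])


def scale_factor(P: Barcode) -> float:
    """Internal spread u(P): the largest sup-norm difference between any two
    bars of P.  A single-bar barcode falls back to that bar's persistence."""
    n = len(P)
    if n == 0:
        raise DegenerateBarcodeError("degenerate barcode: empty")
    if n == 1:
        u = float(P.array[0, 1] - P.array[0, 0])
    else:
        u = float(_cost_matrix(P.array, P.array).max())
    if u <= 0:
        raise DegenerateBarcodeError("zero scale: all bars identical")
    return u


_CLIP_EVENTS: list[float] = []  # raw normalized distances > 1, for inspection


def normalized_bottleneck(P: Barcode, Q: Barcode) -> float:
    """Bottleneck distance after dividing each barcode by its own spread
    u(.), clipped to [0, 1]."""
    d = bottleneck_distance(P.rescaled(scale_factor(P)),
                            Q.rescaled(scale_factor(Q)))
    if d > 1.0:
        _CLIP_EVENTS.append(d)
        d = 1.0
    return d


# ---------------------------------------------------------------------------
# reference construction and scores


def _shrink_to_min(bc: Barcode, keep: np.ndarray) -> np.ndarray:
    """Keep the ``keep`` rows verbatim; every other bar keeps its birth and
    has its length replaced by the minimum bar length of the dimension."""
    arr = bc.array.copy()
    min_len = float(bc.lengths.min())
    mask = np.ones(len(bc), dtype=bool)
    mask[keep] = False
    arr[mask, 1] = arr[mask, 0] + min_len
    return arr


def make_reference(bset: BarcodeSet, mode: str | ReferenceMode = "data") -> BarcodeSet:
    """Idealized-torus reference barcodes built from ``bset`` itself.

    mode="data": keep the two longest H1 bars and the single longest H2 bar
    verbatim.  mode="self": keep the longest H1 bar, stretch the
    second-longest H1 bar to the length of the longest (same birth), keep
    the longest H2 bar.  In both modes every other bar keeps its birth and
    is shrunk to the minimum bar length of its dimension.
    """
    mode = ReferenceMode(mode) if not isinstance(mode, ReferenceMode) else mode
    if len(bset.h1) < 2 or len(bset.h2) < 1:
        raise DegenerateBarcodeError(
            "insufficient bars for reference: need >=2 in H1 and >=1 in H2")
    top2 = bset.h1.longest(2)
    h1 = _shrink_to_min(bset.h1, top2)
    if mode is ReferenceMode.self_:
        longest_len = h1[top2[0], 1] - h1[top2[0], 0]
        h1[top2[1], 1] = h1[top2[1], 0] + longest_len
    top1 = bset.h2.longest(1)
    h2 = _shrink_to_min(bset.h2, top1)
    return BarcodeSet(
        h0=Barcode(0, bset.h0.array, bset.h0.truncated),
        h1=Barcode(1, h1),
        h2=Barcode(2, h2),
        max_filtration=bset.max_filtration,
    )


def toroidality(bset: BarcodeSet, ref: BarcodeSet | None = None,
                reference_mode: str = "data") -> ToroidalityScore:
    """Degree of toroidality Gamma = (Gamma1, Gamma2) of a barcode set.

    ``ref`` defaults to ``make_reference(bset, reference_mode)``.  A
    degenerate barcode (empty, or all bars identical) yields a score
    flagged ``undefined`` rather than a silent 0.
    """
    if ref is None:
        ref = make_reference(bset, reference_mode)
    try:
        g1 = 1.0 - normalized_bottleneck(bset.h1, ref.h1)
        g2 = 1.0 - normalized_bottleneck(bset.h2, ref.h2)
    except DegenerateBarcodeError:
        return ToroidalityScore(np.nan, np.nan, reference_mode, undefined=True)
    return ToroidalityScore(float(g1), float(g2), reference_mode)


def h1h2_gap(bset: BarcodeSet) -> float:
    """Death of the longest H1 bar minus birth of the longest H2 bar.

    Large and positive when the torus' two circles persist well past the
    birth of its cavity (the oscillation-modulated / real-data pattern);
    near zero when the H2 bar only appears as the H1 bars die.
    """
    if len(bset.h1) == 0 or len(bset.h2) == 0:
        raise DegenerateBarcodeError("h1h2_gap needs nonempty H1 and H2")
    i1 = bset.h1.longest(1)[0]
    i2 = bset.h2.longest(1)[0]
    return float(bset.h1.array[i1, 1] - bset.h2.array[i2, 0])


def relative_difference(a: ToroidalityScore, b: ToroidalityScore):
    """Componentwise (a - b) / (a + b); each component in [-1, 1].

    Returns (value1, value2); a zero denominator yields nan for that
    component.
    """
    out = []
    for x, y in zip(a.as_tuple(), b.as_tuple()):
        s = x + y
        out.append((x - y) / s if s != 0 else np.nan)
    return tuple(out)
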