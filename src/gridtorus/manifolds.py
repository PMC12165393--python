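"""Parametric torus samplers for validating the toroidality measure.

The 3D torus of radii (a, c) and a flat 6D torus (three unit circles with
coupled angular frequencies) are sampled by drawing the two angular
coordinates i.i.d. uniform on [0, 2*pi); Gaussian coordinate noise models
departures from the ideal manifold.  ``noise_sweep`` traces the degree of
toroidality as a function of the noise level against the reference built
from a clean sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .barcodes import make_reference, toroidality
from .rips import rips_persistence

__all__ = [
    "Torus3DParams",
    "Torus6DParams",
    "sample_torus_3d",
    "sample_torus_6d",
    "add_gaussian_noise",
    "noise_sweep",
]


@dataclass(frozen=True)
class Torus3DParams:
    """Minor radius a, major radius c of the standard embedded torus."""

    a: float = 5.0
    c: float = 10.0

    def __post_init__(self):
        if not 0 < self.a < self.c:
            raise ValueError("need 0 < a < c")


@dataclass(frozen=True)
class Torus6DParams:
    """Flat torus in R^6: p = (C1 cos(a1 u + b1 v), C1 sin(a1 u + b1 v),
    C2 cos(a2 u + b2 v), C2 sin(a2 u + b2 v), C3 cos(b3 v), C3 sin(b3 v))."""

    C1: float = 1.0
    C2: float = 1.0
    C3: float = 1.0
    a1: float = 1.0
    a2: float = 1.0
    b1: float = 1.0 / 3.0
    b2: float = -1.0 / 3.0
    b3: float = 1.0

    def __post_init__(self):
        if min(self.C1, self.C2, self.C3) <= 0:
            raise ValueError("circle radii must be positive")


def torus_3d_point(u, v, params: Torus3DParams) -> np.ndarray:
    """Embed angles (u, v) on the 3D torus."""
    a, c = params.a, params.c
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return np.stack([(c + a * np.cos(v)) * np.cos(u),
                     (c + a * np.cos(v)) * np.sin(u),
                     a * np.sin(v)], axis=-1)


def torus_6d_point(u, v, params: Torus6DParams) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    p = params
    ph1 = p.a1 * u + p.b1 * v
    ph2 = p.a2 * u + p.b2 * v
    ph3 = p.b3 * v
    return np.stack([p.C1 * np.cos(ph1), p.C1 * np.sin(ph1),
                     p.C2 * np.cos(ph2), p.C2 * np.sin(ph2),
                     p.C3 * np.cos(ph3), p.C3 * np.sin(ph3)], axis=-1)


def sample_torus_3d(n: int, params: Torus3DParams | None = None, seed=None,
                    area_uniform: bool = False) -> np.ndarray:
    """n points on the 3D torus, angles i.i.d. uniform in (u, v).

    ``area_uniform`` instead draws v by rejection so that points are
    uniform with respect to surface area (the default angle-uniform
    measure over-represents the inner rim).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or Torus3DParams()
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 2.0 * np.pi, n)
    if area_uniform:
        v = np.empty(n)
        k = 0
        while k < n:
            cand = rng.uniform(0.0, 2.0 * np.pi, 2 * (n - k))
            acc = cand[rng.uniform(0, 1, len(cand))
                       < (params.c + params.a * np.cos(cand))
                       / (params.c + params.a)]
            take = min(len(acc), n - k)
            v[k:k + take] = acc[:take]
            k += take
    else:
        v = rng.uniform(0.0, 2.0 * np.pi, n)
    return torus_3d_point(u, v, params)


def sample_torus_6d(n: int, params: Torus6DParams | None = None,
                    seed=None) -> np.ndarray:
    """n points on the flat 6D torus, angles i.i.d. uniform."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or Torus6DParams()
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 2.0 * np.pi, n)
    v = rng.uniform(0.0, 2.0 * np.pi, n)
    return torus_6d_point(u, v, params)


def add_gaussian_noise(points: np.ndarray, delta: float, seed=None) -> np.ndarray:
    """i.i.d. N(0, delta^2) added to every coordinate; delta=0 is identity."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta == 0:
        return points.copy()
    rng = np.random.default_rng(seed)
    return points + rng.normal(0.0, delta, size=points.shape)


def noise_sweep(params=None, deltas=None, n: int = 1200, realizations: int = 20,
                seed=None, sampler=sample_torus_3d) -> pd.DataFrame:
    """Mean and sd of (Gamma1, Gamma2) versus noise level delta.

    For each delta, torus samples are corrupted and their Rips barcodes
    (maxdim 2) compared against the data-mode reference constructed from a
    clean (delta = 0) sample of the same size.  Returns a tidy table with
    columns delta, gamma1_mean, gamma1_sd, gamma2_mean, gamma2_sd.
    """
    if params is None:
        params = Torus3DParams() if sampler is sample_torus_3d else Torus6DParams()
    if deltas is None:
        deltas = np.linspace(0.0, 0.4, 9) * getattr(params, "c", 1.0)
    deltas = np.asarray(deltas, dtype=float)
    if (np.diff(deltas) < 0).any():
        raise ValueError("deltas must be sorted ascending")
    root = np.random.default_rng(seed)
    ref_seed, *_ = root.integers(0, 2**31, size=1)
    clean = sampler(n, params, seed=int(ref_seed))
    clean_bset = rips_persistence(clean, maxdim=2)
    ref = make_reference(clean_bset, "data")
    clean_score = toroidality(clean_bset, ref)
    rows = []
    for delta in deltas:
        if delta == 0:
            # noiseless: deterministic score of the clean sample itself
            g1 = [clean_score.gamma1]
            g2 = [clean_score.gamma2]
        else:
            g1, g2 = [], []
            for _ in range(realizations):
                s2 = int(root.integers(0, 2**31))
                noisy = add_gaussian_noise(clean, float(delta), seed=s2)
                score = toroidality(rips_persistence(noisy, maxdim=2), ref)
                g1.append(score.gamma1)
                g2.append(score.gamma2)
        rows.append({"delta": float(delta),
                     "gamma1_mean": float(np.mean(g1)),
                     "gamma1_sd": float(np.std(g1, ddof=1)) if len(g1) > 1 else 0.0,
                     "gamma2_mean": float(np.mean(g2)),
                     "gamma2_sd": float(np.std(g2, ddof=1)) if len(g2) > 1 else 0.0})
    return pd.DataFrame(rows)
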