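"""Timescales, ratemaps, spectra and experiment sweeps.

Sigmoid fits of the degree of toroidality against a perturbation magnitude
give the critical jitter timescale; occupancy-normalized ratemaps and the
rotational grid score quantify spatial hexagonality; FFT power spectra of
binned spike counts give the eta/theta band powers whose ratio tracks
how robustly a module expresses toroidal topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, rotate
from scipy.optimize import curve_fit

from .barcodes import BarcodeSet, make_reference, toroidality, h1h2_gap
from .gridsim import (GridPopulation, OscillatorBank, SpikeData, Trajectory,
                      build_population, displace_fields, simulate,
                      build_oscillator_bank)
from .pipeline import TdaConfig, jitter, run_tda

__all__ = [
    "SigmoidFit",
    "SpectralResult",
    "Ratemap",
    "fit_sigmoid",
    "critical_timescale",
    "behavioral_timescale",
    "ratemap",
    "grid_score",
    "psd",
    "module_psd",
    "band_power",
    "eta_theta_ratio",
    "jitter_sweep",
    "subsample_curve",
    "displacement_sweep",
    "frequency_sweep",
    "gain_sweep",
]

ETA_BAND = (2.5, 5.9)    # Hz, default eta range
THETA_BAND = (5.9, 11.0)  # Hz, default theta range


@dataclass
class SigmoidFit:
    """Parameters of s(x) = L / (1 + exp(-k (x - x_c))) + b."""

    L: float
    k: float
    x_c: float
    b: float
    residual: float
    degenerate: bool = False

    @property
    def slope_at_inflection(self) -> float:
        return self.L * self.k / 4.0

    def __call__(self, x):
        return _sigmoid(np.asarray(x, dtype=float), self.L, self.k,
                        self.x_c, self.b)


def _sigmoid(x, L, k, x_c, b):
    return L / (1.0 + np.exp(-k * (x - x_c))) + b


def fit_sigmoid(x, y) -> SigmoidFit:
    """Least-squares sigmoid fit of y(x).

    Initialization: L = -(max-min) of y for descending data, b = max(y),
    x_c at the steepest empirical slope; bounds keep the inflection inside
    the sampled range.  Near-constant y raises a degenerate-fit error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points to fit a sigmoid")
    span = y.max() - y.min()
    if span < 1e-6:
        raise ValueError("degenerate fit: y is (near-)constant")
    descending = y[np.argmax(x)] < y[np.argmin(x)]
    L0 = -span if descending else span
    b0 = y.max() if descending else y.min()
    order = np.argsort(x)
    slopes = np.diff(y[order]) / np.maximum(np.diff(x[order]), 1e-300)
    i_steep = int(np.argmax(np.abs(slopes)))
    xc0 = 0.5 * (x[order][i_steep] + x[order][i_steep + 1])
    k0 = 4.0 * abs(slopes[i_steep]) / span
    try:
        popt, _ = curve_fit(
            _sigmoid, x, y, p0=[L0, k0, xc0, b0],
            bounds=([-2 * span if descending else 1e-12, 1e-12,
                     x.min(), -np.inf],
                    [-1e-12 if descending else 2 * span, np.inf,
                     x.max(), np.inf]),
            maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"sigmoid fit failed to converge: {err}") from err
    resid = float(np.sqrt(np.mean((_sigmoid(x, *popt) - y) ** 2)))
    L, k, x_c, b = popt
    # report a descending sigmoid as negative k on positive L, matching the
    # convention that the fitted k sign encodes the direction
    if L < 0:
        L, k, b = -L, -k, b + popt[0]
    return SigmoidFit(float(L), float(k), float(x_c), float(b), resid)


def critical_timescale(fit1: SigmoidFit, fit2: SigmoidFit) -> float:
    """Minimum of the two inflection points: the jitter scale at which the
    first toroidality component collapses."""
    if fit1.degenerate or fit2.degenerate:
        return float("nan")
    return float(min(fit1.x_c, fit2.x_c))


def behavioral_timescale(spacing: float, mean_speed: float) -> float:
    """Grid spacing over average running speed (straight-line travel time
    between neighboring fields); any consistent length unit."""
    if mean_speed <= 0:
        raise ValueError("mean speed must be positive")
    return spacing / mean_speed


# ---------------------------------------------------------------------------
# ratemaps and grid scores


@dataclass
class Ratemap:
    """Occupancy-normalized firing-rate map (Hz) on a square spatial grid."""

    rates: np.ndarray     # (B, B), nan where unvisited
    bin_size: float       # m
    occupancy: np.ndarray  # seconds per bin


def ratemap(spike_times: np.ndarray, traj: Trajectory, bin_size: float = 0.03,
            smooth_sigma: float = 0.05, speed_min: float = 0.025) -> Ratemap:
    """Smoothed spike-count map divided by smoothed occupancy map.

    Samples (and the spikes falling on them) with running speed below
    ``speed_min`` are excluded, mirroring the usual behavioral filter.
    """
    arena = traj.arena
    nb = int(np.ceil(arena / bin_size))
    edges = np.linspace(0.0, arena, nb + 1)
    speeds = traj.speeds()
    moving = speeds >= speed_min
    pos = traj.positions[moving]
    occ, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=[edges, edges])
    occ *= traj.dt
    spike_times = np.asarray(spike_times, dtype=float)
    si = np.clip(((spike_times - traj.times[0]) / traj.dt).astype(int),
                 0, len(traj.times) - 1)
    keep = moving[si]
    sp = traj.positions[si[keep]]
    cnt, _, _ = np.histogram2d(sp[:, 0], sp[:, 1], bins=[edges, edges])
    sig = smooth_sigma / bin_size
    occ_s = gaussian_filter(occ, sig)
    cnt_s = gaussian_filter(cnt, sig)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(occ_s > 1e-9, cnt_s / occ_s, np.nan)
    return Ratemap(rates, bin_size, occ)


def _autocorrelogram(rm: np.ndarray) -> np.ndarray:
    """Pearson spatial autocorrelation of a ratemap at all 2D lags."""
    m = np.nan_to_num(rm, nan=np.nanmean(rm))
    m = m - m.mean()
    n = m.shape[0]
    out = np.full((2 * n - 1, 2 * n - 1), np.nan)
    for dy in range(-n + 1, n):
        for dx in range(-n + 1, n):
            a = m[max(0, dy):n + min(0, dy), max(0, dx):n + min(0, dx)]
            b = m[max(0, -dy):n + min(0, -dy), max(0, -dx):n + min(0, -dx)]
            if a.size < 20:
                continue
            aa = a - a.mean()
            bb = b - b.mean()
            den = np.sqrt((aa**2).sum() * (bb**2).sum())
            if den > 1e-12:
                out[dy + n - 1, dx + n - 1] = (aa * bb).sum() / den
    return out


def grid_score(rm: Ratemap) -> float:
    """Hexagonality of a ratemap from its spatial autocorrelogram.

    On an annulus from the first trough around the central peak out to
    1.25x the first hexagonal-peak radius, GS = min(corr at 60, 120 deg) -
    max(corr at 30, 90, 150 deg); positive for hexagonal lattices,
    negative for square ones.  Range [-2, 2].
    """
    ac = _autocorrelogram(rm.rates)
    n = ac.shape[0]
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    # radial profile to find the first trough beyond the center peak
    rmax = c
    prof = np.array([np.nanmean(ac[(r >= k) & (r < k + 1)])
                     for k in range(1, rmax)])
    trough = None
    for k in range(1, len(prof) - 1):
        if prof[k] < prof[k - 1] and prof[k] <= prof[k + 1]:
            trough = k + 1
            break
    if trough is None:
        raise ValueError("degenerate autocorrelogram: no central trough")
    rest = prof[trough:]
    if len(rest) == 0:
        raise ValueError("degenerate autocorrelogram: trough at edge")
    peak = trough + int(np.argmax(rest)) + 1
    r_out = min(1.25 * peak, rmax - 1)
    mask = (r >= trough) & (r <= r_out)
    base = np.where(mask, np.nan_to_num(ac, nan=0.0), np.nan)

    def ring_corr(angle):
        rot = rotate(np.nan_to_num(ac, nan=0.0), angle, reshape=False,
                     order=1)
        a = base[mask]
        b = np.where(mask, rot, np.nan)[mask]
        good = np.isfinite(a) & np.isfinite(b)
        a, b = a[good] - a[good].mean(), b[good] - b[good].mean()
        den = np.sqrt((a**2).sum() * (b**2).sum())
        return float((a * b).sum() / den) if den > 1e-12 else 0.0

    on = min(ring_corr(60), ring_corr(120))
    off = max(ring_corr(30), ring_corr(90), ring_corr(150))
    return on - off


# ---------------------------------------------------------------------------
# spectra


@dataclass
class SpectralResult:
    """Normalized spike-count power spectrum over [0.1, 500] Hz."""

    frequencies: np.ndarray
    power: np.ndarray      # sums to 1 over the normalization range
    norm_range: tuple = (0.1, 500.0)

    def band_power(self, band) -> float:
        lo, hi = band
        if hi <= lo:
            raise ValueError("empty band")
        mask = (self.frequencies >= lo) & (self.frequencies < hi)
        return float(self.power[mask].sum())


def psd(spike_times: np.ndarray, duration: float, fs: float = 1000.0,
        t0: float = 0.0) -> SpectralResult:
    """FFT power spectrum of the binned (1/fs) spike-count signal,
    normalized to unit total power in [0.1, 500] Hz."""
    if duration <= 10:
        raise ValueError("need more than 10 s of data for a stable spectrum")
    spike_times = np.asarray(spike_times, dtype=float)
    if len(spike_times) == 0:
        raise ValueError("empty spike train")
    nbins = int(round(duration * fs))
    counts = np.histogram(spike_times, bins=nbins, range=(t0, t0 + duration))[0]
    sig = counts - counts.mean()
    spec = np.abs(np.fft.rfft(sig)) ** 2
    freqs = np.fft.rfftfreq(nbins, d=1.0 / fs)
    # half-open [0.1, 500) so that half-open band partitions sum to exactly 1
    mask = (freqs >= 0.1) & (freqs < 500.0)
    total = spec[mask].sum()
    if total <= 0:
        raise ValueError("zero spectral power in the normalization range")
    return SpectralResult(freqs[mask], spec[mask] / total)


def band_power(spec: SpectralResult, band) -> float:
    return spec.band_power(band)


def eta_theta_ratio(spec: SpectralResult, eta_band=ETA_BAND,
                    theta_band=THETA_BAND) -> float:
    """A_eta / A_theta, the normalized power ratio of the two bands."""
    return spec.band_power(eta_band) / spec.band_power(theta_band)


def module_psd(spikes: SpikeData, fs: float = 1000.0) -> SpectralResult:
    """Per-neuron spectra averaged over the module (common duration)."""
    t0, t1 = spikes.span
    dur = t1 - t0
    specs = [psd(s, dur, fs, t0) for s in spikes.spikes if len(s)]
    power = np.mean([s.power for s in specs], axis=0)
    return SpectralResult(specs[0].frequencies, power / power.sum())


# ---------------------------------------------------------------------------
# sweep runners


def _score(spikes: SpikeData, config: TdaConfig, ref=None,
           reference_mode: str = "self"):
    bset = run_tda(spikes, config)
    score = (toroidality(bset, ref) if ref is not None
             else toroidality(bset, reference_mode=reference_mode))
    return bset, score


def jitter_sweep(spikes: SpikeData, delta_ts, config: TdaConfig | None = None,
                 n_jitter_seeds: int = 3, seed=None) -> dict:
    """Toroidality versus spike-time jitter magnitude.

    The reference is the data-mode reference of the unjittered barcodes;
    per jitter magnitude, ``n_jitter_seeds`` independent jitters are
    scored and averaged.  Returns the tidy table, the two sigmoid fits and
    the critical timescale (min of the two inflection points).
    """
    cfg = config or TdaConfig()
    delta_ts = np.asarray(delta_ts, dtype=float)
    rng = np.random.default_rng(seed)
    base_bset = run_tda(spikes, cfg)
    ref = make_reference(base_bset, "data")
    base_score = toroidality(base_bset, ref)
    rows = []
    for dt in delta_ts:
        for _ in range(n_jitter_seeds if dt > 0 else 1):
            if dt == 0:
                sc = base_score
            else:
                jit = jitter(spikes, float(dt), seed=int(rng.integers(2**31)))
                _, sc = _score(jit, cfg, ref=ref)
            rows.append({"delta_t": float(dt), "gamma1": sc.gamma1,
                         "gamma2": sc.gamma2})
    table = pd.DataFrame(rows)
    agg = table.groupby("delta_t", as_index=False).mean()
    out = {"table": table, "baseline": base_score, "fit1": None, "fit2": None,
           "critical_timescale": float("nan")}
    try:
        out["fit1"] = fit_sigmoid(agg["delta_t"], agg["gamma1"])
        out["fit2"] = fit_sigmoid(agg["delta_t"], agg["gamma2"])
        out["critical_timescale"] = critical_timescale(out["fit1"], out["fit2"])
    except (ValueError, RuntimeError):
        pass  # low-confidence sweep: table still returned
    return out


def subsample_curve(spikes: SpikeData, sizes, config: TdaConfig | None = None,
                    reps: int = 30, seed=None,
                    reference_mode: str = "self") -> pd.DataFrame:
    """Mean toroidality over random neuron subsets of increasing size.
    The full-population size is a single realization."""
    cfg = config or TdaConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for ns in sizes:
        ns = int(ns)
        if ns > spikes.n_neurons:
            raise ValueError("subset size exceeds the population")
        r = 1 if ns == spikes.n_neurons else reps
        g1, g2 = [], []
        for _ in range(r):
            idx = rng.choice(spikes.n_neurons, size=ns, replace=False)
            try:
                _, sc = _score(spikes.subset(idx), cfg,
                               reference_mode=reference_mode)
                g1.append(sc.gamma1)
                g2.append(sc.gamma2)
            except ValueError:
                g1.append(np.nan)
                g2.append(np.nan)
        rows.append({"n_cells": ns, "gamma1_mean": float(np.nanmean(g1)),
                     "gamma2_mean": float(np.nanmean(g2)), "reps": r})
    return pd.DataFrame(rows)


def _sim_sweep(conditions, build, traj: Trajectory, seeds,
               config: TdaConfig, ref=None, reference_mode: str = "self",
               label: str = "condition") -> pd.DataFrame:
    rows = []
    for cond in conditions:
        for seed in seeds:
            pop, bank = build(cond, seed)
            spikes = simulate(pop, traj, bank, seed=100_000 + seed)
            bset, sc = _score(spikes, config, ref=ref,
                              reference_mode=reference_mode)
            rows.append({label: cond, "seed": seed, "gamma1": sc.gamma1,
                         "gamma2": sc.gamma2, "gap": h1h2_gap(bset)})
    return pd.DataFrame(rows)


def displacement_sweep(fractions, traj: Trajectory, seeds=(1, 2, 3),
                       config: TdaConfig | None = None, N: int = 75,
                       bank: OscillatorBank | None = None,
                       reference_mode: str = "self") -> pd.DataFrame:
    """Toroidality as grid-field centers are displaced by a fraction of the
    spacing (oscillations on by default)."""
    cfg = config or TdaConfig()
    bank = bank or build_oscillator_bank("methods_default")

    def build(frac, seed):
        pop = build_population(N=N, seed=seed)
        return displace_fields(pop, float(frac), seed=7_000 + seed), bank

    return _sim_sweep(fractions, build, traj, seeds, cfg,
                      reference_mode=reference_mode, label="fraction")


def frequency_sweep(freqs, traj: Trajectory, seeds=(1, 2, 3),
                    config: TdaConfig | None = None, N: int = 75,
                    reference_mode: str = "self") -> pd.DataFrame:
    """Toroidality with a single dominant oscillator of varying frequency."""
    cfg = config or TdaConfig()

    def build(freq, seed):
        return (build_population(N=N, seed=seed),
                build_oscillator_bank("single", freq=float(freq)))

    return _sim_sweep(freqs, build, traj, seeds, cfg,
                      reference_mode=reference_mode, label="freq")


def gain_sweep(gains, traj: Trajectory, seeds=(1, 2, 3),
               config: TdaConfig | None = None, N: int = 75,
               oscillations: bool = True,
               reference_mode: str = "self") -> pd.DataFrame:
    """Toroidality versus field gain G0, with or without oscillations."""
    from dataclasses import replace as _replace

    from .gridsim import FieldParams
    cfg = config or TdaConfig()
    bank = (build_oscillator_bank("methods_default") if oscillations
            else build_oscillator_bank("none"))

    def build(g0, seed):
        fp = FieldParams(G0=float(g0))
        return build_population(N=N, field_params=fp, seed=seed), bank

    return _sim_sweep(gains, build, traj, seeds, cfg,
                      reference_mode=reference_mode, label="G0")
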