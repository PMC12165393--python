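"""Poisson grid-cell population simulator with oscillatory rate modulation.

Each of N independent neurons fires as an inhomogeneous Poisson process
whose rate factorizes into a spatial and a temporal part:

    lambda_i(r, t) = [ (lambda0 + sum_k G(|r - r_ik|))
                       * (c1 + c2 * sum_mu A(omega_mu) cos(2 pi omega_mu t)) ]_+

The spatial part places truncated Gaussian firing fields of width ``sigma``
(cut at radius ``x0``) on a hexagonal (or square) lattice of a given
spacing; the lattice is randomly shifted per neuron, so the population
tiles the torus of spatial phases.  The temporal part multiplies the rate
by a bank of sinusoidal oscillators; ``c2`` is calibrated so that the
time-averaged rectified modulation equals one and oscillations leave the
expected spike count unchanged.

Positions are in meters, times in seconds, rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Trajectory",
    "SpikeData",
    "FieldParams",
    "LatticeSpec",
    "OscillatorBank",
    "GridPopulation",
    "make_centers",
    "build_population",
    "firing_rate",
    "build_oscillator_bank",
    "calibrate_c2",
    "simulate",
    "displace_fields",
    "synth_trajectory",
]

ARENA_SIZE = 1.5  # box side length of the open-field arena, meters


@dataclass
class Trajectory:
    """A 2D foraging path sampled at a uniform time step."""

    times: np.ndarray    # (T,) seconds
    positions: np.ndarray  # (T, 2) meters
    arena: float = ARENA_SIZE

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.times), 2):
            raise ValueError("positions must be (T, 2) aligned with times")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0] + self.dt)

    def speeds(self) -> np.ndarray:
        """Instantaneous speed (m/s) by forward differences."""
        v = np.diff(self.positions, axis=0) / self.dt
        s = np.hypot(v[:, 0], v[:, 1])
        return np.append(s, s[-1])

    def resampled(self, dt: float) -> "Trajectory":
        """Linear-interpolation resampling onto a uniform ``dt`` grid."""
        t = np.arange(self.times[0], self.times[-1], dt)
        x = np.interp(t, self.times, self.positions[:, 0])
        y = np.interp(t, self.times, self.positions[:, 1])
        return Trajectory(t, np.column_stack([x, y]), self.arena)


@dataclass
class SpikeData:
    """Per-neuron sorted spike times within a common recording span."""

    spikes: list  # list of 1D float arrays, seconds
    span: tuple   # (t0, t1) seconds

    def __post_init__(self):
        self.spikes = [np.sort(np.asarray(s, dtype=float)) for s in self.spikes]
        t0, t1 = self.span
        for s in self.spikes:
            if len(s) and (s[0] < t0 - 1e-9 or s[-1] > t1 + 1e-9):
                raise ValueError("spike times outside the recording span")

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spikes])

    def subset(self, idx) -> "SpikeData":
        return SpikeData([self.spikes[i] for i in idx], self.span)


@dataclass(frozen=True)
class FieldParams:
    """Truncated-Gaussian firing field: amplitude G0/(2 pi sigma^2) at the
    center, width sigma, hard cutoff at radius x0."""

    lambda0: float = 0.05  # baseline rate, Hz
    G0: float = 1.5        # field gain, Hz m^2
    sigma: float = 0.12    # field width, m
    x0: float = 0.4        # truncation radius, m

    def __post_init__(self):
        if min(self.G0, self.sigma, self.x0) <= 0 or self.lambda0 < 0:
            raise ValueError("field parameters must be positive")
        if self.x0 <= self.sigma:
            raise ValueError("truncation radius x0 must exceed sigma")


@dataclass(frozen=True)
class LatticeSpec:
    kind: str = "hexagonal"          # or "square"
    spacing: float = 0.85            # m, center-to-center
    orientation: float = 0.0         # radians, shared across the module

    def __post_init__(self):
        if self.kind not in ("hexagonal", "square"):
            raise ValueError("lattice kind must be 'hexagonal' or 'square'")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def basis(self) -> np.ndarray:
        """Lattice basis vectors as rows (2, 2)."""
        s = self.spacing
        if self.kind == "hexagonal":
            b = np.array([[1.0, 0.0], [0.5, np.sqrt(3) / 2]]) * s
        else:
            b = np.array([[1.0, 0.0], [0.0, 1.0]]) * s
        c, sn = np.cos(self.orientation), np.sin(self.orientation)
        rot = np.array([[c, -sn], [sn, c]])
        return b @ rot.T


@dataclass
class OscillatorBank:
    """Sinusoidal rate modulators: factor = c1 + c2 * sum A_mu cos(2 pi w_mu t)."""

    omegas: np.ndarray  # Hz, ascending
    amps: np.ndarray    # dimensionless
    c1: float
    c2: float

    def __post_init__(self):
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.amps = np.asarray(self.amps, dtype=float)
        if self.omegas.shape != self.amps.shape:
            raise ValueError("omegas and amps must align")
        if len(self.omegas) and ((np.diff(self.omegas) < 0).any()
                                 or (self.omegas <= 0).any()):
            raise ValueError("frequencies must be positive ascending")
        if (self.amps < 0).any():
            raise ValueError("amplitudes must be nonnegative")

    @property
    def m(self) -> int:
        return len(self.omegas)

    def modulation(self, t: np.ndarray) -> np.ndarray:
        """Temporal factor c1 + c2 * sum_mu A_mu cos(2 pi w_mu t) (not yet
        rectified; rectification happens on the full rate)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.m == 0 or self.c2 == 0:
            return np.full(t.shape, self.c1)
        phases = 2.0 * np.pi * np.outer(t, self.omegas)
        return self.c1 + self.c2 * (np.cos(phases) @ self.amps)


@dataclass
class GridPopulation:
    """N neurons sharing one lattice and field shape; per-neuron random
    lattice shift determines each neuron's field centers."""

    N: int
    field_params: FieldParams
    lattice: LatticeSpec
    centers: list  # per-neuron (K_i, 2) arrays, m
    shifts: np.ndarray | None = None  # (N, 2) fractional shifts, for the record
    arena: float = ARENA_SIZE


def make_centers(lattice: LatticeSpec, shift_frac: np.ndarray,
                 arena: float = ARENA_SIZE, margin: float | None = None,
                 x0: float = 0.4) -> np.ndarray:
    """Field centers of one neuron: the lattice shifted by ``shift_frac``
    (fractional coordinates of one unit cell), restricted to the arena
    expanded by ``margin`` so truncated tails at the walls are included."""
    if margin is None:
        margin = x0
    basis = lattice.basis
    shift = shift_frac @ basis
    # enough lattice shells to cover the expanded arena
    reach = int(np.ceil((arena + 2 * margin) / lattice.spacing)) + 2
    ii, jj = np.meshgrid(np.arange(-reach, reach + 1),
                         np.arange(-reach, reach + 1))
    pts = np.column_stack([ii.ravel(), jj.ravel()]) @ basis + shift
    keep = ((pts[:, 0] >= -margin) & (pts[:, 0] <= arena + margin)
            & (pts[:, 1] >= -margin) & (pts[:, 1] <= arena + margin))
    return pts[keep]


def build_population(N: int = 75, field_params: FieldParams | None = None,
                     lattice: LatticeSpec | None = None,
                     arena: float = ARENA_SIZE, seed=None) -> GridPopulation:
    """Population with i.i.d. uniform per-neuron lattice shifts."""
    rng = np.random.default_rng(seed)
    field_params = field_params or FieldParams()
    lattice = lattice or LatticeSpec()
    shifts = rng.uniform(0, 1, size=(N, 2))
    centers = [make_centers(lattice, s, arena, x0=field_params.x0)
               for s in shifts]
    return GridPopulation(N, field_params, lattice, centers, shifts, arena)


def _spatial_rate(centers: np.ndarray, fp: FieldParams,
                  pos: np.ndarray) -> np.ndarray:
    """lambda0 + sum of truncated Gaussian fields, evaluated at (T, 2) pos."""
    pos = np.atleast_2d(pos)
    amp = fp.G0 / (2.0 * np.pi * fp.sigma**2)
    rate = np.full(len(pos), fp.lambda0)
    for c in centers:
        d2 = (pos[:, 0] - c[0]) ** 2 + (pos[:, 1] - c[1]) ** 2
        mask = d2 < fp.x0**2
        if mask.any():
            rate[mask] += amp * np.exp(-d2[mask] / (2.0 * fp.sigma**2))
    return rate


def firing_rate(pop: GridPopulation, bank: OscillatorBank, neuron: int,
                r: np.ndarray, t: float | np.ndarray) -> np.ndarray:
    """Rectified rate of one neuron at position(s) ``r`` and time(s) ``t``."""
    spatial = _spatial_rate(pop.centers[neuron], pop.field_params, r)
    temporal = bank.modulation(t)
    return np.maximum(spatial * temporal, 0.0)


# ---------------------------------------------------------------------------
# oscillator bank presets


def _log_bank(m: int = 200, f_lo: float = 1.0, f_hi: float = 50.0,
              base_coef: float = 0.25,
              lines: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    """m log-spaced frequencies with a 1/sqrt(w) amplitude law; the grid
    points nearest each line frequency are snapped onto it with the line's
    stronger coefficient."""
    om = np.logspace(np.log10(f_lo), np.log10(f_hi), m)
    coef = np.full(m, base_coef)
    if lines:
        for f, c in lines.items():
            i = int(np.argmin(np.abs(om - f)))
            om[i] = f
            coef[i] = c
    amps = coef * om ** -0.5
    order = np.argsort(om)
    return om[order], amps[order]


def build_oscillator_bank(preset: str = "methods_default",
                          freq: float | None = None,
                          calibrate: bool = True,
                          waveform: str = "cos") -> OscillatorBank:
    """Oscillator-bank presets.

    ``methods_default``: 200 log-spaced frequencies in [1, 50] Hz with
    A(w) = 0.25 w^(-1/2), the points nearest 4 and 8 Hz snapped to exactly
    4 and 8 Hz with coefficients 0.5 and 0.8 (the eta and theta lines);
    c1 = 0 and c2 from :func:`calibrate_c2`.

    ``none``: no modulation (c1 = 1, c2 = 0, empty bank).

    ``single``: the default bank with the eta line removed (its grid point
    restored to the background law) and the remaining dominant line moved
    to ``freq`` with the theta coefficient.
    """
    if preset == "none":
        return OscillatorBank(np.empty(0), np.empty(0), c1=1.0, c2=0.0)
    if preset == "methods_default":
        om, amps = _log_bank(lines={4.0: 0.5, 8.0: 0.8})
    elif preset == "single":
        if freq is None or freq <= 0:
            raise ValueError("preset 'single' needs a positive freq")
        om, amps = _log_bank(lines={freq: 0.8})
    else:
        raise ValueError(f"unknown preset: {preset}")
    bank = OscillatorBank(om, amps, c1=0.0, c2=1.0)
    if calibrate:
        bank.c2 = calibrate_c2(bank, waveform=waveform)
    return bank


def calibrate_c2(bank: OscillatorBank, T: float = 1800.0, dt: float = 0.010,
                 waveform: str = "cos") -> float:
    """Rate-normalization constant: the reciprocal of the time-averaged
    rectified oscillator sum,

        c2 = 1 / mean_t [ sum_mu A_mu wave(2 pi w_mu t) ]_+

    so that multiplying a rate by c2*[sum]_+ conserves the expected spike
    count.  The default window matches the default simulation horizon and
    step, which makes conservation hold by construction over that horizon;
    short windows are biased because all oscillators start in phase at
    t = 0 (e.g. T=36 s, dt=1 ms gives 2.35 instead of the long-run 1.96).
    ``waveform`` selects cos (the simulator's waveform, default) or sin;
    for incommensurate banks the two agree as T grows.
    """
    if bank.m == 0 or not (bank.amps > 0).any():
        raise ValueError("non-modulated bank: nothing to calibrate")
    wave = {"cos": np.cos, "sin": np.sin}[waveform]
    total = 0.0
    count = 0
    chunk = 200_000
    edges = np.arange(0.0, T, chunk * dt)
    for start in edges:
        t = np.arange(start, min(start + chunk * dt, T), dt)
        s = wave(2.0 * np.pi * np.outer(t, bank.omegas)) @ bank.amps
        total += np.maximum(s, 0.0).sum()
        count += len(t)
    mean_rect = total / count
    if mean_rect <= 0:
        raise ValueError("rectified oscillator sum averages to zero")
    return float(1.0 / mean_rect)


# ---------------------------------------------------------------------------
# simulation


def simulate(pop: GridPopulation, traj: Trajectory,
             bank: OscillatorBank | None = None, dt: float = 0.010,
             seed=None) -> SpikeData:
    """Poisson spikes from rate-modulated grid cells along a trajectory.

    The trajectory is resampled to the simulation step if needed; per bin
    the spike count of neuron i is Poisson with mean
    ``lambda_i(r(t), t) * dt`` and spike times are placed uniformly within
    the bin.
    """
    rng = np.random.default_rng(seed)
    bank = bank or build_oscillator_bank("none")
    if abs(traj.dt - dt) > 1e-12:
        traj = traj.resampled(dt)
    t = traj.times
    temporal = bank.modulation(t)
    spikes = []
    for i in range(pop.N):
        lam = np.maximum(
            _spatial_rate(pop.centers[i], pop.field_params, traj.positions)
            * temporal, 0.0)
        counts = rng.poisson(lam * dt)
        nz = np.nonzero(counts)[0]
        if len(nz) == 0:
            spikes.append(np.empty(0))
            continue
        reps = counts[nz]
        starts = np.repeat(t[nz], reps)
        times = starts + rng.uniform(0.0, dt, size=len(starts))
        spikes.append(np.sort(times))
    span = (float(t[0]), float(t[-1] + dt))
    return SpikeData(spikes, span)


def displace_fields(pop: GridPopulation, fraction: float,
                    seed=None, mode: str = "fixed") -> GridPopulation:
    """Perturb every field center by ``fraction`` of the grid spacing.

    mode="fixed": displacement magnitude is exactly fraction*spacing in an
    i.i.d. uniform random direction per center; mode="gaussian": isotropic
    Gaussian displacement with that standard deviation per coordinate.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    rng = np.random.default_rng(seed)
    mag = fraction * pop.lattice.spacing
    new_centers = []
    for c in pop.centers:
        if fraction == 0:
            new_centers.append(c.copy())
            continue
        if mode == "fixed":
            th = rng.uniform(0, 2 * np.pi, size=len(c))
            off = mag * np.column_stack([np.cos(th), np.sin(th)])
        elif mode == "gaussian":
            off = rng.normal(0.0, mag, size=c.shape)
        else:
            raise ValueError("mode must be 'fixed' or 'gaussian'")
        new_centers.append(c + off)
    return GridPopulation(pop.N, pop.field_params, pop.lattice, new_centers,
                          pop.shifts, pop.arena)


def synth_trajectory(duration: float = 1800.0, arena: float = ARENA_SIZE,
                     mean_speed: float = 0.15, dt: float = 0.010,
                     seed=None, tau: float = 1.0) -> Trajectory:
    """Synthetic open-field foraging path.

    The velocity follows a mean-reverting (Ornstein-Uhlenbeck) process with
    relaxation time ``tau`` whose stationary speed averages ``mean_speed``;
    walls reflect.  Emulates a rat foraging in a square box: smooth heading
    changes, broad speed distribution, near-complete arena coverage over
    tens of minutes.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    # 2D OU: stationary per-component sd s gives mean speed s*sqrt(pi/2)
    s = mean_speed / np.sqrt(np.pi / 2.0)
    a = np.exp(-dt / tau)
    noise_sd = s * np.sqrt(1.0 - a * a)
    pos = np.empty((n, 2))
    pos[0] = rng.uniform(0.2 * arena, 0.8 * arena, size=2)
    v = rng.normal(0.0, s, size=2)
    for k in range(1, n):
        v = a * v + rng.normal(0.0, noise_sd, size=2)
        p = pos[k - 1] + v * dt
        for d in range(2):
            if p[d] < 0:
                p[d] = -p[d]
                v[d] = -v[d]
            elif p[d] > arena:
                p[d] = 2 * arena - p[d]
                v[d] = -v[d]
        pos[k] = np.clip(p, 0.0, arena)
    times = np.arange(n) * dt
    return Trajectory(times, pos, arena)
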