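"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive results by exhaustive enumeration
(boundary-matrix reduction over all simplices; min-max matching by subset
DP) so that the package's optimized persistence and bottleneck routines
are checked against a second, independent route.
"""

import itertools

import numpy as np
import pytest

from gridtorus import gridsim as gs
from gridtorus.barcodes import make_reference, toroidality, h1h2_gap
from gridtorus.pipeline import TdaConfig, run_tda


# ---------------------------------------------------------------------------
# oracle: Rips persistence by full boundary-matrix reduction (tiny n only)


def brute_rips(D, maxdim=2, threshold=None):
    """Persistence bars {dim: [(birth, death), ...]} by reducing the full
    boundary matrix of every simplex up to dim maxdim+1.  Zero-persistence
    pairs are kept out; essential classes are truncated at the cutoff."""
    n = D.shape[0]
    if threshold is None:
        threshold = D.max(axis=1).min()
    simplices = []
    for d in range(0, maxdim + 2):
        for vs in itertools.combinations(range(n), d + 1):
            diam = max([D[a, b] for a, b in itertools.combinations(vs, 2)],
                       default=0.0)
            if diam <= threshold:
                simplices.append((diam, d, vs))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    pos = {s[2]: i for i, s in enumerate(simplices)}
    cols = []
    for diam, d, vs in simplices:
        cols.append(set() if d == 0 else
                    {pos[f] for f in itertools.combinations(vs, d)})
    lowinv = {}
    pairs = []
    for j in range(len(cols)):
        c = set(cols[j])
        while c:
            low = max(c)
            if low in lowinv:
                c ^= cols[lowinv[low]]
            else:
                lowinv[low] = j
                pairs.append((low, j))
                break
        cols[j] = c
    paired = set()
    bars = {d: [] for d in range(maxdim + 1)}
    for i, j in pairs:
        paired.add(i)
        paired.add(j)
        diam_i, d, _ = simplices[i]
        diam_j = simplices[j][0]
        if d <= maxdim and diam_j > diam_i:
            bars[d].append((diam_i, diam_j))
    for i, (diam, d, vs) in enumerate(simplices):
        if i not in paired and d <= maxdim:
            bars[d].append((diam, threshold))
    return {d: sorted(bars[d]) for d in bars}


# ---------------------------------------------------------------------------
# oracle: bottleneck distance by exhaustive min-max matching


def brute_bottleneck(P, Q, allow_diagonal=True):
    """Min over all matchings of the max pair cost, by DP over subsets of Q.

    P, Q are (n, 2) arrays with n <= ~8.  With the diagonal allowed, any
    bar may instead pair with the diagonal at cost persistence/2.
    """
    P = np.asarray(P, dtype=float).reshape(-1, 2)
    Q = np.asarray(Q, dtype=float).reshape(-1, 2)
    n1, n2 = len(P), len(Q)
    if not allow_diagonal:
        assert n1 == n2
        best = np.inf
        cost = np.maximum(np.abs(P[:, None, 0] - Q[None, :, 0]),
                          np.abs(P[:, None, 1] - Q[None, :, 1]))
        for perm in itertools.permutations(range(n2)):
            best = min(best, max(cost[i, perm[i]] for i in range(n1))
                       if n1 else 0.0)
        return best
    cost = (np.maximum(np.abs(P[:, None, 0] - Q[None, :, 0]),
                       np.abs(P[:, None, 1] - Q[None, :, 1]))
            if n1 and n2 else np.empty((n1, n2)))
    dp = P[:, 1] - P[:, 0]
    dq = Q[:, 1] - Q[:, 0]
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i, used):
        if i == n1:
            # leftover Q bars go to the diagonal
            rest = [dq[j] / 2 for j in range(n2) if not used >> j & 1]
            return max(rest, default=0.0)
        best = np.inf
        # P_i to the diagonal
        best = min(best, max(dp[i] / 2, rec(i + 1, used)))
        for j in range(n2):
            if not used >> j & 1:
                best = min(best, max(cost[i, j], rec(i + 1, used | 1 << j)))
        return best

    return rec(0, 0)


# ---------------------------------------------------------------------------
# session fixtures: the simulated-module study (shared by the acceptance
# tests and the heavier property tests)

SIM_SEEDS = (1, 2, 3, 4, 5)
DISPLACEMENTS = (0.0, 0.06, 0.12, 0.18, 0.24)
PIPE = TdaConfig(n_points=300, seed=0)


@pytest.fixture(scope="session")
def foraging_trajectory():
    """30-minute synthetic foraging path shared by all simulations."""
    return gs.synth_trajectory(1800.0, seed=1000)


@pytest.fixture(scope="session")
def oscillator_bank():
    return gs.build_oscillator_bank("methods_default")


def _run_module(traj, bank, pop_seed, sim_seed, displacement=0.0):
    pop = gs.build_population(seed=pop_seed)
    if displacement > 0:
        pop = gs.displace_fields(pop, displacement, seed=777 + pop_seed)
    spikes = gs.simulate(pop, traj, bank, seed=sim_seed)
    bset = run_tda(spikes, PIPE)
    return spikes, bset


@pytest.fixture(scope="session")
def osc_spikes(foraging_trajectory, oscillator_bank):
    """Spike trains of one oscillation-modulated module (no pipeline)."""
    pop = gs.build_population(seed=SIM_SEEDS[0])
    return gs.simulate(pop, foraging_trajectory, oscillator_bank,
                       seed=10_000 + SIM_SEEDS[0])


@pytest.fixture(scope="session")
def module_study(foraging_trajectory, oscillator_bank):
    """Simulated-module runs: oscillation-modulated and unmodulated
    populations over the shared trajectory, plus displaced-field variants
    and a designated oscillatory reference run."""
    traj = foraging_trajectory
    bank_none = gs.build_oscillator_bank("none")

    study = {"osc": [], "none": [], "displaced": {}}
    for seed in SIM_SEEDS:
        _, bset = _run_module(traj, oscillator_bank, seed, 10_000 + seed)
        study["osc"].append(bset)
    for seed in SIM_SEEDS:
        _, bset = _run_module(traj, bank_none, seed, 10_000 + seed)
        study["none"].append(bset)
    for frac in DISPLACEMENTS[1:]:
        runs = []
        for seed in SIM_SEEDS[:3]:
            _, bset = _run_module(traj, oscillator_bank, seed,
                                  10_000 + seed, displacement=frac)
            runs.append(bset)
        study["displaced"][frac] = runs
    # level 0 of the displacement scan reuses the undisplaced runs
    study["displaced"][0.0] = study["osc"][:3]
    # external reference: data-mode reference of an independent
    # oscillation-modulated run (synthetic stand-in for a recorded module)
    _, ref_bset = _run_module(traj, oscillator_bank, 99, 99_000)
    study["reference"] = make_reference(ref_bset, "data")
    return study


def score_self(bset):
    return toroidality(bset, make_reference(bset, "self"))
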