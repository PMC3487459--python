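"""Finite-population Moran-type simulator with transformation.

Genotypes are compartments of integer counts ``n_i``. Four event kinds
change the state by independent +1/-1 vectors:

* birth of type ``i`` at rate ``B * f_i * n_i`` (+1 to ``i``), where
  ``f_i = exp(m_i)`` converts Malthusian to Fisherean fitness;
* death of type ``i`` at rate ``B * (N / N0) * n_i`` (-1): the density-
  dependent death term regulates the total ``N`` around the carrying
  capacity ``N0``;
* mutation ``i -> j`` for each of the L single-step neighbors ``j`` at rate
  ``mu * n_i``;
* recombination (transformation) ``i -> j = flip(i, l)`` at rate
  ``(r/L) * n_i * A_l / N``, where ``A_l`` is the number of individuals
  carrying the incoming allele at locus ``l`` (the free-DNA pool mirrors
  the population's allele frequencies).

The simulator core is a hybrid of Gillespie's exact SSA and tau-leaping:
any event channel touching a compartment smaller than
``tau_leap_threshold`` fires exactly, while the remaining channels advance
by Poisson leaps over a step bounded so that no compartment's expected
change exceeds a fraction ``leap_eps`` of its size. Leap draws that would
drive a count negative are re-drawn over a halved step. Setting
``tau_leap_threshold = inf`` recovers the pure (statistically exact) SSA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .landscape import FitnessLandscape

__all__ = [
    "StochParams",
    "PopulationState",
    "ReplicateResult",
    "FixationStats",
    "fisher_fitness",
    "event_rates",
    "simulate",
    "mean_fixation_time",
    "stochastic_t_fix",
]

# replicate status codes (shared with the jit core)
FIXED, CENSORED, EXTINCT, LOST = 0, 1, 2, 3
_STATUS_NAMES = {FIXED: "fixed", CENSORED: "censored",
                 EXTINCT: "extinct", LOST: "lost"}


@dataclass(frozen=True)
class StochParams:
    """Parameters of the finite-population simulator.

    B : birth/death clock scale (per capita per unit time).
    N0 : carrying capacity (target population size).
    mu : per-locus mutation rate.
    r : total per-genome recombination rate (each locus at r/L).
    fixation_threshold : peak-frequency cutoff (default 0.95).
    n_reps : replicates per arm for summary statistics.
    tau_leap_threshold : compartment size above which channels may leap;
        ``inf`` gives pure SSA.
    leap_eps : relative per-step change bound used to select tau.
    t_max : censoring horizon; ``None`` derives 50x the deterministic
        fixation time of the same landscape.
    """

    N0: int = 10_000
    B: float = 1.0
    mu: float = 1e-5
    r: float = 0.05
    fixation_threshold: float = 0.95
    n_reps: int = 50
    seed: int = 0
    tau_leap_threshold: float = 100.0
    leap_eps: float = 0.03
    t_max: float | None = None
    rate_convention: str = "total"

    def __post_init__(self):
        if self.B <= 0:
            raise ValueError(f"B must be positive, got {self.B}")
        if self.N0 < 2:
            raise ValueError(f"N0 must be >= 2, got {self.N0}")
        if not 0 < self.fixation_threshold < 1:
            raise ValueError(
                f"fixation_threshold must be in (0,1), got {self.fixation_threshold}")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mu and r must be >= 0")
        if self.rate_convention not in ("total", "per_locus"):
            raise ValueError(f"unknown rate convention {self.rate_convention!r}")

    def per_locus_rate(self, L: int) -> float:
        return self.r / L if self.rate_convention == "total" else self.r


@dataclass
class PopulationState:
    """Integer count per genotype compartment at model time ``t``."""

    n: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=np.int64)
        if np.any(self.n < 0):
            raise ValueError("compartment counts must be non-negative")
        if self.n.sum() <= 0:
            raise ValueError("total population must be positive")

    @property
    def N(self) -> int:
        return int(self.n.sum())


@dataclass
class ReplicateResult:
    status: str
    time: float
    final_counts: np.ndarray
    seed: int
    trajectory_times: np.ndarray | None = None
    trajectory_counts: np.ndarray | None = None

    @property
    def fixed(self) -> bool:
        return self.status == "fixed"


@dataclass
class FixationStats:
    """Fixation-time summary over replicates; censored/extinct replicates
    are reported separately and never averaged in."""

    mean: float
    sd: float | None
    times: np.ndarray
    n_fixed: int
    n_censored: int
    n_extinct: int


def fisher_fitness(m):
    """Fisherean (multiplicative) fitness ``f = exp(m)`` from Malthusian
    ``m``; strictly increasing, with the LFG value m=0 mapping to f=1."""
    return np.exp(m)


def _channel_tables(landscape: FitnessLandscape):
    """Static per-channel arrays: kind, source, minus/plus compartments,
    locus and own-allele bit (recombination channels only)."""
    sp = landscape.space
    n_gen, L = sp.n_genotypes, sp.L
    kinds, src, minus, plus, locus, ownbit = [], [], [], [], [], []
    for i in range(n_gen):  # births
        kinds.append(0); src.append(i); minus.append(-1); plus.append(i)
        locus.append(-1); ownbit.append(-1)
    for i in range(n_gen):  # deaths
        kinds.append(1); src.append(i); minus.append(i); plus.append(-1)
        locus.append(-1); ownbit.append(-1)
    for i in range(n_gen):  # mutations
        for l in range(L):
            kinds.append(2); src.append(i); minus.append(i)
            plus.append(int(sp.neighbors[i, l])); locus.append(l); ownbit.append(-1)
    for i in range(n_gen):  # recombination (single-allele replacement)
        for l in range(L):
            kinds.append(3); src.append(i); minus.append(i)
            plus.append(int(sp.neighbors[i, l])); locus.append(l)
            ownbit.append(int(sp.bits[i, l]))
    to = lambda a: np.array(a, dtype=np.int64)
    return to(kinds), to(src), to(minus), to(plus), to(locus), to(ownbit)


def event_rates(state: PopulationState, landscape: FitnessLandscape,
                params: StochParams) -> pd.DataFrame:
    """Full rate table over (kind, genotype[, locus, product]) at ``state``.

    Mirrors exactly the rates used by the simulator core; mainly for
    inspection and testing.
    """
    sp = landscape.space
    n = state.n
    N = state.N
    f = fisher_fitness(landscape.m)
    kinds, src, minus, plus, locus, ownbit = _channel_tables(landscape)
    A1 = sp.bits.T.astype(np.int64) @ n  # 1-allele counts per locus
    rL = params.per_locus_rate(sp.L)
    rates = np.empty(len(kinds))
    for c in range(len(kinds)):
        i = src[c]
        if kinds[c] == 0:
            rates[c] = params.B * f[i] * n[i]
        elif kinds[c] == 1:
            rates[c] = params.B * (N / params.N0) * n[i]
        elif kinds[c] == 2:
            rates[c] = params.mu * n[i]
        else:
            pool = A1[locus[c]] if ownbit[c] == 0 else N - A1[locus[c]]
            rates[c] = rL * n[i] * pool / N
    kind_names = np.array(["birth", "death", "mutation", "recombination"])
    return pd.DataFrame({
        "kind": kind_names[kinds],
        "genotype": [sp.to_string(g) for g in src],
        "locus": locus,
        "product": [sp.to_string(g) if g >= 0 and kinds[c] >= 2 else ""
                    for c, g in enumerate(plus)],
        "rate": rates,
    })


@njit(cache=True)
def _hybrid_core(n, f, bits, B, N0, mu, rL, peak, thr, t_max,
                 crit_thresh, leap_eps, seed,
                 ch_kind, ch_src, ch_minus, ch_plus, ch_locus, ch_ownbit,
                 record_times, traj_out):  # pragma: no cover (jit)
    np.random.seed(seed)
    n_gen = n.shape[0]
    L = bits.shape[1]
    n_ch = ch_kind.shape[0]
    rates = np.zeros(n_ch)
    is_crit = np.zeros(n_ch, dtype=np.uint8)
    D = np.zeros(n_gen)
    dn = np.zeros(n_gen, dtype=np.int64)
    A1 = np.zeros(L, dtype=np.int64)
    t = 0.0
    rec_i = 0
    n_rec = record_times.shape[0]
    status = 1  # censored unless decided otherwise
    while True:
        N = 0
        for g in range(n_gen):
            N += n[g]
        if N == 0:
            status = 2
            break
        if n[peak] >= thr * N:
            status = 0
            break
        if mu == 0.0 and rL == 0.0 and n[peak] == 0 and rec_i >= n_rec:
            # peak lost and can never re-arise; nothing left to record
            status = 3
            break
        if t >= t_max:
            status = 1
            break

        for l in range(L):
            a = 0
            for g in range(n_gen):
                a += bits[g, l] * n[g]
            A1[l] = a

        crit_total = 0.0
        for g in range(n_gen):
            D[g] = 0.0
        for c in range(n_ch):
            i = ch_src[c]
            if n[i] == 0:
                rates[c] = 0.0
                is_crit[c] = 0
                continue
            k = ch_kind[c]
            if k == 0:
                rate = B * f[i] * n[i]
            elif k == 1:
                rate = B * (N / N0) * n[i]
            elif k == 2:
                rate = mu * n[i]
            else:
                l = ch_locus[c]
                pool = A1[l] if ch_ownbit[c] == 0 else N - A1[l]
                rate = rL * n[i] * pool / N
            rates[c] = rate
            if rate == 0.0:
                is_crit[c] = 0
                continue
            crit = False
            if ch_minus[c] >= 0 and n[ch_minus[c]] < crit_thresh:
                crit = True
            if ch_plus[c] >= 0 and n[ch_plus[c]] < crit_thresh:
                crit = True
            if crit:
                is_crit[c] = 1
                crit_total += rate
            else:
                is_crit[c] = 0
                if ch_minus[c] >= 0:
                    D[ch_minus[c]] += rate
                if ch_plus[c] >= 0:
                    D[ch_plus[c]] += rate

        tau = np.inf
        for g in range(n_gen):
            if D[g] > 0.0:
                bound = leap_eps * n[g]
                if bound < 1.0:
                    bound = 1.0
                cand = bound / D[g]
                if cand < tau:
                    tau = cand
        if crit_total > 0.0:
            dt_crit = np.random.exponential(1.0 / crit_total)
        else:
            dt_crit = np.inf

        if not np.isfinite(tau) and not np.isfinite(dt_crit):
            # no event can ever happen again
            t = t_max
            status = 1
            break

        fire_crit = dt_crit <= tau
        step = dt_crit if fire_crit else tau
        if t + step > t_max:
            step = t_max - t
            fire_crit = False

        # leap with redraw-on-negativity safeguard
        for _attempt in range(80):
            for g in range(n_gen):
                dn[g] = 0
            for c in range(n_ch):
                if is_crit[c] == 0 and rates[c] > 0.0:
                    kdraw = np.random.poisson(rates[c] * step)
                    if kdraw > 0:
                        if ch_minus[c] >= 0:
                            dn[ch_minus[c]] -= kdraw
                        if ch_plus[c] >= 0:
                            dn[ch_plus[c]] += kdraw
            if fire_crit:
                u = np.random.random() * crit_total
                acc = 0.0
                for c in range(n_ch):
                    if is_crit[c] == 1:
                        acc += rates[c]
                        if u <= acc:
                            if ch_minus[c] >= 0:
                                dn[ch_minus[c]] -= 1
                            if ch_plus[c] >= 0:
                                dn[ch_plus[c]] += 1
                            break
            ok = True
            for g in range(n_gen):
                if n[g] + dn[g] < 0:
                    ok = False
                    break
            if ok:
                break
            step *= 0.5
            fire_crit = False

        while rec_i < n_rec and record_times[rec_i] <= t + step:
            for g in range(n_gen):
                traj_out[rec_i, g] = n[g]
            rec_i += 1
        t += step
        for g in range(n_gen):
            n[g] += dn[g]

    while rec_i < n_rec:
        for g in range(n_gen):
            traj_out[rec_i, g] = n[g]
        rec_i += 1
    return status, t


def _resolve_t_max(landscape: FitnessLandscape, params: StochParams) -> float:
    if params.t_max is not None:
        return float(params.t_max)
    from .deterministic import DynamicsParams, fixation_time
    det = fixation_time(landscape, DynamicsParams(
        mu=params.mu, r=0.0, rate_convention=params.rate_convention))
    if not det.fixed:  # pragma: no cover
        raise ValueError("cannot derive t_max: deterministic reference "
                         "did not fix; set t_max explicitly")
    return 50.0 * det.time / params.B


def simulate(landscape: FitnessLandscape, params: StochParams,
             x0: PopulationState | None = None,
             seed: int | None = None,
             record_times: np.ndarray | None = None) -> ReplicateResult:
    """Run one replicate until (near) fixation of the peak, censoring at
    ``t_max``, extinction, or loss of the peak when it cannot re-arise.

    The default initial state is monomorphic for the least fit genotype at
    size ``N0``. ``record_times`` requests state snapshots on a time grid.
    """
    sp = landscape.space
    if x0 is None:
        counts = np.zeros(sp.n_genotypes, dtype=np.int64)
        counts[sp.bottom] = params.N0
        x0 = PopulationState(counts)
    n = x0.n.copy()
    if seed is None:
        seed = params.seed
    seed32 = int(np.uint32(seed))
    t_max = _resolve_t_max(landscape, params)
    kinds, src, minus, plus, locus, ownbit = _channel_tables(landscape)
    rec = (np.asarray(record_times, dtype=float)
           if record_times is not None else np.empty(0))
    traj = np.zeros((len(rec), sp.n_genotypes), dtype=np.int64)
    crit = params.tau_leap_threshold
    crit = np.inf if not np.isfinite(crit) else float(crit)
    status, t = _hybrid_core(
        n, fisher_fitness(landscape.m), sp.bits.astype(np.int64),
        float(params.B), float(params.N0), float(params.mu),
        float(params.per_locus_rate(sp.L)), sp.peak,
        float(params.fixation_threshold), float(t_max), crit,
        float(params.leap_eps), seed32,
        kinds, src, minus, plus, locus, ownbit, rec, traj)
    return ReplicateResult(
        status=_STATUS_NAMES[int(status)], time=float(t), final_counts=n,
        seed=seed32,
        trajectory_times=rec if record_times is not None else None,
        trajectory_counts=traj if record_times is not None else None)


def replicate_seeds(master_seed: int, n_reps: int) -> np.ndarray:
    """Per-replicate child seeds, derived deterministically from the master
    seed via ``numpy.random.SeedSequence``."""
    return np.random.SeedSequence(int(master_seed)).generate_state(n_reps)


def mean_fixation_time(landscape: FitnessLandscape,
                       params: StochParams) -> FixationStats:
    """Mean and SD of fixation times over ``n_reps`` seeded replicates.

    Censored, lost and extinct replicates are counted separately and never
    enter the mean. All replicates censored raises."""
    if params.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if params.t_max is None:
        params = replace(params, t_max=_resolve_t_max(landscape, params))
    seeds = replicate_seeds(params.seed, params.n_reps)
    times, n_cens, n_ext = [], 0, 0
    for s in seeds:
        rep = simulate(landscape, params, seed=int(s))
        if rep.fixed:
            times.append(rep.time)
        elif rep.status == "extinct":
            n_ext += 1
        else:
            n_cens += 1
    if not times:
        raise RuntimeError(
            f"all {params.n_reps} replicates censored or extinct "
            f"(censored={n_cens}, extinct={n_ext})")
    arr = np.array(times)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
    return FixationStats(mean=float(arr.mean()), sd=sd, times=arr,
                         n_fixed=len(arr), n_censored=n_cens, n_extinct=n_ext)


def stochastic_t_fix(landscape: FitnessLandscape,
                     params: StochParams) -> tuple[float, FixationStats, FixationStats]:
    """T_fix estimate: ratio of mean fixation time with recombination to
    mean fixation time without, each over ``n_reps`` replicates.

    The two arms use independent child seeds derived from the master seed."""
    arm_seeds = np.random.SeedSequence(int(params.seed)).generate_state(4)[2:]
    if params.t_max is None:
        params = replace(params, t_max=_resolve_t_max(landscape, params))
    with_r = mean_fixation_time(landscape, replace(params, seed=int(arm_seeds[0])))
    without_r = mean_fixation_time(
        landscape, replace(params, r=0.0, seed=int(arm_seeds[1])))
    return with_r.mean / without_r.mean, with_r, without_r
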