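"""Infinite-population dynamics: mutation, selection and transformation.

The genotype-frequency vector ``x`` (length ``2**L``, on the simplex) obeys

    dx_i/dt =  mu * sum_{j in N(i)} x_j  -  mu * L * x_i
             + (m_i - mbar) * x_i
             + (r/L) * sum_l [ x_{flip(i,l)} * p_l(a_il) - x_i * p_l(1 - a_il) ]

where ``N(i)`` are the L single-step mutational neighbors of ``i``, ``m_i``
the Malthusian fitness, ``mbar`` the population mean fitness, ``a_il`` the
allele of ``i`` at locus ``l`` and ``p_l(a)`` the frequency of allele ``a``
at locus ``l`` in the population (the free-DNA pool mirrors the population).
Transformation replaces a single allele per event; ``r`` is the *total*
per-genome uptake rate, so each locus is replaced at rate ``r/L``
(``rate_convention="per_locus"`` instead applies ``r`` at every locus).

Fixation of the peak genotype is detected by integrating with an event on
its frequency crossing ``fixation_threshold`` (default 0.99). Non-fixation
by ``t_max`` — possible at high recombination rates on valley landscapes —
is a first-class, flagged result, not an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .landscape import FitnessLandscape, GenotypeSpace

_log = logging.getLogger(__name__)

__all__ = [
    "DynamicsParams",
    "FixationResult",
    "Trajectory",
    "allele_frequencies",
    "recombination_indicator",
    "make_rhs",
    "ode_rhs",
    "integrate",
    "fixation_time",
    "t_fix_ratio",
    "pairwise_LD",
    "critical_recombination_rate",
    "time_to_mean_fitness",
]


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the deterministic dynamics.

    mu : per-locus mutation rate (forward = backward).
    r : total per-genome recombination (DNA-uptake) rate; each locus is
        replaced at r/L under the default ``rate_convention="total"``.
    fixation_threshold : peak-frequency cutoff defining fixation.
    t_max : integration horizon; reaching it without fixation is censoring.
    rtol, atol : integrator tolerances.
    """

    mu: float = 1e-5
    r: float = 0.05
    fixation_threshold: float = 0.99
    t_max: float = 1e6
    rate_convention: str = "total"
    selection_scale: str = "malthusian"
    B: float = 1.0
    rtol: float = 1e-10
    atol: float = 1e-14

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.r < 0:
            raise ValueError(f"r must be >= 0, got {self.r}")
        if not 0 < self.fixation_threshold < 1:
            raise ValueError(
                f"fixation_threshold must be in (0,1), got {self.fixation_threshold}")
        if self.rate_convention not in ("total", "per_locus"):
            raise ValueError(f"unknown rate convention {self.rate_convention!r}")
        if self.selection_scale not in ("malthusian", "fisherean"):
            raise ValueError(f"unknown selection scale {self.selection_scale!r}")
        if self.B <= 0:
            raise ValueError(f"B must be positive, got {self.B}")

    def per_locus_rate(self, L: int) -> float:
        return self.r / L if self.rate_convention == "total" else self.r


@dataclass(frozen=True)
class FixationResult:
    """Outcome of a fixation-time measurement.

    ``fixed`` is False when the threshold was not crossed by ``t_max``; the
    censoring time is then reported in ``time``.
    """

    time: float
    fixed: bool

    def require_fixed(self) -> float:
        if not self.fixed:
            raise RuntimeError(
                f"peak genotype not fixed by t = {self.time:g}; "
                "high recombination can stabilize the unadapted state")
        return self.time


@dataclass
class Trajectory:
    t: np.ndarray
    x: np.ndarray  # shape (len(t), 2**L)
    fixed: bool
    fixation_time: float | None


def allele_frequencies(x: np.ndarray, space: GenotypeSpace) -> np.ndarray:
    """Per-locus frequency of the beneficial (1) allele: p_l = sum over
    genotypes carrying a 1 at locus l."""
    return space.bits.T.astype(float) @ np.asarray(x, dtype=float)


def recombination_indicator(space: GenotypeSpace, acceptor: int, donor: int,
                            locus: int, product: int) -> int:
    """1 iff replacing the acceptor's allele at ``locus`` by the donor's
    yields ``product`` and actually changes the genotype; else 0.

    Same-allele replacement is a no-op and scores 0 for every product."""
    a_bit = (acceptor >> locus) & 1
    d_bit = (donor >> locus) & 1
    if a_bit == d_bit:
        return 0
    recombinant = acceptor ^ (1 << locus)
    return int(product == recombinant)


def make_rhs(landscape: FitnessLandscape,
             params: DynamicsParams) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compiled-closure right-hand side ``f(t, x) -> dx/dt``.

    The returned callable is what :func:`integrate` hands to the ODE solver;
    :func:`ode_rhs` wraps it for one-off evaluation.
    """
    sp = landscape.space
    L = sp.L
    # selection acts on Malthusian differences (the model under study) or,
    # with selection_scale="fisherean", on B*(exp(m_i) - fbar): the exact
    # mean-field limit of the finite-population simulator, used to validate
    # stochastic-to-deterministic convergence.
    if params.selection_scale == "fisherean":
        m = params.B * np.exp(landscape.m)
    else:
        m = landscape.m
    mu = params.mu
    rho = params.per_locus_rate(L)
    nb = sp.neighbors
    bits = sp.bits.astype(float)

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite genotype frequencies")
        dx = (m - m @ x) * x
        if mu > 0:
            dx += mu * x[nb].sum(axis=1) - mu * L * x
        if rho > 0:
            p1 = bits.T @ x
            # p_own[g, l]: pool frequency of g's own allele at locus l
            p_own = bits * p1 + (1.0 - bits) * (1.0 - p1)
            influx = (x[nb] * p_own).sum(axis=1)
            outflux = x * (L - p_own.sum(axis=1))
            dx += rho * (influx - outflux)
        return dx

    return rhs


def ode_rhs(x: np.ndarray, landscape: FitnessLandscape,
            params: DynamicsParams) -> np.ndarray:
    """One-off evaluation of dx/dt at state ``x``."""
    return make_rhs(landscape, params)(0.0, np.asarray(x, dtype=float))


def default_x0(space: GenotypeSpace) -> np.ndarray:
    """Point mass on the least fit (all-0) genotype."""
    x0 = np.zeros(space.n_genotypes)
    x0[space.bottom] = 1.0
    return x0


def _renormalize_states(xs: np.ndarray) -> np.ndarray:
    """Clip negatives and renormalize rows whose mass drifted beyond 1e-8;
    each intervention is logged at DEBUG level."""
    xs = np.clip(xs, 0.0, None)
    sums = xs.sum(axis=1)
    drifted = np.abs(sums - 1.0) > 1e-8
    if np.any(drifted):
        _log.debug("renormalized %d/%d output states (max drift %.3g)",
                   int(drifted.sum()), len(sums), float(np.abs(sums - 1).max()))
        xs[drifted] /= sums[drifted, None]
    return xs


def integrate(landscape: FitnessLandscape, params: DynamicsParams,
              x0: np.ndarray | None = None,
              t_eval: np.ndarray | None = None,
              stop_at_fixation: bool = True) -> Trajectory:
    """Integrate the dynamics from ``x0`` (default: all-0 point mass).

    Uses a stiff-capable adaptive solver (LSODA) with an event on the peak
    frequency crossing the fixation threshold. States are defensively
    clipped/renormalized on output only when drift exceeds 1e-8.
    """
    sp = landscape.space
    if x0 is None:
        x0 = default_x0(sp)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (sp.n_genotypes,):
        raise ValueError(f"x0 must have length {sp.n_genotypes}")
    if abs(x0.sum() - 1.0) > 1e-8 or np.any(x0 < -1e-12):
        raise ValueError("x0 must lie on the simplex")

    rhs = make_rhs(landscape, params)
    peak = sp.peak
    thr = params.fixation_threshold

    def fixation_event(t, x):
        return x[peak] - thr

    fixation_event.terminal = bool(stop_at_fixation)
    fixation_event.direction = 1

    sol = solve_ivp(rhs, (0.0, params.t_max), x0, method="LSODA",
                    rtol=params.rtol, atol=params.atol,
                    t_eval=t_eval, events=fixation_event, dense_output=False)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    fixed = len(sol.t_events[0]) > 0
    tfix = float(sol.t_events[0][0]) if fixed else None
    xs = _renormalize_states(sol.y.T.copy())
    return Trajectory(t=sol.t, x=xs, fixed=fixed, fixation_time=tfix)


def fixation_time(landscape: FitnessLandscape, params: DynamicsParams,
                  x0: np.ndarray | None = None) -> FixationResult:
    """First time the peak genotype's frequency exceeds the threshold."""
    traj = integrate(landscape, params, x0=x0, stop_at_fixation=True)
    if traj.fixed:
        return FixationResult(time=traj.fixation_time, fixed=True)
    return FixationResult(time=params.t_max, fixed=False)


def t_fix_ratio(landscape: FitnessLandscape,
                params: DynamicsParams) -> tuple[float, FixationResult, FixationResult]:
    """T_fix: fixation time with recombination over fixation time without.

    T_fix > 1 means transformation decelerates adaptation. Returns the
    ratio together with both arm results; censored arms raise via
    :meth:`FixationResult.require_fixed` semantics only when the ratio is
    requested, so callers can inspect the flags instead.
    """
    with_r = fixation_time(landscape, params)
    without_r = fixation_time(landscape, replace(params, r=0.0))
    if with_r.fixed and without_r.fixed:
        ratio = with_r.time / without_r.time
    else:
        ratio = np.nan
    return ratio, with_r, without_r


def pairwise_LD(x: np.ndarray, space: GenotypeSpace,
                locus_a: int, locus_b: int) -> float:
    """Linkage disequilibrium D = f_11 - p_a(1) * p_b(1) between two loci,
    marginalized over all other loci. For L=2 this equals
    ``x_11 * x_00 - x_10 * x_01``."""
    if locus_a == locus_b:
        raise ValueError("LD requires two distinct loci")
    x = np.asarray(x, dtype=float)
    ba = space.bits[:, locus_a].astype(float)
    bb = space.bits[:, locus_b].astype(float)
    f11 = float((ba * bb) @ x)
    return f11 - float(ba @ x) * float(bb @ x)


def _require_two_locus_valley(landscape: FitnessLandscape) -> None:
    sp = landscape.space
    if sp.L != 2:
        raise ValueError("critical-rate analysis is defined for L = 2")
    m = landscape.m
    if not (m[1] < m[0] and m[2] < m[0] and m[0] < m[3]):
        raise ValueError(
            "not a fitness valley: need m(01), m(10) < m(00) < m(11); "
            f"got m = {m.tolist()}")


def critical_recombination_rate(landscape: FitnessLandscape,
                                method: str = "eigen",
                                tol: float = 1e-6,
                                r_upper: float | None = None) -> float:
    """Critical recombination rate r_c of the two-locus valley landscape.

    For r > r_c the mutation-free fixed point at the all-0 genotype is
    stable and the peak genotype cannot invade; r_c equals the fitness
    difference m(11) - m(00) between the two extreme genotypes (total-rate
    convention).

    method="eigen" locates the sign change of the leading eigenvalue of the
    numerically evaluated Jacobian of the mutation-free dynamics at the
    00-fixation point; method="invasion" is an independent oracle that
    bisects on the long-time ODE outcome with a small 11-inoculum.
    """
    _require_two_locus_valley(landscape)
    m = landscape.m
    if r_upper is None:
        r_upper = 4.0 * (m[3] - m[0]) + 0.1

    if method == "eigen":
        crit = _leading_eigenvalue_at_bottom
    elif method == "invasion":
        crit = _invasion_growth
    else:
        raise ValueError(f"unknown method {method!r}")

    lo, hi = 0.0, float(r_upper)
    if crit(landscape, lo) <= 0 or crit(landscape, hi) >= 0:
        raise RuntimeError("bracketing failed; enlarge r_upper")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if crit(landscape, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _mutation_free_params(r: float) -> DynamicsParams:
    return DynamicsParams(mu=0.0, r=r)


def _leading_eigenvalue_at_bottom(landscape: FitnessLandscape, r: float) -> float:
    """Max real eigenvalue of the Jacobian of the mu=0 dynamics at x = e_00,
    restricted to directions that perturb away from the fixed point."""
    rhs = make_rhs(landscape, _mutation_free_params(r))
    n = landscape.space.n_genotypes
    x_star = np.zeros(n)
    x_star[landscape.space.bottom] = 1.0
    h = 1e-7
    J = np.empty((n, n))
    f0 = rhs(0.0, x_star)
    for j in range(n):
        xp = x_star.copy()
        xp[j] += h
        J[:, j] = (rhs(0.0, xp) - f0) / h
    eigvals = np.linalg.eigvals(J)
    # remaining modes (00-scaling, valley directions) are strictly negative
    # on a valley landscape, so the max real part is the invasion eigenvalue
    return float(eigvals.real.max())


def _invasion_growth(landscape: FitnessLandscape, r: float,
                     inoculum: float = 1e-5) -> float:
    """Signed invasion score of the peak genotype: positive iff a small
    11-inoculum grows under the mutation-free dynamics."""
    sp = landscape.space
    x0 = np.zeros(sp.n_genotypes)
    x0[sp.bottom] = 1.0 - inoculum
    x0[sp.peak] = inoculum
    params = DynamicsParams(mu=0.0, r=r, t_max=2e4,
                            fixation_threshold=0.5)
    traj = integrate(landscape, params, x0=x0, stop_at_fixation=True)
    if traj.fixed:
        return 1.0
    final_peak = traj.x[-1, sp.peak]
    return float(final_peak - inoculum)


def mean_fitness(x: np.ndarray, landscape: FitnessLandscape) -> float:
    return float(landscape.m @ np.asarray(x, dtype=float))


def time_to_mean_fitness(landscape: FitnessLandscape, params: DynamicsParams,
                         threshold: float,
                         x0: np.ndarray | None = None) -> FixationResult:
    """First time the population mean fitness exceeds ``threshold``.

    An alternative adaptation-rate measure; across topographies it is
    strongly rank-correlated with the peak-fixation time."""
    sp = landscape.space
    if x0 is None:
        x0 = default_x0(sp)
    if mean_fitness(x0, landscape) >= threshold:
        return FixationResult(time=0.0, fixed=True)

    rhs = make_rhs(landscape, params)
    m = landscape.m

    def event(t, x):
        return m @ x - threshold

    event.terminal = True
    event.direction = 1
    sol = solve_ivp(rhs, (0.0, params.t_max), np.asarray(x0, dtype=float),
                    method="LSODA", rtol=params.rtol, atol=params.atol,
                    events=event)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    if len(sol.t_events[0]):
        return FixationResult(time=float(sol.t_events[0][0]), fixed=True)
    return FixationResult(time=params.t_max, fixed=False)
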