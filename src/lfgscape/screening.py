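"""Screens over fitness topographies and parameter grids.

Orchestrates the deterministic and stochastic models over many LFG
configurations: exhaustive screens of T_fix (optionally collapsed over
locus-permutation orbits, which share identical dynamics), box-plot
summaries by LFG count, rank-concordance comparisons between parameter
sets, physiological-epistasis regression, and sampled stochastic screens
with a deterministic reference column.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .deterministic import DynamicsParams, fixation_time, t_fix_ratio
from .landscape import (FitnessLandscape, FitnessTopography, GenotypeSpace,
                        build_landscape, orbit_classes)
from .stochastic import StochParams, stochastic_t_fix

__all__ = [
    "EpistasisEstimate",
    "screen_deterministic",
    "summarize_by_lfg_count",
    "rank_concordance",
    "estimate_physiological_epistasis",
    "screen_stochastic",
]


@dataclass
class EpistasisEstimate:
    """Physiological-epistasis regression result for one landscape:
    least-squares fit of m against k under m(k) = 1 - b * k**eps_hat."""

    topography_id: str
    eps_hat: float
    b_hat: float
    residual: float
    converged: bool


def _grid_frame(grid) -> list[dict]:
    """Normalize a parameter grid to a list of parameter dicts."""
    if isinstance(grid, dict):
        return [grid]
    return [dict(g) for g in grid]


def screen_deterministic(topographies: Iterable[FitnessTopography],
                         grid: Sequence[dict] | dict,
                         use_symmetry: bool = False,
                         done_ids: set | None = None) -> pd.DataFrame:
    """T_fix for every (topography, parameter set) pair.

    Each grid entry may carry s, eps, mu, r (missing keys fall back to the
    standard defaults of :class:`DynamicsParams` and s=0.05, eps=1).
    ``use_symmetry=True`` integrates one representative per locus-
    permutation orbit and copies its T_fix to the other members (orbit
    members have identical dynamics). ``done_ids``: (topography_id, s, eps,
    mu, r) tuples to skip, making screens resumable.
    """
    topos = list(topographies)
    if not topos:
        raise ValueError("no topographies given")
    grid = _grid_frame(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    L = topos[0].L
    space = GenotypeSpace(L)
    if use_symmetry:
        classes = orbit_classes(topos)
    else:
        classes = [[t] for t in topos]

    rows = []
    for params_dict in grid:
        s = params_dict.get("s", 0.05)
        eps = params_dict.get("eps", 1.0)
        dyn = DynamicsParams(
            mu=params_dict.get("mu", DynamicsParams.mu),
            r=params_dict.get("r", DynamicsParams.r),
            fixation_threshold=params_dict.get(
                "fixation_threshold", DynamicsParams.fixation_threshold),
            t_max=params_dict.get("t_max", DynamicsParams.t_max))
        for members in classes:
            rep = members[0]
            key = (rep.label(), s, eps, dyn.mu, dyn.r)
            if done_ids and all(
                    (t.label(), s, eps, dyn.mu, dyn.r) in done_ids
                    for t in members):
                continue
            landscape = build_landscape(space, s, eps, rep)
            ratio, with_r, without_r = t_fix_ratio(landscape, dyn)
            for t in members:
                rows.append({
                    "topography_id": t.label(), "n_lfgs": t.n_lfgs,
                    "s": s, "eps": eps, "mu": dyn.mu, "r": dyn.r,
                    "fixation_time_with_r": with_r.time,
                    "fixation_time_without_r": without_r.time,
                    "t_fix": ratio,
                    "censored_with_r": not with_r.fixed,
                    "censored_without_r": not without_r.fixed,
                })
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["s", "eps", "mu", "r", "n_lfgs", "topography_id"]).reset_index(drop=True)


def summarize_by_lfg_count(results: pd.DataFrame,
                           value: str = "t_fix") -> pd.DataFrame:
    """Box-plot statistics of ``value`` per LFG count: quartiles (inclusive
    linear-interpolation convention), whiskers at the farthest points within
    1.5x IQR of the box ends, and outlier counts."""
    if results.empty:
        raise ValueError("empty results table")
    out = []
    for count, group in results.groupby("n_lfgs"):
        vals = group[value].dropna().to_numpy()
        if len(vals) == 0:
            import warnings
            warnings.warn(f"no uncensored values for n_lfgs={count}; omitted")
            continue
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inliers = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        out.append({
            "n_lfgs": count, "n": len(vals),
            "q1": q1, "median": med, "q3": q3,
            "whisker_low": inliers.min(), "whisker_high": inliers.max(),
            "n_outliers": int(((vals < lo_fence) | (vals > hi_fence)).sum()),
        })
    return pd.DataFrame(out).sort_values("n_lfgs").reset_index(drop=True)


def rank_concordance(results_a: pd.DataFrame, results_b: pd.DataFrame,
                     value: str = "t_fix") -> dict:
    """Compare T_fix across two screens of the same topographies.

    Returns the paired values, the least-squares R^2 of B against A, the
    regression slope, and Spearman's rank correlation.
    """
    a = results_a.set_index("topography_id")[value]
    b = results_b.set_index("topography_id")[value]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("screens share no topographies")
    av, bv = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    keep = np.isfinite(av) & np.isfinite(bv)
    av, bv = av[keep], bv[keep]
    slope, intercept, r, _p, _se = stats.linregress(av, bv)
    rho = stats.spearmanr(av, bv).statistic
    return {"topography_id": np.asarray(shared)[keep],
            "a": av, "b": bv, "r_squared": float(r ** 2),
            "slope": float(slope), "intercept": float(intercept),
            "spearman_rho": float(rho)}


def estimate_physiological_epistasis(landscape: FitnessLandscape,
                                     fix_b: float | None = None) -> EpistasisEstimate:
    """Regress fitness against the number of deleterious mutations.

    Fits ``m(g) = 1 - b * k(g)**eps_hat`` over all genotypes (LFGs enter at
    fitness 0) by nonlinear least squares, multi-started over
    eps in {0.25, 0.5, 1, 2, 4} to avoid local minima.

    With ``fix_b`` set (typically to the basal selection coefficient s),
    the exponent is a pure curvature measure: ``eps_hat > 1`` means the
    fitted fitness schedule dips below the additive line, i.e. intermediates
    are lower than expected (positive magnitude epistasis in the naming used
    for these landscapes). With both parameters free (the default), scale
    and exponent trade off, so the exponent alone is not a curvature sign;
    the free fit recovers (s, eps) exactly on LFG-free landscapes.
    """
    sp = landscape.space
    k = sp.k.astype(float)
    m = landscape.m
    if len(np.unique(k)) < 3:
        raise ValueError("need at least 3 distinct k values to fit epistasis")
    kpos = k > 0

    def resid(theta):
        if fix_b is None:
            b, e = theta
        else:
            b, e = fix_b, theta[0]
        pred = np.ones_like(m)
        pred[kpos] = 1.0 - b * k[kpos] ** e
        return pred - m

    best = None
    for e0 in (0.25, 0.5, 1.0, 2.0, 4.0):
        x0 = [1.0 / sp.L, e0] if fix_b is None else [e0]
        try:
            sol = optimize.least_squares(resid, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None:
        return EpistasisEstimate(landscape.topography.label(),
                                 np.nan, np.nan, np.nan, False)
    if fix_b is None:
        b_hat, eps_hat = best.x
    else:
        b_hat, eps_hat = fix_b, best.x[0]
    return EpistasisEstimate(landscape.topography.label(),
                             float(eps_hat), float(b_hat),
                             float(2 * best.cost), bool(best.success))


def screen_stochastic(topographies: Iterable[FitnessTopography],
                      stoch_params: StochParams,
                      n0_list: Sequence[int],
                      s: float = 0.05, eps: float = 1.0,
                      master_seed: int | None = None) -> pd.DataFrame:
    """Stochastic T_fix per topography and population size, with the
    deterministic T_fix as a reference column; rows sortable by the
    deterministic value. Censored arms are flagged per row."""
    topos = list(topographies)
    if not topos:
        raise ValueError("no topographies given")
    space = GenotypeSpace(topos[0].L)
    if master_seed is None:
        master_seed = stoch_params.seed
    topo_seeds = np.random.SeedSequence(int(master_seed)).generate_state(len(topos))
    rows = []
    for t_idx, topo in enumerate(topos):
        landscape = build_landscape(space, s, eps, topo)
        dyn = DynamicsParams(mu=stoch_params.mu, r=stoch_params.r,
                             rate_convention=stoch_params.rate_convention)
        det_ratio, det_with, det_without = t_fix_ratio(landscape, dyn)
        for n0 in n0_list:
            p = replace(stoch_params, N0=int(n0),
                        seed=int(np.uint32(topo_seeds[t_idx] + n0)))
            try:
                ratio, with_r, without_r = stochastic_t_fix(landscape, p)
                rows.append({
                    "topography_id": topo.label(), "n_lfgs": topo.n_lfgs,
                    "N0": int(n0), "s": s, "eps": eps,
                    "mu": stoch_params.mu, "r": stoch_params.r,
                    "n_reps": stoch_params.n_reps,
                    "det_t_fix": det_ratio, "t_fix": ratio,
                    "mean_time_with_r": with_r.mean,
                    "mean_time_without_r": without_r.mean,
                    "sd_with_r": with_r.sd, "sd_without_r": without_r.sd,
                    "n_censored_with_r": with_r.n_censored,
                    "n_censored_without_r": without_r.n_censored,
                })
            except RuntimeError:
                rows.append({
                    "topography_id": topo.label(), "n_lfgs": topo.n_lfgs,
                    "N0": int(n0), "s": s, "eps": eps,
                    "mu": stoch_params.mu, "r": stoch_params.r,
                    "n_reps": stoch_params.n_reps,
                    "det_t_fix": det_ratio, "t_fix": np.nan,
                    "mean_time_with_r": np.nan, "mean_time_without_r": np.nan,
                    "sd_with_r": np.nan, "sd_without_r": np.nan,
                    "n_censored_with_r": stoch_params.n_reps,
                    "n_censored_without_r": stoch_params.n_reps,
                })
    df = pd.DataFrame(rows)
    return df.sort_values(["det_t_fix", "topography_id", "N0"]).reset_index(drop=True)
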