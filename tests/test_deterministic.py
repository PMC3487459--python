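"""Infinite-population ODE dynamics: RHS structure, integration, T_fix,
LD and the two-locus critical recombination rate."""

import itertools

import numpy as np
import pytest

from lfgscape import (
    DynamicsParams,
    FitnessTopography,
    GenotypeSpace,
    allele_frequencies,
    build_landscape,
    critical_recombination_rate,
    fixation_time,
    integrate,
    ode_rhs,
    pairwise_LD,
    t_fix_ratio,
    time_to_mean_fitness,
)
from lfgscape.deterministic import make_rhs, recombination_indicator
from lfgscape.landscape import FitnessLandscape, _apply_locus_permutation

from conftest import random_simplex


class TestAlleleFrequencies:
    def test_point_mass_bottom(self, space4):
        x = np.zeros(16); x[0] = 1.0
        assert allele_frequencies(x, space4).tolist() == [0, 0, 0, 0]

    def test_half_half(self, space2):
        x = np.array([0, 0.5, 0.5, 0])  # half "01", half "10"
        assert allele_frequencies(x, space2) == pytest.approx([0.5, 0.5])

    def test_uniform(self, space4):
        x = np.full(16, 1 / 16)
        assert allele_frequencies(x, space4) == pytest.approx([0.5] * 4)


class TestRecombinationIndicator:
    def test_single_site_replacement(self, space2):
        # acceptor 00, donor 11, locus 0 -> recombinant 01
        assert recombination_indicator(space2, 0b00, 0b11, 0, 0b01) == 1
        assert recombination_indicator(space2, 0b00, 0b11, 0, 0b10) == 0

    def test_same_allele_is_noop(self, space2):
        for j in (0b01, 0b10, 0b11):
            for l in range(2):
                assert recombination_indicator(space2, 0b00, 0b00, l, j) == 0

    def test_most_significant_locus(self, space4):
        sp = space4
        i, d = sp.from_string("0110"), sp.from_string("1111")
        assert recombination_indicator(sp, i, d, 3, sp.from_string("1110")) == 1


class TestRHS:
    @pytest.mark.parametrize("fixture", ["smooth2", "valley2", "smooth4"])
    def test_conservation(self, fixture, rng, request):
        land = request.getfixturevalue(fixture)
        params = DynamicsParams(mu=1e-4, r=0.05)
        n = land.space.n_genotypes
        for x in random_simplex(rng, n, count=300):
            assert abs(ode_rhs(x, land, params).sum()) < 1e-12

    def test_pure_replicator_when_mu_r_zero(self, smooth4, rng):
        params = DynamicsParams(mu=0.0, r=0.0)
        x = random_simplex(rng, 16)
        m = smooth4.m
        expected = (m - m @ x) * x
        assert ode_rhs(x, smooth4, params) == pytest.approx(expected, abs=1e-14)

    def test_peak_point_mass_is_fixed_point(self, smooth4):
        x = np.zeros(16); x[smooth4.space.peak] = 1.0
        dx = ode_rhs(x, smooth4, DynamicsParams(mu=0.0, r=0.3))
        assert np.abs(dx).max() < 1e-14

    def test_locus_permutation_equivariance(self, rng):
        sp = GenotypeSpace(3)
        perm = (2, 0, 1)
        topo = FitnessTopography(3, frozenset({0b001, 0b011}))
        topo_p = FitnessTopography(
            3, frozenset(_apply_locus_permutation(g, perm, 3) for g in topo.lfgs))
        land = build_landscape(sp, 0.05, 1.0, topo)
        land_p = build_landscape(sp, 0.05, 1.0, topo_p)
        params = DynamicsParams(mu=1e-3, r=0.08)
        gmap = np.array([_apply_locus_permutation(g, perm, 3) for g in range(8)])
        x = random_simplex(rng, 8)
        x_p = np.empty(8); x_p[gmap] = x
        dx = ode_rhs(x, land, params)
        dx_p = ode_rhs(x_p, land_p, params)
        assert dx_p[gmap] == pytest.approx(dx, abs=1e-14)

    def test_nonfinite_rejected(self, smooth2):
        x = np.array([np.nan, 0, 0, 1])
        with pytest.raises(FloatingPointError):
            ode_rhs(x, smooth2, DynamicsParams())


class TestIntegrate:
    def test_mass_conserved_along_trajectory(self, smooth4):
        traj = integrate(smooth4, DynamicsParams(),
                         t_eval=np.linspace(0, 200, 50), stop_at_fixation=False)
        assert np.abs(traj.x.sum(axis=1) - 1).max() < 1e-8

    def test_absorbing_without_mutation(self, smooth4):
        x0 = np.zeros(16); x0[0] = 1.0
        traj = integrate(smooth4, DynamicsParams(mu=0.0, r=0.0, t_max=500.0),
                         x0=x0, t_eval=np.linspace(0, 500, 20),
                         stop_at_fixation=False)
        assert np.abs(traj.x - x0).max() < 1e-10

    def test_against_explicit_euler(self, space2):
        # independent oracle: fine-grained explicit Euler on the same RHS
        land = build_landscape(space2, 0.1, 1.0)
        params = DynamicsParams(mu=1e-3, r=0.0, fixation_threshold=0.9)
        rhs = make_rhs(land, params)
        dt, T = 0.002, 100.0
        x = np.zeros(4); x[0] = 1.0
        euler = {0.0: x.copy()}
        checkpoints = [25.0, 50.0, 75.0, 100.0]
        t = 0.0
        for step in range(int(T / dt)):
            x = x + dt * rhs(t, x)
            t += dt
            for c in checkpoints:
                if abs(t - c) < dt / 2:
                    euler[c] = x.copy()
        traj = integrate(land, params, t_eval=np.array(checkpoints),
                         stop_at_fixation=False)
        for i, c in enumerate(checkpoints):
            assert traj.x[i] == pytest.approx(euler[c], abs=5e-4)

    def test_peak_frequency_monotone_after_burn_in(self, smooth2):
        traj = integrate(smooth2, DynamicsParams(mu=1e-5, r=0.0),
                         t_eval=np.linspace(100, 2500, 100),
                         stop_at_fixation=False)
        peak = traj.x[:, smooth2.space.peak]
        assert np.all(np.diff(peak) > -1e-10)

    def test_mutation_only_uniform_stationary(self):
        # flat landscape: selection off, recombination off -> uniform limit
        for L in (2, 3):
            sp = GenotypeSpace(L)
            land = FitnessLandscape(sp, 0.05, 1.0, FitnessTopography(L),
                                    np.full(sp.n_genotypes, 0.5))
            traj = integrate(land, DynamicsParams(mu=1e-3, r=0.0, t_max=7000.0),
                             t_eval=np.array([7000.0]), stop_at_fixation=False)
            assert traj.x[-1] == pytest.approx(
                np.full(sp.n_genotypes, 1 / sp.n_genotypes), abs=1e-4)


class TestFixationTime:
    def test_deterministic_and_reproducible(self, smooth4):
        a = fixation_time(smooth4, DynamicsParams())
        b = fixation_time(smooth4, DynamicsParams())
        assert a.fixed and a.time == b.time

    def test_decreasing_in_s(self, space4):
        times = []
        for s in (0.03, 0.05, 0.08, 0.12):
            land = build_landscape(space4, s, 1.0)
            times.append(fixation_time(land, DynamicsParams(r=0.0)).time)
        assert all(t1 > t2 for t1, t2 in zip(times, times[1:]))

    def test_supercritical_recombination_prevents_fixation(self, valley2):
        # r above m(11) - m(00) = 0.1 stabilizes the unadapted state
        params = DynamicsParams(mu=1e-5, r=0.2, t_max=5e3)
        res = fixation_time(valley2, params)
        assert not res.fixed
        assert res.time == params.t_max
        with pytest.raises(RuntimeError):
            res.require_fixed()
        ratio, with_r, without_r = t_fix_ratio(valley2, params)
        assert np.isnan(ratio) and not with_r.fixed and without_r.fixed


class TestTfixRatio:
    def test_no_lfg_additive_is_neutral(self, smooth4):
        ratio, _, _ = t_fix_ratio(smooth4, DynamicsParams())
        assert ratio == pytest.approx(1.0, abs=1e-3)

    def test_single_lfg_decelerates(self, space2):
        land = build_landscape(space2, 0.05, 1.0, FitnessTopography(2, frozenset({1})))
        ratio, _, _ = t_fix_ratio(land, DynamicsParams())
        assert ratio > 1

    def test_baseline_epistasis_directions(self, space4):
        # positive epistasis (eps<1, intermediates below the additive chord)
        # decelerates; negative epistasis (eps>1) accelerates
        low, _, _ = t_fix_ratio(build_landscape(space4, 0.05, 0.95),
                                DynamicsParams())
        high, _, _ = t_fix_ratio(build_landscape(space4, 0.05, 1.05),
                                 DynamicsParams())
        assert low > 1 > high

    def test_orbit_members_share_t_fix(self, space4):
        params = DynamicsParams()
        topo_a = FitnessTopography(4, frozenset({0b0001, 0b0110}))
        topo_b = FitnessTopography(4, frozenset({0b1000, 0b0110}))  # loci reversed
        ra, _, _ = t_fix_ratio(build_landscape(space4, 0.05, 1.0, topo_a), params)
        rb, _, _ = t_fix_ratio(build_landscape(space4, 0.05, 1.0, topo_b), params)
        assert ra == pytest.approx(rb, rel=1e-6)


class TestPairwiseLD:
    def test_product_state_zero(self, space2, rng):
        p, q = 0.3, 0.7
        x = np.array([(1 - p) * (1 - q), p * (1 - q), (1 - p) * q, p * q])
        assert pairwise_LD(x, space2, 0, 1) == pytest.approx(0.0, abs=1e-15)

    def test_extremes(self, space2):
        coupled = np.array([0.5, 0, 0, 0.5])
        repulsion = np.array([0, 0.5, 0.5, 0])
        assert pairwise_LD(coupled, space2, 0, 1) == pytest.approx(0.25)
        assert pairwise_LD(repulsion, space2, 0, 1) == pytest.approx(-0.25)

    def test_same_locus_rejected(self, space2):
        with pytest.raises(ValueError):
            pairwise_LD(np.full(4, 0.25), space2, 1, 1)

    def test_matches_two_locus_determinant(self, space2, rng):
        x = random_simplex(rng, 4)
        det = x[3] * x[0] - x[2] * x[1]
        assert pairwise_LD(x, space2, 0, 1) == pytest.approx(det, abs=1e-14)


class TestCriticalRecombinationRate:
    @pytest.mark.parametrize("s", [0.05, 0.2])
    def test_equals_extreme_fitness_difference(self, space2, s):
        land = build_landscape(space2, s, 1.0, FitnessTopography(2, frozenset({1, 2})))
        rc = critical_recombination_rate(land, method="eigen", tol=1e-7)
        assert rc == pytest.approx(2 * s, abs=1e-4)

    def test_tracks_delta_m_under_eps(self, space2):
        # eps moves m(00) = 1 - s*2**eps; the contract r_c = m(11) - m(00) holds
        for eps in (1.0, 1.3):
            land = build_landscape(space2, 0.05, eps,
                                   FitnessTopography(2, frozenset({1, 2})))
            rc = critical_recombination_rate(land, method="eigen", tol=1e-7)
            assert rc == pytest.approx(land.m[3] - land.m[0], abs=1e-4)

    def test_invasion_oracle_agrees(self, valley2):
        rc_eig = critical_recombination_rate(valley2, method="eigen", tol=1e-7)
        rc_inv = critical_recombination_rate(valley2, method="invasion", tol=1e-6)
        assert rc_inv == pytest.approx(rc_eig, abs=1e-4)

    def test_non_valley_rejected(self, smooth2):
        with pytest.raises(ValueError):
            critical_recombination_rate(smooth2)


class TestTimeToMeanFitness:
    def test_threshold_already_met(self, smooth4):
        res = time_to_mean_fitness(smooth4, DynamicsParams(), threshold=0.7)
        assert res.fixed and res.time == 0.0

    def test_monotone_in_threshold(self, smooth4):
        params = DynamicsParams()
        times = [time_to_mean_fitness(smooth4, params, thr).time
                 for thr in (0.85, 0.95, 0.99)]
        assert times[0] < times[1] < times[2]

    def test_correlates_with_fixation_time(self, space4):
        # same ordering across topographies of varying difficulty
        from lfgscape import sample_topographies
        topos = [FitnessTopography(4)]
        for n_lfgs in range(1, 8):
            topos += sample_topographies(4, n_lfgs, 3, seed=100 + n_lfgs)
        # recombination on: fixation times spread across topographies
        params = DynamicsParams()
        tfix, tmean = [], []
        for topo in topos:
            land = build_landscape(space4, 0.05, 1.0, topo)
            tfix.append(fixation_time(land, params).time)
            tmean.append(time_to_mean_fitness(land, params, 0.99).time)
        from scipy.stats import spearmanr
        # strong rank agreement; not perfect, because mean fitness can cross
        # the threshold early when high-fitness genotypes co-segregate
        assert spearmanr(tfix, tmean).statistic > 0.8
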