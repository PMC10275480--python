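"""Fitness landscapes: parabola geometry, noise, cost, optima, and the
post-duplication optimum derivation."""

import numpy as np
import pytest

from paralogdiv import (DEFAULT_CONSTANTS, FitnessFunction, PairState,
                        build_fitness_function, curvature_filter,
                        duplicate_fitness_function, expected_fitness, infer_q,
                        max_admissible_popt, minimal_delta_opt, noise_load,
                        optimal_rates_minimal, optimal_rates_precision_economy,
                        optimal_ratio_from_q, pair_noise_variance,
                        singleton_noise_variance, transcription_cost)

C = DEFAULT_CONSTANTS


def random_admissible(rng, n=50):
    """Random (p_opt, Q) pairs well inside the admissible region."""
    p_opt = 10 ** rng.uniform(1.5, 3.5, n)
    q = 10 ** rng.uniform(-9, np.log10(C.q_max), n)
    keep = noise_load(p_opt, q) <= 1.0
    return p_opt[keep], q[keep]


class TestFitnessFunction:
    def test_vertex_and_symmetry(self):
        f = build_fitness_function(1000.0, 3e-6)
        assert f(1000.0) == pytest.approx(0.42)
        d = 137.0
        assert f(1000 + d) == pytest.approx(f(1000 - d))

    def test_concavity_and_standard_form(self):
        f = build_fitness_function(500.0, 1e-6)
        assert f.a < 0
        p = np.linspace(10, 2000, 7)
        np.testing.assert_allclose(f(p), f.a * p ** 2 + f.b * p + f.c, rtol=1e-12)

    def test_larger_q_is_narrower(self):
        lo = build_fitness_function(1000.0, 1e-6)
        hi = build_fitness_function(1000.0, 5e-6)
        assert hi(1050.0) < lo(1050.0)

    def test_q_bounds(self):
        with pytest.raises(ValueError):
            build_fitness_function(1000.0, 2 * C.q_max)
        with pytest.raises(ValueError):
            build_fitness_function(1000.0, 0.0)


class TestDuplication:
    def test_new_vertex(self):
        f = duplicate_fitness_function(build_fitness_function(1000.0, 3e-6))
        assert f(1870.0) == pytest.approx(0.42)

    def test_overshoot_positive_on_admissible_set(self, rng):
        p_opt, q = random_admissible(rng, 200)
        keep = curvature_filter(p_opt, q, 1e6)
        for p, qq in zip(p_opt[keep], q[keep]):
            fd = duplicate_fitness_function(build_fitness_function(p, qq))
            assert fd(2 * p) > 0

    def test_optimum_side_geometry(self, rng):
        p_opt, q = random_admissible(rng)
        for p, qq in zip(p_opt[:20], q[:20]):
            fd = duplicate_fitness_function(build_fitness_function(p, qq))
            assert fd(p) < fd(2 * p)   # 2x overshoots less than 1x undershoots

    def test_double_application_rejected(self):
        fd = duplicate_fitness_function(build_fitness_function(100.0, 1e-6))
        with pytest.raises(ValueError):
            duplicate_fitness_function(fd)


class TestNoiseVariance:
    def test_singleton_example(self):
        # 100^2 * (1/100 + 1.34/13.4 + 0.01) = 1e4 * 0.12
        assert singleton_noise_variance(100.0, 13.4) == pytest.approx(1200.0)

    def test_floor_limit(self):
        s2 = singleton_noise_variance(1e9, 1e12)
        assert s2 / 1e18 == pytest.approx(0.01, rel=1e-4)

    def test_poisson_plus_floor(self):
        assert singleton_noise_variance(1.0, 1e12) == pytest.approx(1.01, rel=1e-4)

    def test_identical_copies_collapse_to_singleton(self):
        # a pair of equal copies equals one gene at the summed beta_m
        s2_pair = pair_noise_variance(100.0, 100.0, 13.4, 13.4)
        s2_single = singleton_noise_variance(200.0, 26.8)
        assert s2_pair == pytest.approx(s2_single, rel=1e-12)

    def test_pair_floor_limit(self):
        s2 = pair_noise_variance(5e8, 5e8, 1e12, 1e12)
        assert s2 / 1e18 == pytest.approx(0.01, rel=1e-3)

    def test_alignment_lowers_pair_noise(self):
        # unequal abundances: noise is lower when transcription tracks them
        aligned = pair_noise_variance(150.0, 50.0, 20.1, 6.7)
        misaligned = pair_noise_variance(150.0, 50.0, 6.7, 20.1)
        assert aligned < misaligned


class TestTranscriptionCost:
    def test_examples(self):
        assert transcription_cost(0.0, 0.0) == 0.0
        assert transcription_cost(4.0, 6.0) == pytest.approx(1.62e-5)
        assert transcription_cost(10.0, 0.0) == transcription_cost(5.0, 5.0)


class TestExpectedFitness:
    @staticmethod
    def _state(rng):
        p_opt, q = random_admissible(rng, 200)
        i = 0
        f = duplicate_fitness_function(build_fitness_function(p_opt[i], q[i]))
        bm, bp = optimal_rates_minimal(p_opt[i], q[i], convention="optimality")
        return PairState(bm, bp, bm * 1.3, bp * 0.8, f)

    def test_zero_noise_zero_cost_degenerate(self):
        f = duplicate_fitness_function(build_fitness_function(1000.0, 1e-6))
        st = PairState(10.0, 500.0, 10.0, 500.0, f)
        w_direct = f(st.p_tot)
        full = expected_fitness(st, "precision_economy")
        # removing noise and cost terms recovers the deterministic parabola
        assert full - (f.a * st.sigma_tot2 - st.cost) == pytest.approx(w_direct)

    def test_minimal_depends_on_total_only(self, rng):
        st = self._state(rng)
        base = expected_fitness(st, "minimal")
        # move protein abundance between copies at fixed total
        shift = 0.3 * st.p1
        c = st.constants
        bp1 = (st.p1 - shift) * c.alpha_m * c.alpha_p / st.bm1
        bp2 = (st.p2 + shift) * c.alpha_m * c.alpha_p / st.bm2
        st2 = PairState(st.bm1, bp1, st.bm2, bp2, st.fitness_fn)
        assert st2.p_tot == pytest.approx(st.p_tot, rel=1e-12)
        assert expected_fitness(st2, "minimal") == pytest.approx(base, rel=1e-12)

    def test_quadrature_oracle(self, rng):
        # closed form equals Gauss-Hermite expectation of W under
        # Normal(P_tot, sigma_tot) for random states
        nodes, weights = np.polynomial.hermite_e.hermegauss(64)
        for _ in range(50):
            st = self._state(rng)
            f = st.fitness_fn
            mean, sd = st.p_tot, np.sqrt(st.sigma_tot2)
            quad = np.sum(weights * f(mean + sd * nodes)) / np.sqrt(2 * np.pi)
            closed = expected_fitness(st, "precision_economy") + st.cost
            assert closed == pytest.approx(quad, rel=1e-9)


class TestQInference:
    def test_round_trip_both_conventions(self, rng):
        bm = 10 ** rng.uniform(-0.5, 2.5, 30)
        bp = 10 ** rng.uniform(1.5, 4.0, 30)
        p = bm * bp / (C.alpha_m * C.alpha_p)
        for conv in ("balance", "optimality"):
            q = infer_q(bm, bp, convention=conv)
            bm2, bp2 = optimal_rates_minimal(p, q, convention=conv)
            np.testing.assert_allclose(bm2, bm, rtol=1e-9)
            np.testing.assert_allclose(bp2, bp, rtol=1e-9)

    def test_transcription_share_raises_q(self):
        # same protein output, more transcription-heavy -> larger Q
        p = 1000.0 * C.alpha_m * C.alpha_p
        lo = infer_q(10.0, p / 10.0)
        hi = infer_q(40.0, p / 40.0)
        assert hi > lo
        assert infer_q(40.0, p / 40.0, convention="optimality") > \
            infer_q(10.0, p / 10.0, convention="optimality")

    def test_ratio_inversion(self):
        q = infer_q(10.0, 500.0)
        assert optimal_ratio_from_q(q) == pytest.approx(50.0)

    def test_pool_q_tail_is_filtered(self, genes):
        q = infer_q(genes["beta_m"].to_numpy(), genes["beta_p"].to_numpy())
        frac = (q > C.q_max).mean()
        assert 0 < frac < 0.2


class TestOptimalRates:
    def test_minimal_satisfies_abundance(self, rng):
        p_opt, q = random_admissible(rng)
        for conv in ("balance", "optimality"):
            bm, bp = optimal_rates_minimal(p_opt, q, convention=conv)
            np.testing.assert_allclose(bm * bp / (C.alpha_m * C.alpha_p),
                                       p_opt, rtol=1e-9)

    def test_minimal_doubling_scales_sqrt2(self):
        bm1, bp1 = optimal_rates_minimal(1000.0, 2e-6)
        bm2, bp2 = optimal_rates_minimal(2000.0, 2e-6)
        assert bm2 / bm1 == pytest.approx(np.sqrt(2), rel=1e-12)
        assert bp2 / bp1 == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_pe_optimum_dominates_and_undershoots(self, rng):
        p_opt, q = random_admissible(rng, 60)
        from paralogdiv.fitness import _singleton_pe_fitness
        for p, qq in zip(p_opt[:10], q[:10]):
            f = build_fitness_function(p, qq)
            bm, bp, fv = optimal_rates_precision_economy(f, seed=1)
            f_min = _singleton_pe_fitness(
                np.log(np.array(optimal_rates_minimal(p, qq, convention="optimality")
                                ))[:, None], f, C)[0]
            assert fv >= f_min - 1e-12
            assert bm * bp / (C.alpha_m * C.alpha_p) <= p * (1 + 1e-9)

    def test_pe_restart_stability(self):
        f = build_fitness_function(800.0, 1e-6)
        _, _, f1 = optimal_rates_precision_economy(f, seed=1)
        _, _, f2 = optimal_rates_precision_economy(f, seed=99)
        assert f1 == pytest.approx(f2, rel=1e-8)


class TestPairFitnessStructure:
    def test_pe_single_peaked_in_bm_tot(self):
        # at fixed totals and aligned copies, fitness is unimodal in total
        # transcription: noise falls, cost rises
        f = duplicate_fitness_function(build_fitness_function(1000.0, 1e-6))
        p_each = 935.0
        bms = np.linspace(0.5, 400.0, 200)
        w = []
        for bm in bms:
            bp = p_each * C.alpha_m * C.alpha_p / bm
            w.append(expected_fitness(PairState(bm, bp, bm, bp, f),
                                      "precision_economy"))
        w = np.array(w)
        peak = w.argmax()
        assert 0 < peak < len(w) - 1
        assert np.all(np.diff(w[:peak + 1]) > 0)
        assert np.all(np.diff(w[peak:]) < 0)


class TestAdmissibilityAndDeltaOpt:
    def test_envelope_decreases_with_q(self):
        assert max_admissible_popt(C.q_max) < max_admissible_popt(C.q_max / 2)

    def test_delta_opt_value(self):
        assert minimal_delta_opt() == pytest.approx(1.87)

    def test_delta_opt_wider_parabola(self):
        assert minimal_delta_opt(q_max=C.q_max / 2) <= 1.87

    def test_two_always_satisfies_positivity(self):
        # at delta = 2 the doubled abundance sits exactly on the vertex
        p = max_admissible_popt(C.q_max)
        f = FitnessFunction(p_opt=p, q=C.q_max, post_dup=True, delta_opt=2.0)
        assert f(2 * p) == pytest.approx(C.mu)


class TestCurvatureFilter:
    def test_flat_function_fails(self):
        assert not curvature_filter(100.0, 1e-12, 1e6)

    def test_narrow_function_passes(self):
        assert curvature_filter(3000.0, C.q_max, 1e6)

    def test_threshold_monotone_in_n(self, rng):
        p_opt, q = random_admissible(rng, 100)
        small = curvature_filter(p_opt, q, 1e5)
        large = curvature_filter(p_opt, q, 1e6)
        assert np.all(large | ~small)   # pass at 1e5 implies pass at 1e6
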