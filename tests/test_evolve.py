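"""Mutation sampling, Metropolis filtering, and the simulation engine."""

import numpy as np
import pytest
from scipy import stats

from paralogdiv import (DEFAULT_CONSTANTS, MutationModel, MutationSpec,
                        PairState, SimulationConfig, apply_mutation,
                        build_fitness_function, calibrate_bivariate_sigmas,
                        check_stop, duplicate_fitness_function,
                        fixation_probability, initialize_population,
                        post_hoc_loss_filter, run_paired_simulations,
                        run_simulation, sample_mutation)
from paralogdiv.evolve import _sample_effects


class TestMutationSampling:
    def test_target_size_fractions(self, rng):
        mm = MutationModel(sigma_mut=0.02, p_bm=4.0, p_bp=1.0)
        dm, dp, _ = _sample_effects(mm, rng, 100_000)
        frac = (dm != 0).mean()
        assert frac == pytest.approx(0.8, abs=0.004)

    def test_exactly_one_level_hit(self, rng):
        mm = MutationModel(sigma_mut=0.02)
        dm, dp, _ = _sample_effects(mm, rng, 1000)
        assert np.all((dm == 0) ^ (dp == 0))

    def test_skew_normal_moments(self, rng):
        mm = MutationModel(family="skew_normal", sigma_mut=0.05, alpha_skew=-4.0)
        dm, dp, _ = _sample_effects(mm, rng, 200_000)
        eff = np.where(dm != 0, dm, dp)
        assert eff.mean() == pytest.approx(0.0, abs=5e-4)
        assert eff.std() == pytest.approx(0.05, rel=0.01)
        assert stats.skew(eff) < -0.5

    def test_bivariate_correlation(self, rng):
        mm = MutationModel(family="bivariate", sigma_bm=0.04, sigma_bp=0.02,
                           r_mut=0.5)
        dm, dp, _ = _sample_effects(mm, rng, 100_000)
        assert np.all(dm != 0) and np.all(dp != 0)
        assert np.corrcoef(dm, dp)[0, 1] == pytest.approx(0.5, abs=0.01)
        assert dm.std() == pytest.approx(0.04, rel=0.02)

    def test_copy_choice_balanced(self, rng):
        mm = MutationModel(sigma_mut=0.02)
        _, _, to_p1 = _sample_effects(mm, rng, 100_000)
        assert to_p1.mean() == pytest.approx(0.5, abs=0.01)

    def test_scalar_interface(self, rng):
        spec = sample_mutation(MutationModel(sigma_mut=0.02), rng)
        assert spec.target_copy in ("P1", "P2")
        assert (spec.delta_m == 0) ^ (spec.delta_p == 0)

    def test_invalid_families(self):
        with pytest.raises(ValueError):
            MutationModel(family="cauchy")
        with pytest.raises(ValueError):
            MutationModel(family="bivariate")  # missing sigmas
        with pytest.raises(ValueError):
            MutationModel(sigma_mut=-0.1)


class TestApplyMutation:
    @staticmethod
    def _state():
        f = duplicate_fitness_function(build_fitness_function(1000.0, 1e-6))
        return PairState(10.0, 500.0, 10.0, 500.0, f)

    def test_zero_effect_identity(self):
        st = apply_mutation(self._state(), MutationSpec(0.0, 0.0, "P1"))
        assert st.bm1 == 10.0 and st.bp1 == 500.0

    def test_multiplicative(self):
        st = apply_mutation(self._state(), MutationSpec(0.05, 0.0, "P1"))
        assert st.bm1 == pytest.approx(10.5)
        assert st.bm2 == 10.0

    def test_lethal_and_bound_rejections(self):
        assert apply_mutation(self._state(), MutationSpec(-1.0, 0.0, "P2")) is None
        assert apply_mutation(self._state(), MutationSpec(0.5, 0.0, "P1"),
                              bm_max=12.0) is None


class TestFixationProbability:
    def test_beneficial_and_neutral(self):
        assert fixation_probability(0.5, 0.6, 1e6) == 1.0
        assert fixation_probability(0.5, 0.5, 1e6) == 1.0

    def test_printed_example(self):
        f_i = 0.5
        f_j = f_i * np.exp(-1e-7)
        assert fixation_probability(f_i, f_j, 1e6) == pytest.approx(0.81873, abs=1e-5)

    def test_monotone_in_n_and_deficit(self):
        f_i = 0.9
        p1 = fixation_probability(f_i, f_i * np.exp(-5e-6), 1e5)
        p2 = fixation_probability(f_i, f_i * np.exp(-5e-6), 1e6)
        p3 = fixation_probability(f_i, f_i * np.exp(-2e-5), 1e5)
        assert p2 < p1 and p3 < p1

    def test_neutral_drift_limit(self):
        assert fixation_probability(0.9, 0.1, 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_state(self):
        with pytest.raises(ValueError):
            fixation_probability(0.0, 0.5, 1e6)


class TestInitialization:
    def test_copies_identical_and_fitness_positive(self, genes, rng):
        pop = initialize_population(30, genes, "minimal", rng)
        np.testing.assert_array_equal(pop.bm1, pop.bm2)
        np.testing.assert_array_equal(pop.bp1, pop.bp2)
        assert np.all(pop.scaled_fitness() > 0)
        p1, p2 = pop.protein_abundances()
        # cumulative abundance starts at twice the ancestral optimum's rates
        np.testing.assert_allclose(p1 + p2, 2 * p1, rtol=1e-12)

    def test_pe_initialization_positive_fitness(self, genes, rng):
        pop = initialize_population(5, genes, "precision_economy", rng,
                                    de_rng=np.random.default_rng(0))
        assert np.all(pop.scaled_fitness() > 0)

    def test_small_pool_rejected(self, genes, rng):
        with pytest.raises(ValueError):
            initialize_population(3, genes.iloc[:1], "minimal", rng)


class TestCheckStop:
    def test_self_reference_usually_stops(self, rng):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            sample = np.abs(r.normal(0, 2, 300))
            ref = np.abs(r.normal(0, 2, 300))
            hits += check_stop(sample, ref)[0]
        assert hits / 40 > 0.75     # Mood p > 0.1 with probability ~0.9

    def test_undiverged_does_not_stop(self, rng):
        ref = np.abs(rng.normal(0, 2, 300))
        done, p = check_stop(np.zeros(300), ref)
        assert not done and p < 1e-10

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            check_stop(np.ones(5), np.array([]))


class TestSimulationEngine:
    def test_same_seed_bit_identical(self, genes, reference):
        cfg = SimulationConfig(model="minimal", n_pairs=20,
                               mutation_model=MutationModel(sigma_mut=0.05),
                               reference_fc=reference["fc_p"], seed=3,
                               max_rounds=500)
        r1 = run_simulation(cfg, genes)
        r2 = run_simulation(cfg, genes)
        np.testing.assert_array_equal(r1.population.bm1, r2.population.bm1)
        np.testing.assert_array_equal(r1.population.bp2, r2.population.bp2)
        assert r1.rounds_used == r2.rounds_used

    def test_single_model_matches_joint_run(self, genes, reference):
        cfg = SimulationConfig(model="minimal", n_pairs=15,
                               mutation_model=MutationModel(sigma_mut=0.05),
                               reference_fc=reference["fc_p"], seed=5,
                               max_rounds=300)
        solo = run_simulation(cfg, genes)
        both = run_paired_simulations(cfg, genes)
        np.testing.assert_array_equal(solo.population.bm1,
                                      both["minimal"].population.bm1)
        np.testing.assert_array_equal(solo.population.bp1,
                                      both["minimal"].population.bp1)

    def test_flat_fitness_accepts_everything(self, genes):
        cfg = SimulationConfig(model="minimal", n_pairs=50,
                               mutation_model=MutationModel(sigma_mut=0.02),
                               reference_fc=None, seed=2, max_rounds=200,
                               q_override=0.0)
        res = run_simulation(cfg, genes)
        assert res.n_accepted == 50 * 200
        assert res.rounds_used == 200

    def test_paired_models_share_mutation_series(self, genes, reference):
        # the random streams are keyed by (seed, purpose), never by which
        # models run: each model's half of a joint run is bit-identical to
        # its solo run, so the nth pair sees the same mutation series and
        # acceptance uniforms under both models
        import dataclasses
        cfg = SimulationConfig(model="precision_economy", n_pairs=10,
                               mutation_model=MutationModel(sigma_mut=0.02),
                               reference_fc=reference["fc_p"], seed=8,
                               max_rounds=400)
        both = run_paired_simulations(cfg, genes)
        pe_solo = run_simulation(cfg, genes)
        min_solo = run_simulation(dataclasses.replace(cfg, model="minimal"), genes)
        for field in ("bm1", "bp1", "bm2", "bp2"):
            np.testing.assert_array_equal(
                getattr(pe_solo.population, field),
                getattr(both["precision_economy"].population, field))
            np.testing.assert_array_equal(
                getattr(min_solo.population, field),
                getattr(both["minimal"].population, field))


class TestPostHocLossFilter:
    def test_threshold_behaviour(self, genes, reference):
        cfg = SimulationConfig(model="minimal", n_pairs=40,
                               mutation_model=MutationModel(sigma_mut=0.05),
                               reference_fc=reference["fc_p"], seed=11,
                               max_rounds=5000)
        res = run_simulation(cfg, genes)
        keep_strict = post_hoc_loss_filter(res, n_eff=1e6)
        keep_lax = post_hoc_loss_filter(res, n_eff=1e30)
        # an astronomically large N retains every pair contributing anything
        assert keep_lax.sum() >= keep_strict.sum()
        assert keep_lax.all()

    def test_worthless_copy_removed(self, genes, rng):
        res_pop = initialize_population(5, genes, "minimal", rng)
        # make copy 2 of pair 0 contribute (essentially) nothing
        res_pop.bm2[0] = 1e-9
        res_pop.bp2[0] = 1e-9
        from paralogdiv.evolve import SimulationResult
        res = SimulationResult(model="minimal", population=res_pop,
                               rounds_used=0, stopped=True, final_stop_p=1.0,
                               n_accepted=0, mean_fitness_trace=np.array([]),
                               fitness_trace=None, median_fc_bm_trace=None,
                               median_fc_bp_trace=None, trace_rounds=None)
        keep = post_hoc_loss_filter(res, n_eff=1e6)
        assert not keep[0]


class TestBivariateCalibration:
    def test_ratio_constraint_and_recovery(self, rng):
        s_bm, s_bp = calibrate_bivariate_sigmas(2.0, 0.05, rng=rng)
        assert s_bm == pytest.approx(2 * s_bp, rel=1e-12)
        # recovered mean |protein change| matches the univariate reference
        r = np.random.default_rng(0)
        z = r.standard_normal((200_000, 2))
        change = np.abs((1 + s_bm * z[:, 0]) * (1 + s_bp * z[:, 1]) - 1)
        assert change.mean() == pytest.approx(0.05 * np.sqrt(2 / np.pi), rel=0.01)

    def test_correlated_effects_shrink_sigmas(self, rng):
        _, s0 = calibrate_bivariate_sigmas(1.0, 0.05, rng=np.random.default_rng(3),
                                           r_mut=0.0)
        _, s9 = calibrate_bivariate_sigmas(1.0, 0.05, rng=np.random.default_rng(3),
                                           r_mut=0.9)
        assert s9 < s0   # compounding effects need smaller per-level SDs
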