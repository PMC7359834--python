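"""Simulator behaviour: validation, determinism, conservation laws, drift
and selection nulls against the deterministic recursion, and the companion
expression/water generators."""

import numpy as np
import pytest

from tempsel.popgen import allele_frequencies, pair_theta
from tempsel.simulate import (
    BEFORE,
    ExpressionConfig,
    ExpressionGroup,
    MicrosatLocus,
    SimulationConfig,
    SimulationError,
    WaterConfig,
    WaterGroup,
    deterministic_trajectory,
    generate_expression,
    generate_water,
    simulate_two_deme,
)
from tempsel.expression import ratio_of_change


def two_allele_config(**overrides) -> SimulationConfig:
    base = dict(
        deme_sizes=(200, 200),
        migration=[[1.0, 0.0], [0.0, 1.0]],
        candidate_alleles=["A", "B"],
        candidate_init_freqs=[[0.5, 0.5], [0.5, 0.5]],
        n_generations=2,
        switch_generation=2,
        sampling_plan=[],
        seed=1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_oversized_sample_rejected(self):
        cfg = two_allele_config(deme_sizes=(24, 24), sampling_plan=[(1, 0, 30)])
        with pytest.raises(ValueError, match="sample size"):
            cfg.validate()

    def test_migration_rows_must_sum_to_one(self):
        cfg = two_allele_config(migration=[[0.9, 0.2], [0.1, 0.9]])
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()

    def test_frequencies_must_sum_to_one(self):
        cfg = two_allele_config(candidate_init_freqs=[[0.6, 0.5], [0.5, 0.5]])
        with pytest.raises(ValueError, match="sum to"):
            cfg.validate()

    def test_all_zero_fitness_rejected(self):
        cfg = two_allele_config(
            fitness_by_epoch={(0, BEFORE): {"default": 0.0}}
        )
        with pytest.raises(ValueError, match="zero"):
            cfg.validate()

    def test_switch_generation_bounded(self):
        cfg = two_allele_config(switch_generation=5, n_generations=2)
        with pytest.raises(ValueError, match="switch_generation"):
            cfg.validate()


class TestDeterminism:
    def test_same_seed_identical_output(self):
        cfg = two_allele_config(
            n_microsats=2,
            microsat_init_alleles=[
                MicrosatLocus([8, 10], [0.5, 0.5]),
                MicrosatLocus([5, 6, 7], [0.5, 0.3, 0.2]),
            ],
            mu_stepwise=1e-3,
            sampling_plan=[(0, 0, 10), (2, 1, 10)],
            seed=42,
        )
        s1 = simulate_two_deme(cfg)
        s2 = simulate_two_deme(cfg)
        assert [s.genotypes for s in s1] == [s.genotypes for s in s2]

    def test_different_seed_differs(self):
        kw = dict(sampling_plan=[(2, 0, 50)])
        a = simulate_two_deme(two_allele_config(seed=1, **kw))
        b = simulate_two_deme(two_allele_config(seed=2, **kw))
        assert a[0].genotypes != b[0].genotypes


class TestConservation:
    def test_no_new_microsat_alleles_without_mutation(self):
        cfg = two_allele_config(
            n_microsats=1,
            microsat_init_alleles=[MicrosatLocus([10, 12, 14], [0.4, 0.4, 0.2])],
            mu_stepwise=0.0,
            n_generations=5,
            switch_generation=5,
            sampling_plan=[(5, 0, 200), (5, 1, 200)],
        )
        for s in simulate_two_deme(cfg):
            observed = {a for g in s.typed_genotypes("ms01") for a in g}
            assert observed <= {10, 12, 14}

    def test_mutation_respects_floor(self):
        cfg = two_allele_config(
            n_microsats=1,
            microsat_init_alleles=[MicrosatLocus([1, 2], [0.9, 0.1])],
            mu_stepwise=0.2,
            n_generations=4,
            switch_generation=4,
            sampling_plan=[(4, 0, 200)],
        )
        s = simulate_two_deme(cfg)[0]
        assert min(a for g in s.typed_genotypes("ms01") for a in g) >= 1

    def test_extinct_deme_raises_named_error(self):
        cfg = two_allele_config(
            candidate_init_freqs=[[1.0, 0.0], [0.5, 0.5]],
            fitness_by_epoch={(0, BEFORE): {"A/A": 0.0}},
        )
        # the config is viable in principle (heterozygotes survive) but
        # deme 0 is fixed for A, so its parent pool is empty at generation 1
        with pytest.raises(SimulationError, match="deme 0"):
            simulate_two_deme(cfg)


class TestAgainstRecursion:
    def test_neutral_drift_stays_near_initial_frequency(self):
        cfg = two_allele_config(
            deme_sizes=(10_000, 10_000),
            n_generations=10,
            switch_generation=10,
            sampling_plan=[(10, 0, 2000), (10, 1, 2000)],
            seed=7,
        )
        samples = simulate_two_deme(cfg)
        for s in samples:
            p = allele_frequencies(s, "candidate")["A"]
            # ~10 generations of drift at 2N=20000 plus sampling noise
            se = np.sqrt(0.25 * 10 / 20_000 + 0.25 / 4000)
            assert abs(p - 0.5) < 4 * se

    def test_single_generation_selection_matches_hand_recursion(self):
        cfg = two_allele_config(
            deme_sizes=(100_000, 100),
            fitness_by_epoch={(0, BEFORE): {"A/A": 0.5}},
            n_generations=1,
            switch_generation=1,
            sampling_plan=[(1, 0, 50_000)],
            seed=3,
        )
        p = allele_frequencies(simulate_two_deme(cfg)[0], "candidate")["A"]
        se = np.sqrt(0.42857 * (1 - 0.42857) / (2 * 50_000))
        assert abs(p - 3 / 7) < 3 * se

    def test_recursion_symmetric_migration_converges_to_half(self):
        cfg = two_allele_config(
            migration=[[0.7, 0.3], [0.3, 0.7]],
            candidate_init_freqs=[[0.8, 0.2], [0.2, 0.8]],
            n_generations=40,
            switch_generation=40,
        )
        traj = deterministic_trajectory(cfg)
        assert traj[-1, :, 0] == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_recursion_hand_value_and_post_switch_constancy(self):
        cfg = two_allele_config(
            fitness_by_epoch={(0, BEFORE): {"A/A": 0.5}},
            n_generations=6,
            switch_generation=3,
        )
        traj = deterministic_trajectory(cfg)
        assert traj[1, 0, 0] == pytest.approx(3 / 7, abs=1e-12)
        # selection off after the switch, no migration: frequencies frozen
        for g in range(4, 7):
            assert traj[g, 0, 0] == pytest.approx(traj[3, 0, 0], abs=1e-12)
        assert traj[:, 1, 0] == pytest.approx(np.full(7, 0.5), abs=1e-12)

    def test_zero_mean_fitness_raises(self):
        cfg = two_allele_config(
            candidate_init_freqs=[[1.0, 0.0], [0.5, 0.5]],
            fitness_by_epoch={(0, BEFORE): {"A/A": 0.0}},
        )
        with pytest.raises(SimulationError, match="mean fitness"):
            deterministic_trajectory(cfg)


class TestNeutralityNull:
    def test_candidate_theta_distributed_like_microsatellites(self, rng):
        # With all fitness equal and identical initial frequencies, the
        # candidate locus and the microsatellites are exchangeable, so their
        # temporal theta distributions must agree.
        from scipy.stats import mannwhitneyu

        cand_thetas, ms_thetas = [], []
        for rep in range(60):
            cfg = SimulationConfig(
                deme_sizes=(300, 300),
                migration=[[0.9, 0.1], [0.1, 0.9]],
                candidate_alleles=["A", "B", "C", "D"],
                candidate_init_freqs=[[0.4, 0.3, 0.2, 0.1]] * 2,
                n_microsats=2,
                microsat_init_alleles=[
                    MicrosatLocus([8, 9, 10, 11], [0.4, 0.3, 0.2, 0.1]),
                    MicrosatLocus([8, 9, 10, 11], [0.4, 0.3, 0.2, 0.1]),
                ],
                n_generations=6,
                switch_generation=6,
                sampling_plan=[(0, 0, 24), (6, 0, 24)],
                seed=int(rng.integers(2**31)),
            )
            early, late = simulate_two_deme(cfg)
            cand_thetas.append(pair_theta(early, late, ["candidate"]))
            ms_thetas.append(pair_theta(early, late, ["ms01"]))
            ms_thetas.append(pair_theta(early, late, ["ms02"]))
        p = mannwhitneyu(cand_thetas, ms_thetas).pvalue
        assert p > 0.01


class TestExpressionGenerator:
    def test_recovers_configured_fold_change(self):
        cfg = ExpressionConfig(
            groups={
                ("M", "before"): ExpressionGroup(36.0, 5.0, 50, (1e6, 2e6)),
                ("S", "before"): ExpressionGroup(2.0, 5.0, 50, (1e6, 2e6)),
            },
            seed=5,
        )
        table = generate_expression(cfg)
        est = ratio_of_change(table, "M", "S", "before")
        # CV of a group mean ~ sqrt((1/mu_reads + 1/k)/n); ratio SE via delta
        se = 18.0 * np.sqrt(2 * (1 / 5.0) / 50)
        assert abs(est - 18.0) < 3 * se

    def test_equal_means_give_unit_ratio(self):
        cfg = ExpressionConfig(
            groups={
                ("M", "e"): ExpressionGroup(10.0, 5.0, 80, (1e6, 2e6)),
                ("S", "e"): ExpressionGroup(10.0, 5.0, 80, (1e6, 2e6)),
            },
            seed=6,
        )
        est = ratio_of_change(generate_expression(cfg), "M", "S", "e")
        assert abs(est - 1.0) < 0.25

    def test_library_size_asymmetry_reproduced(self):
        cfg = ExpressionConfig(
            groups={
                ("M", "before"): ExpressionGroup(10.0, 4.0, 30, (1.83e6, 4.7e6)),
                ("M", "after"): ExpressionGroup(10.0, 4.0, 30, (11.89e6, 18.74e6)),
            },
            seed=7,
        )
        table = generate_expression(cfg)
        before = table[table["epoch"] == "before"]["total_reads"]
        after = table[table["epoch"] == "after"]["total_reads"]
        assert before.between(1.83e6, 4.7e6).all()
        assert after.between(11.89e6, 18.74e6).all()
        assert after.min() > before.max()

    def test_invalid_mu_rejected(self):
        cfg = ExpressionConfig(
            groups={("M", "e"): ExpressionGroup(-1.0, 5.0, 10, (1e6, 2e6))}
        )
        with pytest.raises(ValueError, match="mean expression"):
            generate_expression(cfg)


class TestWaterGenerator:
    def test_same_distribution_centroids_close(self):
        mean = np.zeros(3)
        cov = np.eye(3)
        cfg = WaterConfig(
            groups={
                ("S", "before"): WaterGroup(mean, cov, [2007], replicates=40),
                ("S", "after"): WaterGroup(mean, cov, [2016], replicates=40),
            },
            variables=["a", "b", "c"],
            seed=8,
        )
        table = generate_water(cfg)
        cb = table[table["epoch"] == "before"][["a", "b", "c"]].mean()
        ca = table[table["epoch"] == "after"][["a", "b", "c"]].mean()
        se = np.sqrt(2 / 40)
        assert np.abs(cb - ca).max() < 3 * se

    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues -1, 3
        cfg = WaterConfig(
            groups={("S", "e"): WaterGroup(np.zeros(2), bad, [2007])},
            variables=["a", "b"],
        )
        with pytest.raises(ValueError, match="positive semidefinite"):
            generate_water(cfg)

    def test_single_replicate_yields_single_row(self):
        cfg = WaterConfig(
            groups={("S", "e"): WaterGroup(np.zeros(2), np.eye(2), [2007], replicates=1)},
            variables=["a", "b"],
            seed=9,
        )
        assert len(generate_water(cfg)) == 1
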