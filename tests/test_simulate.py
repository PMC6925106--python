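import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acidsel.pool_fst import mortality_from_census
from acidsel.simulate import (
    ExperimentConfig,
    GrowthModel,
    SelectionRegime,
    SeqNoiseModel,
    ZygotePool,
    apply_selection_episode,
    assign_phenotypes,
    make_founders,
    make_zygote_pool,
    neutral_regime,
    run_experiment,
    scaled_config,
    sequence_frequencies,
    sequence_pool,
    truncate_by_size,
)


class TestFounders:
    def test_point_mass_half_recovers_frequency(self):
        f = make_founders(n_dams=60, n_sires=80, n_snps=1,
                          af_distribution={"kind": "point", "value": 0.5}, seed=1)
        n_copies = 2 * 140
        se = np.sqrt(0.25 / n_copies)
        assert abs(f.founder_afs[0] - 0.5) < 3 * se

    def test_same_seed_bit_identical(self):
        a = make_founders(n_snps=200, seed=9)
        b = make_founders(n_snps=200, seed=9)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.founder_afs, b.founder_afs)

    def test_default_design_has_28_founders_192_crosses(self):
        f = make_founders(n_snps=50, seed=0)
        assert f.n_founders == 28
        assert f.n_crosses == 192

    def test_degenerate_distribution_names_parameter(self):
        with pytest.raises(ValueError, match="af_distribution"):
            make_founders(n_snps=10, af_distribution={"kind": "point", "value": 1.0})

    def test_no_monomorphic_snps_after_redraw(self):
        f = make_founders(n_snps=500, seed=3,
                          af_distribution={"kind": "uniform", "low": 0.05, "high": 0.95})
        tot = f.genotypes.sum(axis=0)
        assert np.all((tot > 0) & (tot < 2 * f.n_founders))


class TestZygotes:
    def test_mendelian_certainty_for_fixed_cross(self):
        f = make_founders(n_dams=1, n_sires=1, n_snps=5, seed=0)
        f.genotypes[0, :] = 2  # dam homozygous alt
        f.genotypes[1, :] = 0  # sire homozygous ref
        pool = make_zygote_pool(f, 500, seed=1)
        assert np.all(pool.genotypes == 1)

    def test_offspring_frequency_matches_parental_gamete_mean(self):
        """Conditional on the realized cross assignments, the pool frequency
        is the mean parental gamete frequency within Mendelian-sampling SE."""
        f = make_founders(n_snps=100, seed=2)
        pool = make_zygote_pool(f, 100_000, seed=3)
        dam_g = f.genotypes[: f.n_dams][pool.dam_idx].astype(float)
        sire_g = f.genotypes[f.n_dams :][pool.sire_idx].astype(float)
        expected = (dam_g + sire_g).mean(axis=0) / 4.0
        # per-offspring dosage variance: Bernoulli(g/2) for each gamete
        var = (dam_g / 2 * (1 - dam_g / 2) + sire_g / 2 * (1 - sire_g / 2)).sum(axis=0)
        se = np.sqrt(var) / (2.0 * pool.n)
        z = np.abs(pool.allele_frequency() - expected) / se
        assert np.mean(z > 3) < 0.05

    def test_cross_assignment_uniform_chi_square(self):
        f = make_founders(n_snps=10, seed=4)
        pool = make_zygote_pool(f, 96_000, seed=5)
        counts = np.bincount(pool.cross_ids(f.n_sires), minlength=192)
        stat, p = stats.chisquare(counts)
        assert p > 0.01


class TestSelectionEpisode:
    def _pool(self, n_snps=20, n=20_000, p=0.5, seed=7):
        f = make_founders(n_snps=n_snps, seed=seed,
                          af_distribution={"kind": "point", "value": p})
        return f, make_zygote_pool(f, n, seed=seed + 1)

    def test_neutral_episode_is_pure_drift(self):
        """All effects zero: survivor frequencies deviate from the pool only
        by without-replacement sampling noise."""
        f, pool = self._pool()
        before = pool.allele_frequency()
        surv = apply_selection_episode(pool, neutral_regime(), "ambient",
                                       survivors=2_000, drift_fraction=0.5, seed=1)
        after = surv.allele_frequency()
        # hypergeometric SE for 2K copies drawn from 2N
        k, n = 2 * surv.n, 2 * pool.n
        se = np.sqrt(before * (1 - before) / k * (1 - k / n))
        assert np.mean(np.abs(after - before) > 3 * se) < 0.05

    def test_lethal_recessive_leaves_no_homozygotes(self):
        f, pool = self._pool(n_snps=1, p=0.5)
        regime = SelectionRegime(
            loci_shared=np.array([0]), loci_ambient=np.array([], dtype=int),
            loci_lowph=np.array([], dtype=int),
            effects={0: -1e30}, dominance={0: 0.0},
        )
        n_hom = int((pool.genotypes[:, 0] == 2).sum())
        surv = apply_selection_episode(pool, regime, "ambient",
                                       survivors=pool.n - n_hom, drift_fraction=0.0, seed=2)
        assert not np.any(surv.genotypes[:, 0] == 2)

    def test_survivor_count_exact_and_monotone_rounds(self):
        f, pool = self._pool(n_snps=5)
        for rounds in (1, 6):
            surv = apply_selection_episode(pool, neutral_regime(), "ambient",
                                           survivors=1234, seed=3, n_rounds=rounds)
            assert surv.n == 1234

    def test_oversized_request_rejected(self):
        f, pool = self._pool(n_snps=2, n=100)
        with pytest.raises(ValueError):
            apply_selection_episode(pool, neutral_regime(), "ambient", survivors=101)

    def test_no_deaths_identity(self):
        f, pool = self._pool(n_snps=3, n=500)
        surv = apply_selection_episode(pool, neutral_regime(), "ambient", survivors=500)
        assert np.array_equal(surv.genotypes, pool.genotypes)


class TestPhenotypes:
    def _growth(self, **kw):
        return GrowthModel(**kw)

    def test_zero_effects_zero_noise_deterministic_baseline(self):
        f = make_founders(n_snps=4, seed=1)
        pool = make_zygote_pool(f, 50, seed=2)
        g = self._growth(noise_sd=0.0)
        ph = assign_phenotypes(pool, 6, "ambient", g, seed=3)
        assert np.allclose(ph["shell_length"], g.baseline(6))

    def test_low_ph_deficit_schedule(self):
        g = self._growth()
        assert g.deficit("low_pH", 3) == pytest.approx(0.08)
        assert g.deficit("low_pH", 26) == pytest.approx(0.025)
        assert 0.025 < g.deficit("low_pH", 14) < 0.08
        assert g.deficit("ambient", 3) == 0.0

    def test_day3_size_ratio_near_configured_deficit(self):
        f = make_founders(n_snps=4, seed=1)
        pool = make_zygote_pool(f, 4_000, seed=2)
        g = self._growth(noise_sd=2.0)
        amb = assign_phenotypes(pool, 3, "ambient", g, seed=3)
        low = assign_phenotypes(pool, 3, "low_pH", g, seed=4)
        ratio = low["shell_length"].mean() / amb["shell_length"].mean()
        assert ratio == pytest.approx(0.92, abs=0.005)

    def test_cv_monotone_in_growth_variance(self):
        f = make_founders(n_snps=12, seed=5,
                          af_distribution={"kind": "point", "value": 0.5})
        pool = make_zygote_pool(f, 5_000, seed=6)
        cvs = []
        for beta in (0.0, 2.0, 4.0):
            g = GrowthModel(
                loci=np.arange(12), effects=np.full(12, beta),
                env=np.array(["shared"] * 12, dtype=object),
                mean_dosage=2 * f.founder_afs[np.arange(12)], noise_sd=1.0,
            )
            ph = assign_phenotypes(pool, 6, "ambient", g, seed=7)
            cvs.append(ph["shell_length"].std() / ph["shell_length"].mean())
        assert cvs[0] < cvs[1] < cvs[2]


class TestTruncateBySize:
    def test_fraction_018_of_100_distinct(self):
        ph = pd.DataFrame({"individual_id": np.arange(100),
                           "shell_length": np.random.default_rng(0).permutation(100.0 + np.arange(100))})
        fast, slow = truncate_by_size(ph, 0.18)
        assert len(fast) == 18 and len(slow) == 82
        assert fast["shell_length"].min() > slow["shell_length"].max()

    def test_all_ties_split_by_identifier(self):
        ph = pd.DataFrame({"individual_id": np.arange(10), "shell_length": 7.0})
        fast, slow = truncate_by_size(ph, 0.3)
        assert len(fast) == 3
        assert list(fast["individual_id"]) == [0, 1, 2]

    def test_half_split_of_one_to_ten(self):
        ph = pd.DataFrame({"individual_id": np.arange(10),
                           "shell_length": np.arange(1.0, 11.0)})
        fast, _ = truncate_by_size(ph, 0.5)
        assert set(fast["shell_length"]) == {6.0, 7.0, 8.0, 9.0, 10.0}

    def test_single_individual_rejected(self):
        ph = pd.DataFrame({"individual_id": [0], "shell_length": [5.0]})
        with pytest.raises(ValueError):
            truncate_by_size(ph, 0.2)


class TestSequencing:
    def test_fixed_alt_pool_all_reads_alt(self):
        ref, alt = sequence_frequencies(np.ones(50), SeqNoiseModel(100, 200), seed=1)
        assert np.all(ref == 0)
        assert np.all(alt > 0)

    def test_read_frequency_unbiased(self):
        freq = np.full(10_000, 0.37)
        ref, alt = sequence_frequencies(freq, SeqNoiseModel(100, 200), seed=2)
        est = alt.sum() / (alt.sum() + ref.sum())
        se = np.sqrt(0.37 * 0.63 / (alt + ref).sum())
        assert abs(est - 0.37) < 3 * se

    def test_mean_coverage_within_two_percent(self):
        ref, alt = sequence_frequencies(np.full(10_000, 0.5), SeqNoiseModel(100, 200), seed=3)
        mean_cov = (ref + alt).mean()
        assert abs(mean_cov - 100) / 100 < 0.02

    def test_fixed_distribution_exact_depth(self):
        noise = SeqNoiseModel(80, distribution="fixed")
        ref, alt = sequence_frequencies(np.full(20, 0.5), noise, seed=4)
        assert np.all(ref + alt == 80)

    def test_empty_pool_rejected(self):
        pool = ZygotePool(genotypes=np.empty((0, 3), dtype=np.int8),
                          dam_idx=np.empty(0, dtype=np.int32),
                          sire_idx=np.empty(0, dtype=np.int32),
                          ids=np.empty(0, dtype=int))
        with pytest.raises(ValueError):
            sequence_pool(pool, SeqNoiseModel())


class TestRunExperiment:
    def test_sampling_topology_matches_design(self, tiny_sim):
        meta = tiny_sim.meta
        assert len(meta.select(treatment="founder")) == 28
        assert len(meta.select(day=0, treatment="day0")) == 1
        # day 6: per treatment 2 fastest + 2 slowest + 1 full population
        for tr in ("ambient", "low_pH"):
            assert len(meta.select(day=6, treatment=tr, size_class="fastest")) == 2
            assert len(meta.select(day=6, treatment=tr, size_class="slowest")) == 2
            assert len(meta.select(day=6, treatment=tr, size_class="all")) == 1
            assert len(meta.select(day=26, treatment=tr)) == 3
        # ambient replicate 6 is sacrificed before day-43 sequencing
        assert len(meta.select(day=43, treatment="ambient")) == 2
        assert len(meta.select(day=43, treatment="low_pH")) == 3
        # 22 pooled larval samples in total
        pooled = meta.table[meta.table["treatment"] != "founder"]
        assert len(pooled) == 22

    def test_destructive_replicates_absent_later(self, tiny_sim):
        meta = tiny_sim.meta.table
        day6_reps = set(meta.loc[meta["day"] == 6, "replicate"])
        later_reps = set(meta.loc[meta["day"].isin([26, 43]), "replicate"])
        assert day6_reps.isdisjoint(later_reps)

    def test_census_follows_configured_schedule(self, tiny_sim):
        census = tiny_sim.truth.census
        cfg = tiny_sim.config
        for _, row in census.iterrows():
            if row["day"] == 0:
                assert row["count"] == cfg.n_offspring
            else:
                assert row["count"] == cfg.census(row["treatment"], row["day"])

    def test_schedule_mortality_reproduces_published_rates(self):
        cfg = ExperimentConfig()
        for tr, expected in (("ambient", 97.7), ("low_pH", 97.6)):
            ends = [cfg.census(tr, 26)] * 3
            rounded, _ = mortality_from_census(cfg.n_offspring, ends)
            assert rounded == expected

    def test_same_seed_identical_outputs(self):
        cfg = scaled_config(n_offspring=1_000, n_snps=120, with_selection=False,
                            with_growth_loci=False)
        a = run_experiment(cfg, seed=5)
        b = run_experiment(cfg, seed=5)
        assert a.counts.equals(b.counts)
        assert a.meta.table.equals(b.meta.table)
        assert a.phenotypes.equals(b.phenotypes)

    def test_inconsistent_schedule_rejected(self):
        cfg = scaled_config(n_offspring=1_000, n_snps=120)
        cfg.census_fractions["ambient"][26] = 0.5  # above the day-6 census
        with pytest.raises(ValueError, match="non-increasing"):
            run_experiment(cfg, seed=1)

    def test_selected_loci_shift_by_half_their_frequency(self, selection_sim):
        """Default regime produces >=50% relative frequency shifts at the
        environment-specific loci by the end of the experiment."""
        truth = selection_sim.truth
        f0 = truth.true_pool_freq["d0_pool"]
        reg = truth.regime
        for env, loci in (("ambient", reg.loci_ambient), ("low_pH", reg.loci_lowph)):
            for rep in ("r4", "r5", "r6"):
                f26 = truth.true_pool_freq[f"d26_{env}_{rep}"]
                rel = np.abs(f26[loci] - f0[loci]) / f0[loci]
                assert np.mean(rel >= 0.5) >= 0.75
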