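"""Generator behavior: Balding-Nichols moments, mixed mating, selfing, preset."""

import numpy as np
import pytest

from selfkit.genotypes import (MISSING, diversity_summary,
                               observed_heterozygosity)
from selfkit.selfing import multilocus_g2, selfing_to_g2
from selfkit.simulate import (G_CAP, LineageSpec, PopulationSpec,
                              ScenarioConfig, apply_missingness,
                              draw_selfing_depths, self_offspring,
                              simulate_lineage_frequencies,
                              simulate_locus_independent_population,
                              simulate_mixed_mating_population,
                              simulate_study, study_config)
from conftest import make_gm


def _config(n_loci=10_000, fst=0.2, seed=1):
    return ScenarioConfig(
        n_loci=n_loci,
        lineages=[LineageSpec("A", fst)],
        populations=[PopulationSpec("p1", "A", 5, 0.5)],
        seed=seed,
    )


class TestLineageFrequencies:
    def test_fst_limit_copies_ancestral(self):
        cfg = _config(fst=1e-6)
        tab = simulate_lineage_frequencies(cfg)
        assert np.max(np.abs(tab.frequencies[0] - tab.ancestral)) < 0.02

    def test_deterministic_under_seed(self):
        a = simulate_lineage_frequencies(_config(seed=7))
        b = simulate_lineage_frequencies(_config(seed=7))
        np.testing.assert_array_equal(a.frequencies, b.frequencies)

    def test_balding_nichols_moments(self):
        cfg = _config(n_loci=20_000, fst=0.3)
        tab = simulate_lineage_frequencies(cfg)
        p0, p = tab.ancestral, tab.frequencies[0]
        resid = p - p0
        assert abs(resid.mean()) < 0.01
        target_var = np.mean(0.3 * p0 * (1 - p0))
        assert np.var(resid) == pytest.approx(target_var, rel=0.05)

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            _config(fst=1.0)


class TestMixedMating:
    def test_outcrossing_limit_hardy_weinberg(self, rng):
        p = rng.uniform(0.05, 0.95, 2000)
        geno, G = simulate_mixed_mating_population(p, 0.0, 200, rng)
        assert np.all(G == 0)
        ho = (geno == 1).mean(axis=0)
        he = 2 * p * (1 - p)
        # F_IS near 0: observed het tracks 2pq on average
        assert np.mean(ho - he) == pytest.approx(0.0, abs=0.01)

    def test_geometric_depth_distribution(self, rng):
        G = draw_selfing_depths(0.6, 200_000, rng)
        # P(G=0) = 0.4, P(G=1) = 0.24, mean = s/(1-s) = 1.5
        assert (G == 0).mean() == pytest.approx(0.4, abs=0.01)
        assert (G == 1).mean() == pytest.approx(0.24, abs=0.01)
        assert G.mean() == pytest.approx(1.5, abs=0.03)

    def test_s_one_capped_with_warning(self, rng):
        p = np.full(50, 0.5)
        with pytest.warns(UserWarning):
            geno, G = simulate_mixed_mating_population(p, 1.0, 10, rng)
        assert np.all(G == G_CAP)
        assert (geno == 1).mean() < 0.05  # residual heterozygosity ~ 2^-50

    def test_ho_matches_mixed_mating_equilibrium(self, rng):
        # H_O -> H_E (1 - F) with F = s/(2-s); n=200, L=2000, 3 MC SD band
        s, n, L = 0.5, 200, 2000
        reps = []
        for _ in range(10):
            p = rng.uniform(0.05, 0.95, L)
            geno, _ = simulate_mixed_mating_population(p, s, n, rng)
            he = np.mean(2 * p * (1 - p))
            reps.append((geno == 1).mean() / he)
        F = s / (2 - s)
        se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert abs(np.mean(reps) - (1 - F)) < 3 * se

    def test_fis_centered_on_zero_under_random_mating(self, rng):
        # F_IS of a Hardy-Weinberg population: |mean| < 3 SE over 100 reps
        fis = []
        for _ in range(100):
            p = rng.uniform(0.05, 0.95, 300)
            geno, _ = simulate_mixed_mating_population(p, 0.0, 30, rng)
            summ = diversity_summary(make_gm(geno))
            fis.append(summ.per_group["f_is"].iloc[0])
        se = np.std(fis, ddof=1) / np.sqrt(len(fis))
        assert abs(np.mean(fis)) < 3 * se

    @pytest.mark.parametrize("s", [0.2, 0.5, 0.8, 0.95])
    def test_shared_depth_creates_identity_disequilibrium(self, s, rng):
        # ghat2 matches s/((1-s)(4-s)) within 3 MC SDs (n=200, L=2000)
        reps = []
        for _ in range(8):
            p = rng.uniform(0.05, 0.95, 2000)
            geno, _ = simulate_mixed_mating_population(p, s, 200, rng)
            reps.append(multilocus_g2((geno == 1).astype(float)).g2)
        se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert abs(np.mean(reps) - selfing_to_g2(s)) < 3 * se

    def test_locus_independent_variant_kills_g2(self, rng):
        # same heterozygote deficit, but G redrawn per locus -> g2 = 0
        reps = []
        for _ in range(8):
            p = rng.uniform(0.05, 0.95, 2000)
            geno = simulate_locus_independent_population(p, 0.8, 200, rng)
            reps.append(multilocus_g2((geno == 1).astype(float)).g2)
        se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert abs(np.mean(reps)) < 3 * se


class TestSelfOffspring:
    def test_zero_generations_identity(self, rng):
        g = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        np.testing.assert_array_equal(self_offspring(g, 0, rng), g)

    def test_homozygous_rows_invariant(self, rng):
        g = np.array([[0, 2, 0, 2, MISSING]], dtype=np.int8)
        np.testing.assert_array_equal(self_offspring(g, 5, rng), g)

    def test_heterozygosity_halves_per_generation(self, rng):
        g = np.ones((1, 10_000), dtype=np.int8)
        out = self_offspring(g, 3, rng)
        frac = (out == 1).mean()
        se = np.sqrt(0.125 * 0.875 / 10_000)
        assert abs(frac - 0.125) < 3 * se
        # resolved loci split evenly between the homozygote classes
        assert (out == 0).sum() == pytest.approx((out == 2).sum(), rel=0.1)

    def test_negative_generations_rejected(self, rng):
        with pytest.raises(ValueError):
            self_offspring(np.array([[1]]), -1, rng)


class TestMissingness:
    def test_zero_rate_identity(self, small_gm):
        out = apply_missingness(small_gm, 0.0, seed=3)
        np.testing.assert_array_equal(out.genotypes, small_gm.genotypes)

    def test_mean_rate_realized(self, rng):
        gm = make_gm(np.ones((200, 2000), dtype=np.int8))
        out = apply_missingness(gm, 0.065, concentration=1.5, seed=rng)
        assert (out.genotypes == MISSING).mean() == pytest.approx(0.065, abs=0.01)

    def test_same_seed_same_mask(self, small_gm):
        a = apply_missingness(small_gm, 0.2, seed=11)
        b = apply_missingness(small_gm, 0.2, seed=11)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)


class TestStudyPreset:
    def test_structure_of_preset(self):
        gm, truth, cfg = simulate_study("paper_like", seed=0, n_loci=1000)
        assert len(set(gm.population_labels)) == 30
        assert cfg.n_loci == 1000
        assert len(truth) == gm.n_individuals
        assert (truth["category"] == "recent_hybrid").sum() >= 1
        assert (truth["category"] == "historical_hybrid").sum() >= 1

    def test_default_locus_count_study_scale(self):
        assert study_config().n_loci == 6000

    def test_determinism(self):
        a, ta, _ = simulate_study("paper_like", seed=5, n_loci=500)
        b, tb, _ = simulate_study("paper_like", seed=5, n_loci=500)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        assert ta.equals(tb)

    def test_invasive_less_diverse_than_native_outcrosser(self):
        gm, truth, _ = simulate_study("paper_like", seed=0, n_loci=2000)
        ho = observed_heterozygosity(gm)
        inv = truth["lineage"].isin(["RED", "ORANGE", "YELLOW"]).to_numpy()
        native_out = (truth["lineage"] == "BLUE").to_numpy()
        assert np.nanmean(ho[inv]) < np.nanmean(ho[native_out])

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            simulate_study("nope", seed=0)
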