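"""The synthetic F2 design: Mendelian structure, determinism, fixtures."""

import numpy as np
import pytest

from bsamap import simdata
from bsamap.exceptions import ConfigurationError
from bsamap.segregation import chi_square_gof
from bsamap.seqeffect import classify_effect, translate_cds
from bsamap.quantexpr import relative_expression


@pytest.fixture(scope="module")
def big_population(small_map, causal):
    return simdata.simulate_f2_population(small_map, causal, n=10_000, seed=5)


class TestF2Simulation:
    def test_zero_genetic_length_gives_intact_haplotypes(self, causal):
        gmap = simdata.default_map(
            n_chromosomes=2, chromosome_length=5_000_000,
            genetic_length_morgans=0.0, snps_per_chromosome=250,
        )
        pop = simdata.simulate_f2_population(gmap, causal, n=50, seed=3)
        for ind in pop.individuals:
            for codes in ind.genotypes.values():
                # no crossovers: every chromosome is a sum of two constant gametes
                assert np.unique(codes).size == 1

    def test_phenotype_frequency_is_one_quarter(self, big_population):
        frac_short = np.mean([p == "short" for p in big_population.phenotypes])
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert abs(frac_short - 0.25) < 3 * se

    def test_genotype_frequencies_fit_1_2_1(self, big_population):
        """Single-SNP genotype classes in a large F2 fit 1:2:1 (alpha=0.001)."""
        codes = big_population.genotype_matrix("Chr2")[:, 100]
        counts = [int((codes == g).sum()) for g in (0, 1, 2)]
        assert chi_square_gof(counts, (1, 2, 1)).p > 0.001

    def test_phenotype_is_deterministic_at_causal_locus(self, population, causal):
        snps = population.map_spec.snp_positions[causal.chromosome]
        idx = int(np.searchsorted(snps, causal.position))
        for ind in population.individuals:
            assert (ind.phenotype == "short") == (ind.genotypes[causal.chromosome][idx] == 2)

    def test_same_seed_reproduces_population(self, small_map, causal):
        a = simdata.simulate_f2_population(small_map, causal, n=40, seed=9)
        b = simdata.simulate_f2_population(small_map, causal, n=40, seed=9)
        for x, y in zip(a.individuals, b.individuals):
            assert x.phenotype == y.phenotype
            for chrom in x.genotypes:
                np.testing.assert_array_equal(x.genotypes[chrom], y.genotypes[chrom])

    def test_causal_locus_must_be_a_snp(self, small_map):
        bad = simdata.CausalLocusSpec(chromosome="Chr1", position=123)
        with pytest.raises(ConfigurationError):
            simdata.simulate_f2_population(small_map, bad, n=10, seed=0)


class TestBulkDepths:
    def test_short_bulk_is_fixed_at_causal_snp(self, population, depth_records, causal):
        at = depth_records[
            (depth_records["chrom"] == causal.chromosome)
            & (depth_records["pos"] == causal.position)
        ].iloc[0]
        assert at["S_ref"] == 0 and at["S_alt"] > 0  # index exactly 1

    def test_fixed_depth_model(self, population):
        bulk = simdata.BulkSpec(bulk_size=30, mean_depth=30, depth_model="fixed")
        df = simdata.simulate_bulk_depths(population, bulk, seed=1)
        assert ((df["L_ref"] + df["L_alt"]) == 30).all()
        assert ((df["S_ref"] + df["S_alt"]) == 30).all()

    def test_unlinked_chromosome_index_near_half(self, population):
        bulk = simdata.BulkSpec(bulk_size=30, mean_depth=500, depth_model="fixed")
        df = simdata.simulate_bulk_depths(population, bulk, seed=2)
        off = df[df["chrom"] == "Chr2"]
        mean_index = (off["L_alt"] / 500).mean()
        # bulk-composition noise is correlated along the chromosome; generous band
        assert abs(mean_index - 0.5) < 0.06

    def test_insufficient_bulk_members_reported(self, small_map, causal):
        pop = simdata.simulate_f2_population(small_map, causal, n=20, seed=1)
        with pytest.raises(ValueError, match="short"):
            simdata.simulate_bulk_depths(pop, simdata.BulkSpec(bulk_size=15), seed=0)


class TestMarkerExtraction:
    def test_causal_marker_codes_match_phenotype(self, population, causal):
        table = simdata.extract_marker_genotypes(
            population, {causal.chromosome: np.array([causal.position])}
        )
        name = f"M_{causal.chromosome}_{causal.position}"
        for ind in population.individuals:
            if ind.phenotype == "short":
                assert table.genotypes.loc[ind.id, name] == "B"

    def test_empty_marker_list_gives_phenotype_only_table(self, population):
        table = simdata.extract_marker_genotypes(population, {})
        assert table.genotypes.shape[1] == 0
        assert len(table.phenotypes) == len(population.individuals)

    def test_unknown_marker_position_rejected(self, population):
        with pytest.raises(ConfigurationError):
            simdata.extract_marker_genotypes(population, {"Chr1": np.array([999])})

    def test_recombinant_count_matches_haldane_expectation(self, small_map, causal):
        """Markers ~1 cM each side of the causal locus: ~2*n*r recombinants per side."""
        from bsamap.finemap import find_recombinants

        snps = small_map.snp_positions[causal.chromosome]
        # 0.6 M over 5 Mb -> 1.2e-7 M/bp; 1 cM ~ 83 kb ~ 4 SNP steps of 20 kb
        morgans_per_bp = 0.6 / 5_000_000
        idx = int(np.searchsorted(snps, causal.position))
        left, right = int(snps[idx - 4]), int(snps[idx + 4])
        d = (causal.position - left) * morgans_per_bp
        r = (1 - np.exp(-2 * d)) / 2

        total, n, seeds = 0, 200, range(10)
        for s in seeds:
            pop = simdata.simulate_f2_population(small_map, causal, n=n, seed=100 + s)
            table = simdata.extract_marker_genotypes(
                pop, {causal.chromosome: np.array([left, causal.position, right])}
            )
            total += len(
                find_recombinants(table, f"M_Chr1_{left}", f"M_Chr1_{causal.position}")
            )
        expected = 2 * n * len(seeds) * r  # recombinant gametes per individual
        sd = np.sqrt(2 * n * len(seeds) * r * (1 - r))
        assert abs(total - expected) < 4 * sd


class TestCdsFixture:
    def test_default_fixture_reproduces_target_truncation(self):
        ref, mut, domains = simdata.make_cds_fixture(seed=1)
        assert len(ref) == 1200 and ref.startswith("ATG")
        assert len(mut) == len(ref) - 13
        effect = classify_effect(ref, mut, 502, 514, domains)
        assert effect.frameshift
        assert effect.protein_length_mut == 173
        lost = {d.name for d in effect.lost_domains}
        assert lost == {"2OG-FeII_Oxy"}

    def test_reference_has_no_internal_stop(self):
        ref, _, _ = simdata.make_cds_fixture(seed=4)
        assert len(translate_cds(ref)) == len(ref) // 3 - 1

    def test_in_frame_deletion_has_no_premature_stop(self):
        ref, mut, _ = simdata.make_cds_fixture(
            deletion_start=502, deletion_length=3, seed=2
        )
        assert len(translate_cds(mut)) == len(translate_cds(ref)) - 1

    def test_unsatisfiable_target_errors(self):
        with pytest.raises(RuntimeError, match="iterations"):
            simdata.make_cds_fixture(
                total_length=300, deletion_start=250, deletion_length=13,
                target_truncated_aa=10, seed=0, max_iterations=50,
            )


class TestCtSimulation:
    def test_noise_free_fold_changes_recovered_exactly(self):
        table = simdata.simulate_ct_table(
            {"mut": 1.0, "high": 8.0}, calibrator="wt", noise_sd=0.0, seed=0
        )
        res = relative_expression(table, calibrator="wt").set_index("sample")
        assert res.loc["mut", "fold"] == pytest.approx(1.0, abs=1e-12)
        assert res.loc["high", "fold"] == pytest.approx(8.0, abs=1e-9)

    def test_noisy_estimator_mean_matches_lognormal_oracle(self):
        """With Ct noise sd s and r replicates, ddCt noise has variance 4s^2/r
        and E[2^-noise] = exp((ln2)^2 * 4s^2 / (2r)) — a lognormal mean."""
        sd, reps, truth = 0.2, 3, 3.0
        estimates = []
        for seed in range(400):
            table = simdata.simulate_ct_table(
                {"s": truth}, calibrator="cal", noise_sd=sd, replicates=reps, seed=seed
            )
            res = relative_expression(table, "cal").set_index("sample")
            estimates.append(res.loc["s", "fold"])
        expected_mean = truth * np.exp((np.log(2) ** 2) * (4 * sd**2 / reps) / 2)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - expected_mean) < 3 * se
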