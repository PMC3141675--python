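"""Generator tests: map, DH population genetics, expression, artifacts."""
import math

import numpy as np
import pandas as pd
import pytest

from eqtlscan import simdata
from eqtlscan.containers import B73, MISSING, MO17


# ---------------------------------------------------------------------------
# genetic map


class TestSimulateMap:
    def test_marker_count_and_bounds(self):
        cfg = simdata.SimConfig(n_markers=1731, n_chromosomes=10,
                                chrom_length_cM=100.0, seed=1)
        gmap = simdata.simulate_map(cfg)
        assert gmap.n_markers == 1731
        assert (gmap.position_cM >= 0).all() and (gmap.position_cM <= 100).all()
        assert len(gmap.chromosomes) == 10

    def test_even_spacing_endpoints(self):
        cfg = simdata.SimConfig(n_markers=2, n_chromosomes=1,
                                chrom_length_cM=100.0, marker_placement="even",
                                seed=0)
        gmap = simdata.simulate_map(cfg)
        assert list(gmap.position_cM) == [0.0, 100.0]

    @pytest.mark.parametrize("placement", ["even", "uniform"])
    def test_same_seed_identical(self, placement):
        cfg = simdata.SimConfig(n_markers=50, n_chromosomes=3,
                                chrom_length_cM=80.0,
                                marker_placement=placement, seed=9)
        m1 = simdata.simulate_map(cfg)
        m2 = simdata.simulate_map(cfg)
        assert np.array_equal(m1.position_cM, m2.position_cM)
        assert np.array_equal(m1.marker_id, m2.marker_id)

    def test_resolution_limit_rejected(self):
        cfg = simdata.SimConfig(n_markers=200, n_chromosomes=1,
                                chrom_length_cM=1.0, seed=0)
        with pytest.raises(ValueError, match="resolution"):
            simdata.simulate_map(cfg)

    def test_allocation_proportional_to_length(self):
        cfg = simdata.SimConfig(n_markers=300, n_chromosomes=3,
                                chrom_length_cM=[100.0, 200.0, 300.0], seed=0)
        gmap = simdata.simulate_map(cfg)
        counts = [int((gmap.chromosome == c).sum()) for c in gmap.chromosomes]
        assert counts == [50, 100, 150]


# ---------------------------------------------------------------------------
# DH population


def _two_marker_map(d_cM):
    return simdata.GeneticMap(
        np.array(["mA", "mB"], dtype=object),
        np.array(["chr1", "chr1"], dtype=object),
        np.array([0.0, d_cM]),
    )


def oracle_recombinant_fraction(d_cM, n_generations, n_dh, pop, rng):
    """Independent brute-force two-locus gamete tracker.

    Meiosis samples an explicit Poisson number of crossover points on the
    interval; an odd count switches the parental haplotype between the loci.
    Random union of gametes each generation, then one doubled gamete per
    sampled final individual.
    """
    lam = d_cM / 100.0

    def gametes(h1, h2, k):
        # h*: (k, 2) haplotypes; returns (k, 2) gametes
        start = rng.integers(2, size=k)
        odd = rng.poisson(lam, size=k) % 2 == 1
        first = np.where(start == 0, h1[np.arange(k), 0], h2[np.arange(k), 0])
        second_hap = start ^ odd
        second = np.where(second_hap == 0, h1[np.arange(k), 1],
                          h2[np.arange(k), 1])
        return np.column_stack([first, second])

    h1 = np.zeros((pop, 2), dtype=np.int8)   # B73 haplotype
    h2 = np.ones((pop, 2), dtype=np.int8)    # Mo17 haplotype
    for _ in range(n_generations):
        mo = rng.integers(pop, size=pop)
        fa = rng.integers(pop, size=pop)
        eggs = gametes(h1[mo], h2[mo], pop)
        sperm = gametes(h1[fa], h2[fa], pop)
        h1, h2 = eggs, sperm
    chosen = rng.integers(pop, size=n_dh)
    dh = gametes(h1[chosen], h2[chosen], n_dh)
    return float((dh[:, 0] != dh[:, 1]).mean())


def closed_form_recombinant_fraction(d_cM, n_generations):
    """Infinite-population expectation: 1/2 - (1-2r)(1-r)^g / 2, Haldane r."""
    r = 0.5 * (1 - math.exp(-2 * d_cM / 100))
    return 0.5 - (1 - 2 * r) * (1 - r) ** n_generations / 2


class TestDHPopulation:
    def test_all_calls_homozygous_codes(self, small_dataset):
        codes = small_dataset.genotypes.codes
        assert np.isin(codes, (B73, MO17, MISSING)).all()

    def test_zero_distance_markers_never_recombine(self):
        cfg = simdata.SimConfig(n_lines=200, n_chromosomes=1,
                                intermating_pop_size=100, seed=4,
                                missing_genotype_rate=0.0)
        gmap = simdata.GeneticMap(
            np.array(["mA", "mB"], dtype=object),
            np.array(["chr1", "chr1"], dtype=object),
            np.array([5.0, 5.0 + 1e-12]),
        )
        geno = simdata.simulate_dh_population(gmap, cfg)
        assert (geno.codes[:, 0] == geno.codes[:, 1]).all()

    @pytest.mark.parametrize("generations", [0, 10])
    def test_recombination_matches_bruteforce_oracle(self, generations):
        # a single finite population realization carries drift noise, so
        # average each side over independent populations
        d = 10.0
        fracs = []
        for s in range(4):
            cfg = simdata.SimConfig(n_lines=10_000, intermating_pop_size=1000,
                                    n_intermating_generations=generations,
                                    missing_genotype_rate=0.0, seed=21 + s)
            geno = simdata.simulate_dh_population(_two_marker_map(d), cfg)
            fracs.append((geno.codes[:, 0] != geno.codes[:, 1]).mean())
        observed = np.mean(fracs)
        rng = np.random.default_rng(77)
        oracle = np.mean([
            oracle_recombinant_fraction(d, generations, 10_000, 1000, rng)
            for _ in range(4)
        ])
        expected = closed_form_recombinant_fraction(d, generations)
        # oracle and closed form agree; implementation agrees with both
        assert oracle == pytest.approx(expected, abs=0.02)
        assert observed == pytest.approx(oracle, abs=0.025)

    def test_intermating_increases_recombinants(self):
        d = 10.0
        fracs = []
        for g in (0, 5, 10):
            cfg = simdata.SimConfig(n_lines=10_000, intermating_pop_size=1000,
                                    n_intermating_generations=g,
                                    missing_genotype_rate=0.0, seed=31)
            geno = simdata.simulate_dh_population(_two_marker_map(d), cfg)
            fracs.append(float((geno.codes[:, 0] != geno.codes[:, 1]).mean()))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_allele_frequencies_balanced(self):
        cfg = simdata.SimConfig(n_lines=1000, n_markers=20, n_chromosomes=2,
                                chrom_length_cM=100.0,
                                intermating_pop_size=5000,
                                missing_genotype_rate=0.0, seed=8)
        gmap = simdata.simulate_map(cfg)
        geno = simdata.simulate_dh_population(gmap, cfg)
        freqs = geno.allele_frequencies()
        band = 4 * math.sqrt(0.25 / cfg.n_lines)
        assert (np.abs(freqs - 0.5) < band).all()

    def test_missing_rate_and_determinism(self):
        cfg = simdata.SimConfig(n_lines=300, n_markers=50, n_chromosomes=2,
                                chrom_length_cM=100.0,
                                intermating_pop_size=100,
                                missing_genotype_rate=0.1, seed=12)
        gmap = simdata.simulate_map(cfg)
        g1 = simdata.simulate_dh_population(gmap, cfg)
        g2 = simdata.simulate_dh_population(gmap, cfg)
        assert np.array_equal(g1.codes, g2.codes)
        rate = float((g1.codes == MISSING).mean())
        assert rate == pytest.approx(0.1, abs=0.01)

    def test_too_few_lines_rejected(self, tiny_map):
        cfg = simdata.SimConfig(n_lines=1, seed=0)
        with pytest.raises(ValueError, match="n_lines"):
            simdata.simulate_dh_population(tiny_map, cfg)


# ---------------------------------------------------------------------------
# expression


def _noise_free(cfg_kwargs):
    return simdata.SimConfig(noise_sigma_add=0.0, noise_sigma_mult=0.0,
                             array_gain_sd=0.0, array_offset_sd=0.0,
                             baseline_log_sd=0.0, missing_genotype_rate=0.0,
                             frac_background_probes=0.0, **cfg_kwargs)


class TestSimulateExpression:
    def test_noise_free_fold_is_exact(self):
        cfg = _noise_free(dict(n_lines=60, n_markers=20, n_chromosomes=2,
                               chrom_length_cM=100.0, n_probes=10,
                               n_cis_effects=5, n_trans_effects=0,
                               effect_size_fold=9.0, intermating_pop_size=60,
                               seed=2))
        ds = simdata.SimDataset(
            cfg, simdata.simulate_map(cfg), None, None, None)
        gmap = ds.gmap
        geno = simdata.simulate_dh_population(gmap, cfg)
        truth = simdata.make_truth(gmap, cfg)
        expr = simdata.simulate_expression(geno, gmap, truth, cfg, 1)
        bg = cfg.background_level
        for _, row in truth[truth["mode"] == "cis"].iterrows():
            e = expr.row(row["probe_id"])
            j = gmap.nearest_marker(row["locus_chrom"], row["locus_cM"])
            high_code = B73 if row["high_allele"] == "B73" else MO17
            high = e[geno.codes[:, j] == high_code] - bg
            low = e[geno.codes[:, j] != high_code] - bg
            assert np.allclose(high, 9.0 * low[0])
            assert np.allclose(low, low[0])

    def test_fold_one_is_genotype_independent(self):
        cfg = _noise_free(dict(n_lines=40, n_markers=10, n_chromosomes=1,
                               chrom_length_cM=100.0, n_probes=5,
                               n_cis_effects=3, n_trans_effects=0,
                               effect_size_fold=1.0, intermating_pop_size=40,
                               seed=3))
        gmap = simdata.simulate_map(cfg)
        geno = simdata.simulate_dh_population(gmap, cfg)
        truth = simdata.make_truth(gmap, cfg)
        expr = simdata.simulate_expression(geno, gmap, truth, cfg, 1)
        assert np.allclose(expr.values, expr.values[:, :1])

    def test_monte_carlo_class_ratio(self):
        cfg = simdata.SimConfig(n_lines=135, n_markers=30, n_chromosomes=3,
                                chrom_length_cM=100.0, n_probes=100,
                                n_cis_effects=100, n_trans_effects=0,
                                effect_size_fold=2.0, noise_sigma_mult=0.2,
                                noise_sigma_add=0.0, array_gain_sd=0.0,
                                array_offset_sd=0.0, baseline_log_sd=0.0,
                                frac_background_probes=0.0,
                                missing_genotype_rate=0.0,
                                intermating_pop_size=100, seed=6)
        gmap = simdata.simulate_map(cfg)
        geno = simdata.simulate_dh_population(gmap, cfg)
        truth = simdata.make_truth(gmap, cfg)
        expr = simdata.simulate_expression(geno, gmap, truth, cfg, 1)
        bg = cfg.background_level
        ratios = []
        for _, row in truth.iterrows():
            e = expr.row(row["probe_id"])
            j = gmap.nearest_marker(row["locus_chrom"], row["locus_cM"])
            high_code = B73 if row["high_allele"] == "B73" else MO17
            hi = e[geno.codes[:, j] == high_code].mean() - bg
            lo = e[geno.codes[:, j] != high_code].mean() - bg
            ratios.append(hi / lo)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.1)

    def test_replicates_share_truth_not_noise(self, small_config,
                                              small_dataset):
        r1, r2 = small_dataset.replicates
        assert np.array_equal(r1.probe_ids, r2.probe_ids)
        assert not np.allclose(r1.values, r2.values)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            simdata.SimConfig(noise_sigma_add=-1.0)

    def test_seed_reproducibility_end_to_end(self, small_config):
        d1 = simdata.simulate_dataset(small_config, n_replicates=1)
        d2 = simdata.simulate_dataset(small_config, n_replicates=1)
        assert np.array_equal(d1.genotypes.codes, d2.genotypes.codes)
        assert np.array_equal(d1.replicates[0].values, d2.replicates[0].values)
        pd.testing.assert_frame_equal(d1.truth, d2.truth)


# ---------------------------------------------------------------------------
# artifacts


class TestArtifacts:
    def test_pav_mo17_class_at_background(self):
        cfg = simdata.SimConfig(n_lines=80, n_markers=20, n_chromosomes=2,
                                chrom_length_cM=100.0, n_probes=30,
                                n_cis_effects=0, n_trans_effects=0,
                                frac_background_probes=0.0,
                                pav_region=("chr1", 0.0, 100.0),
                                array_gain_sd=0.0, array_offset_sd=0.0,
                                missing_genotype_rate=0.0,
                                intermating_pop_size=80, seed=7)
        gmap = simdata.simulate_map(cfg)
        geno = simdata.simulate_dh_population(gmap, cfg)
        truth = simdata.make_truth(gmap, cfg)
        pav = truth[truth["artifact"] == "pav"]
        assert len(pav) > 0
        expr = simdata.simulate_expression(geno, gmap, truth, cfg, 1)
        expr = simdata.inject_probe_artifacts(expr, geno, gmap, truth, cfg, 1)
        for _, row in pav.iterrows():
            e = expr.row(row["probe_id"])
            j = gmap.nearest_marker(row["gene_chrom"], row["gene_cM"])
            mo17 = geno.codes[:, j] == MO17
            assert e[mo17].mean() == pytest.approx(
                cfg.background_level, abs=4 * cfg.noise_sigma_add)
            assert e[~mo17].mean() > 3 * cfg.background_level

    def test_polymorphic_attenuates_mo17_lines_only(self):
        cfg = simdata.SimConfig(n_lines=60, n_markers=20, n_chromosomes=2,
                                chrom_length_cM=100.0, n_probes=20,
                                n_cis_effects=0, n_trans_effects=0,
                                frac_background_probes=0.0,
                                frac_polymorphic_probes=0.25,
                                noise_sigma_add=0.0, noise_sigma_mult=0.0,
                                array_gain_sd=0.0, array_offset_sd=0.0,
                                baseline_log_sd=0.0,
                                missing_genotype_rate=0.0,
                                intermating_pop_size=60, seed=9)
        gmap = simdata.simulate_map(cfg)
        geno = simdata.simulate_dh_population(gmap, cfg)
        truth = simdata.make_truth(gmap, cfg)
        poly = truth[truth["artifact"] == "polymorphic"]
        assert len(poly) == 5
        raw = simdata.simulate_expression(geno, gmap, truth, cfg, 1)
        expr = simdata.inject_probe_artifacts(raw, geno, gmap, truth, cfg, 1)
        for _, row in poly.iterrows():
            before = raw.row(row["probe_id"])
            after = expr.row(row["probe_id"])
            j = gmap.nearest_marker(row["gene_chrom"], row["gene_cM"])
            mo17 = geno.codes[:, j] == MO17
            assert np.allclose(after[mo17], 0.1 * before[mo17])
            assert np.allclose(after[~mo17], before[~mo17])

    def test_artifact_flags_mutually_exclusive(self, small_dataset):
        per_probe = small_dataset.truth.groupby("probe_id")["artifact"].nunique()
        assert (per_probe == 1).all()

    def test_truth_roundtrip(self, small_dataset, tmp_path):
        path = tmp_path / "truth.tsv"
        simdata.write_truth(small_dataset.truth, path)
        back = simdata.read_truth(path)
        a = small_dataset.truth.reset_index(drop=True)
        # normalize missing-value representation (None vs NaN) before comparing
        a = a.fillna("<NA>")
        b = back.fillna("<NA>")
        pd.testing.assert_frame_equal(a, b, check_dtype=False,
                                      check_exact=False, rtol=1e-12)

    def test_empty_truth_roundtrip(self, tmp_path):
        empty = pd.DataFrame(columns=simdata.TRUTH_COLUMNS)
        path = tmp_path / "truth.tsv"
        simdata.write_truth(empty, path)
        back = simdata.read_truth(path)
        assert list(back.columns) == simdata.TRUTH_COLUMNS
        assert len(back) == 0
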