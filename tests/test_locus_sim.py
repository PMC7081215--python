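"""Generator correctness: LD structure, phenotype scaling, OLS stats,
annotation placement and diameter moments."""

import numpy as np
import pytest

import adipoloc as al
from adipoloc.locus_sim import expected_adjacent_r2, substream
from conftest import make_stats  # noqa: F401  (shared helpers)


class TestHaplotypesAndLD:
    def test_single_variant_ld_is_unit(self):
        cfg = al.SimConfig(n_individuals=50, m_variants=1, seed=3,
                           architecture=al.CausalArchitecture((0,), (0,)))
        ld = al.compute_ld(al.simulate_haplotypes(cfg))
        assert ld.values.shape == (1, 1)
        assert ld.values[0, 0] == pytest.approx(1.0)

    def test_duplicated_column_gives_r2_one(self):
        rng = np.random.default_rng(0)
        col = (rng.random(40) < 0.4).astype(np.uint8)
        other = (rng.random(40) < 0.5).astype(np.uint8)
        haps = al.Haplotypes(
            alleles=np.column_stack([col, col, other]), positions=[10, 20, 30]
        )
        ld = al.compute_ld(haps)
        assert ld.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_toy_r2_is_zero(self):
        # Pearson correlation of [0,0,1,1] and [0,1,1,0] is 0 by hand
        haps = al.Haplotypes(
            alleles=np.array([[0, 0], [0, 1], [1, 1], [1, 0]], dtype=np.uint8),
            positions=[100, 200],
        )
        ld = al.compute_ld(haps)
        assert ld.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_column_errors(self):
        haps = al.Haplotypes.__new__(al.Haplotypes)  # bypass polymorphy check
        haps.alleles = np.array([[1, 0], [1, 1], [1, 0]], dtype=np.uint8)
        haps.positions = np.array([1, 2])
        with pytest.raises(ValueError, match="column 0"):
            al.compute_ld(haps)

    def test_adjacent_r2_matches_copy_scheme_closed_form(self):
        # Monte-Carlo over 20 seeds against r^2 = decay^2 * v_{j-1}/v_j
        decay, samples, expected = 0.95, [], []
        for seed in range(20):
            cfg = al.SimConfig(
                n_individuals=2000, m_variants=200, ld_decay=decay, seed=seed,
                architecture=al.CausalArchitecture((0,), (0,)),
            )
            haps = al.simulate_haplotypes(cfg)
            r2 = al.compute_ld(haps).values
            samples.append(np.mean(np.diag(r2, k=1)))
            expected.append(expected_adjacent_r2(haps, decay))
        assert abs(np.mean(samples) - np.mean(expected)) < 0.05

    def test_deterministic_given_seed(self):
        cfg = al.SimConfig(n_individuals=100, m_variants=30, seed=42,
                           architecture=al.CausalArchitecture((5,), (5,)))
        a, b = al.simulate_haplotypes(cfg), al.simulate_haplotypes(cfg)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.positions, b.positions)

    def test_substreams_are_distinct(self):
        draws = {s: substream(7, s).random() for s in
                 ("haplotypes", "pheno_gwas", "pheno_eqtl", "annotation", "diameters")}
        assert len(set(draws.values())) == len(draws)


class TestPhenotypes:
    def test_h2_zero_gives_genotype_independent_trait(self):
        cfg = al.SimConfig(n_individuals=2000, m_variants=20, seed=5,
                           architecture=al.CausalArchitecture((3,), (3,), h2_gwas=0.0,
                                                              h2_eqtl=0.0))
        haps = al.simulate_haplotypes(cfg)
        y, _ = al.simulate_phenotypes(haps, cfg.architecture, 5)
        g = haps.genotypes()[:, 3]
        assert abs(np.corrcoef(y, g)[0, 1]) < 0.06

    def test_single_causal_variance_explained_targets_h2(self):
        # realized r^2(trait, causal dosage) ~ 0.5 across 20 seeds
        r2 = []
        for seed in range(20):
            cfg = al.SimConfig(
                n_individuals=2000, m_variants=10, seed=seed,
                architecture=al.CausalArchitecture((4,), (4,), h2_gwas=0.5, h2_eqtl=0.5),
            )
            haps = al.simulate_haplotypes(cfg)
            y, _ = al.simulate_phenotypes(haps, cfg.architecture, seed)
            g = haps.genotypes()[:, 4]
            r2.append(np.corrcoef(y, g)[0, 1] ** 2)
        assert np.mean(r2) == pytest.approx(0.5, abs=0.03)

    def test_h2_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="h2"):
            al.CausalArchitecture((0,), (0,), h2_gwas=1.0)

    def test_fixed_seed_reproduces_phenotypes(self):
        cfg = al.SimConfig(n_individuals=200, m_variants=10, seed=9,
                           architecture=al.CausalArchitecture((2,), (2,)))
        haps = al.simulate_haplotypes(cfg)
        a = al.simulate_phenotypes(haps, cfg.architecture, 9)
        b = al.simulate_phenotypes(haps, cfg.architecture, 9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestMarginalSummaryStats:
    def test_matches_statsmodels_ols_on_small_sample(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        haps = al.Haplotypes(
            alleles=(rng.random((10, 3)) < 0.5).astype(np.uint8),
            positions=[5, 15, 25],
        )
        y = rng.standard_normal(5)
        stats = al.marginal_summary_stats(haps, y)
        g = haps.genotypes()
        for j in range(3):
            fit = sm.OLS(y, sm.add_constant(g[:, j])).fit()
            assert stats.beta[j] == pytest.approx(fit.params[1], rel=1e-10)
            assert stats.se[j] == pytest.approx(fit.bse[1], rel=1e-10)

    def test_null_phenotype_mean_z2_near_one(self):
        # under the null, z^2 averages to ~1 (50 seeds)
        z2 = []
        for seed in range(50):
            cfg = al.SimConfig(n_individuals=300, m_variants=40, seed=seed,
                               architecture=al.CausalArchitecture((0,), (0,), h2_gwas=0,
                                                                  h2_eqtl=0))
            haps = al.simulate_haplotypes(cfg)
            y, _ = al.simulate_phenotypes(haps, cfg.architecture, seed)
            z2.append(np.mean(al.marginal_summary_stats(haps, y).z ** 2))
        assert np.mean(z2) == pytest.approx(1.0, abs=0.1)

    def test_perfect_fit_gives_maximal_z(self):
        cfg = al.SimConfig(n_individuals=100, m_variants=8, seed=2,
                           architecture=al.CausalArchitecture((0,), (0,)))
        haps = al.simulate_haplotypes(cfg)
        y = haps.genotypes()[:, 4]
        stats = al.marginal_summary_stats(haps, y)
        assert np.argmax(np.abs(stats.z)) == 4
        assert stats.se[4] < 1e-6

    def test_constant_column_errors(self):
        haps = al.Haplotypes.__new__(al.Haplotypes)
        haps.alleles = np.array(
            [[1, 0], [1, 1], [1, 0], [1, 1], [1, 0], [1, 1]], dtype=np.uint8
        )
        haps.positions = np.array([1, 2])
        with pytest.raises(ValueError, match="constant"):
            al.marginal_summary_stats(haps, np.zeros(3))


class TestAnnotationTrack:
    def test_causal_centered_covers_every_causal_position(self):
        for seed in range(10):
            cfg = al.SimConfig(
                n_individuals=10, m_variants=30, seed=seed,
                architecture=al.CausalArchitecture((4, 20), (4, 20), (1.0, 1.0)),
                enrichment_mode="causal-centered",
            )
            haps = al.simulate_haplotypes(cfg)
            track = al.simulate_annotation_track(cfg, cfg.architecture)
            for idx in (4, 20):
                pos = haps.positions[idx]
                assert any(s <= pos < e for s, e in track.intervals)

    def test_empty_track(self):
        cfg = al.SimConfig(n_individuals=10, m_variants=5, seed=1, n_intervals=0,
                           architecture=al.CausalArchitecture((0,), (0,)))
        track = al.simulate_annotation_track(cfg, cfg.architecture)
        assert track.intervals == []

    def test_null_mode_coverage_matches_interval_density(self):
        # P(variant covered) ~ 1 - (1 - L/span)^k for k uniform intervals
        cfg_proto = dict(n_individuals=10, m_variants=100, n_intervals=10,
                         interval_length_bp=2000, locus_span_bp=1_000_000)
        expect = 1 - (1 - 2000 / 1_000_000) ** 10
        fracs = []
        for seed in range(200):
            cfg = al.SimConfig(seed=seed, enrichment_mode="null",
                               architecture=al.CausalArchitecture((0,), (0,)),
                               **cfg_proto)
            haps = al.simulate_haplotypes(cfg)
            track = al.simulate_annotation_track(cfg, cfg.architecture)
            starts = np.array([s for s, _ in track.intervals])
            ends = np.array([e for _, e in track.intervals])
            covered = [
                np.any((starts <= p) & (p < ends)) for p in haps.positions
            ]
            fracs.append(np.mean(covered))
        assert np.mean(fracs) == pytest.approx(expect, abs=0.01)

    def test_oversized_interval_rejected(self):
        cfg = al.SimConfig(n_individuals=10, m_variants=5, seed=1,
                           locus_span_bp=1000, interval_length_bp=1000,
                           architecture=al.CausalArchitecture((0,), (0,)))
        with pytest.raises(ValueError, match="smaller than"):
            al.simulate_annotation_track(cfg, cfg.architecture)


class TestDiameters:
    def test_sample_moments_hit_configured_targets(self):
        s = al.simulate_diameters(40.4, 17.6, 2000, seed=7)
        assert s.diameters_um.mean() == pytest.approx(40.4, abs=1.5)
        assert s.diameters_um.std() == pytest.approx(17.6, abs=3.0)
        assert (s.diameters_um > 0).all()

    def test_tiny_sd_collapses_to_mean(self):
        s = al.simulate_diameters(50.0, 1e-6, 500, seed=1)
        assert np.allclose(s.diameters_um, 50.0, atol=1e-4)

    def test_same_seed_identical_samples(self):
        a = al.simulate_diameters(40.0, 15.0, 100, seed=3)
        b = al.simulate_diameters(40.0, 15.0, 100, seed=3)
        assert np.array_equal(a.diameters_um, b.diameters_um)

    @pytest.mark.parametrize("mean,sd", [(0, 10), (-5, 10), (40, 0)])
    def test_nonpositive_moments_rejected(self, mean, sd):
        with pytest.raises(ValueError):
            al.simulate_diameters(mean, sd, 10, seed=0)
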