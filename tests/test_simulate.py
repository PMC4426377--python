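"""The synthetic-data generator: pool structure, sampling, read-loss model."""

import numpy as np
import pandas as pd
import pytest

from refbias.simulate import (
    FocalSite,
    SimConfig,
    simulate_allele_pool,
    simulate_bundle,
    simulate_ngs_calls,
    simulate_population,
    window_mismatch_matrix,
)


def _cfg(**kw):
    base = dict(seed=21, n_alleles=128, n_populations=2, n_individuals=30)
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_rates_bounded(self):
        with pytest.raises(ValueError):
            _cfg(mapping_loss=1.5)

    def test_length_vs_window(self):
        with pytest.raises(ValueError):
            _cfg(length=30, read_half_width=25)

    def test_delta_bounded_by_window_span(self):
        with pytest.raises(ValueError, match="delta"):
            _cfg(focal_sites=(FocalSite(100, 0.4, 51),))

    def test_json_round_trip(self):
        cfg = _cfg()
        assert SimConfig.from_json(cfg.to_json()) == cfg


class TestAllelePool:
    def test_deterministic_for_fixed_seed(self):
        p1 = simulate_allele_pool(_cfg())
        p2 = simulate_allele_pool(_cfg())
        assert np.array_equal(p1.haplotypes, p2.haplotypes)
        assert [str(n) for n in p1.names] == [str(n) for n in p2.names]
        assert p1.locus.reference_ars_seq == p2.locus.reference_ars_seq

    def test_linked_flank_variants_ride_with_alt(self):
        pool = simulate_allele_pool(_cfg())
        for f in pool.focal:
            alt_code = pool.alt_code[f.site]
            carriers = pool.haplotypes[:, f.site - 1] == alt_code
            for p in pool.flank_positions[f.site]:
                flank_alt = pool.haplotypes[:, p - 1] == pool.alt_code[p]
                # twins may flip background sites but never linked flanks
                assert np.array_equal(carriers, flank_alt)

    def test_exact_differential_without_background(self):
        """With no background polymorphism, ALT-carrying alleles carry exactly
        delta more flanking mismatches than REF alleles."""
        cfg = _cfg(snp_density=0.0, twin_fraction=0.0,
                   focal_sites=(FocalSite(250, 0.5, 3),))
        pool = simulate_allele_pool(cfg)
        m = window_mismatch_matrix(pool, np.array([250]), include_central=False)[:, 0]
        is_alt = pool.haplotypes[:, 249] == pool.alt_code[250]
        assert set(m[is_alt]) == {3}
        assert set(m[~is_alt]) == {0}

    def test_twins_differ_at_exactly_one_site(self):
        pool = simulate_allele_pool(_cfg(twin_fraction=0.5))
        seen = set()
        for a, b in pool.twin_of.items():
            if (b, a) in seen:
                continue
            seen.add((a, b))
            assert (pool.haplotypes[a] != pool.haplotypes[b]).sum() == 1

    def test_catalog_matches_haplotypes(self):
        pool = simulate_allele_pool(_cfg())
        for i in (0, 5, len(pool.names) - 1):
            (seq,) = pool.catalog.sequences(pool.names[i])
            assert seq == pool.sequence(i)


class TestPopulation:
    def test_no_ambiguity_or_missingness_when_disabled(self):
        pool = simulate_allele_pool(_cfg())
        gold, truth = simulate_population(
            pool, _cfg(ambiguity_rate=0.0, missing_rate=0.0)
        )
        assert len(gold) == 60
        assert not gold["allele1"].str.contains("/").any()
        assert not truth.missing.any()

    def test_missing_rows_dropped(self):
        pool = simulate_allele_pool(_cfg())
        gold, truth = simulate_population(pool, _cfg(missing_rate=0.3))
        assert len(gold) == (~truth.missing).sum()
        assert len(gold) <= 60

    def test_ambiguous_calls_list_twin_partners(self):
        cfg = _cfg(ambiguity_rate=1.0, twin_fraction=0.9)
        pool = simulate_allele_pool(cfg)
        gold, truth = simulate_population(pool, cfg)
        amb = gold["allele1"].str.contains("/")
        assert amb.any()
        # twins share the 2-field prefix and differ at exactly one CDS site
        from refbias.alleles import parse_allele_name

        for call in gold.loc[amb, "allele1"]:
            a, b = call.split("/")
            assert a.rsplit(":", 1)[0] == b.rsplit(":", 1)[0]
            (sa,) = pool.catalog.sequences(parse_allele_name(a))
            (sb,) = pool.catalog.sequences(parse_allele_name(b))
            assert sum(x != y for x, y in zip(sa, sb)) == 1

    def test_empirical_frequencies_converge_to_dirichlet_draw(self):
        cfg = _cfg(
            n_alleles=16,
            n_populations=1,
            n_individuals=5000,
            twin_fraction=0.0,
            ambiguity_rate=0.0,
            missing_rate=0.0,
        )
        pool = simulate_allele_pool(cfg)
        gold, truth = simulate_population(pool, cfg)
        freqs = truth.population_frequencies[0]
        counts = np.bincount(truth.allele_idx.ravel(), minlength=16)
        n = counts.sum()
        for k in range(16):
            se = np.sqrt(freqs[k] * (1 - freqs[k]) / n)
            assert abs(counts[k] / n - freqs[k]) <= 3 * se + 1e-9


class TestNgsModel:
    def test_noise_free_high_depth_recovers_truth(self):
        cfg = _cfg(mapping_loss=0.0, base_error=0.0, mean_depth=60.0,
                   ambiguity_rate=0.0, missing_rate=0.0)
        pool = simulate_allele_pool(cfg)
        _, truth = simulate_population(pool, cfg)
        ngs = simulate_ngs_calls(pool, truth, cfg)
        assert np.array_equal(ngs.genotypes, truth.genotype_codes(pool, ngs.sites))

    def test_total_loss_calls_everything_reference(self):
        """lambda=1 with delta>=1: every ALT read carries a mismatch and is
        dropped, so focal sites are called homozygous REF throughout (the
        deterministic limit, so base-call errors are off)."""
        cfg = _cfg(mapping_loss=1.0, base_error=0.0)
        pool = simulate_allele_pool(cfg)
        _, truth = simulate_population(pool, cfg)
        ngs = simulate_ngs_calls(pool, truth, cfg)
        for f in pool.focal:
            assert ngs.ref_frequency(f.site) == 1.0
            f_gold = truth.true_ref_frequency(pool, f.site)
            assert 1.0 - f_gold > 0  # FE = 1 - f_gold

    def test_zero_read_policy_missing(self):
        cfg = _cfg(mean_depth=0.5, zero_read_policy="missing")
        pool = simulate_allele_pool(cfg)
        _, truth = simulate_population(pool, cfg)
        ngs = simulate_ngs_calls(pool, truth, cfg)
        assert (ngs.genotypes == -1).any()
        assert np.array_equal(ngs.genotypes == -1, ngs.depth == 0)

    def test_depth_is_poisson_scale(self):
        cfg = _cfg(mapping_loss=0.0, mean_depth=8.0)
        pool = simulate_allele_pool(cfg)
        _, truth = simulate_population(pool, cfg)
        ngs = simulate_ngs_calls(pool, truth, cfg)
        assert abs(ngs.depth.mean() - 8.0) < 0.5

    def test_fe_nondecreasing_in_mapping_loss(self):
        """Monte-Carlo monotonicity of focal-site FE in lambda (common seeds)."""
        means = []
        for lam in (0.0, 0.3, 1.0):
            vals = []
            for rep in range(20):
                cfg = _cfg(seed=400 + rep, mapping_loss=lam)
                b = simulate_bundle(cfg)
                vals.append(b.focal_fe()["fe"].mean())
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]


class TestDeterminism:
    def test_bundle_is_bit_identical_across_runs(self):
        b1 = simulate_bundle(_cfg())
        b2 = simulate_bundle(_cfg())
        assert np.array_equal(b1.ngs.genotypes, b2.ngs.genotypes)
        assert np.array_equal(b1.ngs.depth, b2.ngs.depth)
        assert b1.gold.equals(b2.gold)
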