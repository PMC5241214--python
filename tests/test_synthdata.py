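"""Synthetic cohort generator: determinism, HWE, masking, self-consistency."""

import json

import numpy as np
import pytest

from majoref import (
    BASE_FRAME,
    MAJOR_FRAME,
    MajorefError,
    SimConfig,
    build_fixture,
    comparison_report,
    filter_calls,
    idealized_caller,
    make_fixture,
    select_swap_sites,
    simulate_individuals,
    simulate_population_sites,
    simulate_reference,
)
from majoref.synthdata import expected_report_from_genotypes, uncallable_mask
from majoref import vcfio


CFG = SimConfig(n_chroms=2, chrom_length=3000, n_sites=100, n_individuals=4, seed=5)


class TestSimulateReference:
    def test_deterministic_and_shaped(self):
        g1 = simulate_reference(CFG)
        g2 = simulate_reference(CFG)
        assert g1 == g2
        assert g1.names == ("chr1", "chr2")
        assert g1.lengths() == {"chr1": 3000, "chr2": 3000}

    def test_different_seed_differs(self):
        other = SimConfig(n_chroms=2, chrom_length=3000, n_sites=100, n_individuals=4, seed=6)
        assert simulate_reference(other) != simulate_reference(CFG)

    def test_base_composition_near_uniform(self):
        from scipy.stats import binom

        cfg = SimConfig(n_chroms=1, chrom_length=100_000, n_sites=1, seed=3)
        seq = simulate_reference(cfg)["chr1"]
        lo, hi = binom.ppf([0.0005, 0.9995], 100_000, 0.25)
        for base in "ACGT":
            assert lo <= seq.count(base) <= hi


class TestSimulatePopulationSites:
    def test_ref_matches_genome(self):
        genome = simulate_reference(CFG)
        for s in simulate_population_sites(genome, CFG):
            assert s.ref_allele == genome.base_at(s.chrom, s.pos).upper()
            assert s.alt_alleles[0] != s.ref_allele

    def test_positions_distinct(self):
        genome = simulate_reference(CFG)
        sites = simulate_population_sites(genome, CFG)
        keys = [(s.chrom, s.pos) for s in sites]
        assert len(set(keys)) == len(keys) == CFG.n_sites

    def test_fixed_alternating_afs_force_swap_half(self):
        cfg = SimConfig(n_chroms=1, chrom_length=2000, n_sites=50, seed=9,
                        af_distribution=("fixed", (0.7, 0.3)))
        genome = simulate_reference(cfg)
        sites = simulate_population_sites(genome, cfg)
        table = select_swap_sites(sites)
        assert len(table) == 25
        assert all(s.major_af == 0.7 for s in table)

    def test_symmetric_beta_gives_half_swaps(self):
        cfg = SimConfig(n_chroms=2, chrom_length=20_000, n_sites=4000, seed=17,
                        af_distribution=("beta", 0.5, 0.5))
        genome = simulate_reference(cfg)
        table = select_swap_sites(simulate_population_sites(genome, cfg))
        # Beta(0.5, 0.5) is symmetric about 0.5: binomial(4000, 0.5) 4-sigma band
        assert abs(len(table) - 2000) < 4 * np.sqrt(4000 * 0.25)

    def test_too_many_sites_rejected(self):
        with pytest.raises(MajorefError):
            SimConfig(n_chroms=1, chrom_length=10, n_sites=11)


class TestSimulateIndividuals:
    def test_extreme_afs(self):
        cfg = SimConfig(n_chroms=1, chrom_length=100, n_sites=2, n_individuals=10,
                        seed=2, af_distribution=("fixed", (1.0, 0.0)))
        genome = simulate_reference(cfg)
        sites = simulate_population_sites(genome, cfg)
        afs = [s.alt_afs[0] for s in sites]
        for ind in simulate_individuals(sites, cfg):
            for af, g in zip(afs, ind.genotypes):
                assert g == (2 if af == 1.0 else 0)

    def test_deterministic_per_individual(self):
        genome = simulate_reference(CFG)
        sites = simulate_population_sites(genome, CFG)
        a = simulate_individuals(sites, CFG)
        b = simulate_individuals(sites, CFG)
        for x, y in zip(a, b):
            assert x.sample_id == y.sample_id
            assert np.array_equal(x.genotypes, y.genotypes)


class TestIdealizedCaller:
    def test_masking_identity_exhaustive(self, small_fixture):
        """At a callable swap site: base-frame record iff dosage > 0,
        major-frame record iff dosage < 2 — checked for every individual
        and site."""
        fx = small_fixture
        swap_keys = fx.table.positions()
        for ind in fx.individuals:
            base = idealized_caller(ind, fx.sites, BASE_FRAME, fx.table, fx.cfg)
            major = idealized_caller(ind, fx.sites, MAJOR_FRAME, fx.table, fx.cfg)
            masked = uncallable_mask(fx.cfg, len(fx.sites), ind.index)
            for site_rec, g, uncallable in zip(fx.sites, ind.genotypes, masked):
                key = (site_rec.chrom, site_rec.pos)
                if uncallable:
                    assert key not in base.positions() and key not in major.positions()
                    continue
                assert (key in base.positions()) == (g > 0)
                if key in swap_keys:
                    assert (key in major.positions()) == (g < 2)
                else:
                    assert (key in major.positions()) == (g > 0)

    def test_het_in_both_frames_hom_split(self, small_fixture):
        fx = small_fixture
        ind = fx.individuals[0]
        base = idealized_caller(ind, fx.sites, BASE_FRAME, fx.table, fx.cfg)
        major = idealized_caller(ind, fx.sites, MAJOR_FRAME, fx.table, fx.cfg)
        for site_rec, g in zip(fx.sites, ind.genotypes):
            if (site_rec.chrom, site_rec.pos) in fx.table.positions() and g == 1:
                b = base.get(site_rec.chrom, site_rec.pos)
                m = major.get(site_rec.chrom, site_rec.pos)
                assert b is not None and m is not None
                assert sorted(b.genotype) == [0, 1] and sorted(m.genotype) == [0, 1]

    def test_frame_table_inconsistency_raises(self, small_fixture):
        from majoref import SwapSite, SwapTable

        fx = small_fixture
        first_swap = next(iter(fx.table))
        wrong_major = next(b for b in "ACGT" if b not in
                           (first_swap.base_allele, first_swap.major_allele))
        bad = SwapTable([SwapSite(first_swap.chrom, first_swap.pos,
                                  first_swap.base_allele, wrong_major, 0.9)])
        with pytest.raises(MajorefError, match="disagree"):
            idealized_caller(fx.individuals[0], fx.sites, MAJOR_FRAME, bad, fx.cfg)

    def test_noise_hook_changes_calls_deterministically(self):
        cfg = SimConfig(n_chroms=1, chrom_length=3000, n_sites=200, n_individuals=1,
                        seed=5, genotype_flip_prob=0.3)
        fx = build_fixture(cfg)
        a = idealized_caller(fx.individuals[0], fx.sites, BASE_FRAME, fx.table, cfg)
        b = idealized_caller(fx.individuals[0], fx.sites, BASE_FRAME, fx.table, cfg)
        assert a.positions() == b.positions()
        quiet = SimConfig(**{**cfg.to_dict(), "genotype_flip_prob": 0.0,
                             "af_distribution": cfg.af_distribution})
        c = idealized_caller(fx.individuals[0], fx.sites, BASE_FRAME, fx.table, quiet)
        assert a.positions() != c.positions()


class TestMakeFixture:
    def test_byte_identical_reruns(self, tmp_path):
        cfg = SimConfig(n_chroms=1, chrom_length=2000, n_sites=40, n_individuals=2, seed=8)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_fixture(cfg, d1)
        make_fixture(cfg, d2)
        for p1 in sorted(d1.iterdir()):
            p2 = d2 / p1.name
            b1, b2 = p1.read_bytes(), p2.read_bytes()
            if p1.name == "manifest.json":
                m1, m2 = json.loads(b1), json.loads(b2)
                m1.pop("calls"), m2.pop("calls")  # absolute paths differ
                assert m1 == m2
            else:
                assert b1 == b2, p1.name

    def test_end_to_end_self_consistency(self, tmp_path):
        """Rebuilding from the fixture's own files reproduces the swap
        table and the manifest's per-individual accounting."""
        cfg = SimConfig(n_chroms=2, chrom_length=2000, n_sites=80, n_individuals=3,
                        seed=13, uncallable_fraction=0.05)
        fx = make_fixture(cfg, tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())

        genome = vcfio.read_genome_fasta(tmp_path / "base.fa")
        sites = list(vcfio.read_population_sites(tmp_path / "population.vcf"))
        from majoref import apply_swaps

        table = select_swap_sites(sites, cfg.af_threshold, chrom_order=genome.names)
        assert table == fx.table
        assert apply_swaps(genome, table) == fx.major_genome

        for ind in fx.individuals:
            base = filter_calls(vcfio.read_callset_vcf(tmp_path / f"{ind.sample_id}.base.vcf"))
            major = filter_calls(vcfio.read_callset_vcf(tmp_path / f"{ind.sample_id}.major.vcf"))
            report = comparison_report(base, major, table)
            assert report.to_dict() == manifest["expected_reports"][ind.sample_id]

    def test_expected_report_matches_pipeline(self, small_fixture):
        fx = small_fixture
        for ind in fx.individuals:
            pipeline = comparison_report(
                idealized_caller(ind, fx.sites, BASE_FRAME, fx.table, fx.cfg),
                idealized_caller(ind, fx.sites, MAJOR_FRAME, fx.table, fx.cfg),
                fx.table,
            )
            direct = expected_report_from_genotypes(ind, fx.sites, fx.table, fx.cfg)
            assert pipeline.to_dict() == direct.to_dict()
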