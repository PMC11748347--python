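import numpy as np
import pytest

from panelprio.panels import Mode
from panelprio.prioritize import FilterConfig
from panelprio.synthetic import (
    CnvSpike,
    PseudocontrolSpec,
    SimConfig,
    SyntheticGenome,
    VariantSpike,
    default_pseudocontrol_specs,
    make_panel_library,
    run_pseudocontrol_validation,
    simulate_coverage_matrix,
    simulate_pedigree,
    simulate_variant_table,
)
from panelprio.types import ClinClass, Sex, Zygosity


class TestVariantTable:
    def test_no_spikes_empty_manifest(self, genome):
        _, manifest = simulate_variant_table(SimConfig(seed=1), genome)
        assert len(manifest) == 0

    def test_spiked_variant_present_in_table_and_manifest(self, genome):
        cfg = SimConfig(
            seed=2,
            spikes=[VariantSpike(gene="GENE0001", mode=Mode.AR, pattern="HOM")],
        )
        variants, manifest = simulate_variant_table(cfg, genome)
        assert len(manifest) == 1
        row = manifest.iloc[0]
        key = (row["chrom"], row["pos"], row["ref"], row["alt"])
        matches = [v for v in variants if v.key == key]
        assert len(matches) == 1
        assert matches[0].zygosity is Zygosity.HOM

    def test_same_seed_identical_tables(self, genome):
        cfg = SimConfig(seed=3)
        a, _ = simulate_variant_table(cfg, genome)
        b, _ = simulate_variant_table(cfg, genome)
        assert a == b

    def test_different_seeds_differ(self, genome):
        a, _ = simulate_variant_table(SimConfig(seed=4), genome)
        b, _ = simulate_variant_table(SimConfig(seed=5), genome)
        assert a != b

    def test_unknown_spike_gene_rejected(self, genome):
        cfg = SimConfig(
            seed=1, spikes=[VariantSpike(gene="NOPE", mode=Mode.AR, pattern="HOM")]
        )
        with pytest.raises(ValueError, match="NOPE"):
            simulate_variant_table(cfg, genome)

    def test_comphet_spike_yields_two_hets(self, genome):
        cfg = SimConfig(
            seed=6,
            spikes=[VariantSpike(gene="GENE0002", mode=Mode.AR, pattern="COMPHET")],
        )
        variants, manifest = simulate_variant_table(cfg, genome)
        assert len(manifest) == 2
        keys = {
            (r.chrom, r.pos, r.ref, r.alt) for r in manifest.itertuples()
        }
        spiked = [v for v in variants if v.key in keys]
        assert all(v.zygosity is Zygosity.HET for v in spiked)


class TestPedigree:
    def spiked(self, genome, pattern, cis=False):
        cfg = SimConfig(
            seed=7,
            spikes=[VariantSpike(gene="GENE0003", mode=Mode.AR, pattern=pattern)],
        )
        variants, manifest = simulate_variant_table(cfg, genome)
        keys = {(r.chrom, r.pos, r.ref, r.alt) for r in manifest.itertuples()}
        spiked = [v for v in variants if v.key in keys]
        return simulate_pedigree("P1", spiked, manifest, cis=cis), spiked

    def test_trans_comphet_one_allele_per_parent(self, genome):
        ped, spiked = self.spiked(genome, "COMPHET")
        k1, k2 = (v.key for v in spiked)
        f, m = "P1_F", "P1_M"
        carried_f = {k for k in (k1, k2) if ped.genotype(f, k)}
        carried_m = {k for k in (k1, k2) if ped.genotype(m, k)}
        assert len(carried_f) == 1 and len(carried_m) == 1
        assert carried_f != carried_m

    def test_cis_option_one_parent_carries_both(self, genome):
        ped, spiked = self.spiked(genome, "COMPHET", cis=True)
        f = "P1_F"
        assert all(ped.genotype(f, v.key) for v in spiked)
        assert not any(ped.genotype("P1_M", v.key) for v in spiked)

    def test_singleton(self, genome):
        import pandas as pd

        ped = simulate_pedigree(
            "P1", [], pd.DataFrame(columns=["spike_index"]), structure="SINGLETON"
        )
        assert len(ped.members) == 1
        assert ped.parents_of("P1") == (None, None)

    def test_mendelian_consistency_over_many_seeds(self, genome):
        # every proband allele must be explainable by a carrying parent
        # (dominant spikes are constructed de novo and skipped)
        for seed in range(40):
            cfg = SimConfig(
                seed=seed,
                spikes=[
                    VariantSpike(gene="GENE0004", mode=Mode.AR, pattern="HOM"),
                    VariantSpike(gene="GENE0005", mode=Mode.AR, pattern="COMPHET"),
                ],
            )
            variants, manifest = simulate_variant_table(cfg, genome)
            keys = {(r.chrom, r.pos, r.ref, r.alt) for r in manifest.itertuples()}
            spiked = [v for v in variants if v.key in keys]
            ped = simulate_pedigree("P1", spiked, manifest)
            for v in spiked:
                f = ped.genotype("P1_F", v.key)
                m = ped.genotype("P1_M", v.key)
                if v.zygosity is Zygosity.HOM:
                    assert f is not None and m is not None
                elif v.zygosity is Zygosity.HET:
                    assert f is not None or m is not None


class TestCoverageMatrix:
    def test_noise_free_is_rank_one(self):
        cfg = SimConfig(seed=8, depth_noise=0.0)
        m, _ = simulate_coverage_matrix(cfg, 20, 6)
        # outer product of baselines and size factors => all 2x2 minors vanish
        d = m.depth
        ratio = d / d[:, [0]]
        np.testing.assert_allclose(ratio, np.tile(ratio[0], (20, 1)), rtol=1e-12)

    def test_spike_halves_exact_entries(self):
        cfg = SimConfig(seed=9, depth_noise=0.0)
        base, _ = simulate_coverage_matrix(cfg, 20, 6)
        spiked, manifest = simulate_coverage_matrix(
            cfg, 20, 6, [CnvSpike("S002", "", [3, 4], 0.5)]
        )
        expected = base.depth.copy()
        expected[[3, 4], 1] *= 0.5
        np.testing.assert_allclose(spiked.depth, expected)
        assert manifest.iloc[0]["dose"] == 0.5

    def test_same_seed_identical(self):
        cfg = SimConfig(seed=10)
        a, _ = simulate_coverage_matrix(cfg)
        b, _ = simulate_coverage_matrix(cfg)
        np.testing.assert_array_equal(a.depth, b.depth)

    def test_small_batch_rejected(self):
        with pytest.raises(ValueError):
            simulate_coverage_matrix(SimConfig(seed=1), 10, 3)


class TestPseudocontrols:
    def test_default_design_full_recovery(self, genome, library):
        base = SimConfig(seed=11)
        specs = default_pseudocontrol_specs(base, library, genome, 10)
        report = run_pseudocontrol_validation(specs, library, base, genome=genome)
        assert report.total_spiked >= 10
        assert report.recovered == report.total_spiked
        assert report.misses == []

    def test_off_panel_spike_missed_with_panel_reason(self, genome, library):
        on_panel = library["SP1"].genes
        off = next(g for g in genome.gene_names if g.upper() not in on_panel)
        spec = PseudocontrolSpec(
            "PC1",
            [VariantSpike(gene=off, mode=Mode.AR, pattern="HOM")],
            panels=["SP1"],
        )
        report = run_pseudocontrol_validation(
            [spec], library, SimConfig(seed=12), genome=genome
        )
        assert report.recovered == 0
        assert report.misses[0].reason == "panel"

    def test_common_spike_missed_with_frequency_reason(self, genome, library):
        gene = next(e.gene for e in library["SP1"].entries if e.modes == {Mode.AR})
        spec = PseudocontrolSpec(
            "PC1",
            [VariantSpike(gene=gene, mode=Mode.AR, pattern="HOM", maf=0.2)],
            panels=["SP1"],
        )
        report = run_pseudocontrol_validation(
            [spec], library, SimConfig(seed=13), genome=genome
        )
        assert report.misses[0].reason == "frequency"

    def test_benign_spike_missed_with_classification_reason(self, genome, library):
        gene = next(e.gene for e in library["SP1"].entries if e.modes == {Mode.AR})
        spec = PseudocontrolSpec(
            "PC1",
            [
                VariantSpike(
                    gene=gene, mode=Mode.AR, pattern="HOM", clin_class=ClinClass.B
                )
            ],
            panels=["SP1"],
        )
        report = run_pseudocontrol_validation(
            [spec], library, SimConfig(seed=14), genome=genome
        )
        assert report.misses[0].reason == "classification"

    def test_incompatible_zygosity_missed_with_zygosity_reason(self, genome, library):
        gene = next(e.gene for e in library["SP1"].entries if e.modes == {Mode.AR})
        spec = PseudocontrolSpec(
            "PC1",
            [
                VariantSpike(
                    gene=gene, mode=Mode.AR, pattern="HET",
                    clin_class=ClinClass.VUS,
                )
            ],
            panels=["SP1"],
        )
        report = run_pseudocontrol_validation(
            [spec], library, SimConfig(seed=15), genome=genome
        )
        assert report.misses[0].reason == "zygosity"


class TestGenome:
    def test_layout_independent_of_config_seed(self):
        a = SyntheticGenome(100)
        b = SyntheticGenome(100)
        assert a.genes.keys() == b.genes.keys()
        assert a.genes["GENE0050"] == b.genes["GENE0050"]

    def test_x_genes_exist(self, genome):
        assert genome.x_genes()
        assert all(genome.genes[g].chrom == "X" for g in genome.x_genes())
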