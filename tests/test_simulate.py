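"""Synthetic-cohort generator: determinism, validity, and the statistical
properties the downstream stages rely on."""

import collections

import numpy as np
import pytest

from famlof.burden import build_2x2
from famlof.cohort import mendelian_check
from famlof.simulate import (
    SimulationConfig,
    burden_preset,
    discovery_preset,
    make_splice_donor_variant,
    read_fixture_bundle,
    simulate_case_control,
    simulate_families,
    simulate_reference,
    write_fixture_bundle,
)


def small_config(seed=3, **kw):
    defaults = dict(seed=seed, n_genes=6, n_families=6, genes_per_contig=3)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateReference:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for d in ("a", "b"):
            cfg = small_config()
            genome, ts = simulate_reference(cfg)
            write_fixture_bundle(tmp_path / d, cfg, genome, ts, [], [], [])
        for name in ("reference.fa", "genes.gff3"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_single_exon_gene_never_nmd(self):
        from famlof.consequence import predict_nmd

        cfg = SimulationConfig(seed=5, n_genes=1, exons_per_gene=(1, 1))
        genome, (t,) = simulate_reference(cfg)
        assert all(not predict_nmd(t, c) for c in range(1, t.cds_length // 3))

    def test_all_transcripts_valid_across_seeds(self):
        """Spliced CDS starts ATG, ends with a stop, length = 0 mod 3."""
        for seed in range(20):
            cfg = small_config(seed=seed)
            genome, ts = simulate_reference(cfg)
            for t in ts:
                assert t.validate(genome) == [], (seed, t.transcript_id)

    def test_both_strands_represented(self, reference_sim):
        _, _, ts = reference_sim
        assert {t.strand for t in ts} == {"+", "-"}


class TestSimulateFamilies:
    def _sim(self, **kw):
        cfg = small_config(**kw)
        genome, ts = simulate_reference(cfg)
        var = make_splice_donor_variant(ts[0], genome)
        return cfg, simulate_families(cfg, genome, ts, ts[0].gene_id, var)

    def test_full_penetrance_extremes(self):
        cfg, fam = self._sim(
            penetrance_carrier=1.0,
            penetrance_background=0.0,
            plant_discordant=False,
        )
        carriers = fam.allele_counts[fam.spiked_variant.key]
        for ind in fam.individuals:
            is_carrier = carriers.get(ind.individual_id, 0) > 0
            affected = ind.phenotype in ("MM", "MGUS")
            assert affected == is_carrier, ind

    def test_carrier_penetrance_matches_binomial(self):
        """Across many simulated carriers, the affected fraction lies
        within 3 binomial SDs of the configured penetrance."""
        f1 = 0.4
        affected = total = 0
        seed = 0
        while total < 1000:
            cfg, fam = self._sim(
                seed=seed, n_families=20, n_spiked_families=20,
                penetrance_carrier=f1, plant_discordant=False,
                ascertain_affected_carrier=False,
            )
            carriers = fam.allele_counts[fam.spiked_variant.key]
            by_id = {i.individual_id: i for i in fam.individuals}
            for iid, ac in carriers.items():
                if ac > 0:
                    total += 1
                    affected += by_id[iid].phenotype in ("MM", "MGUS")
            seed += 1
        frac = affected / total
        sd = np.sqrt(f1 * (1 - f1) / total)
        assert abs(frac - f1) <= 3 * sd

    def test_transmission_is_mendelian_for_all_trios(self):
        cfg, fam = self._sim(seed=11, background_lof_rate=1.0)
        by_id = {i.individual_id: i for i in fam.individuals}
        for counts in fam.allele_counts.values():
            for iid, ac in counts.items():
                ind = by_id[iid]
                f = counts.get(ind.father_id) if ind.father_id else None
                m = counts.get(ind.mother_id) if ind.mother_id else None
                assert mendelian_check(ac, f, m) == 0

    def test_het_vaf_close_to_half(self):
        cfg, fam = self._sim(seed=2)
        vafs = [
            c.vaf for c in fam.genotypes if c.allele_count == 1 and c.depth > 0
        ]
        assert vafs, "expected heterozygous simulated calls"
        assert abs(float(np.mean(vafs)) - 0.5) < 0.05

    def test_genotyped_subset_size(self):
        cfg = discovery_preset(4)
        genome, ts = simulate_reference(cfg)
        var = make_splice_donor_variant(ts[0], genome)
        fam = simulate_families(cfg, genome, ts, ts[0].gene_id, var)
        assert len(fam.genotyped_ids) == 66
        assert len({i.family_id for i in fam.individuals}) == 23


class TestSimulateCaseControl:
    def test_zero_frequency_means_no_carriers(self):
        cfg = SimulationConfig(
            seed=1, carrier_freq_cases=0.0, carrier_freq_controls=0.0
        )
        sim = simulate_case_control(cfg, ["k"])
        assert sim.genotypes == []

    def test_bernoulli_fraction_within_three_sd(self):
        cfg = SimulationConfig(
            seed=9, n_cases=10_000, n_controls=1,
            carrier_freq_cases=0.5, carrier_freq_controls=0.0,
        )
        sim = simulate_case_control(cfg, ["k"])
        carriers = {c.individual_id for c in sim.genotypes}
        frac = len([i for i in carriers if i.startswith("case")]) / 10_000
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 10_000)

    def test_exact_counts_mode_forces_published_table(self):
        cfg = burden_preset(7)
        sim = simulate_case_control(cfg, ["k1", "k2"], exact_counts=True)
        table, dropped = build_2x2(sim.genotypes, sim.phenotypes, sim.qualifying)
        assert table.cells() == (30, 751, 72, 3462)
        assert dropped == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            simulate_case_control(SimulationConfig(seed=1), [])


class TestFixtureBundle:
    def test_round_trip(self, tmp_path):
        cfg = small_config(seed=8)
        genome, ts = simulate_reference(cfg)
        var = make_splice_donor_variant(ts[0], genome)
        fam = simulate_families(cfg, genome, ts, ts[0].gene_id, var)
        scores = {fam.variants[0].key: 25.0}
        write_fixture_bundle(
            tmp_path, cfg, genome, ts, fam.individuals, fam.variants,
            fam.genotypes, scores=scores, sample_order=fam.genotyped_ids,
        )
        back = read_fixture_bundle(tmp_path)
        assert back.genome.contigs == genome.contigs
        assert sorted(t.transcript_id for t in back.transcripts) == sorted(
            t.transcript_id for t in ts
        )
        for t_in, t_out in zip(
            sorted(ts, key=lambda t: t.transcript_id),
            sorted(back.transcripts, key=lambda t: t.transcript_id),
        ):
            assert t_in.exons == t_out.exons
            assert (t_in.cds_start_g, t_in.cds_end_g) == (
                t_out.cds_start_g,
                t_out.cds_end_g,
            )
        assert back.individuals == fam.individuals
        assert {v.key for v in back.variants} == {v.key for v in fam.variants}
        back_calls = {
            (c.individual_id, c.variant_key): (c.allele_count, c.ref_depth, c.alt_depth)
            for c in back.calls
        }
        for c in fam.genotypes:
            assert back_calls[(c.individual_id, c.variant_key)] == (
                c.allele_count,
                c.ref_depth,
                c.alt_depth,
            )
        assert back.scores == scores
        assert back.manifest["seed"] == cfg.seed

    def test_vcf_reparses_with_strict_parser(self, tmp_path):
        from cyvcf2 import VCF

        cfg = small_config(seed=8)
        genome, ts = simulate_reference(cfg)
        var = make_splice_donor_variant(ts[0], genome)
        fam = simulate_families(cfg, genome, ts, ts[0].gene_id, var)
        paths = write_fixture_bundle(
            tmp_path, cfg, genome, ts, fam.individuals, fam.variants,
            fam.genotypes, sample_order=fam.genotyped_ids,
        )
        vcf = VCF(paths["vcf"])
        assert vcf.raw_header.startswith("##fileformat=VCFv4.2")
        n = sum(1 for _ in vcf)
        assert n == len(fam.variants)

    def test_manifest_seed_reuse_regenerates_identical_bundle(self, tmp_path):
        import json

        cfg = small_config(seed=12)
        genome, ts = simulate_reference(cfg)
        write_fixture_bundle(tmp_path / "x", cfg, genome, ts, [], [], [])
        manifest = json.loads((tmp_path / "x" / "manifest.json").read_text())
        cfg2 = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in manifest["config"].items()
        })
        genome2, ts2 = simulate_reference(cfg2)
        write_fixture_bundle(tmp_path / "y", cfg2, genome2, ts2, [], [], [])
        assert (tmp_path / "x" / "reference.fa").read_bytes() == (
            tmp_path / "y" / "reference.fa"
        ).read_bytes()


class TestSeedDiscipline:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, penetrance_carrier=1.5)

    def test_penetrance_ordering_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                seed=1, penetrance_carrier=0.01, penetrance_background=0.5
            )

    def test_missing_seed_rejected(self):
        with pytest.raises((TypeError, ValueError)):
            SimulationConfig(seed=None)
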