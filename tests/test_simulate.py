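"""Generator contracts: determinism, truth consistency, planted structure."""

import numpy as np
import pytest
from scipy import stats as sps

from m6adyn.models import revcomp
from m6adyn.motifs import is_rrach
from m6adyn.simulate import (
    SimConfig,
    generate_genome,
    plant_m6a_sites,
    simulate_coverage,
    simulate_study,
)


class TestConfigValidation:
    def test_cds_not_divisible_by_three_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SimConfig(utr5_cds_utr3_lengths=(200, 1001, 800)).validate()

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SimConfig(utr5_cds_utr3_lengths=(0, 999, 800)).validate()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"enrichment_factor": 0.5},
            {"tissue_names": ("brain", "brain")},
            {"tissue_names": ()},
            {"tissue_specific_fraction": 1.5},
            {"conservation_prob_m6a": -0.1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs).validate()


class TestGenome:
    def test_transcript_lengths_match_config(self):
        cfg = SimConfig(seed=1, n_genes=10, utr5_cds_utr3_lengths=(200, 999, 800))
        genome, genes = generate_genome(cfg)
        assert len(genes) == 10
        assert all(g.tx_length == 1999 for g in genes)

    def test_determinism_identical_seed(self):
        cfg = SimConfig(seed=7, n_genes=5)
        g1, _ = generate_genome(cfg)
        g2, _ = generate_genome(cfg)
        assert g1 == g2

    def test_different_seed_differs(self):
        g1, _ = generate_genome(SimConfig(seed=7, n_genes=3))
        g2, _ = generate_genome(SimConfig(seed=8, n_genes=3))
        assert g1 != g2

    def test_rrach_occur_inside_and_outside_planted_sites(self, small_study):
        planted = {(s.gene_id, s.tx_offset) for s in small_study.truth.planted_sites}
        from m6adyn.motifs import find_rrach

        background = 0
        for g in small_study.genes:
            tx = g.transcript_seq(small_study.genome[g.chrom])
            for a in find_rrach(tx):
                if (g.gene_id, a) not in planted:
                    background += 1
        assert background > 0 and len(planted) > 0


class TestPlanting:
    def test_truth_validates_against_reference(self, small_study):
        assert small_study.truth.validate(small_study.genome, small_study.genes_by_id)

    def test_planted_motifs_rrach_on_transcript_strand(self, small_study):
        for ps in small_study.truth.planted_sites:
            assert is_rrach(ps.motif)
            gene = small_study.genes_by_id[ps.gene_id]
            chrom_seq = small_study.genome[ps.chrom]
            genomic_mer = chrom_seq[ps.gpos - 2 : ps.gpos + 3]
            expected = ps.motif if gene.strand == "+" else revcomp(ps.motif)
            assert genomic_mer == expected

    def test_fully_tissue_specific_planting(self):
        cfg = SimConfig(seed=3, n_genes=15, tissue_specific_fraction=1.0)
        genome, genes = generate_genome(cfg)
        truth, _ = plant_m6a_sites(genes, genome, cfg)
        assert all(len(ps.tissues) == 1 for ps in truth.planted_sites)

    def test_fully_shared_planting(self):
        cfg = SimConfig(seed=3, n_genes=15, tissue_specific_fraction=0.0)
        genome, genes = generate_genome(cfg)
        truth, _ = plant_m6a_sites(genes, genome, cfg)
        assert all(ps.tissues == set(cfg.tissue_names) for ps in truth.planted_sites)

    def test_site_count_within_poisson_interval(self):
        # density 2/kb over ~20 kb of transcript: Poisson 99% interval oracle
        cfg = SimConfig(seed=9, n_genes=10, site_density=2.0,
                        cleavage_per_gene_prob=0.0, noncoding_fraction=0.0)
        genome, genes = generate_genome(cfg)
        truth, _ = plant_m6a_sites(genes, genome, cfg)
        lam = 2.0 * sum(g.tx_length for g in genes) / 1000.0
        lo, hi = sps.poisson.ppf([0.005, 0.995], lam)
        assert lo <= len(truth.planted_sites) <= hi


class TestCoverage:
    def test_null_enrichment_ip_matches_input(self):
        cfg = SimConfig(seed=5, n_genes=8, enrichment_factor=1.0)
        genome, genes = generate_genome(cfg)
        truth, genome = plant_m6a_sites(genes, genome, cfg)
        tracks, _ = simulate_coverage(genes, truth, cfg)
        tr = tracks[0]
        ip = np.concatenate(list(tr.ip.values()))
        inp = np.concatenate(list(tr.input_.values()))
        # same negative-binomial law: equal means within sampling noise
        assert np.isclose(ip.mean(), inp.mean(), rtol=0.02)
        assert sps.ks_2samp(ip[::7], inp[::7]).pvalue > 0.001

    def test_specific_site_enriched_only_in_its_tissue(self, small_study):
        """IP/input ratio at the site window is higher in the methylated
        tissue than in others, for the vast majority of specific sites."""
        by_tissue = {}
        for tr in small_study.tracks:
            by_tissue.setdefault(tr.tissue, []).append(tr)
        wins = 0
        total = 0
        for ps in small_study.truth.planted_sites:
            if len(ps.tissues) != 1:
                continue
            (tis,) = ps.tissues
            other = next(t for t in small_study.config.tissue_names if t != tis)
            lo, hi = ps.tx_offset - 50, ps.tx_offset + 50

            def ratio(tracks):
                r = [
                    t.ip[ps.gene_id][lo:hi].mean() / max(t.input_[ps.gene_id][lo:hi].mean(), 1)
                    for t in tracks
                ]
                return np.mean(r)

            total += 1
            wins += ratio(by_tissue[tis]) > ratio(by_tissue[other])
        assert total > 10
        assert wins / total > 0.95

    def test_library_sizes_are_track_totals(self, small_study):
        tr = small_study.tracks[0]
        assert tr.ip_library_size == sum(a.sum() for a in tr.ip.values())
        assert tr.input_library_size == sum(a.sum() for a in tr.input_.values())


class TestConservationTable:
    def test_conserved_fraction_gap_matches_binomial_expectation(self, small_study):
        """Planted probabilities (0.9, 0.6): the m6A-vs-control conserved
        fraction gap per species is about 0.3 (binomial oracle)."""
        t = small_study.conservation
        m6a = t[t["is_m6a"]]
        ctrl = t[~t["is_m6a"]]
        for sp in ("mouse", "chicken"):
            gap = (m6a[sp] == "A").mean() - (ctrl[sp] == "A").mean()
            se = np.sqrt(0.9 * 0.1 / len(m6a) + 0.6 * 0.4 / len(ctrl))
            assert abs(gap - 0.3) < 4 * se

    def test_dnds_shared_within_gene(self, small_study):
        per_gene = small_study.conservation.groupby("gene_id")["dnds"].nunique()
        assert (per_gene == 1).all()

    def test_truth_ids_resolve_to_conservation_records(self, small_study):
        emitted = set(small_study.conservation["site_id"])
        for ps in small_study.truth.planted_sites:
            assert ps.site_id in emitted


class TestGenotypes:
    def test_no_selection_when_fraction_zero(self):
        cfg = SimConfig(seed=13, n_genes=10, selected_fraction=0.0)
        study = simulate_study(cfg)
        assert study.truth.selected_snps == set()

    def test_identical_population_frequencies_give_near_zero_fst(self):
        from m6adyn.popgen import weir_cockerham_fst

        cfg = SimConfig(seed=13, n_genes=20, selected_fraction=0.0)
        study = simulate_study(cfg)
        vals = [
            weir_cockerham_fst(list(g.values()))
            for g in study.genotypes.values()
        ]
        vals = [v for v in vals if v is not None]
        assert len(vals) > 50
        assert abs(np.mean(vals)) < 0.02

    def test_gain_snp_reference_carries_the_motif(self, small_study):
        genome = small_study.genome
        for snp in small_study.snps:
            if snp.snp_id in small_study.truth.selected_snps:
                # derived (reference) allele is the motif allele
                assert snp.ref == genome[snp.chrom][snp.pos]
                assert snp.ancestral == snp.alt

    def test_some_records_lack_ancestral_allele(self, small_study):
        assert any(s.ancestral == "" for s in small_study.snps)


def test_study_level_determinism():
    cfg = SimConfig(seed=21, n_genes=6)
    s1, s2 = simulate_study(cfg), simulate_study(cfg)
    assert s1.genome == s2.genome
    assert s1.conservation.equals(s2.conservation)
    assert all(
        np.array_equal(a.ip[g], b.ip[g])
        for a, b in zip(s1.tracks, s2.tracks)
        for g in a.ip
    )
    assert [s.pop_counts for s in s1.snps] == [s.pop_counts for s in s2.snps]
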