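"""Winscore computation, enrichment filters, consensus peaks, site inference."""

import math
import statistics

import numpy as np
import pytest

from m6adyn import peaks as pk
from m6adyn.models import GeneModel, revcomp
from m6adyn.motifs import find_rrach


def flat_gene(length=300, gene_id="g", strand="+", chrom="chr1"):
    cds_start = length // 6
    cds = (length // 2) // 3 * 3
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     exons=[(0, length)], cds_start=cds_start, cds_end=cds_start + cds)


def winscore_oracle(ip, inp, start, end, pc):
    """Independent spreadsheet-style evaluation of the winscore formula."""
    mean_ip = sum(ip[start:end]) / (end - start)
    mean_in = sum(inp[start:end]) / (end - start)
    med_ip = statistics.median(ip)
    med_in = statistics.median(inp)
    return math.log2(((mean_ip + pc) / (med_ip + pc)) / ((mean_in + pc) / (med_in + pc)))


class TestWinscore:
    def test_fourfold_normalized_ratio_gives_two(self):
        gene = flat_gene(300)
        ip = np.array([8.0] * 100 + [2.0] * 200)  # window mean 8, median 2
        inp = np.full(300, 5.0)
        stats = pk.compute_window_stats(gene, ip, inp, 1e6, 1e6, pseudocount=0.0)
        assert stats[0].winscore == pytest.approx(2.0)

    def test_identical_tracks_give_zero_everywhere(self):
        gene = flat_gene(400)
        cov = np.abs(np.sin(np.arange(400))) * 20 + 1
        stats = pk.compute_window_stats(gene, cov, cov.copy(), 2e6, 2e6)
        assert all(w.winscore == pytest.approx(0.0) for w in stats)

    def test_three_window_toy_matches_hand_computed_table(self):
        """Default pseudocount path against an independent arithmetic oracle."""
        gene = flat_gene(200)
        rng = np.random.default_rng(0)
        ip = np.round(rng.gamma(5, 4, size=200))
        inp = np.round(rng.gamma(5, 4, size=200))
        stats = pk.compute_window_stats(gene, ip, inp, 1e6, 1e6)
        assert len(stats) == 3  # starts 0, 50, 100 -> windows at 0,50,100(end)
        for w in stats:
            expected = winscore_oracle(list(ip), list(inp), w.start, w.end, 1.0)
            assert w.winscore == pytest.approx(expected, abs=1e-12)

    def test_short_gene_yields_single_truncated_window(self):
        gene = flat_gene(60)
        stats = pk.compute_window_stats(gene, np.ones(60), np.ones(60), 1e6, 1e6)
        assert len(stats) == 1 and (stats[0].start, stats[0].end) == (0, 60)

    def test_all_zero_input_gene_skipped(self):
        gene = flat_gene(300)
        assert pk.compute_window_stats(gene, np.ones(300), np.zeros(300), 1e6, 1e6) == []

    def test_antisymmetry_under_ip_input_swap(self, rng):
        gene = flat_gene(500)
        ip = rng.poisson(30, 500).astype(float)
        inp = rng.poisson(30, 500).astype(float)
        fwd = pk.compute_window_stats(gene, ip, inp, 1e6, 2e6)
        rev = pk.compute_window_stats(gene, inp, ip, 2e6, 1e6)
        for a, b in zip(fwd, rev):
            assert a.winscore == pytest.approx(-b.winscore, abs=1e-12)

    def test_scale_invariance_of_gene_coverage(self, rng):
        gene = flat_gene(500)
        ip = rng.poisson(30, 500).astype(float)
        inp = rng.poisson(30, 500).astype(float)
        base = pk.compute_window_stats(gene, ip, inp, 1e6, 1e6, pseudocount=0.0)
        scaled = pk.compute_window_stats(gene, 7 * ip, 7 * inp, 1e6, 1e6, pseudocount=0.0)
        for a, b in zip(base, scaled):
            assert a.winscore == pytest.approx(b.winscore, abs=1e-9)

    def test_rpkm_definition(self):
        gene = flat_gene(300)
        ip = np.full(300, 10.0)
        stats = pk.compute_window_stats(gene, ip, np.full(300, 2.0), 1e7, 1e7)
        w = stats[0]
        assert w.ip_rpkm == pytest.approx(10.0 * 100 * 1e9 / (100 * 1e7))
        assert w.input_gene_rpkm == pytest.approx(2.0 * 300 * 1e9 / (300 * 1e7))


class TestEnrichedWindows:
    def _mk(self, ws, ip_rpkm=20.0, gene_rpkm=5.0):
        return pk.WindowStat("s", "g", 0, 100, ws, ip_rpkm, gene_rpkm)

    def test_threshold_is_strict_below(self):
        assert pk.call_enriched_windows([self._mk(1.99)]) == []

    def test_all_thresholds_inclusive(self):
        w = pk.WindowStat("s", "g", 0, 100, 2.0, 10.0, 1.0)
        assert pk.call_enriched_windows([w]) == [w]

    def test_matches_brute_force_filter(self, rng):
        stats = [
            pk.WindowStat("s", "g", i, i + 100, rng.normal(2, 1),
                          rng.uniform(0, 30), rng.uniform(0, 3))
            for i in range(200)
        ]
        got = pk.call_enriched_windows(stats)
        expected = [w for w in stats
                    if w.winscore >= 2 and w.ip_rpkm >= 10 and w.input_gene_rpkm >= 1]
        assert got == expected


def make_windows(sample, gene, spans, winscore=3.0):
    return [pk.WindowStat(sample, gene, s, e, winscore, 20.0, 5.0) for s, e in spans]


class TestConsensusPeaks:
    design = {"a1": "A", "a2": "A", "a3": "A"}

    def setup_method(self):
        self.gene = flat_gene(600, gene_id="g")
        self.genes = {"g": self.gene}

    def _call(self, enriched):
        stats = {sid: dict(per) for sid, per in enriched.items()}
        return pk.consensus_peaks(enriched, stats, self.design, self.genes)

    def test_single_sample_support_is_no_peak(self):
        enriched = {"a1": {"g": make_windows("a1", "g", [(100, 200)])}, "a2": {}, "a3": {}}
        assert self._call(enriched) == []

    def test_two_of_three_replicates_make_a_peak(self):
        enriched = {
            "a1": {"g": make_windows("a1", "g", [(100, 200)])},
            "a2": {"g": make_windows("a2", "g", [(150, 250)])},
            "a3": {},
        }
        peaks = self._call(enriched)
        assert len(peaks) == 1
        assert (peaks[0].tx_start, peaks[0].tx_end) == (100, 250)
        assert peaks[0].support == 2

    def test_overlapping_windows_merge_to_union(self):
        spans = [(0, 100), (50, 150), (100, 200)]
        enriched = {
            "a1": {"g": make_windows("a1", "g", spans)},
            "a2": {"g": make_windows("a2", "g", spans)},
            "a3": {},
        }
        peaks = self._call(enriched)
        assert len(peaks) == 1
        assert (peaks[0].tx_start, peaks[0].tx_end) == (0, 200)

    def test_tissue_with_single_sample_errors_naming_it(self):
        with pytest.raises(ValueError, match="lonely"):
            pk.consensus_peaks({}, {}, {"x": "lonely"}, {})

    def test_peak_winscore_is_max_member_window(self):
        enriched = {
            "a1": {"g": make_windows("a1", "g", [(100, 200)], winscore=2.5)},
            "a2": {"g": make_windows("a2", "g", [(100, 200)], winscore=4.0)},
            "a3": {},
        }
        peaks = self._call(enriched)
        assert peaks[0].winscores == {"a1": 2.5, "a2": 4.0}

    def test_peak_set_independent_of_gene_order(self, small_study, called):
        import m6adyn.pipeline as pipeline

        rev = pipeline.stage_peakcall(list(reversed(small_study.genes)),
                                      small_study.tracks, small_study.design)
        key = lambda p: (p.gene_id, p.tissue, p.tx_start, p.tx_end)
        assert sorted(map(key, rev["peaks"])) == sorted(map(key, called["peaks"]))


class TestInferSites:
    def _one_peak_gene(self, seq, strand="+"):
        gene = GeneModel(gene_id="g", chrom="c", strand=strand,
                         exons=[(0, len(seq))], cds_start=0, cds_end=len(seq) // 3 * 3)
        genome = {"c": seq if strand == "+" else revcomp(seq)}
        peak = pk.Peak(gene_id="g", tissue="A", chrom="c", strand=strand,
                       tx_start=0, tx_end=len(seq), blocks=[])
        return pk.infer_sites([peak], genome, {"g": gene})

    def test_single_motif_found_at_central_a(self):
        sites = self._one_peak_gene("TTGGACTTT")
        assert len(sites) == 1
        assert sites[0].motif == "GGACT" and sites[0].tx_offset == 4

    def test_no_motif_no_sites(self):
        assert self._one_peak_gene("CCTCCCCTCC") == []

    def test_minus_strand_matches_reverse_complement_oracle(self):
        seq = "TTAGGACATTAAACTTT"  # transcript-strand sequence
        plus = self._one_peak_gene(seq, "+")
        minus = self._one_peak_gene(seq, "-")
        assert sorted(s.motif for s in plus) == sorted(s.motif for s in minus)
        assert sorted(s.tx_offset for s in plus) == sorted(s.tx_offset for s in minus)
        # and the genomic coordinates mirror
        assert sorted(len(seq) - 1 - s.gpos for s in minus) == sorted(s.gpos for s in plus)

    def test_motif_spanning_n_skipped(self):
        assert self._one_peak_gene("TTGGNCTTT") == []
        assert self._one_peak_gene("TTGGACTTT".replace("A", "A")) != []

    def test_sites_deduplicated_across_tissues(self, called):
        keys = [(s.chrom, s.gpos, s.strand) for s in called["sites"]]
        assert len(keys) == len(set(keys))

    def test_multitissue_sites_accumulate_tissue_flags(self, called):
        assert any(len(s.tissues) > 1 for s in called["sites"])


class TestTop50Normalization:
    def test_equal_samples_identity(self):
        factors = pk.normalize_winscores_top50({"a": [3.0] * 60, "b": [3.0] * 60})
        assert factors == {"a": 1.0, "b": 1.0}

    def test_doubled_sample_rescaled_to_common_mean(self, rng):
        base = list(rng.uniform(2, 6, size=80))
        doubled = [2 * x for x in base]
        factors = pk.normalize_winscores_top50({"a": base, "b": doubled})
        top = sorted(base, reverse=True)[:50]
        m = np.mean(top)
        assert np.mean(sorted(np.array(doubled) * factors["b"], reverse=True)[:50]) == (
            pytest.approx(np.mean(sorted(np.array(base) * factors["a"], reverse=True)[:50]))
        )
        assert factors["b"] / factors["a"] == pytest.approx(0.5)

    def test_known_factors_recovered(self, rng):
        base = list(rng.uniform(2, 6, size=100))
        scores = {f"s{k}": [k * x for x in base] for k in (1, 2, 4)}
        factors = pk.normalize_winscores_top50(scores)
        ratios = [factors["s1"] / factors[f"s{k}"] for k in (1, 2, 4)]
        assert ratios == pytest.approx([1.0, 2.0, 4.0])

    def test_fewer_than_top_n_uses_all_peaks(self):
        factors = pk.normalize_winscores_top50({"a": [2.0, 4.0], "b": [6.0]})
        assert factors["a"] == pytest.approx((3.0 + 6.0) / 2 / 3.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="no peaks"):
            pk.normalize_winscores_top50({"a": []})
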