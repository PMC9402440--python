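"""Region classification, PWM scans, background and attribution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lymphforge import sv_motif as sv
from lymphforge import synthetic_data as sd
from lymphforge.contexts import reverse_complement


class TestClassifyRegion:
    def test_inside_igh(self):
        assert sv.classify_region("chr14", 106_500_000) == "IgTCR"

    def test_far_away(self):
        assert sv.classify_region("chr1", 1000) == "other"

    def test_left_edge_inclusive(self):
        assert sv.classify_region("chr22", 22_385_390) == "IgTCR"
        assert sv.classify_region("chr22", 22_385_389) == "other"

    def test_tcr_locus(self):
        assert sv.classify_region("chr7", 142_000_000) == "IgTCR"

    def test_unknown_chromosome(self):
        with pytest.raises(ValueError):
            sv.classify_region("chrZZ", 5, known_chroms={"chr1"})


class TestPWM:
    def test_consensus_hit_at_planted_offset(self):
        ref = "T" * 200
        bp = 100
        ref = ref[: bp - 1 + 10] + sv.RSS_HEPTAMER + ref[bp - 1 + 17 :]
        hits = sv.scan_rss(ref, bp, window=50)
        plus = [h for h in hits if h.strand == "+"]
        assert any(h.position == 10 for h in plus)

    def test_reverse_complement_hit_minus_strand(self):
        rc_motif = reverse_complement(sv.RSS_HEPTAMER)  # CACTGTG
        ref = "A" * 95 + rc_motif + "A" * 95
        hits = sv.scan_rss(ref, 100, window=50)
        assert any(h.strand == "-" for h in hits)

    def test_random_hit_rate_matches_enumerated_tail(self):
        """Hit rate over random 107-bp windows agrees with the exact PWM tail."""
        rng = np.random.default_rng(99)
        n_windows = 10_000
        length = 107
        seqs = rng.integers(0, 4, size=(n_windows, length))
        bases = np.array(list("ACGT"))
        hits = 0
        for row in seqs:
            s = "".join(bases[row])
            if sv.HEPTAMER_PWM.scan(s) or sv.HEPTAMER_PWM.scan(reverse_complement(s)):
                hits += 1
        # per-window expectation from the enumerated per-position tail
        p_pos = sv.HEPTAMER_PWM.hit_probability()
        n_pos = 2 * (length - 7 + 1)
        p_window = 1 - (1 - p_pos) ** n_pos
        se = np.sqrt(p_window * (1 - p_window) / n_windows)
        assert abs(hits / n_windows - p_window) <= 3 * se + 1e-12

    def test_exact_tail_is_binomial(self):
        """With a two-level PWM the null score tail reduces to a binomial tail."""
        # exact heptamer match probability = (1/4)^7
        assert sv.HEPTAMER_PWM.hit_probability() == pytest.approx(0.25**7)
        assert sv.HEPTAMER_PWM.pvalue(sv.HEPTAMER_PWM.threshold_score) == pytest.approx(
            0.25**7
        )

    def test_full_rss_requires_nonamer_at_spacer(self):
        for spacer in (12, 23):
            seq = (
                "T" * 60
                + sv.RSS_HEPTAMER
                + "T" * spacer
                + sv.RSS_NONAMER
                + "T" * 60
            )
            hits = sv.scan_rss(seq, 61, window=50)
            full = [h for h in hits if h.kind == "RSS-full"]
            assert full and full[0].spacer == spacer

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        s = s[:100] + sv.RSS_HEPTAMER + s[107:]
        hits_fwd = sv.scan_rss(s, 105, window=60)
        hits_rev = sv.scan_rss(reverse_complement(s), len(s) - 105 + 1, window=60)
        kinds_fwd = sorted((h.kind, h.strand) for h in hits_fwd)
        kinds_rev = sorted((h.kind, {"+": "-", "-": "+"}[h.strand]) for h in hits_rev)
        assert kinds_fwd == kinds_rev


class TestScanCSR:
    def test_five_repeats_cluster(self):
        seq = "T" * 500 + ("AGCT" + "T" * 10) * 5 + "T" * 500
        assert sv.scan_csr(seq, 510)

    def test_single_motif_no_cluster(self):
        seq = "T" * 500 + "AGCT" + "T" * 500
        assert not sv.scan_csr(seq, 502)

    def test_gap_above_100_no_cluster(self):
        seq = "T" * 400 + "AGCT" + "T" * 150 + "AGCT" + "T" * 400
        assert not sv.scan_csr(seq, 402)

    def test_mixed_motifs_cluster(self):
        seq = "T" * 400 + "AGCT" + "T" * 50 + "TGCA" + "T" * 400
        assert sv.scan_csr(seq, 402)


class TestBackground:
    def test_motif_free_reference_zero(self):
        ref = "A" * 20_000  # heptamer needs C/G/T: impossible
        bg, props = sv.genomic_background(
            ref, np.arange(100, 19_900, 10), n_sets=10, set_size=50, seed=0
        )
        assert bg == 0.0 and (props == 0).all()

    def test_tandem_repeat_reference_one(self):
        ref = sv.RSS_HEPTAMER * 3000
        bg, _ = sv.genomic_background(
            ref, np.arange(100, len(ref) - 100, 7), n_sets=10, set_size=50, seed=0
        )
        assert bg == 1.0

    def test_planted_density_matches_binomial(self):
        """Hit proportion near planted-heptamer density follows the binomial."""
        rng = np.random.default_rng(3)
        block = "A" * 493
        ref = "".join(
            block + (sv.RSS_HEPTAMER if rng.random() < 0.3 else "A" * 7)
            for _ in range(400)
        )
        mask = np.arange(300, len(ref) - 300, 11)
        bg, props = sv.genomic_background(ref, mask, n_sets=50, set_size=100, seed=1)
        # windows are 100 bp around a position; planted blocks are 500 bp apart
        # so expected per-position hit probability ~ 0.3 * (107/500)
        expect = 0.3 * 107 / 500
        se = np.sqrt(expect * (1 - expect) / 100)
        assert abs(bg - expect) < 4 * se

    def test_mask_too_small(self):
        with pytest.raises(ValueError):
            sv.genomic_background("A" * 1000, np.arange(10), set_size=50)

    def test_median_invariant_to_set_order(self):
        ref = ("A" * 200 + sv.RSS_HEPTAMER) * 100
        mask = np.arange(100, len(ref) - 100, 13)
        bg1, props = sv.genomic_background(ref, mask, n_sets=30, set_size=40, seed=7)
        assert bg1 == np.median(props)
        assert np.median(props[::-1]) == bg1


class TestAttribution:
    @pytest.mark.parametrize(
        "p_obs,p_bg,expected",
        [(0.96, 0.12, 0.84), (0.24, 0.12, 0.12), (0.05, 0.12, 0.0)],
    )
    def test_background_correction(self, p_obs, p_bg, expected):
        assert sv.rag_attributable_fraction(p_obs, p_bg) == pytest.approx(expected)

    def test_recovers_planted_fraction(self):
        ref, svs, truth = sd.simulate_reference_and_svs(1_200_000, 200, 0.4, 0.0, seed=9)
        ann = sv.annotate_svs(ref, svs)
        mask = np.arange(2000, len(ref) - 2000, 61)
        bg, _ = sv.genomic_background(ref, mask, n_sets=30, set_size=100, seed=9)
        corrected = sv.rag_attributable_fraction(float(ann["rss_hit"].mean()), bg)
        assert corrected == pytest.approx(0.4, abs=0.05)


class TestDistanceProfile:
    def test_planted_offsets_enriched_then_background(self):
        ref, svs, _ = sd.simulate_reference_and_svs(800_000, 100, 1.0, 0.0, seed=12)
        prof = sv.motif_distance_profile(ref, svs, bin_width=25, max_distance=200)
        near = prof[(prof.bin_left >= 0) & (prof.bin_right <= 50)]["proportion"].sum()
        far = prof[prof.bin_left >= 100]["proportion"].mean()
        assert near > 0.8
        assert far < 0.05

    def test_no_deletions_empty(self):
        svs = pd.DataFrame(
            {"chrom1": [], "pos1": [], "chrom2": [], "pos2": [], "svclass": []}
        )
        assert sv.motif_distance_profile("A" * 1000, svs).empty


class TestInsertionEnrichment:
    def test_hand_odds_ratio(self):
        svs = pd.DataFrame(
            {
                "rss_hit": [True] * 100 + [False] * 100,
                "has_insertion": [True] * 44 + [False] * 56 + [True] * 21 + [False] * 79,
            }
        )
        table, odds, p = sv.insertion_enrichment(svs)
        assert table.tolist() == [[44, 56], [21, 79]]
        assert odds == pytest.approx((44 * 79) / (56 * 21), rel=1e-6)
        _, p_ref = stats.fisher_exact(table)
        assert p == pytest.approx(p_ref)

    def test_identical_rows_p_one(self):
        svs = pd.DataFrame(
            {
                "rss_hit": [True] * 50 + [False] * 50,
                "has_insertion": ([True] * 25 + [False] * 25) * 2,
            }
        )
        _, _, p = sv.insertion_enrichment(svs)
        assert p == pytest.approx(1.0)

    def test_empty_margin_nan(self):
        svs = pd.DataFrame({"rss_hit": [True, True], "has_insertion": [True, False]})
        _, odds, p = sv.insertion_enrichment(svs)
        assert np.isnan(p)
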