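"""TSS detection/assignment, 5'-UTR classes, promoter EM and derived
sequence statistics."""

import numpy as np
import pytest

from prokdyn.core import GeneFeature
from prokdyn.motifs import MotifModel, ZoopsEM, consensus_string, em_motif_search
from prokdyn.tss import (TSSRecord, assign_primary_tss, detect_tss,
                         extract_upstream_windows, rbs_and_start_stats, revcomp,
                         spacer_statistics)


def tracks(plus=None, minus=None, length=500):
    fp = {"+": np.zeros(length), "-": np.zeros(length)}
    for pos, count in (plus or {}).items():
        fp["+"][pos - 1] = count
    for pos, count in (minus or {}).items():
        fp["-"][pos - 1] = count
    return fp


class TestDetectTSS:
    def test_flat_track_no_candidates(self):
        assert detect_tss({"+": np.zeros(300), "-": np.zeros(300)}) == []

    def test_single_spike_detected(self):
        cands = detect_tss(tracks(plus={100: 100}))
        assert [(c.position, c.strand) for c in cands] == [(100, "+")]

    def test_spike_below_min_starts_ignored(self):
        assert detect_tss(tracks(plus={100: 5})) == []

    def test_spike_within_background_ignored(self):
        fp = tracks(plus={100: 20})
        fp["+"][40:99] = 10.0  # heavy upstream background masks the spike
        assert (100, "+") not in {(c.position, c.strand) for c in detect_tss(fp)}

    def test_minus_strand_background_is_downstream_in_genome(self):
        fp = tracks(minus={100: 20})
        fp["-"][100:160] = 10.0  # upstream for a minus-strand TSS
        assert (100, "-") not in {(c.position, c.strand) for c in detect_tss(fp)}
        fp2 = tracks(minus={100: 20})
        fp2["-"][30:90] = 10.0   # this side is downstream; must not mask
        assert (100, "-") in {(c.position, c.strand) for c in detect_tss(fp2)}

    def test_recovers_planted_tss(self, sim_bundle):
        cands = detect_tss(sim_bundle["tracks"].five_prime)
        planted = {(t.pos, t.strand) for t in sim_bundle["truth"].tss_list}
        found = {(c.position, c.strand) for c in cands}
        assert len(planted) >= 100
        recall = len(planted & found) / len(planted)
        precision = len(planted & found) / len(found)
        assert recall >= 0.95
        assert precision >= 0.9


class TestAssignPrimaryTSS:
    GENES = [GeneFeature("gp", "+", 200, 400), GeneFeature("gm", "-", 600, 800)]

    def _assign(self, cands, genome=None):
        return assign_primary_tss(cands, self.GENES, max_upstream=500, genome=genome)

    def test_distance_zero_is_leaderless(self):
        (rec,) = self._assign([TSSRecord(200, "+", 50)])
        assert rec.assigned_feature == "gp"
        assert rec.utr_length == 0 and rec.leaderless

    def test_leaderless_boundary_three_vs_four(self):
        (r3,) = self._assign([TSSRecord(197, "+", 50)])
        (r4,) = self._assign([TSSRecord(196, "+", 50)])
        assert r3.utr_length == 3 and r3.leaderless
        assert r4.utr_length == 4 and not r4.leaderless

    def test_strongest_candidate_wins(self):
        recs = self._assign([TSSRecord(150, "+", 50), TSSRecord(120, "+", 10)])
        assert [(r.position, r.utr_length) for r in recs] == [(150, 50)]

    def test_tie_breaks_toward_tls(self):
        recs = self._assign([TSSRecord(150, "+", 50), TSSRecord(170, "+", 50)])
        assert [r.position for r in recs] == [170]

    def test_minus_strand_distance_and_base(self):
        genome = "A" * 810
        genome = genome[:804] + "C" + genome[805:]  # genomic C at 805 -> transcribed G
        (rec,) = self._assign([TSSRecord(805, "-", 30)], genome=genome)
        assert rec.assigned_feature == "gm"
        assert rec.utr_length == 5
        assert rec.start_nucleotide == "G"

    def test_candidate_goes_to_nearest_downstream_tls(self):
        both = [GeneFeature("near", "+", 300, 400), GeneFeature("far", "+", 600, 700)]
        recs = assign_primary_tss([TSSRecord(250, "+", 40)], both, max_upstream=500)
        assert [r.assigned_feature for r in recs] == ["near"]

    def test_partition_leaderless_plus_leadered(self, pipeline_results):
        assigned = pipeline_results["tss_assigned"]
        n_leaderless = sum(t.leaderless for t in assigned)
        n_leadered = sum(not t.leaderless for t in assigned)
        assert n_leaderless + n_leadered == len(assigned)
        assert all(t.leaderless == (t.utr_length <= 3) for t in assigned)


class TestExtractWindows:
    def test_plus_strand_window_excludes_tss_base(self):
        genome = "".join("ACGT"[i % 4] for i in range(200))
        (win,) = extract_upstream_windows([TSSRecord(51, "+", 10)], genome)
        assert win == genome[0:50]
        assert len(win) == 50

    def test_minus_strand_window_is_revcomp_downstream(self):
        genome = "".join("ACGT"[i % 4] for i in range(200))
        (win,) = extract_upstream_windows([TSSRecord(100, "-", 10)], genome)
        assert win == revcomp(genome[100:150])

    def test_truncated_at_contig_edge_with_warning(self):
        genome = "A" * 100
        with pytest.warns(UserWarning):
            (win,) = extract_upstream_windows([TSSRecord(10, "+", 10)], genome)
        assert len(win) == 9


class TestConsensus:
    def test_minus10_frequencies_render_tannnt(self):
        freq = np.full((4, 6), 0.1)
        freq[3, 0] = 0.636
        freq[0, 1] = 0.908
        freq[1, 2] = 0.40  # sub-threshold middles
        freq[2, 3] = 0.45
        freq[1, 4] = 0.48
        freq[3, 5] = 0.857
        assert consensus_string(freq) == "TAnnnT"

    def test_minus35_frequencies_render_ntgacn(self):
        freq = np.full((4, 6), 0.2)
        freq[3, 1] = 0.679
        freq[2, 2] = 0.837
        freq[0, 3] = 0.530
        freq[1, 4] = 0.820
        assert consensus_string(freq) == "nTGACn"

    def test_uniform_matrix_is_all_n(self):
        assert consensus_string(np.full((4, 6), 0.25)) == "nnnnnn"

    def test_consensus_roundtrip_on_strong_matrix(self):
        freq = np.full((4, 5), 0.05)
        for i, b in enumerate([2, 2, 0, 2, 1]):  # GGAGC
            freq[b, i] = 0.85
        assert consensus_string(freq) == "GGAGC"


class TestZoopsEM:
    def test_recovers_planted_motif(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        windows = []
        for i in range(80):
            w = rng.choice(bases, 50)
            if i < 70:
                off = int(rng.integers(40, 44))
                w[off:off + 5] = list("GGATC")
            windows.append("".join(w))
        model = em_motif_search(windows, width=5, n_restarts=10, seed=0)
        assert consensus_string(model) == "GGATC"
        assert model.fraction_with_hit >= 0.8

    def test_loglikelihood_monotone(self):
        rng = np.random.default_rng(6)
        windows = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(40)]
        model = em_motif_search(windows, width=6, n_restarts=3, seed=1)
        diffs = np.diff(model.ll_trace)
        assert np.all(diffs >= -1e-8)

    def test_frequency_columns_sum_to_one(self):
        rng = np.random.default_rng(7)
        windows = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(30)]
        model = em_motif_search(windows, width=6, n_restarts=3, seed=1)
        np.testing.assert_allclose(model.freq.sum(axis=0), 1.0, rtol=1e-12)

    def test_identical_windows_saturate_frequencies(self):
        windows = ["ACGTACGTACGTGGGGGACGTACGT"] * 20
        model = em_motif_search(windows, width=5, n_restarts=5, seed=0)
        # every column concentrates on a single base up to the pseudocount
        assert (model.freq.max(axis=0) > 0.9).all()

    def test_degenerate_single_base_input_flagged(self):
        model = em_motif_search(["AAAAAAAAAA"] * 15, width=4, n_restarts=2, seed=0)
        assert model.degenerate

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            em_motif_search(["ACGTACGT"] * 5, width=4)

    def test_sklearn_style_params(self):
        est = ZoopsEM(width=7, seed=3)
        assert est.get_params()["width"] == 7
        est.set_params(width=5)
        assert est.width == 5


def _model(offsets, hits, width=6):
    n = len(offsets)
    return MotifModel(width, np.full((4, width), 0.25), np.asarray(offsets),
                      np.asarray(hits, dtype=bool),
                      float(np.mean(hits)), 0.5)


class TestSpacerStatistics:
    def test_constant_spacer(self):
        # -10 hexamer ends 6 nt before the window end in every sequence
        m10 = _model([38, 38, 38], [True, True, True])
        stats = spacer_statistics(m10, None, [50, 50, 50])
        s = stats["minus10_to_TSS"]
        assert (s.mean, s.sd, s.n) == (6.0, 0.0, 3)
        assert s.histogram == {6: 3}

    def test_uniform_spacer_moments(self):
        offsets = [39, 38, 37] * 40  # spacers 5, 6, 7
        m10 = _model(offsets, [True] * 120)
        s = spacer_statistics(m10, None, [50] * 120)["minus10_to_TSS"]
        assert s.mean == pytest.approx(6.0)
        assert s.sd == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-9)

    def test_minus10_only_window_excluded_from_pair_stats(self):
        m10 = _model([38, 30, 38], [True, True, True])
        m35 = _model([10, -1, 12], [True, False, True])
        stats = spacer_statistics(m10, m35, [50, 50, 50])
        assert stats["minus10_to_TSS"].n == 3
        assert stats["minus35_to_minus10"].n == 2
        # gaps: 38-(10+6)=22 and 38-(12+6)=20
        assert stats["minus35_to_minus10"].histogram == {20: 1, 22: 1}

    def test_no_hits_empty_stats(self):
        m10 = _model([-1, -1], [False, False])
        s = spacer_statistics(m10, None, [50, 50])["minus10_to_TSS"]
        assert s.n == 0 and np.isnan(s.mean)


class TestRBSAndStartStats:
    def test_planted_rbs_found_in_every_utr(self):
        rng = np.random.default_rng(8)
        genome = list("".join(rng.choice(list("ACGT"), 6000)))
        genes, tss_list = [], []
        for i in range(20):
            tls = 250 + i * 280
            genes.append(GeneFeature(f"g{i}", "+", tls, tls + 150))
            tss_list.append(TSSRecord(tls - 30, "+", 50, f"g{i}", 30, False))
            gap = 7  # RBS 3' end 7 nt upstream of the TLS
            genome[tls - 1 - gap - 5:tls - 1 - gap] = list("GGAGG")
        res = rbs_and_start_stats(tss_list, "".join(genome), genes, seed=0, n_restarts=5)
        assert res["n_searched_utrs"] == 20
        assert res["rbs_fraction"] >= 0.9
        assert "GGAGG" in res["rbs_consensus"] or res["rbs_consensus"].count("G") >= 3

    def test_all_g_starts_give_pure_purine_distribution(self):
        tss_list = [TSSRecord(100 + i, "+", 20, f"g{i}", 0, True, "G") for i in range(10)]
        res = rbs_and_start_stats(tss_list, "A" * 300, [], seed=0)
        assert res["purine_fraction"] == 1.0
        assert res["start_nucleotide_fractions"] == {"A": 0.0, "C": 0.0, "G": 1.0, "T": 0.0}

    def test_no_leadered_transcripts_empty(self):
        tss_list = [TSSRecord(100, "+", 20, "g0", 0, True)]
        res = rbs_and_start_stats(tss_list, "A" * 300, [GeneFeature("g0", "+", 100, 200)])
        assert res["n_searched_utrs"] == 0
        assert np.isnan(res["rbs_fraction"])

    def test_purine_fraction_recovers_planted_probability(self, pipeline_results):
        res = pipeline_results["rbs"]
        n = sum(res["start_nucleotide_counts"].values())
        tol = 3 * np.sqrt(0.754 * (1 - 0.754) / n)
        assert abs(res["purine_fraction"] - 0.754) <= tol


class TestStrandSymmetry:
    def test_detection_mirrors_under_reverse_complement(self):
        fp = tracks(plus={120: 40}, minus={333: 25}, length=500)
        fwd = detect_tss(fp)
        flipped = {"+": fp["-"][::-1].copy(), "-": fp["+"][::-1].copy()}
        rev = detect_tss(flipped)
        mirrored = sorted((500 - c.position + 1, {"+": "-", "-": "+"}[c.strand])
                          for c in rev)
        assert mirrored == sorted((c.position, c.strand) for c in fwd)
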