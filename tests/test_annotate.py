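"""uORF scanning, overlap classes, Kozak scoring, shuffling, and RSCU."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uorfkit import annotate
from uorfkit.annotate import (
    KozakPPM,
    build_kozak_ppm,
    count_uorfs_in_utr,
    dinucleotide_counts,
    dinucleotide_shuffle,
    expected_uorf_count,
    kozak_score,
    rscu_table,
    scan_uorfs,
)
from uorfkit.models import TranscriptModel


def make_transcript(utr5: str, cds_codons: int = 4, utr3: str = "AAAA") -> TranscriptModel:
    cds = "ATG" + "GGC" * (cds_codons - 2) + "TAA"
    return TranscriptModel("t1", "g1", utr5 + cds + utr3, len(utr5), len(utr5) + len(cds))


class TestScanUorfs:
    def test_single_nonoverlapping_uorf(self):
        # ATG at 2, stop TAA at 8..11 -> uORF [2, 11), 9 nt
        t = make_transcript("CCATGGCCTAAGG")
        (u,) = scan_uorfs(t)
        assert (u.start, u.end) == (2, 11)
        assert u.length == 9
        assert u.overlap_class == "nonoverlapping"
        assert u.distance_uaug_to_caug == 11
        assert u.distance_cap_to_uaug == 2
        assert u.distance_stop_to_caug == 2

    def test_no_atg_gives_empty_list(self):
        assert scan_uorfs(make_transcript("CCCCCCGGGGGG")) == []

    def test_stop_inside_cds_out_of_frame(self):
        # uAUG at 2; no in-frame stop in the 13-nt UTR; (13 - 2) % 3 != 0 so
        # the uORF is out of frame with the CDS; its first in-frame stop
        # (TAA spanning CDS codons 2-3) lies inside the CDS region.
        utr = "CCATGGGGGGGGG"
        cds = "ATG" + "TTA" + "AGC" + "TAA"
        t = TranscriptModel("t1", "g1", utr + cds + "AAAA", len(utr), len(utr) + len(cds))
        us = scan_uorfs(t)
        assert len(us) == 1
        assert us[0].overlap_class == "CDS-overlap-outframe"
        assert us[0].end > t.cds_start
        assert us[0].distance_stop_to_caug < 0

    def test_nterm_extension_excluded(self):
        # ATG in frame with the CDS and no stop before the cAUG: not a uORF
        utr = "ATGGGG"
        t = make_transcript(utr)
        assert (t.cds_start - 0) % 3 == 0
        assert scan_uorfs(t) == []

    def test_inframe_atg_with_upstream_stop_is_uorf(self):
        utr = "ATGTAA"  # stop before the CDS -> genuine uORF despite CDS frame
        t = make_transcript(utr)
        (u,) = scan_uorfs(t)
        assert (u.start, u.end) == (0, 6)

    def test_sorted_by_start(self, small_transcriptome):
        _, transcripts, _ = small_transcriptome
        for t in transcripts[:10]:
            starts = [u.start for u in scan_uorfs(t)]
            assert starts == sorted(starts)


class TestOverlapClasses:
    def test_inframe_uorf_overlap(self):
        # uORFs at 0 and 6 sharing nucleotides, 6 % 3 == 0 -> in-frame
        utr = "ATGCCCATGCCCTAACCC"
        t = make_transcript(utr)
        us = scan_uorfs(t)
        pair = [u for u in us if u.start in (0, 6)]
        assert all(u.overlap_class == "uORF-overlap-inframe" for u in pair)

    def test_outframe_uorf_overlap(self):
        # uORFs at 0 ([0,15)) and 7 ([7,22)) sharing nucleotides,
        # 7 % 3 != 0 -> out-of-frame
        utr = "ATGCCCCATGCCTAACCCCTAACC"
        t = make_transcript(utr)
        us = {u.start: u for u in scan_uorfs(t)}
        assert us[0].overlap_class == "uORF-overlap-outframe"
        assert us[7].overlap_class == "uORF-overlap-outframe"

    def test_disjoint_uorfs_nonoverlapping(self):
        utr = "ATGTAACCCCCCATGTAACCC"
        t = make_transcript(utr)
        us = scan_uorfs(t)
        assert len(us) == 2
        assert all(u.overlap_class == "nonoverlapping" for u in us)


class TestKozak:
    def test_uniform_ppm_scores_zero(self):
        ppm = KozakPPM(np.full((7, 4), 0.25))
        assert kozak_score("ACGTACG", ppm) == 0.0

    def test_certain_ppm_scores_two_bits_per_position(self):
        m = np.zeros((7, 4))
        ctx = "ACGTACG"
        for i, c in enumerate(ctx):
            m[i, "ACGT".index(c)] = 1.0
        assert kozak_score(ctx, ppm := KozakPPM(m)) == pytest.approx(14.0)
        assert kozak_score("GTTTTTT", ppm) == -math.inf

    def test_hand_computed_two_position_window(self):
        # window {-2,-1}: P(-2,A)=0.5, P(-1,C)=0.125 -> log2(2) + log2(0.5) = 0
        m = np.array([[0.5, 0.3, 0.1, 0.1], [0.375, 0.125, 0.25, 0.25]])
        ppm = KozakPPM(m, window=(-2, -1))
        assert kozak_score("AC", ppm) == pytest.approx(1.0 - 1.0)

    def test_ppm_from_identical_contexts(self):
        utr = "AAAAAA"
        t = TranscriptModel("t", "g", utr + "ATG" + "A" + "GGTAA", 6, 6 + 9)
        ppm = build_kozak_ppm([t, t])
        assert np.allclose(ppm.matrix[:, 0], 1.0)  # all-A contexts

    def test_ppm_two_contexts_half_half(self):
        t1 = TranscriptModel("a", "g", "AAAAAA" + "ATGA" + "GGTAA", 6, 15)
        t2 = TranscriptModel("b", "g", "CAAAAA" + "ATGA" + "GGTAA", 6, 15)
        ppm = build_kozak_ppm([t1, t2])
        assert ppm.matrix[0, 0] == pytest.approx(0.5)  # A at -6
        assert ppm.matrix[0, 1] == pytest.approx(0.5)  # C at -6
        assert np.allclose(ppm.matrix.sum(axis=1), 1.0)

    def test_short_utr_context_scored_with_missing_positions(self):
        t = TranscriptModel("t", "g", "AA" + "ATGA" + "GGTAA", 2, 11)
        ctx = annotate.extract_context(t, 2)
        assert ctx.startswith("----")
        ppm = KozakPPM(np.full((7, 4), 0.25))
        assert kozak_score(ctx, ppm) == 0.0


class TestDinucleotideShuffle:
    def test_counts_preserved_long_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        out = dinucleotide_shuffle(seq, 1)
        assert dinucleotide_counts(out) == dinucleotide_counts(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_aatt_reachable_outputs(self):
        # Euler paths over dinucleotides {AA, AT, TT} from A to T: only AATT
        target = {"AA": 1, "AT": 1, "TT": 1}
        outs = {dinucleotide_shuffle("AATT", s) for s in range(20)}
        for o in outs:
            assert dinucleotide_counts(o) == target

    def test_short_sequences_identity(self):
        for s in ("A", "AC", "ACG"):
            assert dinucleotide_shuffle(s, 0) == s

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=200), st.integers(0, 2**31 - 1))
    def test_property_counts_always_preserved(self, seq, seed):
        out = dinucleotide_shuffle(seq, seed)
        assert dinucleotide_counts(out) == dinucleotide_counts(seq)


class TestShuffleNull:
    def test_utrs_without_a_or_t_never_form_uorfs(self):
        res = expected_uorf_count(["CCGGCCGG", "GGGGCCCC"], n_reps=5, seed=0)
        assert res["mean"] == 0 and res["q97.5"] == 0

    def test_atgtaa_distribution_matches_enumeration(self):
        # Exhaustive oracle: all dinucleotide-preserving permutations of
        # "ATGTAA" (same first/last base) and their uORF counts.
        seq = "ATGTAA"
        ref = dinucleotide_counts(seq)
        perms = {"A" + "".join(q) + "A" for q in itertools.permutations("TGTA", 4)}
        valid = [s for s in perms if dinucleotide_counts(s) == ref]
        oracle_counts = {count_uorfs_in_utr(s) for s in valid}
        observed = {
            count_uorfs_in_utr(dinucleotide_shuffle(seq, s)) for s in range(200)
        }
        assert observed <= oracle_counts

    def test_observed_below_q25_is_depletion(self, rng):
        utrs = ["".join(rng.choice(list("ACGT"), size=150)) for _ in range(20)]
        res = expected_uorf_count(utrs, n_reps=50, seed=3)
        assert res["q2.5"] <= res["median"] <= res["q97.5"]

    def test_rejects_single_replicate(self):
        with pytest.raises(ValueError):
            expected_uorf_count(["ACGT"], n_reps=1)


class TestRSCU:
    def test_equal_usage_gives_one(self):
        # Phe family TTT/TTC used equally (start+stop excluded)
        seq = "ATG" + "TTT" + "TTC" + "TAA"
        rscu = rscu_table([seq])
        assert rscu["TTT"] == pytest.approx(1.0)
        assert rscu["TTC"] == pytest.approx(1.0)

    def test_three_to_one_family_of_two(self):
        seq = "ATG" + "TTT" * 3 + "TTC" + "TAA"
        rscu = rscu_table([seq])
        assert rscu["TTT"] == pytest.approx(1.5)
        assert rscu["TTC"] == pytest.approx(0.5)

    def test_single_codon_families_are_one(self):
        seq = "ATG" + "TGG" + "ATG" + "TGG" + "TAA"
        rscu = rscu_table([seq])
        assert rscu["TGG"] == pytest.approx(1.0)
        assert rscu["ATG"] == pytest.approx(1.0)

    def test_unused_family_is_nan(self):
        rscu = rscu_table(["ATG" + "TTT" + "TAA"])
        assert math.isnan(rscu["GGT"])

    def test_rejects_frameshifted_input(self):
        with pytest.raises(ValueError):
            rscu_table(["ATGT"])


class TestPlantedRecovery:
    def test_scan_recovers_all_planted_uorfs(self, small_transcriptome):
        _, transcripts, truth = small_transcriptome
        found = set()
        for t in transcripts:
            for u in scan_uorfs(t):
                found.add((u.transcript_id, u.start, u.end))
                # every reported uORF satisfies the structural invariants
                assert t.sequence[u.start : u.start + 3] == "ATG"
                assert t.sequence[u.end - 3 : u.end] in ("TAA", "TAG", "TGA")
                assert (u.end - u.start) % 3 == 0
                assert u.start < t.cds_start
        planted = {(u.transcript_id, u.start, u.end) for u in truth.planted_uorfs}
        assert planted <= found

    def test_uorf_rate_zero_plants_nothing(self):
        from uorfkit.simulate import SimulationConfig, generate_transcriptome

        cfg = SimulationConfig(seed=5, n_genes=10, uorf_rate=0.0)
        _, truth = generate_transcriptome(cfg)
        assert truth.planted_uorfs == []
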