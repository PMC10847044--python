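"""ORF calling, SD detection, RdRP motif scanning and TMD flagging, each
cross-checked against an independent oracle."""

import numpy as np
import pytest

from flds_segvir.annotate import (KYTE_DOOLITTLE, SequenceFormatError,
                                  annotate_bin, detect_sd, find_orfs,
                                  flag_tmd, scan_rdrp_motifs)
from flds_segvir.seqtools import random_seq, revcomp
from oracles import motif_oracle, orf_scan_oracle, tmd_oracle

AAS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(AAS[i] for i in rng.integers(0, len(AAS), size=n))


class TestFindOrfs:
    def test_constructed_orf_found_at_truth_coordinates(self):
        """ATG + 49 sense codons + stop inside neutral padding."""
        rng = np.random.default_rng(0)
        body = "ATG" + "GCT" * 49 + "TAA"
        pad5 = "CCC" * 30
        pad3 = "CCC" * 30
        seq = pad5 + body + pad3
        orfs = find_orfs(seq, min_orf_len=150)
        spans = {(o.start, o.end) for o in orfs}
        assert (len(pad5), len(pad5) + len(body)) in spans

    def test_open_three_prime_orf_flagged(self):
        seq = "CCCCCC" + "ATG" + "GCT" * 60   # no stop before segment end
        orfs = find_orfs(seq, min_orf_len=150)
        assert len(orfs) == 1
        assert orfs[0].open_3p
        assert (orfs[0].end - orfs[0].start) % 3 == 0

    def test_nested_starts_suppressed(self):
        seq = "ATG" + "AAA" * 10 + "ATG" + "AAA" * 60 + "TAA"
        orfs = [o for o in find_orfs(seq, min_orf_len=150) if o.frame == 0]
        assert len(orfs) == 1
        assert orfs[0].start == 0

    def test_invalid_characters_rejected(self):
        with pytest.raises(SequenceFormatError):
            find_orfs("ACGTUACGT" * 30)

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_bruteforce_three_frame_scan(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            seq = random_seq(rng, int(rng.integers(200, 2500)))
            got = {(o.start, o.end, o.open_3p) for o in find_orfs(seq)}
            assert got == orf_scan_oracle(seq)

    def test_planted_orfs_recovered_exactly(self, bipartite_truth):
        total = hit = 0
        for seg in bipartite_truth.segments:
            found = {(o.start, o.end) for o in find_orfs(seg.sequence)}
            for o in seg.orfs:
                total += 1
                hit += (o.start, o.end) in found
        assert hit / total >= 0.95

    def test_strand_consistent_after_reorientation(self, bipartite_truth):
        """Re-orienting the reverse complement yields identical ORF maps."""
        seg = bipartite_truth.segments[0]
        from flds_segvir.binning import orient_coding_strand
        flipped, _, _ = orient_coding_strand(revcomp(seg.sequence))
        a = [(o.start, o.end) for o in find_orfs(seg.sequence)]
        b = [(o.start, o.end) for o in find_orfs(flipped)]
        assert a == b


class TestDetectSd:
    def test_consensus_at_spacer_eight(self):
        rng = np.random.default_rng(1)
        up = "CCTCCTCCTCCT"
        seq = up + "AGGAGG" + "CCTCCTCC"[:8] + "ATG" + "GCA" * 30
        start = len(up) + 6 + 8
        hit = detect_sd(seq, start)
        assert hit is not None
        assert hit.spacer == 8
        assert hit.match_len == 6
        assert hit.motif == "AGGAGG"

    def test_no_consensus_fourmer_gives_none(self):
        seq = "CCCCCCCCCCCCCCCCCCCCCCCCCC" + "ATG" + "GCA" * 30
        assert detect_sd(seq, 26) is None

    def test_partial_match_needs_four_consecutive(self):
        up = "CCCCCCCCCC" + "AGGC" + "CCCCCC"     # only 3-mer AGG present
        seq = up + "ATG" + "GCA" * 30
        assert detect_sd(seq, len(up)) is None
        up2 = "CCCCCCCCCC" + "AGGA" + "CCCCCC"    # AGGA = 4 consecutive
        seq2 = up2 + "ATG" + "GCA" * 30
        hit = detect_sd(seq2, len(up2))
        assert hit is not None and hit.match_len >= 4

    def test_spacer_outside_window_rejected(self):
        up = "AGGAGG" + "C" * 20                  # spacer 20 > 14
        seq = up + "ATG" + "GCA" * 30
        assert detect_sd(seq, len(up)) is None

    def test_recall_and_false_positive_rate_on_fixture(self, bipartite_truth):
        """Planted-SD recall >= 0.95; false-positive rate on SD-free
        planted ORFs <= 0.1, both against the simulator truth."""
        tp = planted = fp = free = 0
        for seg in bipartite_truth.segments:
            for o in seg.orfs:
                hit = detect_sd(seg.sequence, o.start)
                if o.has_sd:
                    planted += 1
                    tp += hit is not None
                else:
                    free += 1
                    fp += hit is not None
        assert planted > 0
        assert tp / planted >= 0.95
        if free:
            assert fp / free <= 0.1


class TestScanRdrpMotifs:
    def test_ordered_b_c_pair(self):
        prot = "M" * 20 + "SGAATT" + "A" * 20 + "GDD" + "K" * 10
        hits = scan_rdrp_motifs(prot)
        b = [h for h in hits if h.motif == "B"]
        c = [h for h in hits if h.motif == "C"]
        assert len(b) == 1 and b[0].ordered
        assert len(c) == 1
        assert b[0].position == 20 and c[0].position == 46

    def test_featureless_protein_empty(self):
        assert scan_rdrp_motifs("A" * 200) == []

    def test_extended_motif_a_classified(self):
        """Asp pair at distance 13 upstream of GDD -> extended class."""
        prot = (["A"] * 300)
        prot[200:203] = list("GDD")
        prot[100] = "D"
        prot[113] = "D"
        hits = scan_rdrp_motifs("".join(prot))
        a = [h for h in hits if h.motif == "A"]
        assert len(a) == 1
        assert a[0].position == 100
        assert a[0].spacing == 13
        assert a[0].a_class == "extended"

    def test_canonical_motif_a_takes_precedence(self):
        prot = (["A"] * 300)
        prot[200:203] = list("GDD")
        prot[100] = "D"
        prot[104] = "D"
        hits = scan_rdrp_motifs("".join(prot))
        a = [h for h in hits if h.motif == "A" and h.position == 100]
        assert a and a[0].a_class == "canonical" and a[0].spacing == 4

    def test_equals_regex_oracle_on_random_proteins(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            prot = random_protein(rng, int(rng.integers(30, 400)))
            hits = scan_rdrp_motifs(prot)
            b_got = sorted(h.position for h in hits if h.motif == "B")
            c_got = sorted(h.position for h in hits if h.motif == "C")
            ordered_got = sorted(h.position for h in hits
                                 if h.motif == "B" and h.ordered)
            b_exp, c_exp, ordered_exp = motif_oracle(prot)
            assert b_got == sorted(b_exp)
            assert c_got == sorted(c_exp)
            assert ordered_got == sorted(ordered_exp)

    def test_nonstandard_residues_never_match(self):
        assert scan_rdrp_motifs("XGDX" * 30) == []


class TestFlagTmd:
    def test_poly_leucine_insert_flags(self):
        prot = "D" * 30 + "L" * 19 + "D" * 30
        res = flag_tmd(prot)
        assert res.flag
        assert res.best_start == 30

    def test_poly_aspartate_never_flags(self):
        assert not flag_tmd("D" * 100).flag

    def test_equals_exhaustive_window_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            prot = random_protein(rng, int(rng.integers(19, 200)))
            res = flag_tmd(prot)
            exp_flag, exp_best = tmd_oracle(prot, KYTE_DOOLITTLE)
            assert res.flag == exp_flag
            assert res.best_score == pytest.approx(exp_best)

    def test_short_protein_not_flagged(self):
        assert not flag_tmd("L" * 10).flag


class TestAnnotateBin:
    def test_rdrp_segment_labelled_from_planted_motifs(self, bipartite_truth):
        """The member carrying the planted RdRP-motif ORF is labelled."""
        for virus in ("V01", "V02", "V03"):
            members = {s.segment_id: s.sequence
                       for s in bipartite_truth.segments
                       if s.virus_id == virus}
            truth_rdrp = next(
                s.segment_id for s in bipartite_truth.segments
                if s.virus_id == virus
                and any(o.is_rdrp for o in s.orfs))
            ba = annotate_bin(virus, members)
            assert ba.rdrp_segment == truth_rdrp

    def test_no_motifs_no_rdrp_segment(self):
        rng = np.random.default_rng(8)
        seqs = {"a": "CCTCCT" * 100, "b": "CCTCCT" * 120}
        ba = annotate_bin("b0", seqs)
        assert ba.rdrp_segment is None

    def test_gff3_round_trip_reproduces_coordinates(self, bipartite_truth):
        import io
        import pandas as pd
        seg = bipartite_truth.segments[0]
        ba = annotate_bin("b1", {seg.segment_id: seg.sequence})
        body = [l for l in ba.gff3.splitlines() if not l.startswith("#")]
        tab = pd.read_csv(io.StringIO("\n".join(body)), sep="\t",
                          header=None,
                          names=["seqid", "source", "type", "start", "end",
                                 "score", "strand", "phase", "attrs"])
        got = sorted(zip(tab.start - 1, tab.end))
        expected = sorted((o.start, o.end)
                          for o in ba.orfs[seg.segment_id])
        assert got == expected
        assert (tab.type == "CDS").all()

    def test_sd_fraction_counts_detected_orfs(self, bipartite_truth):
        seg = bipartite_truth.segments[0]
        ba = annotate_bin("b1", {seg.segment_id: seg.sequence})
        orfs = ba.orfs[seg.segment_id]
        assert ba.orf_count == len(orfs)
        frac = sum(1 for o in orfs if o.sd is not None) / len(orfs)
        assert ba.sd_fraction == pytest.approx(frac)
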