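"""Coding-strand orientation, terminal-identity scoring, single-linkage
binning, strain pairing and the terminal alignment view."""

import numpy as np
import pytest

import flds_segvir as fs
from flds_segvir import binning
from flds_segvir.binning import (SegmentClass, VirusBin, cluster_segments,
                                 fulllength_identity, global_identity,
                                 orient_coding_strand, pair_by_abundance,
                                 terminal_alignment_view, terminal_identity)
from flds_segvir.seqtools import mutate, random_seq, revcomp
from oracles import gotoh_score


@pytest.fixture(scope="module")
def truth_sequences(bipartite_truth):
    return {s.segment_id: s.sequence for s in bipartite_truth.segments}


class TestOrientation:
    def test_truth_orientation_kept(self, truth_sequences):
        for sid, seq in truth_sequences.items():
            out, flipped, low = orient_coding_strand(seq)
            assert out == seq
            assert not flipped and not low

    def test_reverse_complement_round_trip(self, truth_sequences):
        for sid, seq in truth_sequences.items():
            out, flipped, _ = orient_coding_strand(revcomp(seq))
            assert flipped
            assert out == seq

    def test_orf_free_sequence_flagged_low_confidence(self):
        seq = ("TAACCCTAATTACCCTAA" * 20)[:300]
        out, flipped, low = orient_coding_strand(seq)
        assert out == seq
        assert not flipped
        assert low


class TestTerminalIdentity:
    def test_identical_termini_score_one(self):
        s = random_seq(np.random.default_rng(0), 200)
        sc = terminal_identity(s, s)
        assert sc.identity_5 == sc.identity_3 == 1.0
        assert sc.linked

    def test_six_mismatches_in_thirty_gives_point_eight(self):
        """30-mer with 6 scattered mismatches: identity 24/30 = 0.8, and the
        aligner's score equals an independent Gotoh DP."""
        rng = np.random.default_rng(3)
        a = random_seq(rng, 30)
        b = list(a)
        for p in (2, 7, 13, 19, 24, 28):
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        b = "".join(b)
        assert global_identity(a, b) == pytest.approx(24 / 30)
        aln = binning._ALIGNER.align(a, b)[0]
        assert aln.score == gotoh_score(a, b)

    def test_aligner_score_matches_gotoh_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a = random_seq(rng, int(rng.integers(10, 40)))
            b = random_seq(rng, int(rng.integers(10, 40)))
            assert binning._ALIGNER.align(a, b)[0].score == \
                pytest.approx(gotoh_score(a, b))

    def test_cross_virus_termini_not_linked(self, bipartite_truth,
                                            truth_sequences):
        segs = bipartite_truth.segments
        for i, x in enumerate(segs):
            for y in segs[i + 1:]:
                sc = terminal_identity(x.sequence, y.sequence,
                                       x.segment_id, y.segment_id)
                assert sc.linked == (x.virus_id == y.virus_id)

    def test_short_segment_shrinks_window(self):
        sc = terminal_identity("ACGTACGTACGT", "ACGTACGTACGT", window=30)
        assert sc.identity_5 == 1.0


class TestClusterSegments:
    def test_recovers_simulated_bins_exactly(self, bipartite_truth,
                                             truth_sequences):
        """Bin assignment matches virus truth with adjusted Rand index 1."""
        from sklearn.metrics import adjusted_rand_score
        bins = cluster_segments(truth_sequences)
        assignment = {m: vb.bin_id for vb in bins for m in vb.members}
        ids = sorted(truth_sequences)
        ari = adjusted_rand_score(
            [bipartite_truth.bins[i] for i in ids],
            [assignment[i] for i in ids])
        assert ari == 1.0

    def test_no_linked_pairs_gives_singletons(self):
        rng = np.random.default_rng(11)
        seqs = {f"s{i}": random_seq(rng, 400) for i in range(5)}
        bins = cluster_segments(seqs)
        assert len(bins) == 5
        assert all(len(vb.members) == 1 for vb in bins)

    def test_order_invariance(self, truth_sequences):
        bins_a = cluster_segments(dict(truth_sequences))
        reordered = dict(reversed(list(truth_sequences.items())))
        bins_b = cluster_segments(reordered)
        assert [vb.members for vb in bins_a] == [vb.members for vb in bins_b]

    def test_raising_threshold_never_merges(self, truth_sequences):
        """Partitions refine monotonically as link_threshold rises."""
        previous = None
        for thr in (0.4, 0.5, 0.6, 0.7, 0.8, 0.95):
            bins = cluster_segments(truth_sequences, link_threshold=thr)
            parts = {m: vb.bin_id for vb in bins for m in vb.members}
            if previous is not None:
                for m1 in parts:
                    for m2 in parts:
                        if parts[m1] == parts[m2]:
                            assert previous[m1] == previous[m2]
            previous = parts

    def test_variants_grouped_into_one_class(self, truth_sequences):
        """A 2%-mutated copy of a segment lands in the same class."""
        rng = np.random.default_rng(13)
        sid = sorted(truth_sequences)[0]
        seqs = dict(truth_sequences)
        seqs[sid + "v"] = mutate(rng, seqs[sid], 0.02)
        bins = cluster_segments(seqs)
        target = next(vb for vb in bins if sid in vb.members)
        assert target.class_of(sid) == target.class_of(sid + "v")

    def test_alternative_segment_flagged(self, bipartite_truth):
        """Two divergent segment classes of similar length sharing termini
        (the RNA2/RNA2* pattern) land in one bin with the later class
        flagged as alternative."""
        virus = [s for s in bipartite_truth.segments
                 if s.virus_id == "V01"]
        rna1, rna2 = virus
        t = rna2.terminal_length
        rng = np.random.default_rng(21)
        body = random_seq(rng, len(rna2.sequence) - 2 * t)
        rna2star = rna2.sequence[:t] + body + rna2.sequence[-t:]
        seqs = {rna1.segment_id: rna1.sequence,
                rna2.segment_id: rna2.sequence,
                "V01_RNA2star": rna2star}
        orf_counts = {rna1.segment_id: len(rna1.orfs),
                      rna2.segment_id: len(rna2.orfs),
                      "V01_RNA2star": len(rna2.orfs)}
        bins = cluster_segments(seqs, orf_counts=orf_counts)
        assert len(bins) == 1
        vb = bins[0]
        assert len(vb.classes) == 3
        star_class = vb.class_of("V01_RNA2star")
        star = next(c for c in vb.classes if c.class_id == star_class)
        rna2_class = vb.class_of(rna2.segment_id)
        assert star.alternative_of == rna2_class or \
            next(c for c in vb.classes
                 if c.class_id == rna2_class).alternative_of == star_class

    def test_five_prime_only_mode_links_on_5p(self):
        rng = np.random.default_rng(31)
        term5 = random_seq(rng, 25)
        a = term5 + random_seq(rng, 900)
        b = term5 + random_seq(rng, 1400)
        both = cluster_segments({"a": a, "b": b}, require_ends="both")
        five = cluster_segments({"a": a, "b": b}, require_ends="5p")
        assert len(both) == 2
        assert len(five) == 1


class TestPairByAbundance:
    def _bin(self):
        vb = VirusBin(bin_id="b1", members=["x", "y", "z"])
        vb.classes = [SegmentClass(1, ["x"], 2000.0, 4),
                      SegmentClass(2, ["y"], 1800.0, 4),
                      SegmentClass(3, ["z"], 1500.0, 4)]
        return vb

    def test_similar_abundance_same_sample_paired(self):
        vb = pair_by_abundance(self._bin(),
                               {"x": 1000.0, "y": 1100.0, "z": 64000.0},
                               {"x": "H5", "y": "H5", "z": "H5"})
        assert vb.strain_pairs == [("x", "y")]
        assert vb.unpaired == ["z"]

    def test_fivefold_ratio_not_paired(self):
        vb = pair_by_abundance(self._bin(),
                               {"x": 1000.0, "y": 5000.0, "z": 60000.0},
                               {"x": "H5", "y": "H5", "z": "H5"})
        assert vb.strain_pairs == []

    def test_different_samples_never_paired(self):
        vb = pair_by_abundance(self._bin(),
                               {"x": 1000.0, "y": 1000.0, "z": 900.0},
                               {"x": "H4", "y": "H5", "z": "Y66"})
        assert vb.strain_pairs == []

    def test_same_class_members_not_paired(self):
        vb = VirusBin(bin_id="b1", members=["x", "y"])
        vb.classes = [SegmentClass(1, ["x", "y"], 2000.0, 4)]
        vb = pair_by_abundance(vb, {"x": 1000.0, "y": 1000.0},
                               {"x": "H5", "y": "H5"})
        assert vb.strain_pairs == []

    def test_missing_coverage_warns_and_excludes(self):
        vb = self._bin()
        with pytest.warns(UserWarning, match="no coverage"):
            vb = pair_by_abundance(vb, {"x": 1000.0, "y": 1100.0},
                                   {"x": "H5", "y": "H5", "z": "H5"})
        assert vb.strain_pairs == [("x", "y")]

    def test_simulated_strain_pairs_recovered(self, bipartite_truth,
                                              truth_sequences):
        bins = cluster_segments(truth_sequences)
        recovered = set()
        for vb in bins:
            vb = pair_by_abundance(vb, bipartite_truth.coverages,
                                   bipartite_truth.samples)
            recovered.update(frozenset(p) for p in vb.strain_pairs)
        assert recovered == bipartite_truth.strain_pairs()


class TestTerminalAlignmentView:
    def test_identical_termini_fully_conserved(self):
        rng = np.random.default_rng(41)
        term5, term3 = random_seq(rng, 30), random_seq(rng, 30)
        seqs = {f"s{i}": term5 + random_seq(rng, 500) + term3
                for i in range(3)}
        view = terminal_alignment_view(seqs, window=30)
        assert all(c == 1.0 for c in view.conservation_5)
        assert set(view.aligned_5.values()) == {term5}
        assert ">s0|5p" in view.to_fasta()

    def test_conserved_block_matches_simulated_terminal_length(
            self, bipartite_truth, truth_sequences):
        virus = [s.segment_id for s in bipartite_truth.segments
                 if s.virus_id == "V02"]
        view = terminal_alignment_view(
            {sid: truth_sequences[sid] for sid in virus}, window=30)
        t = bipartite_truth.params.terminal_length
        assert abs(view.conserved_block_length("5p") - t) <= 2 or \
            view.conserved_block_length("5p") >= t

    def test_single_member_bin_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            terminal_alignment_view({"only": "ACGT" * 30})


class TestFullLengthIdentity:
    def test_identical_and_divergent(self):
        rng = np.random.default_rng(51)
        a = random_seq(rng, 2000)
        assert fulllength_identity(a, a) == 1.0
        assert fulllength_identity(a, random_seq(rng, 2000)) < 0.9
        assert fulllength_identity(a, mutate(rng, a, 0.02)) > 0.95
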