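"""Grouping complete segments into multipartite virus genomes.

Segments of one multisegmented RNA virus carry (nearly) identical 5' and 3'
terminal sequences on their coding strands, while termini of unrelated
viruses are dissimilar.  Binning therefore:

1. orients every complete segment to its coding strand (the strand with the
   greater total forward-frame ORF length);
2. scores all segment pairs by global-alignment identity of their 5' and 3'
   terminal windows;
3. single-linkage clusters pairs whose termini both (or, optionally, whose
   5' termini only) exceed the link threshold — each cluster is one virus
   bin;
4. inside a bin, groups near-identical members into segment classes, flags
   homologous alternative classes (the RNA2/RNA2* pattern), and pairs
   segments of different classes into virus strains by same-sample
   co-occurrence and similar abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align

from .annotate import find_orfs
from .seqtools import revcomp


@dataclass(frozen=True)
class TerminalPairScore:
    segment_a: str
    segment_b: str
    identity_5: float
    identity_3: float
    linked: bool


@dataclass
class SegmentClass:
    class_id: int
    members: list[str]
    median_length: float
    orf_count: float            # median ORF count over members
    alternative_of: int | None = None


@dataclass
class VirusBin:
    bin_id: str
    members: list[str]
    classes: list[SegmentClass] = field(default_factory=list)
    strain_pairs: list[tuple[str, str]] = field(default_factory=list)
    unpaired: list[str] = field(default_factory=list)

    def class_of(self, segment_id: str) -> int | None:
        for c in self.classes:
            if segment_id in c.members:
                return c.class_id
        return None


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


_ALIGNER = _aligner()


def global_identity(a: str, b: str) -> float:
    """Identity of the best global alignment: matches / alignment columns."""
    if not a or not b:
        return 0.0
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    total = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / total if total else 0.0


def fulllength_identity(a: str, b: str) -> float:
    """Fast whole-sequence identity via edit distance (edlib, NW task).

    Identity is 1 - d / max(len); a conservative proxy adequate for the
    >= 0.9 variant-grouping rule on multi-kb segments.
    """
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return max(0.0, 1.0 - d / max(len(a), len(b)))


def orient_coding_strand(sequence: str, min_orf_len: int = 150):
    """Pick the coding strand: the orientation whose three forward frames
    carry the greater total ORF length (genetic code 11).

    Returns ``(oriented_sequence, flipped, low_confidence)``; ties keep the
    input orientation and are flagged low-confidence when no ORFs exist on
    either strand.
    """
    def score(seq):
        lens = [o.end - o.start
                for o in find_orfs(seq, min_orf_len=min_orf_len)]
        return (sum(lens), max(lens, default=0))

    fwd = score(sequence)
    rc = revcomp(sequence)
    rev = score(rc)
    if rev > fwd:
        return rc, True, False
    return sequence, False, (fwd[0] == 0 and rev[0] == 0)


def terminal_identity(seq_a: str, seq_b: str, id_a: str = "a", id_b: str = "b",
                      window: int = 30,
                      link_threshold: float = 0.6,
                      require_ends: str = "both") -> TerminalPairScore:
    """Score terminal conservation between two coding-strand segments.

    The first ``window`` nt (5') and last ``window`` nt (3') are globally
    aligned; identity = matches / alignment columns.  Segments shorter than
    the window shrink it to their length.
    """
    w = min(window, len(seq_a), len(seq_b))
    id5 = global_identity(seq_a[:w], seq_b[:w])
    id3 = global_identity(seq_a[-w:], seq_b[-w:])
    if require_ends == "5p":
        linked = id5 >= link_threshold
    else:
        linked = min(id5, id3) >= link_threshold
    return TerminalPairScore(segment_a=id_a, segment_b=id_b,
                             identity_5=id5, identity_3=id3, linked=linked)


def score_all_pairs(sequences: dict[str, str], window: int = 30,
                    link_threshold: float = 0.6,
                    require_ends: str = "both") -> list[TerminalPairScore]:
    ids = sorted(sequences)
    return [terminal_identity(sequences[a], sequences[b], a, b,
                              window=window, link_threshold=link_threshold,
                              require_ends=require_ends)
            for i, a in enumerate(ids) for b in ids[i + 1:]]


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def cluster_segments(sequences: dict[str, str],
                     scores: list[TerminalPairScore] | None = None,
                     window: int = 30, link_threshold: float = 0.6,
                     require_ends: str = "both",
                     variant_identity: float = 0.9,
                     length_ratio_tol: float = 0.1,
                     orf_counts: dict[str, int] | None = None,
                     min_orf_len: int = 150) -> list[VirusBin]:
    """Single-linkage clustering of complete segments by shared termini.

    Segments are processed in sorted-id order so the result is invariant to
    input order.  Within each bin, members with full-length identity >=
    ``variant_identity`` form one segment class; distinct classes of similar
    length and ORF count (the "gene content" guard) are flagged as
    alternative segments of one another.
    """
    ids = sorted(sequences)
    if scores is None:
        scores = score_all_pairs(sequences, window=window,
                                 link_threshold=link_threshold,
                                 require_ends=require_ends)
    uf = _UnionFind(ids)
    for sc in sorted(scores, key=lambda s: (s.segment_a, s.segment_b)):
        if sc.linked:
            uf.union(sc.segment_a, sc.segment_b)
    groups: dict[str, list[str]] = {}
    for sid in ids:
        groups.setdefault(uf.find(sid), []).append(sid)

    if orf_counts is None:
        orf_counts = {sid: len(find_orfs(sequences[sid],
                                         min_orf_len=min_orf_len))
                      for sid in ids}

    bins: list[VirusBin] = []
    for n, root in enumerate(sorted(groups), start=1):
        members = sorted(groups[root])
        vb = VirusBin(bin_id=f"bin{n:02d}", members=members)
        # variant grouping into segment classes
        cuf = _UnionFind(members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if fulllength_identity(sequences[a],
                                       sequences[b]) >= variant_identity:
                    cuf.union(a, b)
        croots: dict[str, list[str]] = {}
        for m in members:
            croots.setdefault(cuf.find(m), []).append(m)
        for ci, cr in enumerate(sorted(croots), start=1):
            ms = sorted(croots[cr])
            vb.classes.append(SegmentClass(
                class_id=ci, members=ms,
                median_length=float(np.median([len(sequences[m])
                                               for m in ms])),
                orf_count=float(np.median([orf_counts[m] for m in ms]))))
        # alternative-segment flags (RNA2 / RNA2* pattern): a later class
        # homologous in length and gene content to an earlier one
        for i, ca in enumerate(vb.classes):
            for cb in vb.classes[i + 1:]:
                if cb.alternative_of is not None:
                    continue
                longer = max(ca.median_length, cb.median_length)
                if (abs(ca.median_length - cb.median_length) / longer
                        < length_ratio_tol
                        and abs(ca.orf_count - cb.orf_count) <= 1):
                    cb.alternative_of = ca.class_id
        bins.append(vb)
    return bins


def pair_by_abundance(vbin: VirusBin, coverages: dict[str, float],
                      samples: dict[str, str],
                      max_log2_ratio: float = 1.0) -> VirusBin:
    """Assign strain-level segment pairs inside one bin.

    Segments of *different* classes are paired when they co-occur in the
    same sample and |log2 coverage ratio| <= ``max_log2_ratio``; greedy
    matching from the most similar ratio down, each segment in at most one
    pair.  Segments without coverage are excluded with a warning; unpaired
    members are reported on the bin.
    """
    usable = []
    for m in vbin.members:
        if m not in coverages or coverages[m] is None:
            warnings.warn(f"segment {m} has no coverage; excluded from "
                          f"strain pairing")
            continue
        usable.append(m)
    candidates = []
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            if samples.get(a) != samples.get(b):
                continue
            if vbin.class_of(a) == vbin.class_of(b):
                continue
            ratio = abs(float(np.log2(coverages[a] / coverages[b])))
            if ratio <= max_log2_ratio:
                candidates.append((ratio, a, b))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    paired: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for ratio, a, b in candidates:
        if a in paired or b in paired:
            continue
        pairs.append((a, b))
        paired.update((a, b))
    vbin.strain_pairs = pairs
    vbin.unpaired = [m for m in vbin.members if m not in paired]
    return vbin


@dataclass
class TerminalAlignmentView:
    """Center-star MSA of member termini with column-wise conservation."""

    window: int
    aligned_5: dict[str, str]
    aligned_3: dict[str, str]
    conservation_5: list[float]
    conservation_3: list[float]

    def to_fasta(self) -> str:
        out = []
        for label, block in (("5p", self.aligned_5), ("3p", self.aligned_3)):
            for sid, row in block.items():
                out.append(f">{sid}|{label}\n{row}")
        return "\n".join(out) + "\n"

    def conserved_block_length(self, side: str = "5p",
                               min_conservation: float = 1.0) -> int:
        cons = self.conservation_5 if side == "5p" else self.conservation_3
        best = run = 0
        for c in cons:
            run = run + 1 if c >= min_conservation else 0
            best = max(best, run)
        return best


def _center_star(windows: dict[str, str]) -> tuple[dict[str, str], list[float]]:
    ids = sorted(windows)
    star_id = max(ids, key=lambda s: (len(windows[s]), s))
    star = windows[star_id]
    # per-star-position insertions needed by each member
    pair_data = {}
    max_ins = [0] * (len(star) + 1)
    for sid in ids:
        if sid == star_id:
            pair_data[sid] = ([0] * (len(star) + 1), star)
            continue
        aln = _ALIGNER.align(star, windows[sid])[0]
        s_row, m_row = str(aln[0]), str(aln[1])
        ins = [0] * (len(star) + 1)
        cols = []               # (star_pos or insertion, member char)
        spos = 0
        for sc, mc in zip(s_row, m_row):
            if sc == "-":
                ins[spos] += 1
            else:
                spos += 1
            cols.append((sc, mc))
        pair_data[sid] = (ins, (s_row, m_row))
        for i, v in enumerate(ins):
            max_ins[i] = max(max_ins[i], v)
    aligned: dict[str, str] = {}
    for sid in ids:
        ins, rows = pair_data[sid]
        if sid == star_id:
            out = []
            for i, ch in enumerate(star):
                out.append("-" * max_ins[i])
                out.append(ch)
            out.append("-" * max_ins[len(star)])
            aligned[sid] = "".join(out)
            continue
        s_row, m_row = rows
        out = []
        spos = 0
        pending = []
        for sc, mc in zip(s_row, m_row):
            if sc == "-":
                pending.append(mc)
            else:
                out.append("".join(pending).rjust(max_ins[spos], "-"))
                pending = []
                out.append(mc)
                spos += 1
        out.append("".join(pending).rjust(max_ins[len(star)], "-"))
        aligned[sid] = "".join(out)
    width = len(next(iter(aligned.values())))
    conservation = []
    for col in range(width):
        bases = [aligned[sid][col] for sid in ids]
        counts: dict[str, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        conservation.append(max(counts.values()) / len(bases))
    return aligned, conservation


def terminal_alignment_view(sequences: dict[str, str],
                            window: int = 30) -> TerminalAlignmentView:
    """Aligned view of the 5' and 3' terminal windows of bin members.

    Raises ValueError for bins with fewer than two members.
    """
    if len(sequences) < 2:
        raise ValueError(
            "terminal alignment view needs at least 2 bin members")
    w = min([window] + [len(s) for s in sequences.values()])
    five = {sid: s[:w] for sid, s in sequences.items()}
    three = {sid: s[-w:] for sid, s in sequences.items()}
    a5, c5 = _center_star(five)
    a3, c3 = _center_star(three)
    return TerminalAlignmentView(window=w, aligned_5=a5, aligned_3=a3,
                                 conservation_5=c5, conservation_3=c3)
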