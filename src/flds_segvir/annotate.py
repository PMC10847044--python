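"""Segment annotation: ORF calling (genetic code 11), Shine-Dalgarno motif
detection, RdRP catalytic-motif scanning and a hydropathy transmembrane
flag.

The SD scanner is a plain consensus matcher (``AGGAGG``, >= 4 consecutive
matching bases, spacer 4-14 nt before the start codon) and its hits are
"SD-like" evidence, not a trained ribosome-binding-site model.  The RdRP
scan covers the diagnostic catalytic motifs: B (``SGxxxT``), C (``GDD``)
and the motif-A aspartate pair, including the extended arrangement where
the partner aspartate (Asp*) lies 12-14 residues after the first instead of
the canonical 4-5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqtools import START_CODONS, STOP_CODONS, translate_cds

SD_CONSENSUS = "AGGAGG"
SD_SPACER_RANGE = (4, 14)

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

_VALID_NT = set("ACGTN")


class SequenceFormatError(ValueError):
    """Sequence contains characters outside A/C/G/T/N."""


@dataclass(frozen=True)
class SdHit:
    motif: str                # matched run of consensus bases
    spacer: int               # nt between last matched base and start codon
    match_len: int


@dataclass(frozen=True)
class TmdResult:
    flag: bool
    best_start: int | None
    best_score: float


@dataclass(frozen=True)
class MotifHit:
    motif: str                # 'A' | 'B' | 'C'
    position: int             # 0-based residue index of the motif start
    matched: str
    ordered: bool = False     # B only: a C hit lies 10-60 residues downstream
    spacing: int | None = None  # A only: first Asp -> partner Asp distance
    a_class: str | None = None  # A only: 'canonical' (4-5) | 'extended' (12-14)


@dataclass
class OrfAnnotation:
    segment_id: str
    start: int                # 0-based half-open on the coding strand
    end: int
    strand: str
    frame: int
    start_codon: str
    open_3p: bool
    protein: str
    sd: SdHit | None = None
    tmd: TmdResult | None = None
    rdrp_hits: tuple[MotifHit, ...] = ()

    @property
    def has_ordered_rdrp(self) -> bool:
        return any(h.motif == "B" and h.ordered for h in self.rdrp_hits)


def find_orfs(sequence: str, min_orf_len: int = 150,
              segment_id: str = "", include_open: bool = True
              ) -> list[OrfAnnotation]:
    """Maximal ORFs on the three forward frames of the coding strand.

    Start codons ATG/GTG/TTG; an ORF runs from the first start codon after
    the previous in-frame stop to (and including) the next stop codon, so
    nested starts are suppressed (longest ORF per stop).  An ORF reaching
    the segment end without a stop is reported with ``open_3p`` set.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise SequenceFormatError(
            f"sequence contains non-ACGTN characters: {sorted(bad)}")
    orfs: list[OrfAnnotation] = []
    n = len(seq)
    for frame in range(3):
        pending: int | None = None
        i = frame
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if codon in STOP_CODONS:
                if pending is not None and (i + 3 - pending) >= min_orf_len:
                    nt = seq[pending:i + 3]
                    orfs.append(OrfAnnotation(
                        segment_id=segment_id, start=pending, end=i + 3,
                        strand="+", frame=frame, start_codon=seq[pending:pending + 3],
                        open_3p=False, protein=translate_cds(nt)))
                pending = None
            elif pending is None and codon in START_CODONS:
                pending = i
            i += 3
        if include_open and pending is not None:
            end = pending + 3 * ((n - pending) // 3)
            if end - pending >= min_orf_len:
                nt = seq[pending:end]
                orfs.append(OrfAnnotation(
                    segment_id=segment_id, start=pending, end=end,
                    strand="+", frame=frame, start_codon=seq[pending:pending + 3],
                    open_3p=True, protein=translate_cds(nt)))
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def detect_sd(sequence: str, orf_start: int, consensus: str = SD_CONSENSUS,
              min_match: int = 4,
              spacer_range: tuple[int, int] = SD_SPACER_RANGE
              ) -> SdHit | None:
    """Best ungapped SD-consensus match upstream of an ORF start.

    The consensus is slid over the upstream region; for every placement the
    maximal run of consecutive matching bases is found.  A hit requires a
    run of at least ``min_match`` bases whose last base sits ``spacer``
    (4-14 by default) nt before the start codon.  The longest run wins;
    ties prefer the shorter spacer.
    """
    lo, hi = spacer_range
    alen = len(consensus)
    best: SdHit | None = None
    a_min = max(0, orf_start - (hi + 2 * alen))
    for a in range(a_min, orf_start):
        run_start = None
        run_len = 0
        for t in range(alen):
            pos = a + t
            if pos >= orf_start or pos >= len(sequence):
                break
            if sequence[pos] == consensus[t]:
                if run_start is None:
                    run_start = t
                run_len += 1
                if run_len >= min_match:
                    spacer = orf_start - (pos + 1)
                    if lo <= spacer <= hi:
                        cand = SdHit(
                            motif=consensus[run_start:run_start + run_len],
                            spacer=spacer, match_len=run_len)
                        if (best is None or cand.match_len > best.match_len
                                or (cand.match_len == best.match_len
                                    and cand.spacer < best.spacer)):
                            best = cand
            else:
                run_start = None
                run_len = 0
    return best


def scan_rdrp_motifs(protein: str) -> list[MotifHit]:
    """Scan a protein for the RdRP catalytic motifs A, B and C.

    All GDD occurrences are motif C hits.  SGxxxT occurrences are motif B
    hits, flagged ``ordered`` when a C hit lies 10-60 residues downstream.
    Motif-A candidates are aspartates 80-200 residues upstream of a C hit
    whose partner aspartate lies 4-5 (canonical) or 12-14 (extended,
    HsRV-like) residues downstream.  Non-standard residues never match.
    """
    p = protein.upper()
    n = len(p)
    c_hits = [i for i in range(n - 2) if p[i:i + 3] == "GDD"]
    b_hits = [i for i in range(n - 5)
              if p[i] == "S" and p[i + 1] == "G" and p[i + 5] == "T"]
    hits: list[MotifHit] = []
    a_seen: set[int] = set()
    for c in c_hits:
        for d in range(max(0, c - 200), c - 79):
            if p[d] != "D" or d in a_seen:
                continue
            partner = None
            for off in (4, 5):
                if d + off < n and p[d + off] == "D":
                    partner = (off, "canonical")
                    break
            if partner is None:
                for off in (12, 13, 14):
                    if d + off < n and p[d + off] == "D":
                        partner = (off, "extended")
                        break
            if partner is not None:
                a_seen.add(d)
                hits.append(MotifHit(motif="A", position=d,
                                     matched=p[d:d + partner[0] + 1],
                                     spacing=partner[0], a_class=partner[1]))
    for b in b_hits:
        ordered = any(10 <= c - b <= 60 for c in c_hits)
        hits.append(MotifHit(motif="B", position=b, matched=p[b:b + 6],
                             ordered=ordered))
    for c in c_hits:
        hits.append(MotifHit(motif="C", position=c, matched="GDD"))
    hits.sort(key=lambda h: (h.position, h.motif))
    return hits


def flag_tmd(protein: str, window: int = 19,
             threshold: float = 1.6) -> TmdResult:
    """Transmembrane flag: any ``window``-residue stretch with mean
    Kyte-Doolittle hydropathy >= ``threshold``.

    Residues outside the 20-letter alphabet score 0.  Proteins shorter than
    the window are never flagged.
    """
    if len(protein) < window:
        return TmdResult(flag=False, best_start=None, best_score=float("-inf"))
    values = np.array([KYTE_DOOLITTLE.get(aa, 0.0)
                       for aa in protein.upper()])
    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")
    best = int(np.argmax(means))
    return TmdResult(flag=bool(means[best] >= threshold), best_start=best,
                     best_score=float(means[best]))


def annotate_segment(sequence: str, segment_id: str = "",
                     min_orf_len: int = 150, sd_min_match: int = 4,
                     tmd_window: int = 19, tmd_threshold: float = 1.6
                     ) -> list[OrfAnnotation]:
    """ORFs plus SD, TMD and RdRP-motif evidence for one oriented segment."""
    orfs = find_orfs(sequence, min_orf_len=min_orf_len,
                     segment_id=segment_id)
    out = []
    for o in orfs:
        sd = detect_sd(sequence, o.start, min_match=sd_min_match)
        tmd = flag_tmd(o.protein, window=tmd_window, threshold=tmd_threshold)
        rdrp = tuple(scan_rdrp_motifs(o.protein)) if len(o.protein) >= 30 \
            else ()
        out.append(OrfAnnotation(
            segment_id=o.segment_id, start=o.start, end=o.end,
            strand=o.strand, frame=o.frame, start_codon=o.start_codon,
            open_3p=o.open_3p, protein=o.protein, sd=sd, tmd=tmd,
            rdrp_hits=rdrp))
    return out


@dataclass
class BinAnnotation:
    bin_id: str
    orfs: dict[str, list[OrfAnnotation]]
    rdrp_segment: str | None
    orf_count: int
    sd_fraction: float
    gff3: str = field(repr=False, default="")
    protein_fasta: str = field(repr=False, default="")


def annotate_bin(bin_id: str, sequences: dict[str, str],
                 min_orf_len: int = 150, sd_min_match: int = 4,
                 tmd_window: int = 19, tmd_threshold: float = 1.6
                 ) -> BinAnnotation:
    """Annotate all members of one virus bin.

    The member carrying an ORF with an ordered B-C motif pair is labelled
    the RdRP segment (most ordered hits wins; ties break on segment id).
    GFF3 coordinates are 1-based inclusive per the format spec.
    """
    per_seg: dict[str, list[OrfAnnotation]] = {}
    for sid in sorted(sequences):
        per_seg[sid] = annotate_segment(
            sequences[sid], segment_id=sid, min_orf_len=min_orf_len,
            sd_min_match=sd_min_match, tmd_window=tmd_window,
            tmd_threshold=tmd_threshold)
    rdrp_segment = None
    best_count = 0
    for sid in sorted(per_seg):
        count = sum(1 for o in per_seg[sid] for h in o.rdrp_hits
                    if h.motif == "B" and h.ordered)
        if count > best_count:
            best_count = count
            rdrp_segment = sid
    all_orfs = [o for orfs in per_seg.values() for o in orfs]
    n_orfs = len(all_orfs)
    sd_fraction = (sum(1 for o in all_orfs if o.sd is not None) / n_orfs
                   if n_orfs else 0.0)
    gff_lines = ["##gff-version 3"]
    fasta_lines = []
    for sid in sorted(per_seg):
        gff_lines.append(f"##sequence-region {sid} 1 {len(sequences[sid])}")
        for k, o in enumerate(per_seg[sid], start=1):
            oid = f"{sid}.orf{k:02d}"
            attrs = [f"ID={oid}"]
            if o.sd is not None:
                attrs.append(f"sd_like={o.sd.motif}")
                attrs.append(f"sd_spacer={o.sd.spacer}")
            if o.tmd is not None and o.tmd.flag:
                attrs.append("tmd=1")
            if o.has_ordered_rdrp:
                attrs.append("rdrp_motifs=ordered")
            if o.open_3p:
                attrs.append("partial=3p")
            gff_lines.append("\t".join([
                sid, "flds-segvir", "CDS", str(o.start + 1), str(o.end),
                ".", o.strand, "0", ";".join(attrs)]))
            fasta_lines.append(f">{oid}\n{o.protein}")
    return BinAnnotation(
        bin_id=bin_id, orfs=per_seg, rdrp_segment=rdrp_segment,
        orf_count=n_orfs, sd_fraction=sd_fraction,
        gff3="\n".join(gff_lines) + "\n",
        protein_fasta="\n".join(fasta_lines) + "\n" if fasta_lines else "")
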