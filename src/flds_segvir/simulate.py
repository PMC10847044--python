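"""Synthetic multipartite dsRNA virome and FLDS-style read-library simulator.

The generator emulates the statistical structure the downstream pipeline
relies on:

* several viruses, each with 2-3 genome segments that share (nearly)
  identical 5'/3' terminal sequences on the coding strand, while termini of
  different viruses are kept dissimilar (positional identity <= a cap);
* polycistronic coding strands: non-overlapping ORFs under genetic code 11,
  most of them preceded by a planted Shine-Dalgarno ``AGGAGG`` motif at a
  4-14 nt spacer;
* FLDS library construction: each molecule copy is fragmented into ~1.5 kb
  pieces whose boundaries are clipped at the true segment ends, a U2 adapter
  is ligated to the 3' end of both strands of every fragment, and reads are
  taken from both strands and truncated to the read length.  Reads covering
  a true terminus therefore terminate exactly at it — the read-stop signal
  the terminus caller detects.

Every draw goes through one :class:`numpy.random.Generator` seeded from
``SimParams.seed``, so identical parameters give byte-identical output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqtools import (
    CODONS_BY_AA,
    SENSE_CODONS,
    START_CODONS,
    STOP_CODONS,
    hamming_identity,
    mutate,
    random_seq,
    revcomp,
)

#: adapter ligated to the 3' end of fragmented dsRNA strands (U2)
U2_ADAPTER = "GACGTAAGAACGTCGCACCA"

SD_CONSENSUS = "AGGAGG"
SD_SPACER_RANGE = (4, 14)  # nt between last SD base and the start codon


class InfeasibleParams(ValueError):
    """Raised when the requested genome structure cannot be generated."""


def _as_range(value, name: str) -> tuple:
    if np.isscalar(value):
        return (value, value)
    lo, hi = value
    if lo > hi:
        raise InfeasibleParams(f"{name}: empty range {value!r}")
    return (lo, hi)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated virome.

    Ranges are inclusive ``(lo, hi)`` tuples; scalars are accepted and
    treated as degenerate ranges.
    """

    n_viruses: int = 3
    segments_per_virus: tuple = (2, 3)
    segment_length: tuple = (1500, 6000)
    terminal_length: int = 25
    terminal_identity_within: float = 1.0
    terminal_identity_between: float = 0.3
    orfs_per_segment: tuple = (3, 5)
    sd_fraction: float = 0.95
    fragment_length_mean: int = 1500
    fragment_length_sd: float | None = None  # default 20% of the mean
    min_fragment_length: int = 50
    read_length: int = 300
    depth_per_virus: tuple = (100.0, 300.0)
    error_rate: float = 0.005
    indel_rate: float = 0.0
    terminal_capture_rate: float = 1.0
    plant_rdrp: bool = True
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "segments_per_virus",
                           _as_range(self.segments_per_virus, "segments_per_virus"))
        object.__setattr__(self, "segment_length",
                           _as_range(self.segment_length, "segment_length"))
        object.__setattr__(self, "orfs_per_segment",
                           _as_range(self.orfs_per_segment, "orfs_per_segment"))
        object.__setattr__(self, "depth_per_virus",
                           _as_range(self.depth_per_virus, "depth_per_virus"))
        for name in ("terminal_identity_within", "terminal_identity_between",
                     "sd_fraction", "error_rate", "indel_rate",
                     "terminal_capture_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InfeasibleParams(f"{name} must be in [0,1], got {v}")
        if self.n_viruses < 1 or self.n_samples < 1:
            raise InfeasibleParams("n_viruses and n_samples must be positive")
        if self.terminal_length < 10:
            raise InfeasibleParams("terminal_length must be >= 10")
        if self.terminal_length >= self.segment_length[0] / 2:
            raise InfeasibleParams(
                "terminal_length must be < min segment length / 2")
        if min(self.segment_length) <= 0 or self.read_length <= 0:
            raise InfeasibleParams("lengths must be positive")
        if min(self.depth_per_virus) <= 0:
            raise InfeasibleParams("depths must be positive")
        if self.fragment_length_mean <= 0 or self.min_fragment_length <= 0:
            raise InfeasibleParams("fragment lengths must be positive")

    @property
    def frag_sd(self) -> float:
        return (self.fragment_length_sd
                if self.fragment_length_sd is not None
                else 0.2 * self.fragment_length_mean)


@dataclass(frozen=True)
class TruthOrf:
    start: int        # 0-based, on the coding strand
    end: int          # exclusive, includes the stop codon
    strand: str = "+"
    has_sd: bool = False
    sd_spacer: int | None = None
    is_rdrp: bool = False


@dataclass
class TruthSegment:
    segment_id: str
    virus_id: str
    sample_id: str
    sequence: str
    orfs: tuple[TruthOrf, ...]
    depth: float
    terminal_length: int

    @property
    def termini(self) -> tuple[int, int]:
        """True 5' and 3' end positions (0-based half-open on the contig)."""
        return (0, len(self.sequence))


@dataclass
class TruthSet:
    """Simulator ground truth: genomes, termini, ORFs and bin memberships."""

    segments: list[TruthSegment] = field(default_factory=list)
    params: SimParams | None = None

    @property
    def bins(self) -> dict[str, str]:
        return {s.segment_id: s.virus_id for s in self.segments}

    @property
    def coverages(self) -> dict[str, float]:
        return {s.segment_id: s.depth for s in self.segments}

    @property
    def samples(self) -> dict[str, str]:
        return {s.segment_id: s.sample_id for s in self.segments}

    def by_id(self, segment_id: str) -> TruthSegment:
        for s in self.segments:
            if s.segment_id == segment_id:
                return s
        raise KeyError(segment_id)

    def strain_pairs(self, max_log2_ratio: float = 1.0) -> set[frozenset]:
        """Same-virus, same-sample segment pairs with similar abundance.

        For bipartite viruses this is the unique RNA1/RNA2 pairing the
        co-abundance step is expected to recover.
        """
        pairs: set[frozenset] = set()
        by_virus: dict[str, list[TruthSegment]] = {}
        for s in self.segments:
            by_virus.setdefault(s.virus_id, []).append(s)
        for members in by_virus.values():
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    if a.sample_id != b.sample_id:
                        continue
                    if abs(np.log2(a.depth / b.depth)) <= max_log2_ratio:
                        pairs.add(frozenset((a.segment_id, b.segment_id)))
        return pairs


@dataclass
class SimRead:
    read_id: str
    sequence: str
    quality: str
    mate: int               # 1 or 2
    segment_id: str
    strand: str             # strand of the segment the read derives from
    start: int              # true source span on the segment (0-based)
    end: int                # exclusive
    adapter_len: int        # adapter bases present in the read


@dataclass
class ReadLibrary:
    reads: list[SimRead] = field(default_factory=list)

    def pairs(self):
        r1 = [r for r in self.reads if r.mate == 1]
        r2 = [r for r in self.reads if r.mate == 2]
        return r1, r2

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"read_id": r.read_id, "mate": r.mate, "segment_id": r.segment_id,
              "strand": r.strand, "start": r.start, "end": r.end,
              "adapter_len": r.adapter_len} for r in self.reads])


# ---------------------------------------------------------------------------
# genome construction


def sd_like_hit(seq: str, orf_start: int, min_match: int = 4) -> bool:
    """Generator-side twin of the SD scan: is there a >=min_match consecutive
    match to the consensus upstream of ``orf_start`` at a valid spacer?"""
    lo, hi = SD_SPACER_RANGE
    alen = len(SD_CONSENSUS)
    for a in range(max(0, orf_start - (hi + alen + alen)), orf_start):
        run = 0
        for t in range(alen):
            pos = a + t
            if pos >= orf_start or pos >= len(seq):
                break
            if seq[pos] == SD_CONSENSUS[t]:
                run += 1
                if run >= min_match:
                    spacer = orf_start - (pos + 1)
                    if lo <= spacer <= hi:
                        return True
            else:
                run = 0
    return False


def _draw_virus_termini(rng, n_viruses, tlen, max_between, max_tries=20000):
    """Rejection-sample per-virus 5'/3' terminal sequences so that pairwise
    ungapped identity between viruses stays <= max_between on each side."""
    fives: list[str] = []
    threes: list[str] = []
    for side_list in (fives, threes):
        for _ in range(n_viruses):
            for attempt in range(max_tries):
                cand = random_seq(rng, tlen)
                if all(hamming_identity(cand, t) <= max_between
                       for t in side_list):
                    side_list.append(cand)
                    break
            else:
                raise InfeasibleParams(
                    f"could not draw {n_viruses} termini with pairwise "
                    f"identity <= {max_between} at length {tlen}")
    return fives, threes


def _orf_nt(rng, n_nt: int, plant_rdrp: bool) -> str:
    """A coding sequence of n_nt bases (multiple of 3, incl. stop codon)."""
    n_codons = n_nt // 3
    start = START_CODONS[rng.choice(len(START_CODONS), p=[0.7, 0.2, 0.1])]
    stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    n_internal = n_codons - 2
    if plant_rdrp:
        protein = _rdrp_protein(rng, n_internal)
        internal = "".join(
            CODONS_BY_AA[aa][rng.integers(0, len(CODONS_BY_AA[aa]))]
            for aa in protein)
    else:
        idx = rng.integers(0, len(SENSE_CODONS), size=n_internal)
        internal = "".join(SENSE_CODONS[i] for i in idx)
    return start + internal + stop


_AAS = "ACDEFGHIKLMNPQRSTVWY"


def _rdrp_protein(rng, n: int) -> str:
    """Random protein carrying the diagnostic RdRP motifs.

    Motif C (GDD) sits ~60% into the chain; motif B (SGxxxT) 25 residues
    before it; motif A: an Asp 100 residues before motif C with the partner
    Asp* 13 residues downstream — the extended (HsRV-like) arrangement.
    """
    if n < 140:
        raise InfeasibleParams("RdRP ORF too short to carry motifs")
    aas = [_AAS[i] for i in rng.integers(0, len(_AAS), size=n)]
    c = max(120, int(0.6 * n))
    c = min(c, n - 3)
    aas[c:c + 3] = list("GDD")
    b = c - 25
    aas[b] = "S"
    aas[b + 1] = "G"
    aas[b + 5] = "T"
    a = c - 100
    aas[a] = "D"
    aas[a + 13] = "D"
    return "".join(aas)


def _build_segment(rng, length: int, term5: str, term3: str, n_orfs: int,
                   sd_fraction: float, rdrp_orf: int | None):
    """Assemble one coding-strand segment; returns (sequence, orfs)."""
    tlen5, tlen3 = len(term5), len(term3)
    pre_gap_min = 24           # owns the SD window of SD-free ORFs
    overhead = pre_gap_min + len(SD_CONSENSUS) + SD_SPACER_RANGE[1]
    core = length - tlen5 - tlen3
    # ORF length floors: 180 nt, except 480 nt for the RdRP ORF so the
    # planted catalytic motifs (A ... B ... C) fit with realistic spacing
    lens = [480 if i == rdrp_orf else 180 for i in range(n_orfs)]
    pool = core - sum(lens) - n_orfs * overhead - 10
    if pool < 0:
        raise InfeasibleParams(
            f"{n_orfs} ORFs do not fit in a {length} nt segment")
    # split most of the spare budget over the ORFs (Dirichlet weights) so
    # segments come out gene-dense, as in polycistronic bacterial
    # ribovirus genomes; the remainder becomes intergenic/UTR filler
    weights = rng.dirichlet(np.full(n_orfs, 2.0))
    for i in range(n_orfs):
        add = min(1800, 3 * int(weights[i] * pool / 3))
        lens[i] += add
    pool = core - sum(lens) - n_orfs * overhead - 10

    has_sd = [bool(rng.random() < sd_fraction) for _ in range(n_orfs)]
    spacers = [int(rng.integers(SD_SPACER_RANGE[0], SD_SPACER_RANGE[1] + 1))
               for _ in range(n_orfs)]

    parts = [term5]
    cursor = tlen5
    orfs = []
    spare = pool + 10  # leftover nt distributed over gaps and the tail
    for i in range(n_orfs):
        extra = int(rng.integers(0, spare + 1))
        spare -= extra
        gap = pre_gap_min + extra
        if has_sd[i]:
            sp = spacers[i]
            pre = random_seq(rng, gap)
            # layout: pre | AGGAGG | spacer | ORF ; last 3 spacer bases are an
            # in-frame stop so the planted start is the maximal ORF start
            spacer_seq = random_seq(rng, sp - 3) + "TAA"
            block = pre + SD_CONSENSUS + spacer_seq
        else:
            pre = random_seq(rng, gap + len(SD_CONSENSUS) +
                             spacers[i] - 3) + "TAA"
            block = pre
        start = cursor + len(block)
        # SD-free ORFs: resample the upstream window until no chance SD-like
        # motif remains, so the truth label matches the planted signal
        if not has_sd[i]:
            attempt = 0
            while sd_like_hit(block, len(block)) and attempt < 200:
                block = (random_seq(rng, len(block) - 3) + "TAA")
                attempt += 1
        orf_seq = _orf_nt(rng, lens[i], plant_rdrp=(i == rdrp_orf))
        parts.append(block)
        parts.append(orf_seq)
        orfs.append(TruthOrf(start=start, end=start + lens[i], strand="+",
                             has_sd=has_sd[i],
                             sd_spacer=spacers[i] if has_sd[i] else None,
                             is_rdrp=(i == rdrp_orf)))
        cursor = start + lens[i]

    tail = length - tlen3 - cursor
    if tail < 0:
        raise InfeasibleParams("segment layout overflow")
    parts.append(random_seq(rng, tail))
    parts.append(term3)
    seq = "".join(parts)
    assert len(seq) == length
    return seq, tuple(orfs)


def simulate_virome(params: SimParams) -> TruthSet:
    """Generate virus genomes, ORF truth and per-segment coverages."""
    rng = np.random.default_rng(params.seed)
    fives, threes = _draw_virus_termini(
        rng, params.n_viruses, params.terminal_length,
        params.terminal_identity_between)

    truth = TruthSet(params=params)
    for v in range(params.n_viruses):
        virus_id = f"V{v + 1:02d}"
        sample_id = f"S{v % params.n_samples + 1}"
        n_seg = int(rng.integers(params.segments_per_virus[0],
                                 params.segments_per_virus[1] + 1))
        depth_v = float(rng.uniform(*params.depth_per_virus))
        for s in range(n_seg):
            length = int(rng.integers(params.segment_length[0],
                                      params.segment_length[1] + 1))
            n_orfs = int(rng.integers(params.orfs_per_segment[0],
                                      params.orfs_per_segment[1] + 1))
            term5, term3 = fives[v], threes[v]
            if params.terminal_identity_within < 1.0:
                term5 = mutate(rng, term5,
                               1.0 - params.terminal_identity_within)
                term3 = mutate(rng, term3,
                               1.0 - params.terminal_identity_within)
            rdrp_orf = None
            if params.plant_rdrp and s == 0:
                rdrp_orf = int(rng.integers(0, n_orfs))
            seq, orfs = _build_segment(rng, length, term5, term3, n_orfs,
                                       params.sd_fraction, rdrp_orf)
            depth = depth_v * float(2.0 ** rng.uniform(-0.3, 0.3))
            truth.segments.append(TruthSegment(
                segment_id=f"{virus_id}_RNA{s + 1}",
                virus_id=virus_id, sample_id=sample_id, sequence=seq,
                orfs=orfs, depth=depth,
                terminal_length=params.terminal_length))
    return truth


# ---------------------------------------------------------------------------
# FLDS read simulation


def _fragment_bounds(rng, a0: int, a1: int, params: SimParams) -> list[int]:
    """Cut one molecule copy spanning [a0, a1) into consecutive fragments.

    Drawn lengths are truncated-normal around the fragmentation mean; the
    terminal fragment is the remainder (floored at min_fragment_length by
    merging into its neighbour).
    """
    bounds = [a0]
    pos = a0
    lo = max(params.min_fragment_length, params.read_length)
    while pos < a1:
        ln = max(lo, int(rng.normal(params.fragment_length_mean,
                                    params.frag_sd)))
        nxt = pos + ln
        if a1 - nxt < params.min_fragment_length:
            # sub-minimum remainder: merge it into this fragment.  A larger
            # remainder becomes its own terminal fragment on the next pass —
            # possibly shorter than a read, so its reads show the U2 adapter.
            nxt = a1
        bounds.append(nxt)
        pos = nxt
    return bounds


def simulate_flds_reads(truth: TruthSet, params: SimParams,
                        molecule_ranges: dict[str, tuple[int, int]] | None = None,
                        ) -> ReadLibrary:
    """Simulate paired FLDS reads with per-read provenance.

    ``molecule_ranges`` restricts the physical molecule of a segment to a
    sub-interval of its contig (e.g. to emulate a 3'-truncated population
    whose reads never reach the annotated contig end).
    """
    if not truth.segments:
        raise ValueError("truth set is empty")
    rng = np.random.default_rng([params.seed, 7919])
    R = params.read_length
    qual = "I" * max(R, params.fragment_length_mean + len(U2_ADAPTER))
    lib = ReadLibrary()
    for seg in truth.segments:
        m0, m1 = (0, len(seg.sequence))
        if molecule_ranges and seg.segment_id in molecule_ranges:
            m0, m1 = molecule_ranges[seg.segment_id]
        L = m1 - m0
        frags_per_copy = max(1, round(L / params.fragment_length_mean))
        n_copies = max(1, int(round(seg.depth * L / (2 * R * frags_per_copy))))
        for c in range(n_copies):
            a0, a1 = m0, m1
            if params.terminal_capture_rate < 1.0:
                if rng.random() > params.terminal_capture_rate:
                    a0 = min(a1 - params.min_fragment_length,
                             a0 + int(rng.integers(1, 31)))
                if rng.random() > params.terminal_capture_rate:
                    a1 = max(a0 + params.min_fragment_length,
                             a1 - int(rng.integers(1, 31)))
            bounds = _fragment_bounds(rng, a0, a1, params)
            for k in range(len(bounds) - 1):
                fa, fb = bounds[k], bounds[k + 1]
                frag = seg.sequence[fa:fb]
                base = f"{seg.segment_id}:{c}:{k}"
                for mate, strand, src in ((1, "+", frag + U2_ADAPTER),
                                          (2, "-", revcomp(frag) + U2_ADAPTER)):
                    read = src[:R]
                    adapter_len = max(0, min(len(read) - (fb - fa),
                                             len(U2_ADAPTER)))
                    span = min(R, fb - fa)
                    if strand == "+":
                        s0, s1 = fa, fa + span
                    else:
                        s0, s1 = fb - span, fb
                    read = mutate(rng, read, params.error_rate)
                    if params.indel_rate > 0:
                        read = _apply_indels(rng, read, params.indel_rate)
                    lib.reads.append(SimRead(
                        read_id=base, sequence=read, quality=qual[:len(read)],
                        mate=mate, segment_id=seg.segment_id, strand=strand,
                        start=s0, end=s1, adapter_len=adapter_len))
    return lib


def _apply_indels(rng, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue                       # deletion
        out.append(ch)
        if rate / 2 <= r < rate:
            out.append(random_seq(rng, 1))  # insertion
    return "".join(out)


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(truth: TruthSet, reads: ReadLibrary, outdir: str) -> dict:
    """Write genomes (FASTA), reads (paired FASTQ) and truth tables (TSV).

    Output is byte-stable for a fixed seed; ``read_fixture`` reproduces the
    in-memory objects exactly.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genomes": os.path.join(outdir, "genomes.fasta"),
        "reads_1": os.path.join(outdir, "reads_1.fastq"),
        "reads_2": os.path.join(outdir, "reads_2.fastq"),
        "segments": os.path.join(outdir, "truth_segments.tsv"),
        "orfs": os.path.join(outdir, "truth_orfs.tsv"),
        "provenance": os.path.join(outdir, "provenance.tsv"),
    }
    try:
        with open(paths["genomes"], "w") as fh:
            for seg in truth.segments:
                fh.write(f">{seg.segment_id}\n{seg.sequence}\n")
        r1, r2 = reads.pairs()
        for key, recs in (("reads_1", r1), ("reads_2", r2)):
            with open(paths[key], "w") as fh:
                for r in recs:
                    fh.write(f"@{r.read_id}/{r.mate}\n{r.sequence}\n+\n"
                             f"{r.quality}\n")
        with open(paths["segments"], "w") as fh:
            fh.write("segment_id\tvirus_id\tsample_id\tlength\tdepth\t"
                     "terminal_length\n")
            for seg in truth.segments:
                fh.write(f"{seg.segment_id}\t{seg.virus_id}\t{seg.sample_id}"
                         f"\t{len(seg.sequence)}\t{seg.depth:.6f}"
                         f"\t{seg.terminal_length}\n")
        with open(paths["orfs"], "w") as fh:
            fh.write("segment_id\tstart\tend\tstrand\thas_sd\tsd_spacer\t"
                     "is_rdrp\n")
            for seg in truth.segments:
                for o in seg.orfs:
                    fh.write(f"{seg.segment_id}\t{o.start}\t{o.end}\t"
                             f"{o.strand}\t{int(o.has_sd)}\t"
                             f"{'' if o.sd_spacer is None else o.sd_spacer}\t"
                             f"{int(o.is_rdrp)}\n")
        with open(paths["provenance"], "w") as fh:
            fh.write("read_id\tmate\tsegment_id\tstrand\tstart\tend\t"
                     "adapter_len\n")
            for r in reads.reads:
                fh.write(f"{r.read_id}\t{r.mate}\t{r.segment_id}\t{r.strand}"
                         f"\t{r.start}\t{r.end}\t{r.adapter_len}\n")
    except OSError as exc:
        raise OSError(f"failed writing fixture under {outdir}: {exc}") from exc
    return paths


def read_fixture(outdir: str) -> tuple[TruthSet, ReadLibrary]:
    """Inverse of :func:`write_fixture` (modulo SimParams, which are not
    serialized with the fixture)."""
    seg_path = os.path.join(outdir, "truth_segments.tsv")
    seqs: dict[str, str] = {}
    with open(os.path.join(outdir, "genomes.fasta")) as fh:
        name = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name is not None:
                seqs[name] += line
    truth = TruthSet()
    seg_tab = pd.read_csv(seg_path, sep="\t") if os.path.getsize(seg_path) else None
    orf_tab = pd.read_csv(os.path.join(outdir, "truth_orfs.tsv"), sep="\t")
    if seg_tab is not None and len(seg_tab):
        for _, row in seg_tab.iterrows():
            sub = orf_tab[orf_tab.segment_id == row.segment_id]
            orfs = tuple(
                TruthOrf(start=int(o.start), end=int(o.end), strand=o.strand,
                         has_sd=bool(o.has_sd),
                         sd_spacer=None if pd.isna(o.sd_spacer) else int(o.sd_spacer),
                         is_rdrp=bool(o.is_rdrp))
                for o in sub.itertuples())
            truth.segments.append(TruthSegment(
                segment_id=row.segment_id, virus_id=row.virus_id,
                sample_id=row.sample_id, sequence=seqs[row.segment_id],
                orfs=orfs, depth=float(row.depth),
                terminal_length=int(row.terminal_length)))
    lib = ReadLibrary()
    prov = pd.read_csv(os.path.join(outdir, "provenance.tsv"), sep="\t")
    seq_by_key: dict[tuple, tuple[str, str]] = {}
    for mate, key in ((1, "reads_1"), (2, "reads_2")):
        path = os.path.join(outdir, f"reads_{mate}.fastq")
        with open(path) as fh:
            lines = fh.read().splitlines()
        for i in range(0, len(lines), 4):
            rid = lines[i][1:].rsplit("/", 1)[0]
            seq_by_key[(rid, mate)] = (lines[i + 1], lines[i + 3])
    for row in prov.itertuples():
        seq, qual = seq_by_key[(row.read_id, row.mate)]
        lib.reads.append(SimRead(
            read_id=row.read_id, sequence=seq, quality=qual, mate=int(row.mate),
            segment_id=row.segment_id, strand=row.strand, start=int(row.start),
            end=int(row.end), adapter_len=int(row.adapter_len)))
    return truth, lib
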