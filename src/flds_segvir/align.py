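"""Read-to-contig alignments and read start/stop pileups.

Alignments either come from a standard SAM file (any external mapper) or
from the built-in minimal mapper: exact k-mer seed plus gapless extension,
adequate for low-error synthetic reads.  Stop profiles record, per contig
position, how many alignments start and end there — the evidence consumed
by the terminus caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .seqtools import revcomp, seq_to_array


class SamFormatError(ValueError):
    """SAM file is malformed or references a contig absent from @SQ."""


@dataclass(frozen=True)
class ReadAlignment:
    """One gapless read placement in 0-based half-open contig coordinates."""

    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str               # '+' or '-'
    n_mismatches: int = 0
    left_clip: int = 0        # read bases clipped at the contig 5' boundary
    right_clip: int = 0

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid alignment span [{self.start}, {self.end})")


@dataclass
class MapStats:
    total: int = 0
    mapped: int = 0
    ambiguous: int = 0
    unmapped: int = 0
    too_short: int = 0


def read_sam(path: str) -> list[ReadAlignment]:
    """Load primary, mapped records from a plain-text SAM file.

    Unmapped, secondary and supplementary records are excluded; SAM 1-based
    coordinates become 0-based half-open.
    """
    alignments: list[ReadAlignment] = []
    try:
        sam = pysam.AlignmentFile(path, "r", check_sq=True)
    except ValueError as exc:
        raise SamFormatError(f"{path}: {exc}") from exc
    with sam:
        lengths = dict(zip(sam.references, sam.lengths))
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name not in lengths:
                raise SamFormatError(
                    f"{path}: record {rec.query_name} references "
                    f"{rec.reference_name!r} missing from @SQ")
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            end = rec.reference_end
            if end is None or end > lengths[rec.reference_name]:
                raise SamFormatError(
                    f"{path}: record {rec.query_name} extends past contig end")
            alignments.append(ReadAlignment(
                read_id=rec.query_name,
                contig_id=rec.reference_name,
                start=rec.reference_start,
                end=end,
                strand="-" if rec.is_reverse else "+",
                n_mismatches=int(nm)))
    return alignments


class MinimalMapper:
    """Exact-seed, gapless mapper for low-error synthetic reads.

    A read is placed at the unique position where some k-mer seed extends
    end-to-end with mismatch rate <= ``max_mismatch_rate``.  Reads with more
    than one passing locus are discarded (multi-mapping would fabricate
    read-stop signals).  Alignments are clipped at contig boundaries and the
    clip is recorded, so reads running off a segment end still register a
    stop exactly at the end.
    """

    def __init__(self, contigs: dict[str, str], k: int = 21,
                 max_mismatch_rate: float = 0.05, max_seeds: int = 6,
                 max_seed_hits: int = 50):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.max_mismatch_rate = max_mismatch_rate
        self.max_seeds = max_seeds
        self.max_seed_hits = max_seed_hits
        self.contig_ids = list(contigs)
        self.contig_seqs = {c: contigs[c] for c in contigs}
        self.contig_arrays = {c: seq_to_array(s) for c, s in contigs.items()}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for cid, seq in contigs.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((cid, i))

    def map_read(self, read_id: str, seq: str) -> ReadAlignment | None:
        k = self.k
        if len(seq) < k:
            raise ValueError(
                f"read {read_id} shorter than seed length {k}")
        placements: dict[tuple, ReadAlignment] = {}
        for strand in ("+", "-"):
            rs = seq if strand == "+" else revcomp(seq)
            rarr = seq_to_array(rs)
            offsets = list(range(0, len(rs) - k + 1, k))[: self.max_seeds]
            candidates = set()
            for off in offsets:
                hits = self.index.get(rs[off:off + k])
                if hits is None or len(hits) > self.max_seed_hits:
                    continue
                for cid, pos in hits:
                    candidates.add((cid, pos - off))
            for cid, p in candidates:
                carr = self.contig_arrays[cid]
                s = max(0, p)
                e = min(len(carr), p + len(rs))
                if e - s < k:
                    continue
                mism = int(np.count_nonzero(
                    carr[s:e] != rarr[s - p: s - p + (e - s)]))
                if mism <= self.max_mismatch_rate * (e - s):
                    placements[(cid, s, e, strand)] = ReadAlignment(
                        read_id=read_id, contig_id=cid, start=s, end=e,
                        strand=strand, n_mismatches=mism,
                        left_clip=s - p, right_clip=(p + len(rs)) - e)
        if len(placements) == 1:
            return next(iter(placements.values()))
        return None if not placements else AMBIGUOUS

    def map_reads(self, reads) -> tuple[list[ReadAlignment], MapStats]:
        """Map ``(read_id, sequence)`` pairs; ambiguous reads are counted."""
        stats = MapStats()
        out: list[ReadAlignment] = []
        for read_id, seq in reads:
            stats.total += 1
            if len(seq) < self.k:
                stats.too_short += 1
                continue
            aln = self.map_read(read_id, seq)
            if aln is AMBIGUOUS:
                stats.ambiguous += 1
            elif aln is None:
                stats.unmapped += 1
            else:
                stats.mapped += 1
                out.append(aln)
        return out, stats


#: sentinel distinguishing multi-locus reads from unmapped ones
AMBIGUOUS = object()


def map_reads_minimal(reads, contigs: dict[str, str], k: int = 21,
                      max_mismatch_rate: float = 0.05):
    """Functional wrapper over :class:`MinimalMapper`."""
    mapper = MinimalMapper(contigs, k=k, max_mismatch_rate=max_mismatch_rate)
    return mapper.map_reads(reads)


@dataclass
class StopProfile:
    """Per-position alignment starts, ends and coverage for one contig.

    ``starts`` and ``ends`` have length L+1 (an alignment may end at the
    exclusive coordinate L); ``coverage`` has length L.
    """

    contig_id: str
    length: int
    starts: np.ndarray = field(repr=False)
    ends: np.ndarray = field(repr=False)
    coverage: np.ndarray = field(repr=False)
    n_alignments: int = 0

    def validate(self) -> None:
        """Conservation identities over the accumulated alignments."""
        if int(self.starts.sum()) != self.n_alignments:
            raise AssertionError("total starts != number of alignments")
        if int(self.ends.sum()) != self.n_alignments:
            raise AssertionError("total ends != number of alignments")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "contig_id": self.contig_id,
            "position": np.arange(self.length + 1),
            "starts": self.starts,
            "ends": self.ends,
            "coverage": np.append(self.coverage, 0),
        })


def build_stop_profile(alignments, contig_id: str,
                       contig_length: int) -> StopProfile:
    """Accumulate starts/ends/coverage for one contig.

    Raises ValueError when an alignment references another contig or falls
    outside the contig bounds.
    """
    starts = np.zeros(contig_length + 1, dtype=np.int64)
    ends = np.zeros(contig_length + 1, dtype=np.int64)
    delta = np.zeros(contig_length + 1, dtype=np.int64)
    n = 0
    for aln in alignments:
        if aln.contig_id != contig_id:
            raise ValueError(
                f"alignment {aln.read_id} references {aln.contig_id!r}, "
                f"expected {contig_id!r}")
        if aln.end > contig_length:
            raise ValueError(
                f"alignment {aln.read_id} out of contig bounds")
        starts[aln.start] += 1
        ends[aln.end] += 1
        delta[aln.start] += 1
        delta[aln.end] -= 1
        n += 1
    coverage = np.cumsum(delta)[:contig_length]
    profile = StopProfile(contig_id=contig_id, length=contig_length,
                          starts=starts, ends=ends, coverage=coverage,
                          n_alignments=n)
    profile.validate()
    return profile
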