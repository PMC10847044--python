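"""Cleaning of raw FLDS reads: U2 / U2-comp adapter removal and quality
filtering.

FLDS library construction ligates the U2 oligonucleotide to the 3' end of
both strands of every dsRNA fragment, so a read that sequences through its
fragment runs into the adapter at its 3' end.  Trimming is therefore
3'-anchored: the read is cut at the leftmost position where a prefix of the
adapter matches the rest of the read (semiglobal suffix-overlap with a
mismatch tolerance), which removes both full internal adapter occurrences
and partial adapter suffixes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from numpy.lib.stride_tricks import sliding_window_view

from .seqtools import seq_to_array

U2 = "GACGTAAGAACGTCGCACCA"
U2_COMP = "TGGTGCGACGTTCTTACGTC"


class FastqFormatError(ValueError):
    """Malformed FASTQ record (e.g. sequence/quality length mismatch)."""


@dataclass(frozen=True)
class AdapterSpec:
    """One 3' adapter to search for.

    min_overlap: shortest adapter prefix accepted at the read's 3' end.
    max_mismatch_rate: mismatches allowed per overlap length (floor).
    """

    name: str
    sequence: str
    min_overlap: int = 8
    max_mismatch_rate: float = 0.1

    def __post_init__(self):
        if not self.sequence or any(c not in "ACGT" for c in self.sequence):
            raise ValueError(
                f"adapter {self.name!r}: sequence must be nonempty uppercase "
                f"ACGT, got {self.sequence!r}")
        if not 1 <= self.min_overlap <= len(self.sequence):
            raise ValueError(
                f"adapter {self.name!r}: min_overlap must be in "
                f"[1, {len(self.sequence)}]")
        if not 0.0 <= self.max_mismatch_rate < 1.0:
            raise ValueError("max_mismatch_rate must be in [0, 1)")


DEFAULT_ADAPTERS: tuple[AdapterSpec, ...] = (
    AdapterSpec("U2", U2),
    AdapterSpec("U2comp", U2_COMP),
)


def _pigeonhole_blocks(adapter: AdapterSpec) -> tuple[str, ...]:
    """Exact sub-blocks for prescreening full-length occurrences.

    Any window matching the whole adapter with <= ``allowed`` mismatches
    must contain at least one of ``allowed + 1`` contiguous adapter blocks
    exactly, so ``str.find`` on the blocks is a sound (superset) filter.
    """
    alen = len(adapter.sequence)
    allowed = int(adapter.max_mismatch_rate * alen)
    k = allowed + 1
    size = alen // k
    return tuple(adapter.sequence[i * size: (i + 1) * size if i < k - 1
                                  else alen]
                 for i in range(k))


_BLOCK_CACHE: dict[tuple, tuple[str, ...]] = {}


def find_trim_point(seq: str, adapter: AdapterSpec) -> int | None:
    """Leftmost position ``p`` such that ``seq[p:]`` matches a prefix of the
    adapter with overlap >= min_overlap and mismatch rate <= the cap.

    Returns None when no position qualifies.  The match length at position
    ``p`` is ``min(len(adapter), len(seq) - p)``: a full internal adapter
    occurrence removes everything from ``p`` on; near the 3' end only an
    adapter prefix fits.
    """
    n = len(seq)
    alen = len(adapter.sequence)
    if n < adapter.min_overlap:
        return None
    aseq = adapter.sequence
    if n >= alen:
        key = (aseq, adapter.max_mismatch_rate)
        blocks = _BLOCK_CACHE.get(key)
        if blocks is None:
            blocks = _BLOCK_CACHE[key] = _pigeonhole_blocks(adapter)
        if any(seq.find(b) != -1 for b in blocks):
            arr = seq_to_array(seq)
            ad = seq_to_array(aseq)
            windows = sliding_window_view(arr, alen)  # positions 0 .. n-alen
            mism = (windows != ad).sum(axis=1)
            allowed = int(adapter.max_mismatch_rate * alen)
            hits = np.nonzero(mism <= allowed)[0]
            if hits.size:
                return int(hits[0])
    tail_start = max(0, n - alen + 1)
    for p in range(tail_start, n - adapter.min_overlap + 1):
        ell = n - p
        allowed = int(adapter.max_mismatch_rate * ell)
        mism = 0
        for a, b in zip(seq[p:], aseq):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return p
    return None


@dataclass
class TrimResult:
    sequence: str
    quality: str | None
    kept: bool
    reason: str | None          # None when kept
    trimmed_bases: int
    passes: int                 # trimming iterations applied


def trim_adapter(seq: str, qual: str | None = None,
                 adapters: tuple[AdapterSpec, ...] = DEFAULT_ADAPTERS,
                 min_len: int = 50) -> TrimResult:
    """Trim 3' adapter(s) off one read; qualities are cut in lockstep.

    Trimming is iterated to a fixed point (a removed adapter can expose an
    upstream adapter remnant), which makes the operation idempotent.  Reads
    shorter than ``min_len`` after trimming are flagged, not dropped.
    """
    if not seq:
        raise FastqFormatError("empty read")
    if qual is not None and len(qual) != len(seq):
        raise FastqFormatError(
            f"sequence length {len(seq)} != quality length {len(qual)}")
    original = len(seq)
    passes = 0
    while True:
        cuts = [p for p in (find_trim_point(seq, a) for a in adapters)
                if p is not None]
        if not cuts:
            break
        p = min(cuts)
        seq = seq[:p]
        if qual is not None:
            qual = qual[:p]
        passes += 1
        if not seq:
            break
    kept = len(seq) >= min_len
    return TrimResult(sequence=seq, quality=qual, kept=kept,
                      reason=None if kept else "too_short_after_trim",
                      trimmed_bases=original - len(seq), passes=passes)


def quality_filter(records, min_mean_q: float = 20.0, min_len: int = 50):
    """Keep reads with mean Phred quality and length above the thresholds.

    ``records`` yields ``(read_id, sequence, quality)`` triples.  Returns
    ``(kept, rejections)`` where rejections is a Counter keyed by reason.
    """
    kept = []
    rejections: Counter = Counter()
    for idx, rec in enumerate(records):
        try:
            read_id, seq, qual = rec
        except (TypeError, ValueError) as exc:
            raise FastqFormatError(f"malformed record at index {idx}") from exc
        if len(seq) != len(qual):
            raise FastqFormatError(
                f"record {idx} ({read_id}): sequence/quality length mismatch")
        if len(seq) < min_len:
            rejections["too_short"] += 1
            continue
        mean_q = float(np.frombuffer(qual.encode("ascii"),
                                     dtype=np.uint8).mean()) - 33.0
        if mean_q < min_mean_q:
            rejections["low_quality"] += 1
            continue
        kept.append((read_id, seq, qual))
    return kept, rejections


def trim_fastq(in_path: str, out_path: str,
               adapters: tuple[AdapterSpec, ...] = DEFAULT_ADAPTERS,
               min_len: int = 50, min_mean_q: float | None = None) -> dict:
    """Trim a FASTQ file; returns a summary of kept/rejected counts."""
    counts = Counter()
    with open(in_path) as ih, open(out_path, "w") as oh:
        for title, seq, qual in FastqGeneralIterator(ih):
            counts["input"] += 1
            res = trim_adapter(seq, qual, adapters=adapters, min_len=min_len)
            if res.trimmed_bases:
                counts["trimmed"] += 1
            if not res.kept:
                counts[res.reason] += 1
                continue
            if min_mean_q is not None:
                mean_q = float(np.frombuffer(res.quality.encode(),
                                             dtype=np.uint8).mean()) - 33.0
                if mean_q < min_mean_q:
                    counts["low_quality"] += 1
                    continue
            counts["kept"] += 1
            oh.write(f"@{title}\n{res.sequence}\n+\n{res.quality}\n")
    return dict(counts)
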