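"""Terminus calling and full-length segment classification.

A genome segment end reveals itself as a pileup of read alignments that all
stop at the same position near a contig boundary.  The calling rule is
count-based: a position within ``end_window`` of the boundary is a terminus
iff strictly more than ``min_stop_reads`` alignments stop exactly there and
the stop is dominant relative to local coverage.  Contigs with both termini
called are complete (full-length) segments; complete segments with mean
coverage above ``major_coverage_threshold`` are flagged "major".
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import StopProfile


@dataclass(frozen=True)
class TerminusCall:
    contig_id: str
    side: str                 # '5p' (left) or '3p' (right, exclusive coord)
    position: int
    stop_count: int
    local_coverage: int
    dominance: float          # stop_count / local coverage, capped at 1

    def __post_init__(self):
        if self.stop_count < 1:
            raise ValueError("stop_count must be >= 1")
        if not 0.0 < self.dominance <= 1.0:
            raise ValueError("dominance must be in (0, 1]")


@dataclass
class Segment:
    contig_id: str
    sequence: str             # trimmed to the called termini when complete
    status: str               # complete | partial_5 | partial_3 | incomplete
    termini: tuple[TerminusCall, ...] = ()
    mean_coverage: float = 0.0
    sample_id: str = ""
    is_major: bool = False
    orientation_flipped: bool = False
    low_confidence_orientation: bool = False

    @property
    def complete(self) -> bool:
        return self.status == "complete"


def call_termini(profile: StopProfile, min_stop_reads: int = 10,
                 end_window: int = 50,
                 min_dominance: float = 0.2) -> list[TerminusCall]:
    """Call at most one terminus per contig side from a stop profile.

    The threshold on the stop count is strict (``> min_stop_reads``): 10
    stacked read ends are not enough, 11 are.  Among qualifying positions on
    a side, the highest stop count wins; ties go to the position closest to
    the contig boundary.
    """
    L = profile.length
    if end_window >= L / 2:
        raise ValueError(
            f"end_window {end_window} must be < contig length/2 ({L / 2:g})")
    calls: list[TerminusCall] = []
    for side in ("5p", "3p"):
        if side == "5p":
            positions = range(0, end_window)
            counts = profile.starts
            boundary = 0
        else:
            positions = range(L - end_window + 1, L + 1)
            counts = profile.ends
            boundary = L
        candidates = []
        for p in positions:
            c = int(counts[p])
            if c <= min_stop_reads:
                continue
            cov_pos = p if side == "5p" else p - 1
            cov = int(profile.coverage[cov_pos]) if 0 <= cov_pos < L else c
            cov = max(cov, c)
            dom = min(1.0, c / cov)
            if dom < min_dominance:
                continue
            candidates.append((c, -abs(p - boundary), -p if side == "5p" else p,
                               TerminusCall(contig_id=profile.contig_id,
                                            side=side, position=p,
                                            stop_count=c, local_coverage=cov,
                                            dominance=dom)))
        if candidates:
            candidates.sort(key=lambda t: (t[0], t[1], t[2]), reverse=True)
            calls.append(candidates[0][3])
    return calls


def classify_segment(contig_id: str, sequence: str,
                     termini: list[TerminusCall],
                     profile: StopProfile | None = None,
                     mean_coverage: float | None = None,
                     sample_id: str = "",
                     major_coverage_threshold: float = 1000.0) -> Segment:
    """Assign completeness status and trim the sequence to called termini.

    Status encodes which end is still missing: both called -> ``complete``;
    only the 5' end -> ``partial_3`` (3' end missing); only the 3' end ->
    ``partial_5``; neither -> ``incomplete``.  ``is_major`` requires mean
    coverage strictly above the threshold.
    """
    for t in termini:
        if t.contig_id != contig_id:
            raise ValueError(
                f"terminus for {t.contig_id!r} applied to {contig_id!r}")
    five = next((t for t in termini if t.side == "5p"), None)
    three = next((t for t in termini if t.side == "3p"), None)
    if five and three:
        status = "complete"
        lo, hi = five.position, three.position
    elif five:
        status = "partial_3"
        lo, hi = five.position, len(sequence)
    elif three:
        status = "partial_5"
        lo, hi = 0, three.position
    else:
        status = "incomplete"
        lo, hi = 0, len(sequence)
    seq = sequence[lo:hi] if status == "complete" else sequence
    if mean_coverage is None:
        if profile is not None and hi > lo:
            mean_coverage = float(profile.coverage[lo:hi].mean())
        else:
            mean_coverage = 0.0
    return Segment(contig_id=contig_id, sequence=seq, status=status,
                   termini=tuple(t for t in (five, three) if t),
                   mean_coverage=mean_coverage, sample_id=sample_id,
                   is_major=mean_coverage > major_coverage_threshold)


def segment_report(segments: list[Segment]) -> pd.DataFrame:
    """One row per contig: status, termini, coverage, major flag."""
    rows = []
    for s in segments:
        five = next((t for t in s.termini if t.side == "5p"), None)
        three = next((t for t in s.termini if t.side == "3p"), None)
        rows.append({
            "contig_id": s.contig_id,
            "sample_id": s.sample_id,
            "status": s.status,
            "length": len(s.sequence),
            "terminus_5p": "" if five is None else five.position,
            "stops_5p": "" if five is None else five.stop_count,
            "terminus_3p": "" if three is None else three.position,
            "stops_3p": "" if three is None else three.stop_count,
            "mean_coverage": round(s.mean_coverage, 3),
            "is_major": s.is_major,
        })
    columns = ["contig_id", "sample_id", "status", "length", "terminus_5p",
               "stops_5p", "terminus_3p", "stops_3p", "mean_coverage",
               "is_major"]
    return pd.DataFrame(rows, columns=columns)
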