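"""Shared fixtures: session-scoped synthetic viromes and mapped reads."""

from __future__ import annotations

import collections

import pytest

import flds_segvir as fs
from flds_segvir.align import MinimalMapper
from flds_segvir.preprocess import trim_adapter


@pytest.fixture(scope="session")
def bipartite_params():
    """Three bipartite viruses at 200x, 0.5% error — the default study
    conditions for recovery tests."""
    return fs.SimParams(n_viruses=3, segments_per_virus=(2, 2), seed=1,
                        depth_per_virus=(200, 200), error_rate=0.005)


@pytest.fixture(scope="session")
def bipartite_truth(bipartite_params):
    return fs.simulate_virome(bipartite_params)


@pytest.fixture(scope="session")
def bipartite_reads(bipartite_truth, bipartite_params):
    return fs.simulate_flds_reads(bipartite_truth, bipartite_params)


@pytest.fixture(scope="session")
def clean_params():
    """Error-free single-virus library (round-trip / exactness checks)."""
    return fs.SimParams(n_viruses=2, segments_per_virus=(2, 2), seed=3,
                        depth_per_virus=(150, 150), error_rate=0.0)


@pytest.fixture(scope="session")
def clean_truth(clean_params):
    return fs.simulate_virome(clean_params)


@pytest.fixture(scope="session")
def clean_reads(clean_truth, clean_params):
    return fs.simulate_flds_reads(clean_truth, clean_params)


@pytest.fixture(scope="session")
def mapped_bipartite(bipartite_truth, bipartite_reads):
    """Trimmed and mapped bipartite library, grouped per contig."""
    trimmed = []
    for r in bipartite_reads.reads:
        res = trim_adapter(r.sequence, r.quality)
        if res.kept:
            trimmed.append((f"{r.read_id}/{r.mate}", res.sequence))
    contigs = {s.segment_id: s.sequence for s in bipartite_truth.segments}
    alignments, stats = MinimalMapper(contigs).map_reads(trimmed)
    by_contig = collections.defaultdict(list)
    for a in alignments:
        by_contig[a.contig_id].append(a)
    return {"contigs": contigs, "alignments": alignments, "stats": stats,
            "by_contig": by_contig}
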