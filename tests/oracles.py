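"""Independent reference implementations used to cross-check the package.

These are deliberately written with different algorithms/structures than
the library code they verify (exhaustive scans, stop-list formulations,
regex, dynamic programming) so that agreement is informative.
"""

from __future__ import annotations

import re

STOPS = {"TAA", "TAG", "TGA"}
STARTS = {"ATG", "GTG", "TTG"}


# --- adapter trimming ------------------------------------------------------

def trim_oracle(seq: str, adapters, min_len: int = 50):
    """Exhaustive suffix/prefix-overlap trim, iterated to a fixed point.

    adapters: iterable of (sequence, min_overlap, max_mismatch_rate).
    Returns (trimmed_seq, kept).
    """
    while True:
        cuts = []
        for aseq, min_ov, rate in adapters:
            n = len(seq)
            found = None
            for p in range(0, n - min_ov + 1):
                ell = min(len(aseq), n - p)
                if ell < min_ov:
                    continue
                mism = sum(1 for a, b in zip(seq[p:p + ell], aseq[:ell])
                           if a != b)
                if mism <= int(rate * ell):
                    found = p
                    break
            if found is not None:
                cuts.append(found)
        if not cuts:
            break
        seq = seq[:min(cuts)]
        if not seq:
            break
    return seq, len(seq) >= min_len


# --- ORF scanning ----------------------------------------------------------

def orf_scan_oracle(seq: str, min_len: int = 150):
    """Three-frame ORF scan via stop lists.

    For each frame, list the in-frame stop codons; each inter-stop region
    contributes the ORF running from its first start codon to the closing
    stop (inclusive).  The trailing region yields an open-ended ORF.
    Returns a set of (start, end, open_3p) tuples.
    """
    out = set()
    n = len(seq)
    for f in range(3):
        stop_positions = [i for i in range(f, n - 2, 3)
                          if seq[i:i + 3] in STOPS]
        region_edges = [f] + [s + 3 for s in stop_positions]
        closers = stop_positions + [None]
        for lo, stop in zip(region_edges, closers):
            hi = stop if stop is not None else f + 3 * ((n - f) // 3)
            start = None
            for i in range(lo, hi, 3):
                if seq[i:i + 3] in STARTS:
                    start = i
                    break
            if start is None:
                continue
            end = (stop + 3) if stop is not None else hi
            if end - start >= min_len:
                out.add((start, end, stop is None))
    return out


# --- RdRP motifs -----------------------------------------------------------

_B_RE = re.compile(r"(?=(SG...T))")
_C_RE = re.compile(r"(?=(GDD))")


def motif_oracle(protein: str):
    """Regex-based motif B/C positions, overlapping matches included."""
    b = [m.start() for m in _B_RE.finditer(protein)]
    c = [m.start() for m in _C_RE.finditer(protein)]
    ordered_b = [p for p in b if any(10 <= q - p <= 60 for q in c)]
    return b, c, ordered_b


# --- hydropathy ------------------------------------------------------------

def tmd_oracle(protein: str, scale: dict, window: int = 19,
               threshold: float = 1.6):
    """All-window recomputation of the transmembrane flag."""
    best = float("-inf")
    for i in range(len(protein) - window + 1):
        w = protein[i:i + window]
        score = sum(scale.get(aa, 0.0) for aa in w) / window
        best = max(best, score)
    return best >= threshold, best


# --- global alignment ------------------------------------------------------

def gotoh_score(a: str, b: str, match: float = 2.0, mismatch: float = -3.0,
                gap_open: float = -5.0, gap_extend: float = -2.0) -> float:
    """Optimal global alignment score with affine gaps (Gotoh DP).

    Gap of length k costs gap_open + (k-1) * gap_extend, matching the
    pairwise-aligner parameterization used by the binning module.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a aligned to -)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


# --- misc ------------------------------------------------------------------

def positional_identity(a: str, b: str) -> float:
    """Ungapped identity over the shorter prefix, divisor = longer length."""
    matches = sum(x == y for x, y in zip(a, b))
    return matches / max(len(a), len(b)) if a and b else 0.0
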