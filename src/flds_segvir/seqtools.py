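"""Small nucleotide/protein sequence helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: genetic code 11 (bacteria/archaea) — the code used throughout the package
TABLE11 = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = tuple(sorted(TABLE11.stop_codons))
START_CODONS = ("ATG", "GTG", "TTG")
SENSE_CODONS = tuple(sorted(TABLE11.forward_table))

# amino acid -> synonymous codons, for reverse translation in the simulator
CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in TABLE11.forward_table.items():
    CODONS_BY_AA.setdefault(_aa, ())
    CODONS_BY_AA[_aa] = CODONS_BY_AA[_aa] + (_codon,)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array for fast vectorized comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform random ACGT string of length ``n``."""
    return rng.choice(_ACGT_CODES, size=n).tobytes().decode("ascii")


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply i.i.d. substitutions at per-base probability ``rate``.

    Substituted bases are drawn uniformly from the three alternatives, so a
    'mutated' position never silently keeps its original base.
    """
    if rate <= 0 or not seq:
        return seq
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    arr = bytearray(seq, "ascii")
    positions = rng.choice(n, size=k, replace=False)
    for p in positions:
        current = arr[p]
        choices = [c for c in _ACGT_CODES.tolist() if c != current]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.decode("ascii")


def hamming_identity(a: str, b: str) -> float:
    """Ungapped positional identity: matches / compared length.

    Sequences of unequal length are compared over the shorter prefix and the
    overhang counts as mismatch (divisor is the longer length).
    """
    if not a or not b:
        return 0.0
    m = min(len(a), len(b))
    matches = sum(1 for x, y in zip(a[:m], b[:m]) if x == y)
    return matches / max(len(a), len(b))


def translate_cds(nt: str) -> str:
    """Translate a coding sequence under genetic code 11.

    The initiator codon is rendered as M regardless of ATG/GTG/TTG (CDS
    convention); a trailing stop is dropped; internal stops, if any, appear
    as ``*``.
    """
    if len(nt) < 3:
        return ""
    aas = []
    for i in range(3, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in TABLE11.forward_table:
            aas.append(TABLE11.forward_table[codon])
        elif codon in STOP_CODONS:
            aas.append("*")
        else:
            aas.append("X")
    body = "".join(aas)
    if body.endswith("*"):
        body = body[:-1]
    return "M" + body
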