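"""Low-level DNA/RNA sequence helpers shared across the package.

All genome sequences are uppercase strings over {A,C,G,T,N}.  An ``N``
never matches anything, including another ``N``: every comparison in this
package treats it as an automatic mismatch (conservative matching).
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A,C,G,T -> 0..3; everything else (incl. N) -> 4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

VALID_DNA = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def transcribe(seq: str) -> str:
    """DNA -> RNA (T becomes U); used only for display/scoring parity."""
    return seq.replace("T", "U").replace("t", "u")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N mismatches everything."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length sequences")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def mismatch_offsets(a: str, b: str) -> list[int]:
    """0-based offsets where ``a`` and ``b`` differ (N never matches)."""
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y or x == "N" or y == "N"]


def at_fraction(seq: str) -> float:
    """A+T fraction; empty sequence gives 0.0."""
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("T")) / len(seq)


def sliding_mismatches(enc_genome: np.ndarray, enc_pattern: np.ndarray) -> np.ndarray:
    """Mismatch count of ``enc_pattern`` against every window of the genome.

    Returns an int32 array of length ``len(genome) - len(pattern) + 1``
    (empty when the genome is shorter than the pattern).  Genome positions
    encoded as 4 (N) mismatch every pattern base.
    """
    n, length = len(enc_genome), len(enc_pattern)
    if n < length:
        return np.empty(0, dtype=np.int32)
    out = np.zeros(n - length + 1, dtype=np.int32)
    for j in range(length):
        out += enc_genome[j : n - length + 1 + j] != enc_pattern[j]
    return out


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """i.i.d. random DNA with the given GC fraction."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
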