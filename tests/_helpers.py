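"""Independent oracles and small builders used across the test suite.

Everything here is deliberately naive — per-position loops, explicit
recursion — so it constitutes an independent check on the package's
vectorised / dynamic-programming implementations.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_scan(contigs: dict[str, str], spacer: str, max_mm: int):
    """Per-position Hamming scan over both strands; N never matches.

    Returns a set of (contig_id, start, strand, n_mismatches).
    """
    out = set()
    L = len(spacer)
    rc = naive_revcomp(spacer)
    for cid, seq in contigs.items():
        n = len(seq)
        for start in range(n - L + 1):
            for strand, pat in (("+", spacer), ("-", rc)):
                mm = 0
                for j in range(L):
                    b = seq[start + j]
                    if b != pat[j] or b == "N":
                        mm += 1
                        if mm > max_mm:
                            break
                if mm <= max_mm:
                    out.add((cid, start, strand, mm))
    return out


_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}


def enum_max_pairs(rna: str, min_loop: int = 3, allow_gu: bool = True) -> int:
    """Maximum pair count by explicit recursion over all nested structures.

    No memoisation: every admissible structure of the interval is
    explored, so this is exponential and only usable for short RNAs.
    """
    rna = rna.upper().replace("T", "U")

    def can(a: str, b: str) -> bool:
        return (a, b) in _WC or (allow_gu and (a, b) in _GU)

    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        value = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if can(rna[i], rna[k]):
                value = max(value, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return value

    return best(0, len(rna) - 1) if rna else 0


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT")) for _ in range(length))


def build_planted_genome(rng, repeat: str, spacers: list[str],
                         bg_len: int = 50_000, pos: int = 20_000):
    """Background + one exact [R S1 R ... Sn R] array at ``pos``."""
    from crisprself.genome_io import Genome

    body = repeat + "".join(s + repeat for s in spacers)
    bg = random_dna(rng, bg_len)
    return Genome("planted", {"c1": bg[:pos] + body + bg[pos:]}), pos, body
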