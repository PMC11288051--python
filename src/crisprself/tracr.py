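"""tracrRNA anti-repeat search and base-pair-maximisation RNA folding.

The tracrRNA is located by reverse-complement similarity of its
anti-repeat region to the array's consensus repeat within a window
around the CRISPR locus.  Secondary structures of crRNAs and of the
crRNA:tracrRNA duplex are predicted with an explicit Nussinov-style
base-pair-maximisation dynamic program (Watson-Crick plus G:U wobble,
minimum hairpin loop enforced).  This is a combinatorial folder, not a
thermodynamic one: its claims are limited to pair counts and dot-bracket
topology, never free energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import revcomp
from .genome_io import Genome, GenomicInterval

_PAIRS_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_PAIRS_GU = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class AntiRepeatCandidate:
    interval: GenomicInterval
    strand: str
    matched_length: int
    identity_to_revcomp_repeat: float
    distance_to_locus: int
    sequence: str


def _match_identity(window: str, pattern: str) -> float:
    """Identity of a full-length gapless alignment (N never matches)."""
    return sum(
        1 for a, b in zip(window, pattern) if a == b and a != "N"
    ) / len(pattern)


def find_anti_repeat(
    genome: Genome,
    consensus_repeat: str,
    locus_interval: GenomicInterval,
    window_bp: int = 2000,
    min_len: int = 20,
    min_identity: float = 0.6,
) -> list[AntiRepeatCandidate]:
    """Anti-repeat candidates near a CRISPR locus.

    Candidates are gapless full-repeat-length alignments between the
    windowed genome sequence and the reverse complement of the repeat
    (searched on both strands), excluding positions inside the locus
    itself, sorted by identity then proximity; overlapping candidates
    are suppressed in favour of the better one.
    """
    seq = genome.contigs[locus_interval.contig_id]
    wstart = max(0, locus_interval.start - window_bp)
    wend = min(len(seq), locus_interval.end + window_bp)
    L = len(consensus_repeat)
    raw: list[AntiRepeatCandidate] = []
    for strand, pattern in (("+", revcomp(consensus_repeat)), ("-", consensus_repeat)):
        for s in range(wstart, wend - L + 1):
            iv_probe = GenomicInterval(locus_interval.contig_id, s, s + L)
            if iv_probe.overlaps(locus_interval):
                continue
            identity = _match_identity(seq[s : s + L], pattern)
            if L < min_len or identity < min_identity:
                continue
            iv = GenomicInterval(locus_interval.contig_id, s, s + L, strand)
            span = L
            dist = (
                0 if iv.overlaps(locus_interval)
                else (locus_interval.start - iv.end
                      if iv.end <= locus_interval.start
                      else iv.start - locus_interval.end)
            )
            raw.append(
                AntiRepeatCandidate(iv, strand, span, identity, dist,
                                    genome.fetch(iv))
            )
    raw.sort(key=lambda c: (-c.identity_to_revcomp_repeat, c.distance_to_locus,
                            c.interval.start))
    kept: list[AntiRepeatCandidate] = []
    for c in raw:
        if not any(c.interval.overlaps(k.interval) for k in kept):
            kept.append(c)
    return kept


@dataclass
class FoldResult:
    sequence: str
    structure: str  # dot-bracket
    n_pairs: int
    paired_positions: list[tuple[int, int]]
    inter_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_inter_pairs(self) -> int:
        return len(self.inter_pairs)


def _can_pair(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in _PAIRS_WC or (allow_gu and (a, b) in _PAIRS_GU)


def nussinov_fold(
    rna: str,
    min_loop: int = 3,
    allow_gu: bool = True,
    forbidden=(),
) -> FoldResult:
    """Maximum base-pairing nested structure of an RNA.

    Pairs are Watson-Crick plus (optionally) G:U; a pair (i, j) requires
    at least ``min_loop`` unpaired bases between i and j.  Positions in
    ``forbidden`` (e.g. a duplex linker) never pair.  Traceback is
    deterministic: at each subproblem, position i pairs with the largest
    admissible j; otherwise it is left unpaired.
    """
    rna = rna.upper().replace("T", "U")
    if set(rna) - set("ACGUN"):
        raise ValueError("RNA must contain only A/C/G/U (or N for a linker)")
    n = len(rna)
    forbidden = set(forbidden)

    def pairable(i: int, j: int) -> bool:
        return (
            i not in forbidden
            and j not in forbidden
            and j - i - 1 >= min_loop
            and _can_pair(rna[i], rna[j], allow_gu)
        )

    # dp[i][j] = max pairs in rna[i..j]
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if pairable(i, k):
                    left = dp[i + 1][k - 1] if k - 1 > i else 0
                    right = dp[k + 1][j] if k + 1 <= j else 0
                    best = max(best, 1 + left + right)
            dp[i][j] = best

    pairs: list[tuple[int, int]] = []

    def trace(i: int, j: int) -> None:
        while i < j:
            target = dp[i][j]
            if target == 0:
                return
            chosen = None
            for k in range(j, i + min_loop, -1):  # largest admissible j first
                if pairable(i, k):
                    left = dp[i + 1][k - 1] if k - 1 > i else 0
                    right = dp[k + 1][j] if k + 1 <= j else 0
                    if 1 + left + right == target:
                        chosen = k
                        break
            if chosen is None:
                i += 1
                continue
            pairs.append((i, chosen))
            trace(i + 1, chosen - 1)
            i = chosen + 1

    if n:
        trace(0, n - 1)
    pairs.sort()
    structure = ["."] * n
    for i, j in pairs:
        structure[i], structure[j] = "(", ")"
    return FoldResult(rna, "".join(structure), len(pairs), pairs)


def cofold_duplex(crrna: str, tracrrna: str, linker_len: int = 4,
                  min_loop: int = 3, allow_gu: bool = True) -> FoldResult:
    """Co-fold crRNA and tracrRNA joined by an unpairable N linker.

    The two molecules are concatenated with ``linker_len`` N positions
    that are forbidden from pairing, then folded by
    :func:`nussinov_fold`; pairs with one side in the crRNA and the other
    in the tracrRNA are reported as inter-molecular.
    """
    cr = crrna.upper().replace("T", "U")
    tr = tracrrna.upper().replace("T", "U")
    joined = cr + "N" * linker_len + tr
    linker = range(len(cr), len(cr) + linker_len)
    result = nussinov_fold(joined, min_loop=min_loop, allow_gu=allow_gu,
                           forbidden=linker)
    cut = len(cr) + linker_len
    result.inter_pairs = [(i, j) for i, j in result.paired_positions
                          if i < len(cr) and j >= cut]
    return result


def write_fold(result: FoldResult, path) -> None:
    """Two-line dot-bracket text file (sequence, structure)."""
    with open(path, "w") as fh:
        fh.write(result.sequence + "\n" + result.structure + "\n")


def write_candidates_tsv(candidates, path) -> None:
    import pandas as pd

    rows = [
        {
            "contig": c.interval.contig_id,
            "start": c.interval.start,
            "end": c.interval.end,
            "strand": c.strand,
            "matched_length": c.matched_length,
            "identity": round(c.identity_to_revcomp_repeat, 4),
            "distance_to_locus": c.distance_to_locus,
            "sequence": c.sequence,
        }
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "strand", "matched_length",
                 "identity", "distance_to_locus", "sequence"],
    ).to_csv(path, sep="\t", index=False)
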