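"""PAM / anti-tag flank extraction and sequence-logo mathematics.

Flanks are always reported in the protospacer's 5'->3' frame.  Aggregated
flanks become a position-frequency matrix with per-column information
content IC_i = 2 - H_i bits (the height scale of a sequence logo), where
H_i is the Shannon entropy of the observed base frequencies.  The type
III anti-tag is scored as antiparallel Watson-Crick complementarity
between the downstream flank and the crRNA 5' tag (the repeat's 3'
terminal k-mer, transcribed to RNA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp, transcribe
from .genome_io import Genome, GenomicInterval

#: Flank windows the study's subtypes use for their printed PAM/anti-tag
#: calls: type I-E recognises a 3-nt PAM 5' of the protospacer; type II-A
#: a 6-nt PAM 3' of it; the type III anti-tag is the 6-mer 3' of the
#: protospacer on the target-sense strand.
SUBTYPE_FLANK_WINDOWS: dict[str, tuple[str, int]] = {
    "I-E": ("upstream", 3),
    "II-A": ("downstream", 6),
    "III-A": ("downstream", 6),
}

RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def extract_flanks(
    genome: Genome,
    hit_interval: GenomicInterval,
    upstream_len: int = 10,
    downstream_len: int = 10,
) -> tuple[str, str]:
    """Oriented flanks of a protospacer, truncated at contig edges.

    For a minus-strand hit both flanks are reverse-complemented and
    swapped so "upstream" is always 5' of the protospacer in its own
    frame.
    """
    seq = genome.contigs[hit_interval.contig_id]
    if hit_interval.strand == "-":
        up = revcomp(seq[hit_interval.end : hit_interval.end + upstream_len])
        down = revcomp(
            seq[max(0, hit_interval.start - downstream_len) : hit_interval.start]
        )
    else:
        up = seq[max(0, hit_interval.start - upstream_len) : hit_interval.start]
        down = seq[hit_interval.end : hit_interval.end + downstream_len]
    return up, down


def subtype_motif(genome: Genome, hit, subtype: str | None = None) -> str:
    """The subtype's conventional PAM/anti-tag string for one hit."""
    subtype = subtype or hit.subtype
    side, width = SUBTYPE_FLANK_WINDOWS.get(subtype, ("downstream", 6))
    up, down = extract_flanks(genome, hit.target, width, width)
    return up[-width:] if side == "upstream" else down[:width]


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts over equal-length flank sequences.

    Sequences contributing an N at a position are excluded from that
    column; ``column_totals`` tracks the per-column effective counts.
    """

    counts: np.ndarray  # shape (window_length, 4), columns A,C,G,T
    n_sequences: int
    column_totals: np.ndarray

    BASES = "ACGT"

    @property
    def window_length(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        totals = np.where(self.column_totals > 0, self.column_totals, 1)
        return self.counts / totals[:, None]

    def information_content(self, small_sample_correction: bool = False) -> np.ndarray:
        """IC_i = 2 - H_i bits per column, in [0, 2].

        With ``small_sample_correction`` a WebLogo-style e_n = 3/(2 ln 2 n)
        penalty is subtracted (clamped at 0); the default is the plain
        uncorrected value.
        """
        freqs = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1)), 0.0)
        entropy = -(freqs * logs).sum(axis=1)
        ic = 2.0 - entropy
        if small_sample_correction:
            n = np.where(self.column_totals > 0, self.column_totals, 1)
            ic = np.maximum(ic - 3.0 / (2.0 * np.log(2) * n), 0.0)
        return ic


def build_pfm(flank_sequences) -> PositionFrequencyMatrix:
    """Count matrix over equal-length sequences; errors on empty input."""
    seqs = [s.upper() for s in flank_sequences]
    if not seqs:
        raise ValueError("build_pfm requires at least one sequence")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("all sequences must share one window length")
    counts = np.zeros((length, 4), dtype=np.int64)
    idx = {b: i for i, b in enumerate(PositionFrequencyMatrix.BASES)}
    for s in seqs:
        for i, b in enumerate(s):
            if b in idx:
                counts[i, idx[b]] += 1
    return PositionFrequencyMatrix(counts, len(seqs), counts.sum(axis=1))


def write_pfm_tsv(pfm: PositionFrequencyMatrix, path) -> None:
    import pandas as pd

    df = pd.DataFrame(pfm.counts, columns=list(pfm.BASES))
    df.insert(0, "position", np.arange(pfm.window_length))
    df["information_content"] = pfm.information_content()
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AntiTagScore:
    anti_tag: str  # RNA, 5'->3'
    crrna_tag: str  # RNA, 5'->3' (repeat 3'-terminal k-mer)
    matched_pairs: int
    k: int

    def is_anti_tag(self, min_pairs: int = 4) -> bool:
        """Anti-tag call: present iff at least ``min_pairs`` of k pair."""
        return self.matched_pairs >= min_pairs


def anti_tag_score(downstream_flank: str, repeat: str, k: int = 6) -> AntiTagScore:
    """Complementarity of a downstream flank to the crRNA 5' tag.

    The tag is the last ``k`` nt of the repeat (RNA); the flank's first
    ``k`` nt are compared position-wise against the reverse complement of
    the tag (antiparallel Watson-Crick pairing, no G:U wobble).
    """
    if k > len(repeat):
        raise ValueError("k exceeds repeat length")
    flank = transcribe(downstream_flank.upper())
    if len(flank) < k:
        raise ValueError("flank shorter than k")
    tag = transcribe(repeat.upper())[-k:]
    anti = flank[:k]
    expected = "".join(RNA_COMPLEMENT.get(b, "N") for b in reversed(tag))
    matched = sum(1 for a, b in zip(anti, expected) if a == b and a != "N")
    return AntiTagScore(anti, tag, matched, k)
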