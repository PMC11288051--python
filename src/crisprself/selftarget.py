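"""Self-targeting spacer detection.

A self-targeting spacer (STS) is a spacer whose protospacer lies in the
host's own genome outside any CRISPR array.  The search is an exhaustive
Hamming scan of every spacer against both strands of every contig: every
window at Hamming distance <= ``max_mismatches`` is a hit (substitutions
only, no indels; the default budget is 0 because confirmed self-targets
typically show perfect complementarity to their sites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import encode, revcomp, sliding_mismatches
from .genome_io import GeneAnnotation, Genome, GenomicInterval


@dataclass(frozen=True)
class SelfTargetHit:
    """One spacer-to-genome match outside any array.

    ``protospacer_sequence`` and both flanks are reported in the
    protospacer's 5'->3' frame (reverse-complemented for minus-strand
    hits), so "upstream" is always 5' of the protospacer.
    """

    array_id: str
    spacer_index: int
    spacer_sequence: str
    target: GenomicInterval
    mismatches: tuple[int, ...]
    protospacer_sequence: str
    upstream_flank: str = ""
    downstream_flank: str = ""
    target_gene: GeneAnnotation | None = None
    subtype: str | None = None

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


def scan_spacer(
    genome: Genome, spacer_sequence: str, max_mismatches: int = 0
) -> list[tuple[GenomicInterval, tuple[int, ...]]]:
    """All windows within the mismatch budget of a spacer, both strands.

    Returns ``(interval, mismatch_offsets)`` pairs sorted by
    (contig, start, strand); offsets are in the spacer's 5'->3' frame.
    ``N`` in the genome never matches.
    """
    spacer_sequence = spacer_sequence.upper()
    if set(spacer_sequence) - set("ACGT"):
        raise ValueError("spacer must contain only A/C/G/T")
    if len(spacer_sequence) < 18:
        raise ValueError("spacer shorter than 18 nt")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")

    length = len(spacer_sequence)
    fwd = encode(spacer_sequence)
    rev = encode(revcomp(spacer_sequence))
    hits = []
    for contig_id in genome.contigs:
        enc = genome.encoded(contig_id)
        seq = genome.contigs[contig_id]
        for strand, pat in (("+", fwd), ("-", rev)):
            mm = sliding_mismatches(enc, pat)
            for start in np.nonzero(mm <= max_mismatches)[0]:
                start = int(start)
                window = seq[start : start + length]
                proto = window if strand == "+" else revcomp(window)
                offsets = tuple(
                    i
                    for i, (a, b) in enumerate(zip(spacer_sequence, proto))
                    if a != b or b == "N"
                )
                hits.append(
                    (GenomicInterval(contig_id, start, start + length, strand),
                     offsets)
                )
    order = {cid: i for i, cid in enumerate(genome.contigs)}
    hits.sort(key=lambda h: (order[h[0].contig_id], h[0].start, h[0].strand))
    return hits


def _overlapping_gene(genome: Genome, iv: GenomicInterval) -> GeneAnnotation | None:
    """Gene overlapping the target; max overlap wins, then genome order."""
    best, best_olap = None, 0
    for g in genome.genes:
        if g.contig_id != iv.contig_id:
            continue
        olap = min(g.end, iv.end) - max(g.start, iv.start)
        if olap > best_olap:
            best, best_olap = g, olap
    return best


def find_self_targets(
    genome: Genome,
    arrays,
    max_mismatches: int = 0,
    upstream_len: int = 10,
    downstream_len: int = 10,
) -> list[SelfTargetHit]:
    """Scan every spacer of every array; keep hits outside all arrays.

    Spacers with identical sequence within the genome (up to reverse
    complement, since array orientation is inferred) are collapsed to one
    "unique" spacer (the first occurrence in array order) before scanning,
    so spacer-level tallies count unique sequences.  Each surviving hit is
    annotated with the overlapping gene (if any) and oriented flanks.
    """
    from .pam import extract_flanks

    array_ivs = [a.interval for a in arrays]
    seen: dict[str, tuple] = {}
    for a in arrays:
        for s in a.spacers:
            key = min(s.sequence, revcomp(s.sequence))
            if key not in seen:
                seen[key] = (s.sequence, a.array_id, s.index, a.subtype)

    hits: list[SelfTargetHit] = []
    for seq, array_id, idx, subtype in seen.values():
        for iv, offsets in scan_spacer(genome, seq, max_mismatches):
            if any(iv.overlaps(aiv) for aiv in array_ivs):
                continue
            window = genome.fetch(GenomicInterval(iv.contig_id, iv.start, iv.end))
            proto = window if iv.strand == "+" else revcomp(window)
            up, down = extract_flanks(genome, iv, upstream_len, downstream_len)
            hits.append(
                SelfTargetHit(
                    array_id, idx, seq, iv, offsets, proto, up, down,
                    _overlapping_gene(genome, iv), subtype,
                )
            )
    return hits


def unique_sts_count(hits) -> int:
    """Number of distinct self-targeting spacer sequences among hits
    (strand-invariant: a spacer and its reverse complement count once)."""
    return len({
        min(h.spacer_sequence, revcomp(h.spacer_sequence)) for h in hits
    })


def write_hits_tsv(hits, path) -> None:
    import pandas as pd

    rows = [
        {
            "array_id": h.array_id,
            "spacer_index": h.spacer_index,
            "subtype": h.subtype or "",
            "contig": h.target.contig_id,
            "start": h.target.start,
            "end": h.target.end,
            "strand": h.target.strand,
            "n_mismatches": h.n_mismatches,
            "spacer": h.spacer_sequence,
            "protospacer": h.protospacer_sequence,
            "upstream_flank": h.upstream_flank,
            "downstream_flank": h.downstream_flank,
            "target_gene_product": h.target_gene.product if h.target_gene else "",
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=[
            "array_id", "spacer_index", "subtype", "contig", "start", "end",
            "strand", "n_mismatches", "spacer", "protospacer",
            "upstream_flank", "downstream_flank", "target_gene_product",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_hits_bed(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            name = f"{h.array_id}.sp{h.spacer_index}"
            fh.write(
                f"{h.target.contig_id}\t{h.target.start}\t{h.target.end}"
                f"\t{name}\t{h.n_mismatches}\t{h.target.strand}\n"
            )
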