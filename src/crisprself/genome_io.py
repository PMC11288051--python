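"""Genome and annotation I/O.

Internal convention: every coordinate in this package is 0-based,
half-open, on the forward strand of the named contig.  GFF3 is converted
from (and emitted as) 1-based closed; BED is already 0-based half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

from ._seq import VALID_DNA, encode, revcomp


class FormatError(ValueError):
    """A record in an input file does not parse as its declared format."""


class ReferenceError_(ValueError):
    """An annotation refers to a contig absent from the genome."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a contig; strand in {+,-,.}."""

    contig_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(
                f"empty interval {self.contig_id}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene/CDS feature with its free-text product description."""

    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig_id, self.start, self.end, self.strand)


@dataclass
class Genome:
    """Named contigs (uppercase A/C/G/T/N) plus optional gene annotations."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self._enc_cache: dict = {}
        for cid, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {cid!r} has an empty sequence")
            bad = set(seq) - VALID_DNA
            if bad:
                raise FormatError(
                    f"contig {cid!r} contains non-DNA characters {sorted(bad)}"
                )
        for g in self.genes:
            self._check_gene(g)

    def _check_gene(self, g: GeneAnnotation) -> None:
        if g.contig_id not in self.contigs:
            raise ReferenceError_(
                f"annotation references unknown contig {g.contig_id!r}"
            )
        if not (0 <= g.start < g.end <= len(self.contigs[g.contig_id])):
            raise FormatError(
                f"annotation {g.contig_id}:{g.start}-{g.end} outside contig"
            )

    def encoded(self, contig_id: str):
        """uint8 encoding of a contig, cached."""
        if contig_id not in self._enc_cache:
            self._enc_cache[contig_id] = encode(self.contigs[contig_id])
        return self._enc_cache[contig_id]

    def fetch(self, interval: GenomicInterval) -> str:
        """Forward-strand sequence of an interval, clipped to the contig."""
        seq = self.contigs[interval.contig_id]
        return seq[max(0, interval.start) : min(len(seq), interval.end)]

    def reverse_complemented(self) -> "Genome":
        """Mirror-image genome (used by strand-symmetry checks)."""
        contigs = {cid: revcomp(s) for cid, s in self.contigs.items()}
        genes = [
            GeneAnnotation(
                g.contig_id,
                len(self.contigs[g.contig_id]) - g.end,
                len(self.contigs[g.contig_id]) - g.start,
                {"+": "-", "-": "+"}.get(g.strand, g.strand),
                g.product,
            )
            for g in self.genes
        ]
        return Genome(self.genome_id, contigs, genes)


def load_genome(fasta_path, gff_path=None, genome_id: str | None = None) -> Genome:
    """Read a (multi-)FASTA assembly and optional GFF3 gene annotations.

    Sequences are uppercased; GFF3 coordinates are converted from 1-based
    closed to the internal 0-based half-open convention.  A GFF3 feature on
    a contig absent from the FASTA raises :class:`ReferenceError_`.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate FASTA record id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r} has an empty sequence")
        bad = set(seq) - VALID_DNA
        if bad:
            raise FormatError(
                f"FASTA record {rec.id!r} contains non-DNA characters {sorted(bad)}"
            )
        contigs[rec.id] = seq
    if not contigs:
        raise FormatError(f"no FASTA records found in {fasta_path}")

    genes: list[GeneAnnotation] = []
    if gff_path is not None:
        genes = _read_gff_genes(gff_path)
    gid = genome_id if genome_id is not None else _stem(fasta_path)
    return Genome(gid, contigs, genes)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def _gff_db(path):
    return gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )


def _read_gff_genes(gff_path) -> list[GeneAnnotation]:
    db = _gff_db(gff_path)
    types = set(db.featuretypes())
    want = "CDS" if "CDS" in types else "gene"
    genes = []
    for f in db.features_of_type(want, order_by=("seqid", "start")):
        product = f.attributes.get("product", [""])[0]
        genes.append(
            GeneAnnotation(f.seqid, f.start - 1, f.end, f.strand or ".", product)
        )
    return genes


def load_regions(path, fmt: str) -> list:
    """Read prophage regions from BED4 or GFF3.

    The completeness label is the BED name column, or the GFF3
    ``completeness``/``Name`` attribute, defaulting to ``"unknown"``.  It is
    passed through as free text; downstream classification never branches
    on it.
    """
    from .prophage import ProphageRegion

    fmt = fmt.upper()
    regions: list[ProphageRegion] = []
    if fmt == "BED":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t") if "\t" in line else line.split()
                if len(cols) < 3:
                    raise FormatError(f"{path}:{lineno}: BED line has <3 columns")
                contig, start, end = cols[0], int(cols[1]), int(cols[2])
                if end <= start:
                    raise FormatError(
                        f"{path}:{lineno}: interval end {end} <= start {start}"
                    )
                label = cols[3] if len(cols) > 3 else "unknown"
                regions.append(
                    ProphageRegion(GenomicInterval(contig, start, end), label)
                )
    elif fmt == "GFF3":
        db = _gff_db(path)
        for f in db.all_features(order_by=("seqid", "start")):
            label = f.attributes.get(
                "completeness", f.attributes.get("Name", ["unknown"])
            )[0]
            if f.end < f.start:
                raise FormatError(f"{path}: feature end {f.end} < start {f.start}")
            regions.append(
                ProphageRegion(GenomicInterval(f.seqid, f.start - 1, f.end), label)
            )
    else:
        raise ValueError(f"unsupported region format {fmt!r} (use BED or GFF3)")
    return regions


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genes_gff3(genome: Genome, path) -> None:
    """Emit gene annotations as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genome.genes, 1):
            attrs = f"ID=gene{i}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.contig_id}\tcrisprself\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def write_regions_bed(regions, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            iv = r.interval
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{r.completeness}\n")
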