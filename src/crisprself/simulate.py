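"""Synthetic genomes with planted CRISPR features and machine-readable truth.

The generator emulates a low-GC lactobacillus chromosome: a ~2 Mb
background contig (GC 0.35 by default) carrying CRISPR arrays whose
repeat/spacer lengths follow the per-subtype modes observed in the
genus (repeat modes 29/36/36 bp for types I-E/II-A/III-A; spacer modes
32 and 30 bp, with type III-A spacers ranging 30-44 bp), prophage
regions of tens of kb annotated with phage-keyword gene products,
protospacers copied from named spacers with a configurable mismatch
count and explicit PAM/anti-tag flanks, planted mutations in the
repeats flanking chosen spacers, and tracrRNA-style anti-repeats near a
locus.  Every feature is recorded in a truth table mirroring the
analysis modules' output schemas, and generation is fully deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp
from .genome_io import GeneAnnotation, Genome, GenomicInterval
from .prophage import (
    GenomeSelfTargeting,
    ProphageRegion,
    TargetClassification,
    DEFAULT_KEYWORDS,
    DEFAULT_DISTANCE_BP,
)
from .repeat_mutation import positional_class

SUBTYPE_REPEAT_MODE = {"I-E": 29, "II-A": 36, "III-A": 36}
SUBTYPE_SPACER_LEN = {"I-E": 32, "II-A": 30, "III-A": (30, 44)}

_NEUTRAL_PRODUCTS = (
    "hypothetical protein",
    "DNA polymerase III subunit alpha",
    "30S ribosomal protein S4",
    "ABC transporter permease",
    "bile salt hydrolase",
    "glycosyltransferase family 2 protein",
)
_PHAGE_PRODUCTS = (
    "phage terminase large subunit",
    "phage portal protein",
    "phage major capsid protein",
    "tail fiber protein",
    "phage holin",
)


class ConfigurationError(ValueError):
    """A simulation config requests an infeasible (e.g. overlapping) layout."""


@dataclass
class PlantedRepeatMutation:
    """Substitutions to apply to one repeat unit, by consensus offset."""

    repeat_index: int
    offsets: tuple[int, ...]


@dataclass
class ArraySpec:
    subtype: str = "II-A"
    n_spacers: int = 7
    repeat_length: int | None = None  # default: the subtype's modal length
    spacer_length: int | tuple[int, int] | None = None
    position: int | None = None
    repeat_mutations: list[PlantedRepeatMutation] = field(default_factory=list)


@dataclass
class ProphageSpec:
    start: int
    length: int = 40_000
    completeness: str = "intact"


@dataclass
class SelfTargetSpec:
    """A protospacer copied from a planted spacer.

    ``position`` is the genomic start of the protospacer window; flank
    strings are given in the protospacer's 5'->3' frame and written
    adjacent to the site (reverse-complemented for minus-strand plants).
    """

    array_index: int
    spacer_index: int
    position: int
    strand: str = "+"
    n_mismatches: int = 0
    upstream_flank: str = ""
    downstream_flank: str = ""
    target_gene_product: str | None = None


@dataclass
class AntiRepeatSpec:
    """A reverse-complement copy of an array's consensus repeat.

    ``offset`` is the distance in bp from the array end (negative values
    place it before the array start)."""

    array_index: int
    offset: int = 500
    identity: float = 1.0
    strand: str = "+"


@dataclass
class SimulationConfig:
    seed: int = 0
    contig_length: int = 2_000_000
    gc_fraction: float = 0.35
    contig_id: str = "contig_1"
    genome_id: str = "synthetic_genome"
    arrays: list[ArraySpec] = field(default_factory=list)
    prophages: list[ProphageSpec] = field(default_factory=list)
    self_targets: list[SelfTargetSpec] = field(default_factory=list)
    anti_repeats: list[AntiRepeatSpec] = field(default_factory=list)
    n_background_genes: int = 40
    leader_at_fraction: float = 0.85
    leader_len: int = 150


@dataclass
class PlantedArray:
    spec: ArraySpec
    start: int
    end: int
    consensus: str
    repeat_starts: list[int]
    repeat_seqs: list[str]
    spacer_seqs: list[str]

    @property
    def repeat_length(self) -> int:
        return len(self.consensus)


@dataclass
class TruthTable:
    arrays: list[dict] = field(default_factory=list)
    self_targets: list[dict] = field(default_factory=list)
    prophages: list[dict] = field(default_factory=list)
    repeat_mutations: list[dict] = field(default_factory=list)
    anti_repeats: list[dict] = field(default_factory=list)
    n_genes: int = 0


@dataclass
class SyntheticGenome:
    genome: Genome
    prophage_regions: list[ProphageRegion]
    truth: TruthTable
    config: SimulationConfig
    planted_arrays: list[PlantedArray] = field(default_factory=list)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna_bytes(rng, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return _BASES[rng.choice(4, size=length, p=p)]


def _rand_seq(rng, length: int, gc: float = 0.5) -> str:
    return bytes(_random_dna_bytes(rng, length, gc)).decode()


def _mutate(rng, seq: str, offsets) -> str:
    out = list(seq)
    for o in offsets:
        out[o] = rng.choice([b for b in "ACGT" if b != out[o]])
    return "".join(out)


class _Claims:
    """Non-overlap bookkeeping for sequence-altering planted features."""

    def __init__(self):
        self.items: list[tuple[int, int, str]] = []

    def add(self, start: int, end: int, label: str, contig_length: int):
        if start < 0 or end > contig_length:
            raise ConfigurationError(
                f"feature {label} at [{start}, {end}) falls outside the contig"
            )
        for s, e, other in self.items:
            if start < e and s < end:
                raise ConfigurationError(
                    f"feature {label} at [{start}, {end}) overlaps {other} "
                    f"at [{s}, {e})"
                )
        self.items.append((start, end, label))


def _build_array(rng, spec: ArraySpec, used_spacers: set) -> PlantedArray:
    rep_len = spec.repeat_length or SUBTYPE_REPEAT_MODE.get(spec.subtype, 36)
    sp_spec = (
        spec.spacer_length
        if spec.spacer_length is not None
        else SUBTYPE_SPACER_LEN.get(spec.subtype, 30)
    )
    consensus = _rand_seq(rng, rep_len)
    spacer_seqs = []
    for j in range(spec.n_spacers):
        while True:  # rejection sampling keeps spacers unique
            if isinstance(sp_spec, tuple):
                length = int(rng.integers(sp_spec[0], sp_spec[1] + 1))
            else:
                length = int(sp_spec)
            # Cycle the spacer edge bases so no column adjacent to a
            # repeat is conserved across units: planted array boundaries
            # are then always identifiable, as real multi-unit arrays'
            # boundaries are.
            s = "ACGT"[j % 4] + _rand_seq(rng, length - 2) + "ACGT"[(j + 1) % 4]
            if s not in used_spacers and revcomp(s) not in used_spacers:
                used_spacers.add(s)
                spacer_seqs.append(s)
                break
    repeat_seqs = [consensus] * (spec.n_spacers + 1)
    for pm in spec.repeat_mutations:
        if not 0 <= pm.repeat_index < len(repeat_seqs):
            raise ConfigurationError(
                f"repeat_index {pm.repeat_index} out of range for array with "
                f"{len(repeat_seqs)} repeats"
            )
        repeat_seqs[pm.repeat_index] = _mutate(
            rng, repeat_seqs[pm.repeat_index], pm.offsets
        )
    return PlantedArray(spec, 0, 0, consensus, [], repeat_seqs, spacer_seqs)


def _expected_class(
    iv: GenomicInterval, prophage_ivs, gene_product: str | None
) -> str:
    dist = None
    for piv in prophage_ivs:
        if piv.contig_id != iv.contig_id:
            continue
        if iv.start < piv.end and piv.start < iv.end:
            return "within_prophage"
        gap = piv.start - iv.end if iv.end <= piv.start else iv.start - piv.end
        dist = gap if dist is None else min(dist, gap)
    if dist is not None and dist <= DEFAULT_DISTANCE_BP:
        return "near_prophage"
    if gene_product and any(k in gene_product.lower() for k in DEFAULT_KEYWORDS):
        return "phage_keyword_gene"
    return "other"


def synthesize_genome(config: SimulationConfig) -> SyntheticGenome:
    """Build the genome, annotations and truth table for one config."""
    rng = np.random.default_rng(config.seed)
    n = config.contig_length
    seq = _random_dna_bytes(rng, n, config.gc_fraction)
    claims = _Claims()
    truth = TruthTable()
    genes: list[GeneAnnotation] = []
    cid = config.contig_id

    def write(start: int, s: str):
        seq[start : start + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)

    # --- CRISPR arrays -------------------------------------------------
    used_spacers: set[str] = set()
    planted: list[PlantedArray] = []
    n_arr = len(config.arrays)
    for i, spec in enumerate(config.arrays):
        arr = _build_array(rng, spec, used_spacers)
        body = arr.repeat_seqs[0]
        for sp, rep in zip(arr.spacer_seqs, arr.repeat_seqs[1:]):
            body += sp + rep
        pos = (
            spec.position
            if spec.position is not None
            else int(round(n * (i + 1) / (n_arr + 1)))
        )
        leader_start = pos - config.leader_len
        claims.add(leader_start, pos + len(body), f"array[{i}]", n)
        # AT-rich leader so orientation is deterministic for planted arrays
        write(leader_start, _rand_seq(rng, config.leader_len,
                                      gc=1 - config.leader_at_fraction))
        write(pos, body)
        starts = []
        cursor = pos
        for rep, sp in zip(arr.repeat_seqs, arr.spacer_seqs + [None]):
            starts.append(cursor)
            cursor += len(rep) + (len(sp) if sp else 0)
        arr.start, arr.end = pos, pos + len(body)
        arr.repeat_starts = starts
        planted.append(arr)
        truth.arrays.append(
            {
                "array_index": i,
                "contig": cid,
                "start": arr.start,
                "end": arr.end,
                "n_repeats": len(arr.repeat_seqs),
                "n_spacers": len(arr.spacer_seqs),
                "consensus_repeat": arr.consensus,
                "repeat_length": arr.repeat_length,
                "subtype": spec.subtype,
                "spacer_lengths": [len(s) for s in arr.spacer_seqs],
            }
        )
        for pm in spec.repeat_mutations:
            truth.repeat_mutations.append(
                {
                    "array_index": i,
                    "repeat_index": pm.repeat_index,
                    "offsets": sorted(pm.offsets),
                    "classes": [
                        positional_class(o, arr.repeat_length)
                        for o in sorted(pm.offsets)
                    ],
                }
            )

    # --- prophage regions (coordinate features + phage-keyword genes) --
    prophage_regions: list[ProphageRegion] = []
    for j, p in enumerate(config.prophages):
        iv = GenomicInterval(cid, p.start, p.start + p.length)
        if iv.end > n:
            raise ConfigurationError(f"prophage[{j}] extends past the contig")
        prophage_regions.append(ProphageRegion(iv, p.completeness))
        truth.prophages.append(
            {"contig": cid, "start": iv.start, "end": iv.end,
             "completeness": p.completeness}
        )
        for k in range(3):
            gstart = p.start + 2000 + k * 3000
            genes.append(
                GeneAnnotation(cid, gstart, gstart + 1500, "+",
                               _PHAGE_PRODUCTS[(j + k) % len(_PHAGE_PRODUCTS)])
            )

    prophage_ivs = [r.interval for r in prophage_regions]

    # --- self-target protospacers --------------------------------------
    for j, st in enumerate(config.self_targets):
        if not 0 <= st.array_index < len(planted):
            raise ConfigurationError(f"self_target[{j}] names an unknown array")
        arr = planted[st.array_index]
        if not 0 <= st.spacer_index < len(arr.spacer_seqs):
            raise ConfigurationError(f"self_target[{j}] names an unknown spacer")
        spacer = arr.spacer_seqs[st.spacer_index]
        mm_offsets = sorted(
            int(x) for x in rng.choice(len(spacer), size=st.n_mismatches,
                                       replace=False)
        )
        proto = _mutate(rng, spacer, mm_offsets)
        up, down = st.upstream_flank.upper(), st.downstream_flank.upper()
        if st.strand == "+":
            block = up + proto + down
            block_start = st.position - len(up)
        else:
            block = revcomp(up + proto + down)
            block_start = st.position - len(down)
        claims.add(block_start, block_start + len(block), f"self_target[{j}]", n)
        write(block_start, block)
        iv = GenomicInterval(cid, st.position, st.position + len(spacer), st.strand)
        if st.target_gene_product is not None:
            gstart = max(0, st.position - 300)
            genes.append(
                GeneAnnotation(cid, gstart, min(n, st.position + len(spacer) + 300),
                               st.strand, st.target_gene_product)
            )
        truth.self_targets.append(
            {
                "array_index": st.array_index,
                "spacer_index": st.spacer_index,
                "spacer": spacer,
                "contig": cid,
                "start": iv.start,
                "end": iv.end,
                "strand": st.strand,
                "n_mismatches": st.n_mismatches,
                "mismatch_offsets": mm_offsets,
                "upstream_flank": up,
                "downstream_flank": down,
                "target_gene_product": st.target_gene_product or "",
                "expected_class": _expected_class(iv, prophage_ivs,
                                                  st.target_gene_product),
                "subtype": arr.spec.subtype,
            }
        )

    # --- anti-repeats ---------------------------------------------------
    for j, ar in enumerate(config.anti_repeats):
        arr = planted[ar.array_index]
        anti = revcomp(arr.consensus)
        n_sub = int(round((1 - ar.identity) * len(anti)))
        if n_sub:
            offs = rng.choice(len(anti), size=n_sub, replace=False)
            anti = _mutate(rng, anti, offs)
        if ar.strand == "-":
            anti = revcomp(anti)
        start = arr.end + ar.offset if ar.offset >= 0 else arr.start + ar.offset
        claims.add(start, start + len(anti), f"anti_repeat[{j}]", n)
        write(start, anti)
        truth.anti_repeats.append(
            {
                "array_index": ar.array_index,
                "contig": cid,
                "start": start,
                "end": start + len(anti),
                "strand": ar.strand,
                "identity": round(1 - n_sub / len(anti), 4),
            }
        )

    # --- neutral background genes --------------------------------------
    for _ in range(config.n_background_genes):
        for _attempt in range(100):
            gstart = int(rng.integers(0, n - 1000))
            iv = (gstart, gstart + 900)
            if not any(
                iv[0] < e and s < iv[1] for s, e, _ in claims.items
            ) and not any(
                iv[0] < g.end and g.start < iv[1] for g in genes
            ):
                genes.append(
                    GeneAnnotation(
                        cid, iv[0], iv[1], "+",
                        _NEUTRAL_PRODUCTS[int(rng.integers(len(_NEUTRAL_PRODUCTS)))],
                    )
                )
                break

    genes.sort(key=lambda g: g.start)
    truth.n_genes = len(genes)
    genome = Genome(config.genome_id, {cid: bytes(seq).decode()}, genes)
    return SyntheticGenome(genome, prophage_regions, truth, config, planted)


def study_fixture_config(seed: int = 0, contig_length: int = 2_000_000
                         ) -> SimulationConfig:
    """The standard planted-truth fixture used across the test suite.

    A low-GC contig (2 Mb by default; positions scale with
    ``contig_length``, minimum 400 kb) with five arrays covering all
    three subtypes — including a 30-spacer type I-E array and small 4-7
    spacer arrays — four prophage regions of tens of kb, six
    self-targets covering all four target classes (the near_prophage
    site sits exactly 9 kb from a region boundary at every scale),
    flanking-repeat mutation plants of 0/1/2 substitutions in the
    3'-terminal third, subtype-conventional PAM/anti-tag flank strings,
    and one exact anti-repeat near the type II-A locus.
    """
    n = contig_length
    if n < 400_000:
        raise ConfigurationError("study fixture needs a contig of >= 400 kb")
    at = lambda f: int(round(n * f))  # noqa: E731
    plen = min(40_000, max(15_000, int(round(0.018 * n))))
    arrays = [
        # I-E: 30 spacers; 2 mutations in each repeat flanking spacer 10,
        # placed in the 3' third of the 29-nt consensus (offsets 25, 27).
        ArraySpec("I-E", 30, position=at(0.10), repeat_mutations=[
            PlantedRepeatMutation(10, (25, 27)),
            PlantedRepeatMutation(11, (25, 27)),
        ]),
        # II-A: single upstream mutation flanking spacer 2 (3' third).
        ArraySpec("II-A", 7, position=at(0.30), repeat_mutations=[
            PlantedRepeatMutation(2, (33,)),
        ]),
        ArraySpec("III-A", 5, position=at(0.50)),
        ArraySpec("II-A", 4, position=at(0.70)),
        ArraySpec("III-A", 6, position=at(0.90)),
    ]
    prophages = [
        ProphageSpec(at(0.05), plen, "intact"),
        ProphageSpec(at(0.35), plen, "incomplete"),
        ProphageSpec(at(0.60), plen, "intact"),
        ProphageSpec(at(0.80), plen, "questionable"),
    ]
    self_targets = [
        # inside a prophage (type II-A spacer; II-A PAM written downstream)
        SelfTargetSpec(1, 2, at(0.05) + plen // 2, "+", 0,
                       downstream_flank="CTAAGT"),
        # exactly 9 kb past a prophage boundary -> near_prophage
        SelfTargetSpec(1, 3, at(0.35) + plen + 9_000, "-", 0),
        # phage-keyword gene far from any region (tape-measure emulation)
        SelfTargetSpec(2, 1, at(0.45), "+", 0, downstream_flank="CTTTTC",
                       target_gene_product=
                       "phage tail-length tape-measure protein"),
        # plain chromosomal gene -> other (I-E; AAC PAM upstream)
        SelfTargetSpec(0, 10, at(0.25), "+", 0, upstream_flank="AAC",
                       target_gene_product="epsG exopolysaccharide "
                       "biosynthesis glycosyltransferase"),
        # second within_prophage, minus strand
        SelfTargetSpec(4, 0, at(0.60) + plen // 3, "-", 0),
        # other, intergenic
        SelfTargetSpec(3, 1, at(0.95), "+", 0),
    ]
    anti_repeats = [AntiRepeatSpec(1, offset=500, identity=1.0)]
    return SimulationConfig(
        seed=seed,
        contig_length=contig_length,
        arrays=arrays,
        prophages=prophages,
        self_targets=self_targets,
        anti_repeats=anti_repeats,
    )


@dataclass
class CohortConfig:
    """Cohort-level planted truth for summary arithmetic.

    Defaults mirror a cohort of 40 system-bearing genomes of which 13
    carry self-targeting spacers, with 9 of 40 unique STS classed
    prophage-targeting — the planted analogue of the genus-wide survey
    rates (32.5% of system-bearing genomes with STS; 22.5%
    prophage-targeting).
    """

    n_system_bearing: int | None = None  # default: every genome
    n_genomes_with_sts: int = 13
    n_unique_sts: int = 40
    n_prophage_targeting: int = 9
    subtype_weights: dict = field(
        default_factory=lambda: {"II-A": 109, "III-A": 62, "I-E": 18}
    )


_PROPHAGE_CYCLE = ("within_prophage", "near_prophage", "phage_keyword_gene")


def sample_cohort(
    n_genomes: int, config: CohortConfig | None = None, seed: int = 0
) -> tuple[list[GenomeSelfTargeting], dict]:
    """Draw per-genome self-targeting records matching exact planted counts.

    Returns the records (consumable by
    :func:`crisprself.prophage.summarize_selftargeting`) plus the planted
    truth counts.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    n_sys = (
        n_genomes if config.n_system_bearing is None else config.n_system_bearing
    )
    if not 0 <= n_sys <= n_genomes:
        raise ValueError("n_system_bearing out of range")
    if config.n_genomes_with_sts > n_sys:
        raise ValueError("more STS-bearing genomes than system-bearing genomes")
    if 0 < config.n_unique_sts < config.n_genomes_with_sts:
        raise ValueError("fewer unique STS than genomes carrying them")
    if config.n_prophage_targeting > config.n_unique_sts:
        raise ValueError("more prophage-targeting STS than STS")

    system_flags = [True] * n_sys + [False] * (n_genomes - n_sys)
    rng.shuffle(system_flags)
    sys_idx = [i for i, f in enumerate(system_flags) if f]
    sts_genomes = list(rng.choice(sys_idx, size=config.n_genomes_with_sts,
                                  replace=False)) if config.n_genomes_with_sts else []
    # distribute STS counts: each chosen genome gets >= 1, extras at random
    counts = {int(g): 1 for g in sts_genomes}
    for _ in range(config.n_unique_sts - len(sts_genomes)):
        g = int(rng.choice(sts_genomes))
        counts[g] += 1

    classes = [_PROPHAGE_CYCLE[i % 3] for i in range(config.n_prophage_targeting)]
    classes += ["other"] * (config.n_unique_sts - config.n_prophage_targeting)
    rng.shuffle(classes)

    subs, weights = zip(*config.subtype_weights.items())
    w = np.array(weights, dtype=float)
    w /= w.sum()

    records = []
    ci = 0
    for i in range(n_genomes):
        gid = f"genome_{i + 1:03d}"
        cls_list = []
        for j in range(counts.get(i, 0)):
            cls = classes[ci]
            ci += 1
            subtype = str(rng.choice(subs, p=w))
            cls_list.append(
                TargetClassification(
                    array_id=f"{gid}_array1",
                    spacer_index=j,
                    spacer_sequence=_rand_seq(rng, 30),
                    subtype=subtype,
                    target_class=cls,
                    distance_to_nearest_region=(
                        0 if cls == "within_prophage"
                        else 5000 if cls == "near_prophage" else None
                    ),
                    matched_keyword="phage" if cls == "phage_keyword_gene" else None,
                )
            )
        records.append(GenomeSelfTargeting(gid, system_flags[i], cls_list))
    truth = {
        "n_genomes": n_genomes,
        "n_system_bearing": n_sys,
        "n_genomes_with_sts": config.n_genomes_with_sts,
        "n_unique_sts": config.n_unique_sts,
        "n_prophage_targeting": config.n_prophage_targeting,
    }
    return records, truth


def write_fixture(sg: SyntheticGenome, outdir) -> None:
    """Write FASTA + GFF3 + BED + truth TSVs for one synthetic genome."""
    import json
    import os

    import pandas as pd

    from .genome_io import write_fasta, write_genes_gff3, write_regions_bed

    os.makedirs(outdir, exist_ok=True)
    write_fasta(sg.genome, os.path.join(outdir, "genome.fasta"))
    write_genes_gff3(sg.genome, os.path.join(outdir, "genes.gff3"))
    write_regions_bed(sg.prophage_regions, os.path.join(outdir, "prophages.bed"))
    for name in ("arrays", "self_targets", "prophages", "repeat_mutations",
                 "anti_repeats"):
        rows = getattr(sg.truth, name)
        pd.DataFrame(rows).to_csv(
            os.path.join(outdir, f"truth_{name}.tsv"), sep="\t", index=False
        )
    with open(os.path.join(outdir, "truth_meta.json"), "w") as fh:
        json.dump({"seed": sg.config.seed, "n_genes": sg.truth.n_genes}, fh,
                  indent=2)
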