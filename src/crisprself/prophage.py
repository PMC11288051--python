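"""Prophage-target classification of self-targeting spacers.

A self-target site counts as prophage-targeting when it falls inside a
predicted prophage region, within a distance window of one (10 kb by
default, inclusive), or — as a fallback — when the targeted gene's
product contains a phage-associated keyword.  Precedence is
within > near > keyword > other; each hit receives exactly one class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import GenomicInterval

DEFAULT_KEYWORDS = ("phage", "tail", "terminase")
DEFAULT_DISTANCE_BP = 10_000

PROPHAGE_CLASSES = frozenset(
    {"within_prophage", "near_prophage", "phage_keyword_gene"}
)


@dataclass(frozen=True)
class ProphageRegion:
    """A contig interval with a free-text completeness label.

    Completeness ("intact"/"incomplete"/...) is carried through verbatim
    for reporting; classification is positional and never branches on it.
    """

    interval: GenomicInterval
    completeness: str = "unknown"


@dataclass(frozen=True)
class TargetClassification:
    array_id: str
    spacer_index: int
    spacer_sequence: str
    subtype: str | None
    target_class: str  # within_prophage | near_prophage | phage_keyword_gene | other
    distance_to_nearest_region: int | None = None
    matched_keyword: str | None = None

    @property
    def is_prophage_targeting(self) -> bool:
        return self.target_class in PROPHAGE_CLASSES


def _gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Bases between two intervals on one contig; 0 when they overlap."""
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if a.end <= b.start else a.start - b.end


def classify_target(
    hit,
    regions,
    keywords=DEFAULT_KEYWORDS,
    distance_bp: int = DEFAULT_DISTANCE_BP,
) -> TargetClassification:
    """Classify one self-target hit (within > near > keyword > other).

    ``distance_to_nearest_region`` is reported whenever a region exists on
    the hit's contig (0 for an overlap).  Keyword matching is
    case-insensitive substring search on the targeted gene's product.
    """
    if distance_bp < 0:
        raise ValueError("distance_bp must be >= 0")
    same_contig = [
        r for r in regions if r.interval.contig_id == hit.target.contig_id
    ]
    distance = None
    if same_contig:
        distance = min(_gap(hit.target, r.interval) for r in same_contig)

    def make(cls, keyword=None):
        return TargetClassification(
            hit.array_id, hit.spacer_index, hit.spacer_sequence, hit.subtype,
            cls, distance, keyword,
        )

    if distance == 0:
        return make("within_prophage")
    if distance is not None and distance <= distance_bp:
        return make("near_prophage")
    if hit.target_gene is not None:
        product = hit.target_gene.product.lower()
        for kw in keywords:
            if kw.lower() in product:
                return make("phage_keyword_gene", kw)
    return make("other")


@dataclass
class GenomeSelfTargeting:
    """One genome's self-targeting record for cohort summaries.

    ``classifications`` holds one entry per *unique* self-targeting spacer
    (best class by precedence when a spacer has several sites).
    """

    genome_id: str
    has_complete_system: bool
    classifications: list[TargetClassification] = field(default_factory=list)


_CLASS_PRECEDENCE = {
    "within_prophage": 0, "near_prophage": 1, "phage_keyword_gene": 2, "other": 3,
}


def best_class_per_spacer(classifications) -> list[TargetClassification]:
    """Collapse site-level classifications to one per unique spacer."""
    best: dict[str, TargetClassification] = {}
    for c in classifications:
        key = c.spacer_sequence
        if key not in best or (
            _CLASS_PRECEDENCE[c.target_class]
            < _CLASS_PRECEDENCE[best[key].target_class]
        ):
            best[key] = c
    return list(best.values())


@dataclass
class SelfTargetingSummary:
    n_genomes: int
    n_system_bearing: int
    n_genomes_with_sts: int
    n_unique_sts: int
    n_prophage_targeting: int
    pct_genomes_with_sts: float | None  # over system-bearing genomes
    pct_prophage_targeting: float | None  # over unique STS
    pct_other: float | None
    per_subtype: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_genomes": self.n_genomes,
            "n_system_bearing": self.n_system_bearing,
            "n_genomes_with_sts": self.n_genomes_with_sts,
            "n_unique_sts": self.n_unique_sts,
            "n_prophage_targeting": self.n_prophage_targeting,
            "pct_genomes_with_sts": self.pct_genomes_with_sts,
            "pct_prophage_targeting": self.pct_prophage_targeting,
            "pct_other": self.pct_other,
            "per_subtype": self.per_subtype,
        }


def _pct(num: int, den: int) -> float | None:
    """Percentage to one decimal; None (undefined) on a zero denominator."""
    if den == 0:
        return None
    return round(100.0 * num / den, 1)


def summarize_selftargeting(per_genome_results) -> SelfTargetingSummary:
    """Aggregate per-genome STS records into cohort-level rates.

    Genome-level rates are computed over genomes flagged as carrying a
    complete CRISPR-Cas system; target-class rates over unique STS.
    """
    results = list(per_genome_results)
    system = [g for g in results if g.has_complete_system]
    with_sts = [g for g in system if g.classifications]
    all_cls = [c for g in system for c in g.classifications]
    n_prophage = sum(1 for c in all_cls if c.is_prophage_targeting)

    per_subtype: dict[str, dict[str, int]] = {}
    for c in all_cls:
        sub = c.subtype or "unknown"
        d = per_subtype.setdefault(sub, {"n_unique_sts": 0, "n_prophage_targeting": 0})
        d["n_unique_sts"] += 1
        d["n_prophage_targeting"] += int(c.is_prophage_targeting)

    if len(system) == 0:
        # no system-bearing genomes: every rate is undefined, never zero
        pct_with, pct_pro, pct_other = None, None, None
    elif not all_cls:
        # systems but no STS at all: rates are genuinely zero
        pct_with, pct_pro, pct_other = _pct(0, len(system)), 0.0, 0.0
    else:
        pct_with = _pct(len(with_sts), len(system))
        pct_pro = _pct(n_prophage, len(all_cls))
        pct_other = _pct(len(all_cls) - n_prophage, len(all_cls))
    return SelfTargetingSummary(
        n_genomes=len(results),
        n_system_bearing=len(system),
        n_genomes_with_sts=len(with_sts),
        n_unique_sts=len(all_cls),
        n_prophage_targeting=n_prophage,
        pct_genomes_with_sts=pct_with,
        pct_prophage_targeting=pct_pro,
        pct_other=pct_other,
        per_subtype=per_subtype,
    )


def sankey_edges(per_genome_results) -> list[tuple[str, str, int]]:
    """(source, target, count) edge list for a Sankey-style flow diagram."""
    results = list(per_genome_results)
    system = [g for g in results if g.has_complete_system]
    edges: dict[tuple[str, str], int] = {}
    for g in system:
        key = ("complete_system", "has_sts" if g.classifications else "no_sts")
        edges[key] = edges.get(key, 0) + 1
        for c in g.classifications:
            cls = "prophage" if c.is_prophage_targeting else "other"
            key2 = ("has_sts", cls)
            edges[key2] = edges.get(key2, 0) + 1
    return [(s, t, n) for (s, t), n in sorted(edges.items())]


def write_classifications_tsv(classifications, path) -> None:
    import pandas as pd

    rows = [
        {
            "array_id": c.array_id,
            "spacer_index": c.spacer_index,
            "subtype": c.subtype or "",
            "spacer": c.spacer_sequence,
            "target_class": c.target_class,
            "distance_to_nearest_region": (
                "" if c.distance_to_nearest_region is None
                else c.distance_to_nearest_region
            ),
            "matched_keyword": c.matched_keyword or "",
        }
        for c in classifications
    ]
    pd.DataFrame(
        rows,
        columns=["array_id", "spacer_index", "subtype", "spacer", "target_class",
                 "distance_to_nearest_region", "matched_keyword"],
    ).to_csv(path, sep="\t", index=False)
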