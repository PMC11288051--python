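"""End-to-end pipeline driver.

Stages run in a fixed order: array detection -> self-target scan ->
flanking-repeat mutation calling -> flank/PFM aggregation -> prophage
classification -> cohort summary.  Every stage logs the number of
records surviving its filters, and a manifest records the configuration
and input checksums so a rerun with identical inputs is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

from . import __version__
from .arrays import (
    DetectionParams,
    detect_arrays,
    write_arrays_gff3,
    write_arrays_tsv,
)
from .genome_io import load_genome, load_regions
from .pam import build_pfm, write_pfm_tsv
from .prophage import (
    DEFAULT_DISTANCE_BP,
    DEFAULT_KEYWORDS,
    GenomeSelfTargeting,
    best_class_per_spacer,
    classify_target,
    summarize_selftargeting,
    write_classifications_tsv,
)
from .repeat_mutation import call_repeat_mutations, write_reports_tsv
from .selftarget import find_self_targets, write_hits_bed, write_hits_tsv

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str
    outdir: str
    gff: str | None = None
    regions: str | None = None
    regions_format: str = "BED"
    subtype_map: dict = field(default_factory=dict)  # ordinal -> label
    detection: DetectionParams = field(default_factory=DetectionParams)
    max_mismatches: int = 0
    upstream_len: int = 10
    downstream_len: int = 10
    keywords: tuple = DEFAULT_KEYWORDS
    distance_bp: int = DEFAULT_DISTANCE_BP
    has_complete_system: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be >= 0")
        if self.upstream_len < 0 or self.downstream_len < 0:
            raise ValueError("flank lengths must be >= 0")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the full artifact set to ``outdir``."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)  # noqa: E731

    genome = load_genome(config.fasta, config.gff)
    regions = (
        load_regions(config.regions, config.regions_format)
        if config.regions
        else []
    )

    arrays = detect_arrays(genome, config.detection, subtypes=config.subtype_map)
    log.info("detect: %d arrays", len(arrays))
    write_arrays_tsv(arrays, out("arrays.tsv"))
    write_arrays_gff3(arrays, out("arrays.gff3"))

    hits = find_self_targets(
        genome, arrays, config.max_mismatches,
        config.upstream_len, config.downstream_len,
    )
    log.info("selftarget: %d hits outside arrays", len(hits))
    write_hits_tsv(hits, out("self_targets.tsv"))
    write_hits_bed(hits, out("self_targets.bed"))

    by_id = {a.array_id: a for a in arrays}
    reports = [
        call_repeat_mutations(by_id[h.array_id], h.spacer_index) for h in hits
    ]
    write_reports_tsv(reports, out("repeat_mutations.tsv"))

    for side in ("upstream", "downstream"):
        width = config.upstream_len if side == "upstream" else config.downstream_len
        flanks = [
            getattr(h, f"{side}_flank") for h in hits
            if len(getattr(h, f"{side}_flank")) == width
        ]
        if flanks:
            write_pfm_tsv(build_pfm(flanks), out(f"pfm_{side}.tsv"))

    site_cls = [
        classify_target(h, regions, config.keywords, config.distance_bp)
        for h in hits
    ]
    unique_cls = best_class_per_spacer(site_cls)
    log.info("classify: %d sites, %d unique spacers", len(site_cls),
             len(unique_cls))
    write_classifications_tsv(site_cls, out("classifications.tsv"))

    record = GenomeSelfTargeting(
        genome.genome_id, config.has_complete_system, unique_cls
    )
    summary = summarize_selftargeting([record])
    with open(out("summary.json"), "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2)

    manifest = {
        "version": __version__,
        "config": {
            k: (asdict(v) if isinstance(v, DetectionParams) else v)
            for k, v in asdict(config).items()
        },
        "inputs": {
            os.path.basename(p): _sha256(p)
            for p in (config.fasta, config.gff, config.regions)
            if p
        },
        "counts": {
            "arrays": len(arrays),
            "self_target_sites": len(hits),
            "unique_self_targeting_spacers": len(unique_cls),
        },
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "genome": genome,
        "arrays": arrays,
        "hits": hits,
        "reports": reports,
        "site_classifications": site_cls,
        "unique_classifications": unique_cls,
        "summary": summary,
        "manifest": manifest,
    }
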