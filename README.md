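# crisprself

Detection and characterization of CRISPR-Cas self-targeting in bacterial
genomes: array detection, self-targeting spacer (STS) discovery, flanking
repeat mutation calling, PAM / type III anti-tag analysis, prophage-aware
target classification, tracrRNA anti-repeat search with duplex folding, and
a fully seeded synthetic-genome generator for end-to-end validation.

## Scientific background

CRISPR-Cas systems store fragments of past invaders as *spacers* between
near-identical *direct repeats*. Occasionally a spacer matches the host's
own genome — a **self-targeting spacer**. Because a perfect self-match
should be lethal, persistent self-targeting implies an escape route, and
the flanking sequence of the protospacer carries the evidence:

- **Flanking repeat mutations.** Mutations in the repeats on either side of
  the spacer (especially toward the 3' end, which seeds crRNA processing)
  can inactivate that spacer's expression or processing.
- **PAM loss.** Type I and II interference requires a protospacer-adjacent
  motif; a protospacer without the consensus PAM is tolerated.
- **Type III anti-tag pairing.** Type III systems are *activated* when the
  protospacer flank does **not** pair with the crRNA 5' tag; extensive
  complementarity between flank and tag (an "anti-tag") suppresses
  interference. `crisprself` scores the canonical worked case — a repeat
  tag `5'-GAAAAC-3'` beside the hexamer `5'-CUUUUC-3'` pairs at 5 of 6
  positions, signalling suppression.
- **Prophage targeting.** Many self-targets fall within or near integrated
  prophages, suggesting the spacer was acquired against the phage and the
  "self" match is a remnant of that conflict.

The package classifies every self-target site by precedence
`within_prophage > near_prophage (≤ 10 kb) > phage_keyword_gene > other`,
summarizes cohorts of genomes (percentage of system-bearing genomes with
at least one STS; prophage- vs other-targeting fractions among unique STS),
and searches for tracrRNA anti-repeats near type II loci, scoring the
crRNA:tracrRNA duplex by base-pair-maximization folding.

## Model and algorithms

| Step | Method |
| --- | --- |
| Array detection | Seed-and-extend: exact 8-mer seed pairs at repeat spacing, chained into runs of ≥ 3 repeats (repeat 19–40 bp, spacer 18–60 bp, identity ≥ 0.8), boundary refinement by cross-unit column conservation |
| Orientation | Degenerate terminal repeat + AT-rich leader flank; manual override supported |
| STS scan | Exhaustive Hamming scan of every unique spacer against both strands (substitutions only, default 0 mismatches; `N` never matches) |
| Repeat mutations | Per-column calls against the array consensus, positional class by thirds (5'-end / middle / 3'-end); 5'-anchored comparison with tail-indel annotation for length-discordant repeats |
| PAM / logo math | Position frequency matrix, per-column information content `2 − H` bits, optional small-sample correction |
| Anti-tag | Watson-Crick + G:U pairing of the protospacer flank against the repeat-derived crRNA tag |
| Folding | Nussinov base-pair maximization (WC + G:U, minimum loop 3) with deterministic traceback; co-folding via an unpairable linker, reporting inter-molecular pairs |
| Statistics | Per-subtype repeat/spacer length histograms, modes (ties → smaller), quartiles by linear interpolation |

All coordinates are 0-based half-open internally; GFF3 output is 1-based
closed, BED stays 0-based half-open.

## Worked example

Generate a seeded 400 kb synthetic genome with five planted arrays, four
prophages and six planted self-targets, then analyse it:

```sh
$ crisprself simulate --seed 7 --contig-length 400000 -o fixture
fixture with 5 arrays, 6 self-targets -> fixture/

$ crisprself detect fixture/genome.fasta -o arrays
5 arrays -> arrays.tsv / arrays.gff3

$ head -3 arrays.tsv | cut -f1-8
array_id	contig	start	end	n_repeats	n_spacers	consensus_repeat	orientation
contig_1_array1	contig_1	40000	41859	31	30	TCAACCTACCTTACTATTATGTATCGGTG	+
contig_1_array2	contig_1	120000	120498	8	7	AGTTGAGAGGGGTCCAACATTTTCTCCGGTGTAAGC	+

$ crisprself selftarget fixture/genome.fasta --gff fixture/genes.gff3 -o st
6 self-target sites -> st.tsv
```

Classification against prophage coordinates, from Python:

```python
import crisprself as cs

g = cs.load_genome("fixture/genome.fasta", gff_path="fixture/genes.gff3")
arrays = cs.detect_arrays(g)
hits = cs.find_self_targets(g, arrays)
regions = cs.load_regions("fixture/prophages.bed", "bed")
for h in hits:
    c = cs.classify_target(h, regions)
    print(f"{h.array_id}.sp{h.spacer_index}  {h.target.start:>7}{h.target.strand}  {c.target_class}")
```

prints

```text
contig_1_array1.sp10   100000+  other
contig_1_array2.sp2    27500+  within_prophage
contig_1_array2.sp3   164000-  near_prophage
contig_1_array3.sp1   180000+  phage_keyword_gene
contig_1_array4.sp1   380000+  other
contig_1_array5.sp0   245000-  within_prophage
```

RNA folding from the command line:

```sh
$ crisprself fold GGGCGACUUCAAGCGUCCC
GGGCGACUUCAAGCGUCCC
(((((.((...)))).)))
# 7 pairs
```

The full pipeline (`crisprself run config.yaml`) takes a YAML config with
`fasta`, optional `gff` / `regions` / `subtype_map`, and an `outdir`; it
writes arrays, self-targets, repeat mutations, flank logos, classifications,
a JSON summary and a manifest with input checksums.

## Reproduction

Every analysis is deterministic given its seed. To recompute the headline
quantities (planted-truth recovery on a 2 Mb genome, fold-vs-enumeration
agreement, cohort rates, worked numerical examples):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This synthesizes all data at runtime and writes a JSON report; with any
seed, planted arrays, self-targets, target classes and repeat mutations are
recovered at 100% with zero false positives, and the default cohort
reproduces 32.5% of system-bearing genomes carrying an STS with a
22.5% / 77.5% prophage:other split.

See `docs/methods.md` for the underlying model, parameter choices and
limitations.
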